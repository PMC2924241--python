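"""Network construction and (de)serialization.

A network is a table of directed synapses over a population of excitatory
regular-spiking and inhibitory fast-spiking neurons.  Every synapse carries an
integer axonal conduction delay (ms); excitatory delays are uniform in a
configured range (default [1, 20] ms), inhibitory delays are fixed (1 ms).
Only excitatory->excitatory synapses are plastic; their weights live in
[0, w_max] mV at all times.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .neurons import RS, FS, NeuronParams

_FORMAT_VERSION = 1


class ConfigurationError(ValueError):
    """Raised for invalid network or protocol configuration."""


@dataclass(frozen=True)
class NetworkConfig:
    """Structural and drive parameters of the default network.

    ``mini_rate`` is the per-neuron rate (events/s) of stochastic miniature
    synaptic potentials; ``mini_amplitude`` (mV) is calibrated so the
    background excitatory multiunit rate is ~0.3 Hz (a single mini is
    suprathreshold from rest, so each mini elicits about one spike).
    """

    n_neurons: int = 1000
    excitatory_fraction: float = 0.8
    connection_prob: float = 0.1
    exc_delay_range: tuple[int, int] = (1, 20)
    inh_delay: int = 1
    w_max: float = 8.0
    w_inh: float = -30.0            # fixed I->E/I->I weight (fast somatic clamp)
    w_exc_inh: float = 8.0          # fixed (non-plastic) E->I weight
    mini_rate: float = 7.2
    mini_amplitude: float = 12.0
    init_weight_mode: str = "mature"  # "mature" (bimodal) or "growth" (small random)
    # The mature preset emulates an STDP-evolved network: a minority of E->E
    # synapses sit at the ceiling w_max, the rest near the floor.
    mature_strong_fraction: float = 0.25
    mature_weak_weight: float = 1.0
    rs: NeuronParams = RS
    fs: NeuronParams = FS

    def validate(self) -> None:
        if self.n_neurons < 2:
            raise ConfigurationError("n_neurons must be >= 2")
        if not (0.0 <= self.excitatory_fraction <= 1.0):
            raise ConfigurationError("excitatory_fraction must be in [0, 1]")
        if not (0.0 < self.connection_prob <= 1.0):
            raise ConfigurationError("connection_prob must be in (0, 1]")
        lo, hi = self.exc_delay_range
        if not (1 <= lo <= hi):
            raise ConfigurationError("exc_delay_range must be positive integers lo<=hi")
        if self.inh_delay < 1:
            raise ConfigurationError("inh_delay must be a positive integer")
        if self.w_max <= 0:
            raise ConfigurationError("w_max must be positive")
        if self.init_weight_mode not in ("mature", "growth"):
            raise ConfigurationError("init_weight_mode must be 'mature' or 'growth'")
        if self.mini_rate < 0:
            raise ConfigurationError("mini_rate must be >= 0")


@dataclass
class Network:
    """Neuron population plus flat synapse arrays.

    Synapses are stored as parallel arrays (pre, post, delay, weight,
    plastic).  ``sd`` is the associative short-term scaling state (decays to
    0); it travels with the network so that serialization round-trips the
    full plasticity state.
    """

    config: NetworkConfig
    seed: int
    exc: np.ndarray          # (n,) bool, True for excitatory neurons
    a: np.ndarray            # (n,) per-neuron model parameters
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray
    pre: np.ndarray          # (m,) int32 presynaptic neuron
    post: np.ndarray         # (m,) int32 postsynaptic neuron
    delay: np.ndarray        # (m,) int16 conduction delay, ms
    weight: np.ndarray       # (m,) float64 synaptic weight, mV
    plastic: np.ndarray      # (m,) bool, True only for E->E
    sd: np.ndarray = None    # (m,) float64 short-term scaling state

    _eff_indptr: np.ndarray = field(default=None, repr=False)
    _eff_order: np.ndarray = field(default=None, repr=False)
    _aff_indptr: np.ndarray = field(default=None, repr=False)
    _aff_order: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.sd is None:
            self.sd = np.zeros(len(self.pre))

    # -- derived quantities -------------------------------------------------

    @property
    def n_neurons(self) -> int:
        return len(self.exc)

    @property
    def n_synapses(self) -> int:
        return len(self.pre)

    @property
    def max_delay(self) -> int:
        return int(self.delay.max()) if len(self.delay) else 1

    def excitatory_ids(self) -> np.ndarray:
        return np.flatnonzero(self.exc)

    def _build_index(self) -> None:
        n, m = self.n_neurons, self.n_synapses
        self._eff_order = np.argsort(self.pre, kind="stable").astype(np.int64)
        self._eff_indptr = np.zeros(n + 1, dtype=np.int64)
        np.cumsum(np.bincount(self.pre, minlength=n), out=self._eff_indptr[1:])
        self._aff_order = np.argsort(self.post, kind="stable").astype(np.int64)
        self._aff_indptr = np.zeros(n + 1, dtype=np.int64)
        np.cumsum(np.bincount(self.post, minlength=n), out=self._aff_indptr[1:])

    def efferent_synapses(self, neuron: int) -> np.ndarray:
        """Indices of synapses whose presynaptic neuron is ``neuron``."""
        if self._eff_indptr is None:
            self._build_index()
        return self._eff_order[self._eff_indptr[neuron]:self._eff_indptr[neuron + 1]]

    def afferent_synapses(self, neuron: int) -> np.ndarray:
        """Indices of synapses targeting ``neuron``."""
        if self._aff_indptr is None:
            self._build_index()
        return self._aff_order[self._aff_indptr[neuron]:self._aff_indptr[neuron + 1]]

    def add_synapses(self, pre, post, delay, weight, plastic) -> None:
        """Append synapses (e.g. engineered group wiring) and rebuild indices."""
        self.pre = np.concatenate([self.pre, np.asarray(pre, dtype=np.int32)])
        self.post = np.concatenate([self.post, np.asarray(post, dtype=np.int32)])
        self.delay = np.concatenate([self.delay, np.asarray(delay, dtype=np.int16)])
        self.weight = np.concatenate([self.weight, np.asarray(weight, dtype=np.float64)])
        self.plastic = np.concatenate([self.plastic, np.asarray(plastic, dtype=bool)])
        self.sd = np.concatenate([self.sd, np.zeros(len(np.atleast_1d(pre)))])
        self._eff_indptr = self._eff_order = None
        self._aff_indptr = self._aff_order = None

    def copy(self) -> "Network":
        return Network(
            config=self.config, seed=self.seed, exc=self.exc.copy(),
            a=self.a, b=self.b, c=self.c, d=self.d,
            pre=self.pre.copy(), post=self.post.copy(),
            delay=self.delay.copy(), weight=self.weight.copy(),
            plastic=self.plastic.copy(), sd=self.sd.copy(),
        )


def build_network(config: NetworkConfig, seed: int) -> Network:
    """Build a random delayed network; deterministic given ``seed``.

    Each ordered neuron pair (i, j), i != j, is connected independently with
    probability ``connection_prob``.  The first ``excitatory_fraction`` of
    neuron ids are excitatory (RS), the rest inhibitory (FS).
    """
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n_neurons
    n_exc = int(round(n * config.excitatory_fraction))
    exc = np.zeros(n, dtype=bool)
    exc[:n_exc] = True

    a = np.where(exc, config.rs.a, config.fs.a).astype(np.float64)
    b = np.where(exc, config.rs.b, config.fs.b).astype(np.float64)
    c = np.where(exc, config.rs.c, config.fs.c).astype(np.float64)
    d = np.where(exc, config.rs.d, config.fs.d).astype(np.float64)

    # connection mask over ordered pairs, no self-synapses
    mask = rng.random((n, n)) < config.connection_prob
    np.fill_diagonal(mask, False)
    pre, post = np.nonzero(mask)
    pre = pre.astype(np.int32)
    post = post.astype(np.int32)

    is_exc_pre = exc[pre]
    lo, hi = config.exc_delay_range
    delay = np.where(
        is_exc_pre,
        rng.integers(lo, hi + 1, size=len(pre)),
        config.inh_delay,
    ).astype(np.int16)

    if config.init_weight_mode == "mature":
        strong = rng.random(len(pre)) < config.mature_strong_fraction
        w_exc = np.where(strong, config.w_max, config.mature_weak_weight)
    else:  # growth: weak random initial weights
        w_exc = rng.uniform(0.0, config.w_max / 8.0, size=len(pre))
    plastic = is_exc_pre & exc[post]
    weight = np.where(is_exc_pre, w_exc, config.w_inh)
    weight[is_exc_pre & ~exc[post]] = config.w_exc_inh

    return Network(
        config=config, seed=seed, exc=exc, a=a, b=b, c=c, d=d,
        pre=pre, post=post, delay=delay, weight=weight, plastic=plastic,
    )


# -- serialization ----------------------------------------------------------

def _config_to_dict(config: NetworkConfig) -> dict:
    d = asdict(config)
    d["rs"] = asdict(config.rs)
    d["fs"] = asdict(config.fs)
    d["exc_delay_range"] = list(config.exc_delay_range)
    return d


def _config_from_dict(d: dict) -> NetworkConfig:
    d = dict(d)
    d["rs"] = NeuronParams(**d["rs"])
    d["fs"] = NeuronParams(**d["fs"])
    d["exc_delay_range"] = tuple(d["exc_delay_range"])
    return NetworkConfig(**d)


def save_network(network: Network, path) -> None:
    """Write a network container: JSON metadata header + flat arrays (npz)."""
    meta = {
        "format": "polywm-network",
        "version": _FORMAT_VERSION,
        "seed": int(network.seed),
        "config": _config_to_dict(network.config),
    }
    np.savez(
        path,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        exc=network.exc, pre=network.pre, post=network.post,
        delay=network.delay, weight=network.weight,
        plastic=network.plastic, sd=network.sd,
    )


def load_network(path) -> Network:
    """Load a network saved by :func:`save_network`; lossless round trip."""
    with np.load(path) as data:
        try:
            meta = json.loads(bytes(data["meta"].tobytes()).decode())
        except Exception as exc:
            raise IOError(f"not a polywm network file: {path}") from exc
        if meta.get("format") != "polywm-network":
            raise IOError(f"not a polywm network file: {path}")
        if meta.get("version") != _FORMAT_VERSION:
            raise IOError(
                f"unsupported network format version {meta.get('version')} "
                f"(expected {_FORMAT_VERSION})"
            )
        config = _config_from_dict(meta["config"])
        exc = data["exc"].astype(bool)
        a = np.where(exc, config.rs.a, config.fs.a)
        b = np.where(exc, config.rs.b, config.fs.b)
        c = np.where(exc, config.rs.c, config.fs.c)
        d = np.where(exc, config.rs.d, config.fs.d)
        return Network(
            config=config, seed=int(meta["seed"]), exc=exc,
            a=a, b=b, c=c, d=d,
            pre=data["pre"].astype(np.int32), post=data["post"].astype(np.int32),
            delay=data["delay"].astype(np.int16),
            weight=data["weight"].astype(np.float64),
            plastic=data["plastic"].astype(bool),
            sd=data["sd"].astype(np.float64),
        )
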