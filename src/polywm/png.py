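"""Polychronous neuronal groups: templates, discovery, insertion, detection.

A PNG is defined by synapses and matched conduction delays, not by its
neurons, so neurons can belong to many groups.  A :class:`PNGTemplate` is the
group's stereotyped firing pattern — ordered (neuron, relative time) events —
plus the anchor subset whose correctly timed firing ignites the cascade.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .network import Network
from .plasticity import PlasticityConfig, LongTermConfig, ShortTermConfig
from .raster import SpikeRaster
from .simulator import CUE_AMPLITUDE, StimulusEvent, simulate


@dataclass
class PNGTemplate:
    """Stereotyped polychronous pattern of one group."""
    id: int
    neurons: np.ndarray   # (k,) int, one entry per event
    times: np.ndarray     # (k,) float ms, relative, min == 0
    anchors: list[tuple[int, float]]  # (neuron, relative time) initiating subset

    def __post_init__(self):
        self.neurons = np.asarray(self.neurons, dtype=np.int32)
        self.times = np.asarray(self.times, dtype=np.float64)
        order = np.argsort(self.times, kind="stable")
        self.neurons = self.neurons[order]
        self.times = self.times[order]
        if len(self.times):
            self.times = self.times - self.times.min()

    @property
    def size(self) -> int:
        """Number of distinct member neurons."""
        return len(np.unique(self.neurons))

    @property
    def duration(self) -> float:
        return float(self.times.max() - self.times.min()) if len(self.times) else 0.0

    @property
    def member_set(self) -> set[int]:
        return set(int(x) for x in np.unique(self.neurons))

    def early_neurons(self, fraction: float = 0.2) -> np.ndarray:
        """The first ``fraction`` of member neurons by relative time (>= 1)."""
        k = max(1, int(np.ceil(fraction * len(self.neurons))))
        return np.unique(self.neurons[:k])


@dataclass
class ActivationEvent:
    """One detected (partial) reactivation of a template."""
    template_id: int
    onset: float            # ms, raster time aligned to template time 0
    fraction: float         # matched members / template size
    matched: set[int] = field(default_factory=set)


@dataclass
class PNGStats:
    count: int
    sizes: np.ndarray
    durations: np.ndarray
    pairwise_shared: np.ndarray       # shared-neuron count per template pair
    membership_counts: np.ndarray     # groups per neuron
    activation_counts: np.ndarray | None = None     # per template, real raster
    surrogate_counts: np.ndarray | None = None      # per template, inverted time


# -- noise-free cascade -----------------------------------------------------

_FROZEN = PlasticityConfig(
    longterm=LongTermConfig(enabled=False),
    shortterm=ShortTermConfig(enabled=False),
)


def simulate_template(
    network: Network,
    anchors: list[tuple[int, float]],
    min_size: int | None = None,
    max_duration: int = 1000,
) -> PNGTemplate | None:
    """Deterministic, noise-free, plasticity-frozen cascade from anchor firings.

    Anchor neurons are forced to fire at the given times; downstream neurons
    fire when converging arrivals drive them past threshold.  Returns the full
    realized (neuron, relative time) pattern, or None if the cascade involves
    fewer than ``min_size`` distinct neurons (default: anchors + 1).
    """
    if min_size is None:
        min_size = len(anchors) + 1
    stim = [StimulusEvent(time=int(round(t)), neuron=int(j), amplitude=CUE_AMPLITUDE)
            for j, t in anchors]
    res = simulate(
        network, max_duration, stimuli=stim, plasticity=_FROZEN,
        mini_rate=0.0, seed=0, stop_when_silent=True,
        silence_margin=network.max_delay + 5,
    )
    r = res.raster
    if len(r) == 0:
        return None
    t0 = float(r.times.min())
    anchor_t0 = min(t for _, t in anchors)
    template = PNGTemplate(
        id=-1, neurons=r.neurons, times=r.times - t0,
        anchors=[(int(j), float(t) - anchor_t0) for j, t in anchors],
    )
    if template.size < min_size:
        return None
    return template


# -- engineered group insertion --------------------------------------------

#: Milliseconds between coincident suprathreshold arrivals and the resulting
#: spike (integrate-to-peak lag of the quadratic dynamics at ~3 maximal EPSPs).
IGNITION_LAG = 3

#: Summed 1 ms input (mV) that just lifts a resting RS neuron past its
#: threshold saddle (two maximal 8 mV arrivals stay below it, three exceed it).
THRESHOLD_KICK = 17.0


def insert_pngs(
    network: Network,
    n: int = 100,
    size: int = 40,
    duration: int = 200,
    convergence: int = 3,
    redundancy: int = 2,
    seed: int = 0,
    weight: float | None = None,
    ignition_lag: int = IGNITION_LAG,
    probe_sd: float = 0.8,
) -> tuple[Network, list[PNGTemplate]]:
    """Wire ``n`` engineered polychronous groups into a copy of the network.

    Each group is a chain of ``size`` excitatory neurons spanning
    ``duration`` ms: three anchors fire simultaneously at time 0 and every
    later member receives ``convergence`` intra-group synapses whose delays
    make the arrivals coincide ``ignition_lag`` ms before its scheduled
    firing time (the time the dynamics need to integrate coincident
    suprathreshold drive to a spike), plus ``redundancy`` extra
    near-coincident synapses (delays capped at the maximum conduction delay)
    for noise robustness.  The default insertion weight is w_max, so the
    minimally required ``convergence`` coincident arrivals reliably fire
    each member.  Returns the new network and the realized templates
    (simulated noise-free from the anchors under a facilitated,
    inhibition-silenced probe — the group's structural pattern).
    """
    cfg = network.config
    max_delay = cfg.exc_delay_range[1]
    if size < convergence + 2:
        raise ValueError("size too small for the requested convergence")
    n_anchors = 3
    lag = int(ignition_lag)
    t_first = lag + 2  # earliest member: anchor->member delay >= 2
    spacing = (duration - t_first) / max(size - n_anchors - 1, 1)
    if spacing > max_delay - 1 or spacing < 1:
        raise ValueError(
            f"{size} neurons over {duration} ms cannot satisfy convergence "
            f"{convergence} with delays <= {max_delay} ms")
    rng = np.random.default_rng(seed)
    exc_ids = network.excitatory_ids()
    if len(exc_ids) < size:
        raise ValueError("not enough excitatory neurons")
    w_new = network.config.w_max if weight is None else weight

    net = network.copy()
    templates: list[PNGTemplate] = []
    new_pre, new_post, new_delay = [], [], []
    designed = []
    group_bounds = []
    for g in range(n):
        group_start = len(new_pre)
        members = rng.choice(exc_ids, size=size, replace=False)
        times = np.zeros(size, dtype=np.int64)
        for i in range(n_anchors, size):
            times[i] = int(round(t_first + (i - n_anchors) * spacing))
        for i in range(n_anchors, size):
            # delay from predecessor j lands the spike lag ms before t_i
            lags = times[i] - times[:i] - lag
            in_window = np.flatnonzero((lags >= 1) & (lags <= max_delay))
            if len(in_window) < convergence:
                raise ValueError("infeasible chain layout")  # pragma: no cover
            # exact-coincidence afferents: the latest in-window predecessors
            chosen = in_window[np.argsort(times[in_window])[::-1][:convergence]]
            for j in chosen:
                new_pre.append(members[j])
                new_post.append(members[i])
                new_delay.append(times[i] - times[j] - lag)
            # redundant afferents: next-most-recent, delay capped (near-coincident)
            rest = [j for j in np.argsort(times[:i])[::-1] if j not in set(chosen)]
            for j in rest[:redundancy]:
                new_pre.append(members[j])
                new_post.append(members[i])
                new_delay.append(min(int(times[i] - times[j] - lag), max_delay))
        designed.append((members, times))
        group_bounds.append((group_start, len(new_pre)))

    k = len(new_pre)
    m0 = net.n_synapses
    net.add_synapses(new_pre, new_post, new_delay,
                     np.full(k, float(w_new)), np.ones(k, dtype=bool))
    # realization probe: the template is the group's structural pattern, so
    # only the group's own synapses carry weight during the probe (all other
    # synapses silenced) and the group is facilitated
    w_all_saved = net.weight.copy()
    sd_all_saved = net.sd.copy()
    for g, (members, times) in enumerate(designed):
        anchors = [(int(members[i]), float(times[i])) for i in range(n_anchors)]
        lo, hi = group_bounds[g]
        group_syn = np.arange(m0 + lo, m0 + hi)
        net.weight[:] = 0.0
        net.weight[group_syn] = np.maximum(w_all_saved[group_syn], cfg.w_max)
        net.sd[group_syn] = probe_sd
        tpl = simulate_template(net, anchors, min_size=size // 2)
        net.sd[group_syn] = 0.0
        if tpl is None:  # pragma: no cover - engineered groups always ignite
            raise RuntimeError(f"inserted group {g} failed to ignite")
        tpl.id = g
        templates.append(tpl)
    net.weight[:] = w_all_saved
    net.sd[:] = sd_all_saved
    return net, templates


# -- discovery --------------------------------------------------------------

def _dedupe_match(a: PNGTemplate, b: PNGTemplate, frac: float = 0.9,
                  tol: float = 1.0) -> bool:
    """True if >= frac of a's events coincide with b's within +-tol after the
    best single time shift (mode of pairwise offsets on shared neurons)."""
    shared = a.member_set & b.member_set
    if len(shared) < frac * min(a.size, b.size):
        return False
    offsets = []
    b_by = {}
    for nrn, t in zip(b.neurons, b.times):
        b_by.setdefault(int(nrn), []).append(t)
    for nrn, t in zip(a.neurons, a.times):
        for tb in b_by.get(int(nrn), ()):
            offsets.append(tb - t)
    if not offsets:
        return False
    offsets = np.round(np.asarray(offsets)).astype(int)
    shift = np.bincount(offsets - offsets.min()).argmax() + offsets.min()
    matched = 0
    for nrn, t in zip(a.neurons, a.times):
        if any(abs(tb - (t + shift)) <= tol for tb in b_by.get(int(nrn), ())):
            matched += 1
    return matched >= frac * len(a.neurons)


def find_pngs(
    network: Network,
    anchor_count: int = 3,
    min_size: int = 5,
    strong_fraction: float = 0.95,
    max_combos_per_target: int = 20,
    max_groups: int | None = None,
    targets: np.ndarray | None = None,
    anchor_pool: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    progress: bool = False,
) -> list[PNGTemplate]:
    """Reconstruct polychronous groups from structure (connections + delays +
    weights), with the network's weights held static.

    For every candidate target neuron, sets of ``anchor_count`` strong
    (weight >= strong_fraction * w_max) excitatory afferents are fired so
    that their spikes arrive at the target simultaneously; the resulting
    noise-free cascade is kept when it reaches ``min_size`` distinct neurons,
    and near-identical templates are deduplicated.  The search is bounded by
    ``max_combos_per_target`` (anchor sets are subsampled beyond it) and
    ``max_groups``.
    """
    rng = rng or np.random.default_rng(0)
    w_thresh = strong_fraction * network.config.w_max
    exc = network.exc
    if targets is None:
        targets = np.flatnonzero(exc)
    pool = None if anchor_pool is None else set(int(x) for x in anchor_pool)

    found: list[PNGTemplate] = []
    for tcount, j in enumerate(targets):
        aff = network.afferent_synapses(int(j))
        strong = aff[(network.weight[aff] >= w_thresh) & exc[network.pre[aff]]]
        if pool is not None:
            strong = strong[np.isin(network.pre[strong], list(pool))]
        if len(strong) < anchor_count:
            continue
        combos = list(itertools.combinations(range(len(strong)), anchor_count))
        if len(combos) > max_combos_per_target:
            pick = rng.choice(len(combos), size=max_combos_per_target,
                              replace=False)
            combos = [combos[i] for i in pick]
        for combo in combos:
            syn = strong[list(combo)]
            pres = network.pre[syn]
            if len(set(int(p) for p in pres)) < anchor_count:
                continue  # the same anchor cannot fire twice in one ignition
            delays = network.delay[syn].astype(int)
            t_conv = int(delays.max())
            anchors = [(int(p), float(t_conv - int(d)))
                       for p, d in zip(pres, delays)]
            tpl = simulate_template(network, anchors, min_size=min_size)
            if tpl is None:
                continue
            if any(_dedupe_match(tpl, other) for other in found):
                continue
            tpl.id = len(found)
            found.append(tpl)
            if max_groups is not None and len(found) >= max_groups:
                return found
        if progress and (tcount + 1) % 100 == 0:  # pragma: no cover
            print(f"find_pngs: {tcount + 1}/{len(targets)} targets, "
                  f"{len(found)} groups")
    return found


# -- detection --------------------------------------------------------------

def detect_activations(
    raster: SpikeRaster,
    template: PNGTemplate,
    min_fraction: float = 0.25,
    jitter: float = 5.0,
    anchor_fraction: float = 0.2,
) -> list[ActivationEvent]:
    """Find (partial) reactivations of a template in a spike raster.

    Candidate onsets are seeded from every spike of the template's earliest
    ``anchor_fraction`` of neurons; a candidate counts the distinct template
    members with a spike within +-jitter of their expected time, and becomes
    an event when the matched fraction strictly exceeds ``min_fraction``.
    Overlapping candidates (within one template duration) are merged, keeping
    the best-matching onset.
    """
    if len(raster) == 0 or len(template.neurons) == 0:
        return []
    by_neuron = raster.by_neuron()
    uniq = np.unique(template.neurons)
    rel = {int(n): template.times[template.neurons == n] for n in uniq}
    size = len(uniq)

    onsets: list[float] = []
    for e in template.early_neurons(anchor_fraction):
        for t_rel in rel[int(e)]:
            for t_spk in by_neuron.get(int(e), ()):
                onsets.append(float(t_spk) - float(t_rel))
    if not onsets:
        return []
    onsets = np.unique(np.asarray(onsets))

    cands: list[ActivationEvent] = []
    for onset in onsets:
        matched: set[int] = set()
        for n in uniq:
            spikes = by_neuron.get(int(n))
            if spikes is None:
                continue
            expected = onset + rel[int(n)]
            lo = np.searchsorted(spikes, expected - jitter, side="left")
            hi = np.searchsorted(spikes, expected + jitter, side="right")
            if np.any(hi > lo):
                matched.add(int(n))
        frac = len(matched) / size
        if frac > min_fraction:
            cands.append(ActivationEvent(template.id, float(onset), frac, matched))

    # merge overlapping candidate alignments: keep the best onset per cluster
    cands.sort(key=lambda e: e.onset)
    events: list[ActivationEvent] = []
    window = max(template.duration, 1.0)
    cluster: list[ActivationEvent] = []
    for ev in cands:
        if cluster and ev.onset - cluster[-1].onset > window:
            events.append(max(cluster, key=lambda e: (e.fraction, -e.onset)))
            cluster = []
        cluster.append(ev)
    if cluster:
        events.append(max(cluster, key=lambda e: (e.fraction, -e.onset)))
    return events


def surrogate_raster(raster: SpikeRaster) -> SpikeRaster:
    """Time-inverted raster (t -> duration - t); the null for significance."""
    times = raster.duration - raster.times
    order = np.argsort(times, kind="stable")
    return SpikeRaster(times[order], raster.neurons[order],
                       raster.duration, raster.n_neurons)


# -- statistics -------------------------------------------------------------

def png_statistics(
    templates: list[PNGTemplate],
    raster: SpikeRaster | None = None,
    min_fraction: float = 0.25,
    jitter: float = 5.0,
) -> PNGStats:
    """Group-level statistics: sizes, durations, overlap, membership, and
    (when a raster is given) activation counts on real vs time-inverted data."""
    if not templates:
        raise ValueError("template list is empty")
    sizes = np.array([t.size for t in templates])
    durations = np.array([t.duration for t in templates])
    members = [t.member_set for t in templates]
    shared = []
    for i in range(len(templates)):
        for j in range(i + 1, len(templates)):
            shared.append(len(members[i] & members[j]))
    n_neurons = 1 + max((max(m) for m in members if m), default=0)
    counts = np.zeros(n_neurons, dtype=int)
    for m in members:
        for nrn in m:
            counts[nrn] += 1

    act = sur = None
    if raster is not None:
        act = np.array([len(detect_activations(raster, t, min_fraction, jitter))
                        for t in templates])
        inv = surrogate_raster(raster)
        sur = np.array([len(detect_activations(inv, t, min_fraction, jitter))
                        for t in templates])
    return PNGStats(
        count=len(templates), sizes=sizes, durations=durations,
        pairwise_shared=np.asarray(shared, dtype=int),
        membership_counts=counts,
        activation_counts=act, surrogate_counts=sur,
    )


# -- template text format ---------------------------------------------------

def write_templates(templates: list[PNGTemplate], path) -> None:
    with open(path, "w") as fh:
        fh.write("# polywm templates\n")
        for t in templates:
            fh.write(f"template\t{t.id}\n")
            for nrn, tt in t.anchors:
                fh.write(f"anchor\t{nrn},{tt:g}\n")
            for nrn, tt in zip(t.neurons, t.times):
                fh.write(f"event\t{nrn},{tt:g}\n")


def read_templates(path) -> list[PNGTemplate]:
    templates: list[PNGTemplate] = []
    cur = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            kind, _, rest = line.partition("\t")
            if kind == "template":
                if cur is not None:
                    templates.append(_finish_template(cur))
                cur = {"id": int(rest), "anchors": [], "events": []}
            elif kind in ("anchor", "event"):
                if cur is None:
                    raise ValueError(f"{path}:{lineno}: event before template header")
                nrn, t = rest.split(",")
                cur[kind + "s"].append((int(nrn), float(t)))
            else:
                raise ValueError(f"{path}:{lineno}: unknown record {kind!r}")
    if cur is not None:
        templates.append(_finish_template(cur))
    return templates


def _finish_template(d: dict) -> PNGTemplate:
    neurons = np.array([n for n, _ in d["events"]], dtype=np.int32)
    times = np.array([t for _, t in d["events"]])
    return PNGTemplate(id=d["id"], neurons=neurons, times=times,
                       anchors=[(int(n), float(t)) for n, t in d["anchors"]])
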