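"""Millisecond-loop network simulator with per-synapse conduction delays.

Each simulated millisecond t:

1. deliver every presynaptic spike whose emission time + delay equals t,
   scaled by the synapse's short-term state;
2. add stochastic minis and scheduled stimulus currents;
3. advance all neurons by one 1 ms step (two 0.5 ms substeps for v);
4. apply plasticity for this step's arrivals and spikes.

Delay bookkeeping is exact integer arithmetic via a ring buffer of synapse
index lists, so delivery_time - emission_time always equals the synapse
delay.  Runs are bit-for-bit reproducible for a given network and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import Network
from .neurons import step_population
from .plasticity import PlasticityConfig, PlasticityState
from .raster import SpikeRaster

#: Stimulus current (mV) strong enough to fire a resting RS neuron within 1 ms.
CUE_AMPLITUDE = 100.0


@dataclass
class StimulusEvent:
    """A single scheduled current injection."""
    time: int        # ms
    neuron: int
    amplitude: float = CUE_AMPLITUDE


@dataclass
class GainInterval:
    """Plasticity rate gain over [start, end) ms (neuromodulator schedule)."""
    start: float
    end: float
    longterm_gain: float = 1.0
    shortterm_gain: float = 1.0


@dataclass
class TrialResult:
    """Everything recorded in one simulation run."""
    raster: SpikeRaster
    seed: int
    duration: float
    final_weights: np.ndarray
    final_sd: np.ndarray
    final_g: np.ndarray = None        # NMDA-mode activation per synapse
    final_upstate: np.ndarray = None  # NMDA-mode up-state flags
    sd_traces: dict = field(default_factory=dict)   # name -> (times, mean sd)
    activations: dict = field(default_factory=dict)  # template id -> [ActivationEvent]
    rate_curves: dict = field(default_factory=dict)  # name -> RateCurve
    config_echo: dict = field(default_factory=dict)


def _compile_stimuli(stimuli, n_neurons: int):
    """Sort stimulus events by time into flat arrays; validate targets."""
    if not stimuli:
        return (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64),
                np.empty(0))
    times = np.array([int(s.time) for s in stimuli], dtype=np.int64)
    neurons = np.array([s.neuron for s in stimuli], dtype=np.int64)
    amps = np.array([s.amplitude for s in stimuli], dtype=np.float64)
    if neurons.min() < 0 or neurons.max() >= n_neurons:
        bad = neurons[(neurons < 0) | (neurons >= n_neurons)]
        raise ValueError(f"stimulus target ids out of range: {bad[:5]}")
    order = np.argsort(times, kind="stable")
    return times[order], neurons[order], amps[order]


def _gain_at(t: float, schedule, which: str) -> float:
    g = 1.0
    for iv in schedule:
        if iv.start <= t < iv.end:
            g *= getattr(iv, which)
    return g


def simulate(
    network: Network,
    duration_ms: float,
    stimuli: list[StimulusEvent] | None = None,
    plasticity: PlasticityConfig | None = None,
    seed: int = 0,
    mini_rate: float | None = None,
    mini_amplitude: float | None = None,
    gain_schedule: list[GainInterval] | None = None,
    sd_groups: dict[str, np.ndarray] | None = None,
    sd_sample_every: int = 100,
    stop_when_silent: bool = False,
    silence_margin: int = 10,
    update_network: bool = False,
) -> TrialResult:
    """Run the network for ``duration_ms`` and return a :class:`TrialResult`.

    ``mini_rate``/``mini_amplitude`` override the network config (pass 0 to
    silence the background).  ``sd_groups`` maps trace names to synapse index
    arrays whose mean short-term scaling is sampled every
    ``sd_sample_every`` ms.  With ``stop_when_silent`` the loop ends once no
    spikes, deliveries or stimuli remain pending (used for noise-free
    cascades).  Unless ``update_network`` is set, the input network's weight
    and sd arrays are left untouched; the evolved copies are returned in the
    result.
    """
    plasticity = plasticity or PlasticityConfig()
    lt, st = plasticity.longterm, plasticity.shortterm
    lt.validate()
    st.validate()
    gain_schedule = gain_schedule or []
    rng = np.random.default_rng(seed)

    n = network.n_neurons
    duration = int(round(duration_ms))
    if duration <= 0:
        raise ValueError("duration must be positive")

    rate = network.config.mini_rate if mini_rate is None else mini_rate
    amp = network.config.mini_amplitude if mini_amplitude is None else mini_amplitude
    lam = rate * n / 1000.0  # expected minis per ms, whole population

    stim_t, stim_n, stim_a = _compile_stimuli(stimuli, n)
    stim_ptr = 0

    # neuron state at the exact resting point of the subthreshold dynamics
    v = np.full(n, -70.0)
    u = network.b * v
    a_par, b_par = network.a, network.b
    c_par, d_par = network.c, network.d

    weight = network.weight if update_network else network.weight.copy()
    pstate = PlasticityState(n, network.n_synapses, plasticity, sd=network.sd)
    nmda_mode = st.mode == "nmda"

    # efferent CSR (delivery) and plastic-afferent CSR (LTP on post spike)
    if network._eff_indptr is None:
        network._build_index()
    eff_indptr, eff_order = network._eff_indptr, network._eff_order
    plastic = network.plastic
    aff_order_all = network._aff_order
    aff_keep = plastic[aff_order_all]
    aff_plastic = aff_order_all[aff_keep]
    aff_counts = np.bincount(network.post[aff_plastic], minlength=n)
    aff_indptr = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(aff_counts, out=aff_indptr[1:])

    delay = network.delay.astype(np.int64)
    post = network.post
    D = max(int(network.max_delay) + 1, 2)
    pending: list[list] = [[] for _ in range(D)]
    n_pending = 0

    spike_t_chunks: list[np.ndarray] = []
    spike_n_chunks: list[np.ndarray] = []

    sd_groups = sd_groups or {}
    trace_t: list[float] = []
    trace_vals: dict[str, list] = {name: [] for name in sd_groups}

    current = np.empty(n)

    for t in range(duration):
        # 1. deliveries
        slot = pending[t % D]
        if slot:
            arriving = np.concatenate(slot) if len(slot) > 1 else slot[0]
            slot.clear()
            n_pending -= len(arriving)
        else:
            arriving = None

        current.fill(0.0)
        if arriving is not None and len(arriving):
            eff = weight[arriving].copy()
            is_pl = plastic[arriving]
            pl_idx = arriving[is_pl]
            if st.enabled and len(pl_idx):
                if nmda_mode:
                    pstate.decay_g_to(pl_idx, t)
                    up = pstate.upstate[pl_idx]
                    low = pstate.g[pl_idx] < st.theta_down
                    up &= ~low
                    pstate.upstate[pl_idx] = up
                    mult = np.where(up, st.upstate_gain, 1.0)
                    eff[is_pl] = eff[is_pl] * mult
                else:
                    pstate.decay_sd_to(pl_idx, t)
                    eff[is_pl] = eff[is_pl] * (1.0 + pstate.sd[pl_idx])
            np.add.at(current, post[arriving], eff)

            # plasticity: presynaptic-arrival events
            if len(pl_idx):
                pj = post[pl_idx]
                dec = np.exp(-(t - pstate.xpost_t[pj]) / lt.tau_minus)
                xpost_now = pstate.xpost[pj] * dec
                stg = _gain_at(t, gain_schedule, "shortterm_gain")
                if st.enabled and not nmda_mode and stg != 0.0:
                    pstate.sd[pl_idx] = np.clip(
                        pstate.sd[pl_idx] - stg * st.s_minus * xpost_now,
                        st.sd_min, st.sd_max)
                if lt.enabled:
                    ltg = lt.rate_gain * _gain_at(t, gain_schedule, "longterm_gain")
                    weight[pl_idx] = np.clip(
                        weight[pl_idx] - ltg * lt.a_minus * xpost_now,
                        lt.w_min, lt.w_max)
                # arrival trace (shared window for long- and short-term rules)
                decp = np.exp(-(t - pstate.xpre_t[pl_idx]) / lt.tau_plus)
                if lt.nearest_neighbor:
                    pstate.xpre[pl_idx] = 1.0
                else:
                    pstate.xpre[pl_idx] = pstate.xpre[pl_idx] * decp + 1.0
                pstate.xpre_t[pl_idx] = t
                if nmda_mode:
                    pstate.g[pl_idx] += st.g_increment

        # 2. background minis and stimuli
        if lam > 0.0 and amp != 0.0:
            k = rng.poisson(lam)
            if k:
                targets = rng.integers(0, n, size=k)
                np.add.at(current, targets, amp)
        while stim_ptr < len(stim_t) and stim_t[stim_ptr] == t:
            current[stim_n[stim_ptr]] += stim_a[stim_ptr]
            stim_ptr += 1

        # 3. neuron dynamics
        spiked = step_population(v, u, a_par, b_par, current)
        if spiked.any():
            fired = np.flatnonzero(spiked)
            v[fired] = c_par[fired]
            u[fired] += d_par[fired]
            spike_t_chunks.append(np.full(len(fired), t, dtype=np.float64))
            spike_n_chunks.append(fired.astype(np.int32))

            # 4. plasticity: postsynaptic-spike events (afferent plastic synapses)
            aff = [aff_plastic[aff_indptr[j]:aff_indptr[j + 1]] for j in fired]
            aff_idx = np.concatenate(aff) if aff else np.empty(0, dtype=np.int64)
            if len(aff_idx):
                xpre_now = pstate.xpre[aff_idx] * np.exp(
                    -(t - pstate.xpre_t[aff_idx]) / lt.tau_plus)
                stg = _gain_at(t, gain_schedule, "shortterm_gain")
                if st.enabled and not nmda_mode and stg != 0.0:
                    pstate.decay_sd_to(aff_idx, t)
                    pstate.sd[aff_idx] = np.clip(
                        pstate.sd[aff_idx] + stg * st.s_plus * xpre_now,
                        st.sd_min, st.sd_max)
                if lt.enabled:
                    ltg = lt.rate_gain * _gain_at(t, gain_schedule, "longterm_gain")
                    weight[aff_idx] = np.clip(
                        weight[aff_idx] + ltg * lt.a_plus * xpre_now,
                        lt.w_min, lt.w_max)
                if st.enabled and nmda_mode:
                    pstate.decay_g_to(aff_idx, t)
                    enter = pstate.g[aff_idx] > st.theta_up
                    pstate.upstate[aff_idx] |= enter
            # post-spike trace
            dec = np.exp(-(t - pstate.xpost_t[fired]) / lt.tau_minus)
            if lt.nearest_neighbor:
                pstate.xpost[fired] = 1.0
            else:
                pstate.xpost[fired] = pstate.xpost[fired] * dec + 1.0
            pstate.xpost_t[fired] = t

            # schedule deliveries
            eff_syn = [eff_order[eff_indptr[j]:eff_indptr[j + 1]] for j in fired]
            out_idx = np.concatenate(eff_syn) if eff_syn else np.empty(0, dtype=np.int64)
            if len(out_idx):
                slots = (t + delay[out_idx]) % D
                order = np.argsort(slots, kind="stable")
                out_sorted = out_idx[order]
                slots_sorted = slots[order]
                bounds = np.flatnonzero(np.diff(slots_sorted)) + 1
                start = 0
                for chunk in np.split(out_sorted, bounds):
                    pending[int(slots_sorted[start])].append(chunk)
                    start += len(chunk)
                n_pending += len(out_idx)

        if not np.isfinite(v).all():
            raise FloatingPointError(f"non-finite membrane potential at t={t} ms")

        # recorders
        if sd_groups and t % sd_sample_every == 0:
            trace_t.append(float(t))
            for name, idx in sd_groups.items():
                trace_vals[name].append(float(np.mean(pstate.sd_now(idx, t)))
                                        if len(idx) else 0.0)

        if (stop_when_silent and n_pending == 0 and stim_ptr >= len(stim_t)
                and not spiked.any()):
            # allow the configured margin of silent ms before stopping
            if _silent_for(spike_t_chunks, t, silence_margin):
                duration = t + 1
                break

    times = (np.concatenate(spike_t_chunks) if spike_t_chunks
             else np.empty(0))
    ids = (np.concatenate(spike_n_chunks) if spike_n_chunks
           else np.empty(0, dtype=np.int32))
    raster = SpikeRaster(times, ids, float(duration), n)

    # bring sd up to date at the end of the run
    all_idx = np.arange(network.n_synapses)
    pstate.decay_sd_to(all_idx, duration)
    if update_network:
        network.sd = pstate.sd

    sd_traces = {name: (np.asarray(trace_t), np.asarray(vals))
                 for name, vals in trace_vals.items()}
    return TrialResult(
        raster=raster, seed=seed, duration=float(duration),
        final_weights=weight, final_sd=pstate.sd,
        final_g=pstate.g, final_upstate=pstate.upstate, sd_traces=sd_traces,
        config_echo={"mini_rate": rate, "mini_amplitude": amp,
                     "duration_ms": duration_ms},
    )


def _silent_for(spike_chunks, t: int, margin: int) -> bool:
    if not spike_chunks:
        return True
    return t - spike_chunks[-1][-1] >= margin


def arrival_schedule(raster: SpikeRaster, network: Network) -> dict[int, list[tuple[int, int]]]:
    """Exact per-millisecond delivery lists for a slice of emissions.

    Returns {delivery_time: [(synapse_index, postsynaptic_neuron), ...]};
    every emitted spike yields exactly one delivery per efferent synapse at
    emission time + that synapse's delay.
    """
    out: dict[int, list[tuple[int, int]]] = {}
    for t, j in zip(raster.times, raster.neurons):
        syn = network.efferent_synapses(int(j))
        for s in syn:
            arr = int(round(t)) + int(network.delay[s])
            out.setdefault(arr, []).append((int(s), int(network.post[s])))
    return {k: sorted(v) for k, v in sorted(out.items())}
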