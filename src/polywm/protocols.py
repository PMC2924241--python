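"""Working-memory experiment protocols.

A group is loaded into working memory by stimulating (part of) its neurons
with the group's own polychronous pattern, repeatedly within a short window.
The associative short-term strengthening of the intra-group synapses then
biases spontaneous, mini-triggered reactivations toward the cued group,
which in turn re-strengthen its synapses — maintenance without any
reverberant loop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .network import Network
from .plasticity import PlasticityConfig, LongTermConfig, ShortTermConfig
from .png import ActivationEvent, PNGTemplate, detect_activations, simulate_template
from .simulator import CUE_AMPLITUDE, GainInterval, StimulusEvent, TrialResult, simulate


@dataclass
class StimulusProtocol:
    """How a template is cued: repetitions of its pattern within a window."""
    repetitions: int = 10
    window: float = 1000.0          # ms over which repetitions are spread
    segment_fraction: float = 0.8   # initial fraction of the pattern stimulated
    response_probability: float = 1.0
    start: float = 0.0              # ms, first presentation onset
    amplitude: float = CUE_AMPLITUDE

    def validate(self):
        if not (0.0 < self.segment_fraction <= 1.0):
            raise ValueError("segment_fraction must be in (0, 1]")
        if not (0.0 <= self.response_probability <= 1.0):
            raise ValueError("response_probability must be in [0, 1]")
        if self.repetitions < 0:
            raise ValueError("repetitions must be >= 0")

    @property
    def offset(self) -> float:
        """End of the stimulation window."""
        return self.start + self.window


@dataclass
class NeuromodulatorSchedule:
    """Intervals of elevated plasticity rate (e.g. dopamine); gain >= 1."""
    intervals: list[tuple[float, float]] = field(default_factory=list)
    gain: float = 5.0

    def to_gain_intervals(self) -> list[GainInterval]:
        if self.gain < 1.0:
            raise ValueError("neuromodulator gain must be >= 1")
        return [GainInterval(a, b, longterm_gain=self.gain,
                             shortterm_gain=self.gain)
                for a, b in self.intervals]


def prepare_wm_network(
    n_groups: int = 100,
    network_seed: int = 0,
    insert_seed: int = 0,
    config: "NetworkConfig | None" = None,
    weight: float | None = None,
    **insert_kwargs,
):
    """Standard preparation for inserted-group WM experiments.

    Builds a fresh randomly connected network with weak excitatory weights
    (the engineered groups supply the only strong E->E structure, as when
    groups are wired into a random network) and inserts ``n_groups``
    engineered polychronous groups.  Returns (network, templates).
    """
    from dataclasses import replace as _replace
    from .network import NetworkConfig, build_network
    from .png import insert_pngs
    cfg = config or NetworkConfig()
    cfg = _replace(cfg, init_weight_mode="growth")
    net = build_network(cfg, seed=network_seed)
    return insert_pngs(net, n=n_groups, seed=insert_seed, weight=weight,
                       **insert_kwargs)


#: Inserted-group weight for NMDA-mode trials: the 10-fold up-state efficacy
#: then sits just at the firing threshold for single arrivals, the regime in
#: which up-state propagation is selective rather than an unconditional relay.
NMDA_TRIAL_WEIGHT = 1.7


def cue_png(template: PNGTemplate, protocol: StimulusProtocol,
            rng: np.random.Generator | None = None) -> list[StimulusEvent]:
    """Compile a cue protocol into scheduled suprathreshold current injections.

    The first ``segment_fraction`` of the template's events (by relative
    time) are driven at their pattern times, once per repetition; pattern
    starts are spaced uniformly over the window.  Each injection is kept
    independently with ``response_probability``.
    """
    protocol.validate()
    rng = rng or np.random.default_rng(0)
    k = max(1, int(round(protocol.segment_fraction * len(template.neurons))))
    seg_n = template.neurons[:k]
    seg_t = template.times[:k]
    spacing = protocol.window / max(protocol.repetitions, 1)
    events: list[StimulusEvent] = []
    for rep in range(protocol.repetitions):
        onset = protocol.start + rep * spacing
        for nrn, t in zip(seg_n, seg_t):
            if protocol.response_probability < 1.0 and \
                    rng.random() >= protocol.response_probability:
                continue
            events.append(StimulusEvent(time=int(round(onset + t)),
                                        neuron=int(nrn),
                                        amplitude=protocol.amplitude))
    return events


def _check_overlap(cues: list[list[StimulusEvent]]) -> None:
    seen: set[tuple[int, int]] = set()
    for ev_list in cues:
        for ev in ev_list:
            key = (ev.time, ev.neuron)
            if key in seen:
                warnings.warn("overlapping cue schedules for the same neuron; "
                              "currents superposed")
                return
            seen.add(key)


def intra_group_synapses(network: Network, template: PNGTemplate) -> np.ndarray:
    """Indices of plastic synapses with both endpoints inside the template."""
    members = np.fromiter(template.member_set, dtype=np.int64)
    inside = np.zeros(network.n_neurons, dtype=bool)
    inside[members] = True
    return np.flatnonzero(network.plastic & inside[network.pre]
                          & inside[network.post])


def run_wm_trial(
    network: Network,
    templates: list[PNGTemplate],
    cue_times: list[float] | None = None,
    duration: float = 21_000.0,
    plasticity: PlasticityConfig | None = None,
    protocol: StimulusProtocol | None = None,
    seed: int = 0,
    gain_schedule: list[GainInterval] | None = None,
    detect_kwargs: dict | None = None,
) -> TrialResult:
    """Cue one or more templates and record maintenance statistics.

    Each template is presented ``protocol.repetitions`` times within
    ``protocol.window`` starting at its entry of ``cue_times`` (default: all
    at 0 ms).  Short-term plasticity must be enabled; long-term STDP is off
    by default.  The result carries the raster, per-template activation
    events, and mean-sd traces for intra-group vs background synapses.
    """
    plasticity = plasticity or PlasticityConfig()
    if not plasticity.shortterm.enabled:
        warnings.warn("running a WM trial with short-term plasticity disabled")
    protocol = protocol or StimulusProtocol()
    cue_times = cue_times if cue_times is not None else [0.0] * len(templates)
    if len(cue_times) != len(templates):
        raise ValueError("need one cue time per template")

    rng = np.random.default_rng(seed + 1)
    cues = []
    for tpl, t0 in zip(templates, cue_times):
        cues.append(cue_png(tpl, replace(protocol, start=t0), rng=rng))
    _check_overlap(cues)
    stimuli = [ev for lst in cues for ev in lst]

    sd_groups = {}
    intra_all = np.empty(0, dtype=np.int64)
    for i, tpl in enumerate(templates):
        idx = intra_group_synapses(network, tpl)
        sd_groups[f"intra_{tpl.id}"] = idx
        intra_all = np.union1d(intra_all, idx)
    other = np.flatnonzero(network.plastic)
    sd_groups["background"] = np.setdiff1d(other, intra_all)

    res = simulate(
        network, duration, stimuli=stimuli, plasticity=plasticity,
        seed=seed, gain_schedule=gain_schedule, sd_groups=sd_groups,
    )
    kw = detect_kwargs or {}
    for tpl in templates:
        res.activations[tpl.id] = detect_activations(res.raster, tpl, **kw)
    res.config_echo["cue_times"] = list(cue_times)
    res.config_echo["cue_offsets"] = [t + protocol.window for t in cue_times]
    res.config_echo["protocol"] = {
        "repetitions": protocol.repetitions, "window": protocol.window,
        "segment_fraction": protocol.segment_fraction,
        "response_probability": protocol.response_probability,
    }
    return res


def erase_wm(at_time: float, duration: float = float("inf")) -> GainInterval:
    """Schedule entry that suppresses short-term increments from ``at_time``.

    With the short-term rate at zero the per-synapse scaling sd is no longer
    replenished by reactivations and relaxes to baseline with tau_sd, after
    which detection rates return to the surrogate level.
    """
    return GainInterval(at_time, duration, longterm_gain=1.0,
                        shortterm_gain=0.0)


def neuromodulator_cue(
    network: Network,
    template: PNGTemplate,
    presentations: int = 3,
    gain: float = 5.0,
    duration: float = 21_000.0,
    plasticity: PlasticityConfig | None = None,
    seed: int = 0,
    response_probability: float = 1.0,
) -> TrialResult:
    """Cue with few presentations under elevated plasticity rate.

    With a ``gain``-fold faster short-term plasticity rate, 1-3 pattern
    presentations are enough to reach the same intra-group strengthening as
    the default 10-presentation protocol.
    """
    window = max(100.0 * presentations, 1.0)
    protocol = StimulusProtocol(repetitions=presentations, window=window,
                                response_probability=response_probability)
    sched = NeuromodulatorSchedule(intervals=[(0.0, window + 50.0)], gain=gain)
    return run_wm_trial(network, [template], [0.0], duration=duration,
                        plasticity=plasticity, protocol=protocol, seed=seed,
                        gain_schedule=sched.to_gain_intervals())


def maintenance_verdict(
    events: list[ActivationEvent],
    cue_offset: float,
    duration: float,
    persistence_ms: float = 10_000.0,
    gap_window: float = 2_000.0,
) -> dict:
    """Both maintenance criteria for one cued template.

    ``persistent``: last reactivation later than ``persistence_ms`` after cue
    offset.  ``continuous``: at least one detected activation in every
    consecutive ``gap_window`` bin between cue offset and the last event.
    """
    post = sorted(e.onset for e in events if e.onset >= cue_offset)
    last = (post[-1] - cue_offset) if post else 0.0
    persistent = last >= persistence_ms
    continuous = False
    if post:
        span = np.arange(cue_offset, min(cue_offset + persistence_ms, duration),
                         gap_window)
        hits = [any(a <= t < a + gap_window for t in post) for a in span]
        continuous = all(hits) and len(hits) > 0
    return {"persistent": persistent, "continuous": continuous,
            "last_reactivation_ms": last, "n_events": len(post)}


def run_novel_cue_experiment(
    network: Network,
    n_stimulated: int = 60,
    pattern_duration: float = 100.0,
    presentations_every: float = 15_000.0,
    total_duration: float = 90_000.0,
    reps_per_presentation: int = 10,
    rep_window: float = 1000.0,
    mini_rate: float | None = None,
    shortterm_enabled: bool = True,
    plasticity: PlasticityConfig | None = None,
    seed: int = 0,
) -> tuple[TrialResult, PNGTemplate | None]:
    """Repeatedly present a novel polychronous pattern and test whether a new
    group forms and is held in working memory.

    A fixed random pattern over ``n_stimulated`` excitatory neurons is
    presented ``reps_per_presentation`` times within ``rep_window`` at every
    multiple of ``presentations_every``; long-term STDP is on (short-term
    per the flag).  After the run the formed template is identified by a
    noise-free probe of the weight-updated network driven by the cue pattern;
    its members include both stimulated and recruited (non-stimulated)
    neurons.  Returns the trial and the template (None if nothing formed).
    """
    rng = np.random.default_rng(seed)
    exc_ids = network.excitatory_ids()
    stim_neurons = rng.choice(exc_ids, size=n_stimulated, replace=False)
    stim_times = np.sort(rng.integers(0, int(pattern_duration),
                                      size=n_stimulated))
    pattern = PNGTemplate(id=0, neurons=stim_neurons, times=stim_times,
                          anchors=[(int(n), float(t)) for n, t in
                                   zip(stim_neurons[:3], stim_times[:3])])

    if plasticity is None:
        plasticity = PlasticityConfig(
            longterm=LongTermConfig(enabled=True),
            shortterm=ShortTermConfig(enabled=shortterm_enabled),
        )

    stimuli: list[StimulusEvent] = []
    t0 = 0.0
    protocol = StimulusProtocol(repetitions=reps_per_presentation,
                                window=rep_window)
    while t0 < total_duration - rep_window:
        stimuli.extend(cue_png(pattern, replace(protocol, start=t0), rng=rng))
        t0 += presentations_every

    res = simulate(network, total_duration, stimuli=stimuli,
                   plasticity=plasticity, seed=seed, mini_rate=mini_rate,
                   update_network=False)

    # probe the evolved weights for the formed group
    probe_net = network.copy()
    probe_net.weight = res.final_weights.copy()
    anchors = [(int(n), float(t)) for n, t in zip(stim_neurons, stim_times)]
    formed = simulate_template(probe_net, anchors, min_size=n_stimulated + 1)
    if formed is not None:
        formed.id = 0
        res.activations[0] = detect_activations(res.raster, formed)
    res.config_echo["stimulated_neurons"] = [int(x) for x in stim_neurons]
    res.config_echo["pattern_times"] = [int(x) for x in stim_times]
    res.config_echo["presentation_starts"] = list(
        np.arange(0.0, total_duration - rep_window, presentations_every))
    return res, formed


def capacity_experiment(
    network: Network,
    templates: list[PNGTemplate],
    loads: list[int],
    duration: float = 16_000.0,
    plasticity: PlasticityConfig | None = None,
    seed: int = 0,
    **trial_kwargs,
) -> dict[int, TrialResult]:
    """Cue the first k templates simultaneously for each k in ``loads``."""
    out: dict[int, TrialResult] = {}
    for k in loads:
        if k > len(templates):
            raise ValueError("not enough templates for requested load")
        out[k] = run_wm_trial(network, templates[:k], [0.0] * k,
                              duration=duration, plasticity=plasticity,
                              seed=seed + k, **trial_kwargs)
    return out
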