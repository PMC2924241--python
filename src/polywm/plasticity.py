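"""Synaptic plasticity: long-term STDP, associative short-term STDP, and the
NMDA up-state mechanism.

All timing rules act on the *arrival* time of the presynaptic spike at the
postsynaptic target (emission time + conduction delay), not on the emission
time.  Pre-arrival before postsynaptic spike by dt potentiates by
``A_plus * exp(-dt/tau_plus)``; the reverse order depresses by
``A_minus * exp(-dt/tau_minus)``.  Long-term changes act on the bounded
weight w in [0, w_max] mV.  Short-term STDP applies the same window to a
per-synapse scaling factor ``sd`` (effective weight ``w * (1 + sd)``) which
relaxes to 0 with a 5 s time constant; its ceiling sd=1 caps the temporary
gain at +100% of baseline.  The NMDA alternative keeps a per-synapse
activation ``g`` (250 ms decay, incremented by each arrival) and a hysteretic
up-state: entered when g > theta_up coincident with a postsynaptic spike,
left when g < theta_down; in the up-state transmission is 10-fold effective.

The simulator uses the vectorized :class:`PlasticityState`; the scalar
functions below define the rules per synapse and serve as its reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


@dataclass
class LongTermConfig:
    enabled: bool = False          # blocked by default in WM experiments
    a_plus: float = 0.1            # potentiation magnitude, mV per optimal pair
    a_minus: float = 0.12          # depression magnitude, mV per optimal pair
    tau_plus: float = 20.0         # ms
    tau_minus: float = 20.0        # ms
    w_min: float = 0.0             # mV
    w_max: float = 8.0             # mV
    rate_gain: float = 1.0         # neuromodulator multiplier (elevated: 5)
    nearest_neighbor: bool = False  # pair with last event only instead of all pairs

    def validate(self):
        if self.a_plus <= 0 or self.a_minus <= 0:
            raise ValueError("STDP magnitudes must be positive")
        if self.w_min >= self.w_max:
            raise ValueError("w_min must be < w_max")


@dataclass
class ShortTermConfig:
    enabled: bool = True
    mode: str = "stdp"             # "stdp" or "nmda"
    # short-term STDP: ~10 optimal pre-then-post pairs saturate sd at 1;
    # depression is deliberately stronger than potentiation so that
    # disordered (non-replay) activity produces net weakening, which keeps
    # non-selected groups from being entrained by a maintained one
    s_plus: float = 0.1
    s_minus: float = 0.2
    tau_sd: float = 5000.0         # ms, relaxation of sd toward 0
    sd_min: float = -0.5           # depression floor (keeps transmission positive)
    sd_max: float = 1.0            # +100% ceiling
    # NMDA mode: three arrivals within 250 ms exceed theta_up
    tau_nmda: float = 250.0        # ms, decay of per-synapse NMDA activation
    g_increment: float = 1.0       # activation added per presynaptic arrival
    theta_up: float = 1.9          # up-state entry threshold on g (with post spike)
    theta_down: float = 0.475      # up-state exit threshold on g (theta_up / 4)
    upstate_gain: float = 10.0     # efficacy multiplier in up-state

    def validate(self):
        if self.mode not in ("stdp", "nmda"):
            raise ValueError("shortterm mode must be 'stdp' or 'nmda'")
        if not (self.theta_down < self.theta_up):
            raise ValueError("theta_down must be < theta_up")
        if not (self.sd_min <= 0.0 <= self.sd_max):
            raise ValueError("sd bounds must bracket 0")


@dataclass
class PlasticityConfig:
    longterm: LongTermConfig = field(default_factory=LongTermConfig)
    shortterm: ShortTermConfig = field(default_factory=ShortTermConfig)


# -- scalar reference rules -------------------------------------------------

@dataclass
class ShortTermState:
    """Per-synapse short-term STDP state for the scalar API."""
    sd: float = 0.0
    pre_trace: float = 0.0   # arrivals, decays with tau_plus
    post_trace: float = 0.0  # post spikes, decays with tau_minus
    t_last: float = 0.0      # time of last update


@dataclass
class NmdaState:
    g: float = 0.0
    upstate: bool = False
    t_last: float = 0.0


def longterm_update(w: float, event: str, dt: float, config: LongTermConfig) -> float:
    """Weight change for a single pre-arrival/post-spike pair separated by dt >= 0.

    ``event='post'`` means the pre-spike arrived dt ms before the postsynaptic
    spike (potentiation); ``event='pre'`` means the arrival came dt ms after
    the postsynaptic spike (depression).  Returns the new clipped weight.
    """
    if event == "post":
        w = w + config.rate_gain * config.a_plus * math.exp(-dt / config.tau_plus)
    elif event == "pre":
        w = w - config.rate_gain * config.a_minus * math.exp(-dt / config.tau_minus)
    else:
        raise ValueError("event must be 'pre' or 'post'")
    return min(max(w, config.w_min), config.w_max)


def shortterm_update(state: ShortTermState, event: str, t: float,
                     config: ShortTermConfig,
                     longterm: LongTermConfig | None = None,
                     rate_gain: float = 1.0) -> ShortTermState:
    """Advance one synapse's short-term STDP state to time t and apply event.

    ``event`` is ``'pre'`` (presynaptic arrival) or ``'post'`` (postsynaptic
    spike).  Isolated pre- or post-activity leaves sd unchanged
    (associativity); only paired activity moves it, and it decays toward 0
    with tau_sd between events.
    """
    lt = longterm or LongTermConfig()
    dt = t - state.t_last
    sd = state.sd * math.exp(-dt / config.tau_sd)
    pre = state.pre_trace * math.exp(-dt / lt.tau_plus)
    post = state.post_trace * math.exp(-dt / lt.tau_minus)
    if event == "pre":
        sd -= rate_gain * config.s_minus * post
        pre += 1.0
    elif event == "post":
        sd += rate_gain * config.s_plus * pre
        post += 1.0
    else:
        raise ValueError("event must be 'pre' or 'post'")
    sd = min(max(sd, config.sd_min), config.sd_max)
    return ShortTermState(sd=sd, pre_trace=pre, post_trace=post, t_last=t)


def decay_sd(sd: float, dt: float, config: ShortTermConfig) -> float:
    """Relaxation of sd toward baseline over a silent interval dt."""
    return sd * math.exp(-dt / config.tau_sd)


def nmda_update(state: NmdaState, pre_arrival: bool, post_spike: bool,
                t: float, config: ShortTermConfig) -> NmdaState:
    """Advance one NMDA-mode synapse to time t and apply the step's events.

    g decays with tau_nmda and is incremented per presynaptic arrival.  The
    up-state turns on only when g > theta_up coincident with a postsynaptic
    spike, and turns off as soon as g falls below theta_down.
    """
    g = state.g * math.exp(-(t - state.t_last) / config.tau_nmda)
    up = state.upstate
    if g < config.theta_down:
        up = False
    if pre_arrival:
        g += config.g_increment
    if post_spike and g > config.theta_up:
        up = True
    return NmdaState(g=g, upstate=up, t_last=t)


def effective_weight(w: float, state: ShortTermState | NmdaState,
                     config: ShortTermConfig | None = None) -> float:
    """Transmission strength of one presynaptic spike given short-term state."""
    config = config or ShortTermConfig()
    if isinstance(state, NmdaState):
        return w * (config.upstate_gain if state.upstate else 1.0)
    return w * (1.0 + state.sd)


# -- vectorized engine state ------------------------------------------------

class PlasticityState:
    """Flat per-synapse plasticity state with lazy exponential decay.

    Traces are stored together with their last-touch time; decay is applied
    only when a synapse is visited, which keeps the per-millisecond cost
    proportional to the number of spike deliveries rather than to the total
    synapse count.  ``xpre`` counts presynaptic arrivals (tau_plus window),
    ``xpost`` counts postsynaptic spikes per neuron (tau_minus window); both
    long-term and short-term STDP read the same normalized traces scaled by
    their own magnitudes.
    """

    def __init__(self, n_neurons: int, n_synapses: int, config: PlasticityConfig,
                 sd: np.ndarray | None = None):
        self.config = config
        m = n_synapses
        self.sd = np.zeros(m) if sd is None else np.asarray(sd, dtype=np.float64).copy()
        self.sd_t = np.zeros(m)
        self.xpre = np.zeros(m)
        self.xpre_t = np.zeros(m)
        self.xpost = np.zeros(n_neurons)
        self.xpost_t = np.zeros(n_neurons)
        self.g = np.zeros(m)
        self.g_t = np.zeros(m)
        self.upstate = np.zeros(m, dtype=bool)

    def decay_sd_to(self, idx: np.ndarray, t: float) -> None:
        st = self.config.shortterm
        self.sd[idx] = self.sd[idx] * np.exp(-(t - self.sd_t[idx]) / st.tau_sd)
        self.sd_t[idx] = t

    def decay_g_to(self, idx: np.ndarray, t: float) -> None:
        st = self.config.shortterm
        self.g[idx] = self.g[idx] * np.exp(-(t - self.g_t[idx]) / st.tau_nmda)
        self.g_t[idx] = t

    def sd_now(self, idx: np.ndarray, t: float) -> np.ndarray:
        """Current (decayed) sd values without mutating state."""
        st = self.config.shortterm
        return self.sd[idx] * np.exp(-(t - self.sd_t[idx]) / st.tau_sd)
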