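"""Two-variable spiking neuron model.

The membrane dynamics are the canonical quadratic-integrate form with a linear
recovery variable::

    v' = 0.04 v^2 + 5 v + 140 - u + I
    u' = a (b v - u)

with the after-spike resetting ``v <- c, u <- u + d`` whenever ``v`` reaches
the spike-peak cutoff (+30 mV).  Two presets are provided: ``RS`` (regular
spiking, excitatory pyramidal) and ``FS`` (fast spiking, inhibitory).

With b = 0.2 both presets have an exact resting fixed point at
``v = -70, u = -14``; the unstable (threshold) branch sits near -55 mV, which
is what makes three simultaneous 8 mV synaptic arrivals suprathreshold while
two are not.

Integration follows the companion-model convention: a 1 ms global step with
two 0.5 ms substeps for ``v`` and a single 1 ms Euler step for ``u``.  The
synaptic drive ``I`` (mV) is applied inside the derivative over that 1 ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SPIKE_PEAK = 30.0  # mV, spike cutoff / detection level


@dataclass(frozen=True)
class NeuronParams:
    """Parameters of the two-variable model.

    a : recovery time scale (1/ms)
    b : recovery sensitivity to subthreshold v (dimensionless)
    c : after-spike membrane reset (mV)
    d : after-spike recovery increment
    """

    a: float
    b: float
    c: float
    d: float


#: Regular-spiking pyramidal preset (excitatory).
RS = NeuronParams(a=0.02, b=0.2, c=-65.0, d=8.0)
#: Fast-spiking interneuron preset (inhibitory).
FS = NeuronParams(a=0.1, b=0.2, c=-65.0, d=2.0)


@dataclass
class NeuronState:
    v: float
    u: float


def resting_state(params: NeuronParams) -> NeuronState:
    """Exact resting fixed point of the subthreshold dynamics.

    Solves 0.04 v^2 + 5 v + 140 - b v = 0 for the stable (lower) root and
    sets u = b v.  For b=0.2 this is v=-70, u=-14 exactly.
    """
    # 0.04 v^2 + (5 - b) v + 140 = 0
    b = params.b
    disc = (5.0 - b) ** 2 - 4 * 0.04 * 140.0
    if disc < 0:
        raise ValueError("parameters have no subthreshold resting point")
    v = (-(5.0 - b) - np.sqrt(disc)) / (2 * 0.04)
    return NeuronState(v=float(v), u=float(b * v))


def neuron_step(
    state: NeuronState,
    params: NeuronParams,
    input_current: float,
    dt: float = 1.0,
    n_substeps: int = 2,
) -> tuple[NeuronState, bool]:
    """Advance one neuron by one global step of length ``dt`` ms.

    ``input_current`` is the summed synaptic drive (mV) for this step.
    Returns the new state and whether a spike (peak crossing) occurred; the
    after-spike reset is already applied in the returned state.
    """
    if not (np.isfinite(state.v) and np.isfinite(state.u)):
        raise FloatingPointError(
            f"non-finite neuron state v={state.v} u={state.u}"
        )
    v, u = state.v, state.u
    h = dt / n_substeps
    for _ in range(n_substeps):
        if v >= SPIKE_PEAK:
            break
        v = v + h * (0.04 * v * v + 5.0 * v + 140.0 - u + input_current)
    spiked = v >= SPIKE_PEAK
    if spiked:
        v = SPIKE_PEAK  # clamp the overshoot at the peak cutoff
    u = u + dt * params.a * (params.b * v - u)
    if spiked:
        v = params.c
        u = u + params.d
    return NeuronState(v=v, u=u), spiked


def step_population(
    v: np.ndarray,
    u: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    current: np.ndarray,
    dt: float = 1.0,
    n_substeps: int = 2,
) -> np.ndarray:
    """Vectorized population update, in place; returns boolean spike mask.

    The after-spike reset is *not* applied here (the caller owns c/d and the
    spike bookkeeping); ``v`` of spiking neurons is left at/above the peak.
    """
    h = dt / n_substeps
    for _ in range(n_substeps):
        active = v < SPIKE_PEAK
        dv = 0.04 * v * v + 5.0 * v + 140.0 - u + current
        v += np.where(active, h * dv, 0.0)
    spiked = v >= SPIKE_PEAK
    np.minimum(v, SPIKE_PEAK, out=v)  # clamp overshoot before the u update
    u += dt * a * (b * v - u)
    return spiked
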