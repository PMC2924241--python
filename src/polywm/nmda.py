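"""Passive dendritic compartment with voltage-dependent NMDA conductance.

A minimal demonstration of why coincident pre- and postsynaptic activity
flips a dendritic site into a sustained depolarized state (an NMDA-spike
plateau), which the network-level hysteresis synapse abstracts:

* presynaptic spikes increment both an AMPA conductance (fast decay) and an
  NMDA conductance (250 ms decay);
* the NMDA current is gated by the magnesium-block factor B(V), a sigmoid of
  the dendritic membrane potential that is ~0 near rest and ->1 at full
  depolarization;
* a postsynaptic (back-propagating) spike transiently depolarizes the
  compartment, relieving the block; if enough NMDA conductance has
  accumulated, the inward NMDA current then sustains the depolarization on
  its own — a plateau that outlasts the trigger.

The maximal NMDA conductance is chosen so the NMDA:AMPA current ratio at
full depolarization (B = 1) is 9:1, which (together with the baseline EPSP)
corresponds to a 10-fold efficacy of transmission in the up-state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class CompartmentParams:
    c_m: float = 1.0           # membrane capacitance, uF/cm^2
    g_leak: float = 0.1        # leak conductance, mS/cm^2 (tau_m = 10 ms)
    e_leak: float = -70.0      # mV
    e_syn: float = 0.0         # reversal of AMPA and NMDA currents, mV
    g_ampa: float = 0.05       # peak AMPA conductance per spike, mS/cm^2
    nmda_ampa_ratio: float = 9.0   # NMDA:AMPA current ratio at B(V)=1
    tau_ampa: float = 5.0      # ms
    tau_nmda: float = 250.0    # ms
    v_block: float = -60.0     # mV, full magnesium block at/below this potential
    v_unblock: float = 0.0     # mV, block fully relieved at/above this potential
    spike_amp: float = 60.0    # depolarization of a back-propagating spike, mV
    spike_width: float = 2.0   # ms

    @property
    def g_nmda(self) -> float:
        """Peak NMDA conductance per spike: pinned by the 9:1 current ratio."""
        return self.nmda_ampa_ratio * self.g_ampa


def magnesium_block(v, v_block: float = -60.0, v_unblock: float = 0.0):
    """Voltage nonlinearity B(V) of the NMDA conductance.

    Piecewise: B = 0 at or below ``v_block`` (full magnesium block near
    rest), B = 1 at or above ``v_unblock`` (block fully relieved), linear in
    between.  The hard zero below v_block is what makes the compartment
    cleanly bistable: presynaptic input alone produces only small AMPA
    EPSPs, while a coincident postsynaptic depolarization unblocks the
    accumulated NMDA conductance and latches the plateau.
    """
    v = np.asarray(v, dtype=float)
    return np.clip((v - v_block) / (v_unblock - v_block), 0.0, 1.0)


def nmda_ampa_current_ratio(params: CompartmentParams | None = None,
                            v: float | None = None) -> float:
    """I_NMDA / I_AMPA for one coincident unit activation at potential ``v``.

    Both currents share the same reversal, so the driving-force factor
    cancels and the ratio is B(v) * g_nmda / g_ampa.  With ``v`` omitted the
    ratio is evaluated at full depolarization (B = 1), where it equals the
    configured 9.
    """
    p = params or CompartmentParams()
    b = 1.0 if v is None else float(magnesium_block(v, p.v_block, p.v_unblock))
    return float(b * p.g_nmda / p.g_ampa)


def nmda_compartment_demo(
    pre_spike_times,
    post_spike_times,
    params: CompartmentParams | None = None,
    duration: float | None = None,
    dt: float = 0.1,
):
    """Integrate the compartment; returns (time, voltage) arrays.

    ``pre_spike_times`` increment the synaptic conductances;
    ``post_spike_times`` inject the back-propagating depolarization.
    """
    p = params or CompartmentParams()
    pre = np.sort(np.asarray(pre_spike_times, dtype=float))
    post = np.sort(np.asarray(post_spike_times, dtype=float))
    if duration is None:
        last = max(pre[-1] if len(pre) else 0.0, post[-1] if len(post) else 0.0)
        duration = last + 300.0
    n = int(round(duration / dt))
    t = np.arange(n) * dt
    v = np.empty(n)
    v[0] = p.e_leak
    g_a = 0.0
    g_n = 0.0
    dec_a = np.exp(-dt / p.tau_ampa)
    dec_n = np.exp(-dt / p.tau_nmda)
    ip = 0
    vi = p.e_leak
    for i in range(1, n):
        now = t[i]
        while ip < len(pre) and pre[ip] <= now:
            g_a += p.g_ampa
            g_n += p.g_nmda
            ip += 1
        g_a *= dec_a
        g_n *= dec_n
        b = float(magnesium_block(vi, p.v_block, p.v_unblock))
        i_syn = (g_a + g_n * b) * (vi - p.e_syn)
        dv = (-p.g_leak * (vi - p.e_leak) - i_syn) / p.c_m
        vi = vi + dt * dv
        # back-propagating spike: clamp-like depolarizing pulse
        for ts in post:
            if ts <= now < ts + p.spike_width:
                vi = max(vi, p.e_leak + p.spike_amp)
                break
        v[i] = vi
    return t, v
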