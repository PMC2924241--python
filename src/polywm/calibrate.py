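"""Mini-rate calibration: match the background multiunit rate to a target."""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .network import NetworkConfig, build_network
from .plasticity import PlasticityConfig
from .simulator import simulate


def measure_background_rate(config: NetworkConfig, seed: int = 0,
                            duration_ms: float = 20_000.0,
                            plasticity: PlasticityConfig | None = None) -> float:
    """Mean excitatory multiunit rate (Hz) of the network driven only by minis."""
    net = build_network(config, seed=seed)
    res = simulate(net, duration_ms, plasticity=plasticity, seed=seed + 1)
    r = res.raster
    n_exc = int(net.exc.sum())
    return float(np.sum(net.exc[r.neurons]) / (n_exc * duration_ms / 1000.0))


def calibrate_minis(config: NetworkConfig, target_hz: float = 0.3,
                    rate_lo: float = 1.0, rate_hi: float = 30.0,
                    tol: float = 0.02, max_iter: int = 12,
                    seed: int = 0, duration_ms: float = 10_000.0) -> float:
    """Bisect the per-neuron mini rate until the background excitatory rate
    matches ``target_hz`` within ``tol``; returns the calibrated rate.

    The background rate is monotone in the mini rate at fixed amplitude, so
    simple bisection suffices.
    """
    lo, hi = rate_lo, rate_hi
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        r = measure_background_rate(replace(config, mini_rate=mid),
                                    seed=seed, duration_ms=duration_ms)
        if abs(r - target_hz) <= tol:
            return mid
        if r < target_hz:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
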