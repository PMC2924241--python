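"""Spike-train analysis: rates, ISI variability, cross-correlograms,
working-memory duration and capacity summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import SpikeRaster


@dataclass
class RateCurve:
    edges: np.ndarray   # bin edges, ms
    rate: np.ndarray    # Hz, averaged over the subset

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def multiunit_rate(raster: SpikeRaster, subset, bin_ms: float = 100.0) -> RateCurve:
    """Population-averaged firing rate of ``subset`` in Hz per bin."""
    subset = np.asarray(subset)
    if subset.size == 0:
        raise ValueError("subset is empty")
    edges = np.arange(0.0, raster.duration + bin_ms, bin_ms)
    mask = np.isin(raster.neurons, subset)
    counts, _ = np.histogram(raster.times[mask], bins=edges)
    rate = counts / (subset.size * bin_ms / 1000.0)
    return RateCurve(edges=edges, rate=rate)


def mean_rate(raster: SpikeRaster, subset, t0: float = 0.0,
              t1: float | None = None) -> float:
    """Mean rate (Hz) of ``subset`` over [t0, t1)."""
    subset = np.asarray(subset)
    t1 = raster.duration if t1 is None else t1
    mask = np.isin(raster.neurons, subset) & (raster.times >= t0) & (raster.times < t1)
    return float(np.sum(mask) / (subset.size * (t1 - t0) / 1000.0))


def isi_cv(train) -> float:
    """Coefficient of variation of interspike intervals: std(ISI)/mean(ISI)."""
    train = np.sort(np.asarray(train, dtype=float))
    if len(train) < 3:
        raise ValueError("CV needs at least 3 spikes")
    isi = np.diff(train)
    return float(np.std(isi) / np.mean(isi))


def isi_cv2(train) -> float:
    """Local coefficient of variation: mean of 2|ISI_{i+1}-ISI_i|/(ISI_{i+1}+ISI_i).

    CV2 compares each interval only to its successor, so it is far less
    inflated than CV by slow nonstationarity of the firing rate.
    """
    train = np.sort(np.asarray(train, dtype=float))
    if len(train) < 3:
        raise ValueError("CV2 needs at least 3 spikes")
    isi = np.diff(train)
    pairs = 2.0 * np.abs(isi[1:] - isi[:-1]) / (isi[1:] + isi[:-1])
    return float(np.mean(pairs))


@dataclass
class CVStats:
    neurons: np.ndarray
    cv: np.ndarray
    cv2: np.ndarray


def population_cv(raster: SpikeRaster, subset, t0: float = 0.0,
                  t1: float | None = None, min_spikes: int = 3) -> CVStats:
    """Per-neuron CV and CV2 over [t0, t1); neurons with too few spikes are
    skipped."""
    t1 = raster.duration if t1 is None else t1
    ids, cvs, cv2s = [], [], []
    by = raster.window(t0, t1).by_neuron()
    for n in np.asarray(subset):
        train = by.get(int(n))
        if train is None or len(train) < min_spikes:
            continue
        ids.append(int(n))
        cvs.append(isi_cv(train))
        cv2s.append(isi_cv2(train))
    return CVStats(np.asarray(ids), np.asarray(cvs), np.asarray(cv2s))


@dataclass
class CCG:
    lags: np.ndarray     # bin centers, ms
    counts: np.ndarray   # per reference spike


def cross_correlogram(train_a, train_b, max_lag: float = 50.0,
                      bin_ms: float = 1.0) -> CCG:
    """Counts of (b - a) lag differences within +-max_lag, per a-spike."""
    a = np.sort(np.asarray(train_a, dtype=float))
    b = np.sort(np.asarray(train_b, dtype=float))
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both trains must be nonempty")
    edges = np.arange(-max_lag, max_lag + bin_ms, bin_ms)
    counts = np.zeros(len(edges) - 1)
    for t in a:
        lo = np.searchsorted(b, t - max_lag)
        hi = np.searchsorted(b, t + max_lag)
        counts += np.histogram(b[lo:hi] - t, bins=edges)[0]
    return CCG(lags=0.5 * (edges[:-1] + edges[1:]), counts=counts / len(a))


def wm_duration(events, stim_offset: float) -> float:
    """Time of the last reactivation after the stimulation offset, in ms.

    Returns 0.0 when no reactivation followed the cue.
    """
    onsets = [e.onset for e in events if e.onset >= stim_offset]
    return float(max(onsets) - stim_offset) if onsets else 0.0


def capacity_curve(maintained_by_load: dict[int, list[bool]]) -> tuple[np.ndarray, np.ndarray]:
    """Mean number of maintained items per load k -> (loads, held)."""
    loads = np.array(sorted(maintained_by_load))
    held = np.array([float(np.sum(maintained_by_load[k])) for k in loads])
    return loads, held
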