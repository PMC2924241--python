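"""Spike rasters: the universal exchange object for all experiments.

A raster is a time-ordered list of (time_ms, neuron_id) events with a known
duration and population size.  On disk it is a two-column tab-separated text
file with ``#``-prefixed header lines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class SpikeRaster:
    times: np.ndarray    # float64 ms, nondecreasing
    neurons: np.ndarray  # int32 neuron ids
    duration: float      # ms
    n_neurons: int

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.float64)
        self.neurons = np.asarray(self.neurons, dtype=np.int32)
        if len(self.times) != len(self.neurons):
            raise ValueError("times and neurons must have equal length")
        if len(self.times) and np.any(np.diff(self.times) < 0):
            raise ValueError("raster times must be nondecreasing")
        if len(self.neurons) and self.neurons.max() >= self.n_neurons:
            raise ValueError("neuron id out of range")

    def __len__(self) -> int:
        return len(self.times)

    def spike_train(self, neuron: int) -> np.ndarray:
        """Sorted spike times of one neuron."""
        return self.times[self.neurons == neuron]

    def subset(self, neurons) -> "SpikeRaster":
        mask = np.isin(self.neurons, np.asarray(neurons))
        return SpikeRaster(self.times[mask], self.neurons[mask],
                           self.duration, self.n_neurons)

    def window(self, t0: float, t1: float) -> "SpikeRaster":
        """Events with t0 <= t < t1, times re-referenced to t0."""
        mask = (self.times >= t0) & (self.times < t1)
        return SpikeRaster(self.times[mask] - t0, self.neurons[mask],
                           t1 - t0, self.n_neurons)

    def by_neuron(self) -> dict[int, np.ndarray]:
        """Mapping neuron id -> sorted spike-time array (spiking neurons only)."""
        order = np.argsort(self.neurons, kind="stable")
        ns, ts = self.neurons[order], self.times[order]
        out: dict[int, np.ndarray] = {}
        if len(ns) == 0:
            return out
        bounds = np.flatnonzero(np.diff(ns)) + 1
        for chunk_n, chunk_t in zip(np.split(ns, bounds), np.split(ts, bounds)):
            out[int(chunk_n[0])] = np.sort(chunk_t)
        return out


def write_raster(raster: SpikeRaster, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# polywm raster\tduration_ms={raster.duration:g}"
                 f"\tn_neurons={raster.n_neurons}\n")
        fh.write("# time_ms\tneuron_id\n")
        for t, n in zip(raster.times, raster.neurons):
            fh.write(f"{t:.10g}\t{n}\n")


def read_raster(path, n_neurons: int | None = None) -> SpikeRaster:
    """Read a tab-separated raster; unsorted input is sorted with a warning."""
    times, neurons = [], []
    duration = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split("\t"):
                    tok = tok.strip()
                    if tok.startswith("duration_ms="):
                        duration = float(tok.split("=", 1)[1])
                    elif tok.startswith("n_neurons=") and n_neurons is None:
                        n_neurons = int(tok.split("=", 1)[1])
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated "
                                 f"columns, got {len(parts)}")
            try:
                times.append(float(parts[0]))
                neurons.append(int(parts[1]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed line: {line!r}") from exc
    times = np.asarray(times, dtype=np.float64)
    neurons = np.asarray(neurons, dtype=np.int32)
    if len(times) and np.any(np.diff(times) < 0):
        warnings.warn(f"{path}: raster not time-sorted; sorting on read")
        order = np.argsort(times, kind="stable")
        times, neurons = times[order], neurons[order]
    if duration is None:
        duration = float(times[-1]) + 1.0 if len(times) else 0.0
    if n_neurons is None:
        n_neurons = int(neurons.max()) + 1 if len(neurons) else 0
    return SpikeRaster(times, neurons, duration, n_neurons)
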