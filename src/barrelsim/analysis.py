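"""Spike-train statistics: mean rates, peristimulus time histograms, windowed counts.

All windows are half-open ``[start, end)`` on 0-based millisecond
timestamps. PSTH normalisation is per neuron, per alignment and per second:
``rate = count / (n_neurons * n_alignments * bin_width_s)``, so the PSTH
integral times (neurons x alignments) recovers the in-window event count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np

from .core import InvalidParameterError
from .records import SpikeRecord

__all__ = ["PSTH", "CountMap", "mean_rate", "psth", "window_counts"]


@dataclass
class PSTH:
    """Trial-averaged, stimulus-aligned firing-rate estimate (Hz per neuron)."""

    bin_edges: np.ndarray       # ms, uniform width, relative to alignment
    rate: np.ndarray            # Hz per neuron, one entry per bin
    population: str
    n_neurons: int
    n_alignments: int

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def total_events(self) -> float:
        """Invert the normalisation: integral * neurons * alignments = event count."""
        return float(self.rate.sum() * (self.bin_width / 1000.0)
                     * self.n_neurons * self.n_alignments)


@dataclass
class CountMap:
    """Per-neuron spike counts over a union of windows (global-id indexed)."""

    counts: np.ndarray          # int64, length = global index space
    windows: Tuple[Tuple[float, float], ...]
    populations: Tuple

    def for_population(self, name: str) -> np.ndarray:
        for pname, start, size in self.populations:
            if pname == name:
                return self.counts[start:start + size]
        raise KeyError(f"unknown population {name!r}")

    def total(self) -> int:
        return int(self.counts.sum())


def mean_rate(record: SpikeRecord, population: str,
              window: Tuple[float, float]) -> float:
    """Population mean firing rate (Hz) over a half-open window."""
    t0, t1 = window
    if not t1 > t0:
        raise InvalidParameterError(f"empty window [{t0}, {t1})")
    start, size = record.population_slice(population)
    if size <= 0:
        raise InvalidParameterError(f"population {population!r} is empty")
    in_pop = (record.ids >= start) & (record.ids < start + size)
    in_win = (record.times >= t0) & (record.times < t1)
    n = int(np.count_nonzero(in_pop & in_win))
    return n / (size * (t1 - t0) / 1000.0)


def psth(records: Union[SpikeRecord, Sequence[SpikeRecord]], population: str,
         align_times: Sequence[float], bin_width: float = 5.0,
         window: Tuple[float, float] = (-100.0, 300.0)) -> PSTH:
    """Stimulus-aligned PSTH pooled over records and alignment times.

    Events are re-referenced to each alignment time (the same alignment
    times are applied to every record), binned on ``window`` and normalised
    per neuron, per alignment and per second.
    """
    if isinstance(records, SpikeRecord):
        records = [records]
    align_times = list(align_times)
    if not align_times:
        raise InvalidParameterError("at least one alignment time is required")
    if bin_width <= 0:
        raise InvalidParameterError("bin_width must be positive")
    lo, hi = window
    if not hi > lo:
        raise InvalidParameterError(f"empty PSTH window [{lo}, {hi})")
    n_bins = int(np.ceil((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts = np.zeros(n_bins)
    start, size = records[0].population_slice(population)
    for rec in records:
        in_pop = (rec.ids >= start) & (rec.ids < start + size)
        t = rec.times[in_pop]
        for a in align_times:
            rel = t - a
            sel = (rel >= lo) & (rel < edges[-1])
            counts += np.bincount(((rel[sel] - lo) // bin_width).astype(np.int64),
                                  minlength=n_bins)
    n_align = len(align_times) * len(records)
    rate = counts / (size * n_align * bin_width / 1000.0)
    return PSTH(edges, rate, population, size, n_align)


def window_counts(record: SpikeRecord, onset_times: Sequence[float],
                  width: float = 25.0) -> CountMap:
    """Per-neuron spike counts over the union of ``[onset, onset + width)`` windows.

    The count map covers the whole global index space of the record; windows
    are half-open, so an event at exactly onset + width is excluded.
    """
    n = sum(size for _, _, size in record.populations)
    counts = np.zeros(n, dtype=np.int64)
    span = float(record.duration)
    windows = []
    for onset in onset_times:
        if onset < 0 or onset > span:
            raise InvalidParameterError(f"onset {onset} outside the record span [0, {span}]")
        windows.append((float(onset), float(onset) + width))
        sel = (record.times >= onset) & (record.times < onset + width)
        if np.any(sel):
            counts += np.bincount(record.ids[sel], minlength=n)
    return CountMap(counts, tuple(windows), record.populations)
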