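"""Spike records: time-ordered (time, neuron) events with a population index map.

A :class:`SpikeRecord` is the universal currency of the package — the output
of the simulation engine and of the thalamic spike generator, and the input
to every analysis. Events are stored as parallel numpy arrays sorted by
time then neuron id; neuron ids are *global* indices into the model's
contiguous index space, decoded through the attached population map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np

__all__ = ["PopulationEntry", "SpikeRecord"]


#: (name, first global id, size)
PopulationEntry = Tuple[str, int, int]


@dataclass
class SpikeRecord:
    times: np.ndarray          # float64 ms, non-decreasing, within [0, duration]
    ids: np.ndarray            # int32 global neuron ids
    duration: float            # ms
    dt: float = 1.0            # ms
    populations: Tuple[PopulationEntry, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.ids = np.asarray(self.ids, dtype=np.int32)
        if self.times.shape != self.ids.shape:
            raise ValueError("times and ids must be parallel arrays")
        if self.times.size:
            if np.any(np.diff(self.times) < 0):
                raise ValueError("spike times must be non-decreasing")
            if self.times[0] < 0 or self.times[-1] > self.duration:
                raise ValueError("spike times must lie within [0, duration]")
        self.populations = tuple(self.populations)

    def __len__(self) -> int:
        return int(self.times.size)

    # -- population decoding ------------------------------------------------

    def population_slice(self, name: str) -> Tuple[int, int]:
        """(first global id, size) of a named population."""
        for pname, start, size in self.populations:
            if pname == name:
                return start, size
        raise KeyError(f"unknown population {name!r}")

    def population_of(self, global_id: int) -> str:
        for pname, start, size in self.populations:
            if start <= global_id < start + size:
                return pname
        raise KeyError(f"global id {global_id} outside every population")

    def for_population(self, name: str) -> "SpikeRecord":
        """Events restricted to one population (ids stay global)."""
        start, size = self.population_slice(name)
        mask = (self.ids >= start) & (self.ids < start + size)
        return SpikeRecord(self.times[mask], self.ids[mask], self.duration,
                           self.dt, self.populations)

    def counts_per_population(self) -> dict:
        out = {}
        for pname, start, size in self.populations:
            out[pname] = int(np.count_nonzero((self.ids >= start) & (self.ids < start + size)))
        return out

    # -- construction helpers ----------------------------------------------

    @staticmethod
    def from_events(times: np.ndarray, ids: np.ndarray, duration: float,
                    populations: Sequence[PopulationEntry], dt: float = 1.0) -> "SpikeRecord":
        """Sort (time, id) lexicographically and wrap in a record."""
        times = np.asarray(times, dtype=np.float64)
        ids = np.asarray(ids, dtype=np.int32)
        order = np.lexsort((ids, times))
        return SpikeRecord(times[order], ids[order], duration, dt, tuple(populations))

    @staticmethod
    def empty(duration: float, populations: Sequence[PopulationEntry] = (),
              dt: float = 1.0) -> "SpikeRecord":
        return SpikeRecord(np.empty(0), np.empty(0, dtype=np.int32), duration, dt,
                           tuple(populations))
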