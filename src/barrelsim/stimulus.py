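"""Thalamic drive: inhomogeneous Poisson sources with piecewise-linear rate profiles.

Thalamic relay cells are modelled as independent Poisson spike trains. At
rest they fire at 6 Hz; a whisker-deflection *onset* transiently ramps the
rate from 6 to 30 Hz in 5 ms and back down in 30 ms, and an *offset* is the
mirror-image triangle (30-ms rise, 5-ms fall) of equal amplitude — the two
stimuli differ only in their rate of onset. Deflections are organised into
stimulus *batteries*: a 500-ms rest period followed by one onset/offset pair
(separated by 150 ms), or by five onset+offset repetitions at 10 Hz for the
multi-column protocol.

Spikes are drawn by Bernoulli thinning on the 1-ms simulation grid: each
source emits at most one spike per bin with probability rate(t) * dt. At the
30-Hz peak that probability is 0.03, so the thinning bias relative to exact
exponential waiting times is negligible, and the scheme matches the clocked
1-ms delivery of the simulation engine exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .core import InvalidParameterError, as_seed_sequence
from .records import PopulationEntry, SpikeRecord

__all__ = [
    "RateProfile",
    "StimulusSchedule",
    "PoissonSourceArray",
    "triangle",
    "battery_single",
    "battery_chain",
    "schedule_to_profile",
    "generate_spikes",
    "thalamic_drive",
    "BASE_RATE",
    "PEAK_RATE",
    "ONSET_RISE",
    "ONSET_FALL",
    "REST_PERIOD",
]

BASE_RATE = 6.0      # Hz, spontaneous thalamic rate
PEAK_RATE = 30.0     # Hz, deflection-evoked peak
ONSET_RISE = 5.0     # ms (offset stimuli mirror these)
ONSET_FALL = 30.0    # ms
REST_PERIOD = 500.0  # ms preceding each battery


@dataclass
class RateProfile:
    """Instantaneous rate (Hz) sampled at 1-ms resolution on [0, duration)."""

    rates: np.ndarray
    params: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=np.float64)
        if np.any(self.rates < 0):
            raise InvalidParameterError("rates must be non-negative")

    @property
    def duration(self) -> float:
        return float(self.rates.size)

    @staticmethod
    def constant(rate: float, duration: float) -> "RateProfile":
        if rate < 0:
            raise InvalidParameterError("rate must be non-negative")
        return RateProfile(np.full(int(round(duration)), float(rate)),
                           {"kind": "constant", "rate": rate})


def triangle(base: float, peak: float, rise: float, fall: float, t0: float,
             duration: Optional[float] = None) -> RateProfile:
    """Triangular rate excursion: base -> peak over ``rise`` ms, back over ``fall`` ms.

    Linear from ``base`` at t0 to ``peak`` at t0+rise, then linear back to
    ``base`` at t0+rise+fall; equal to ``base`` elsewhere. ``duration``
    defaults to the end of the triangle.
    """
    if not (peak >= base >= 0):
        raise InvalidParameterError("need peak >= base >= 0")
    if rise <= 0 or fall <= 0:
        raise InvalidParameterError("rise and fall must be positive")
    if duration is None:
        duration = t0 + rise + fall
    t = np.arange(int(round(duration)), dtype=np.float64)
    rates = np.full(t.size, float(base))
    up = (t >= t0) & (t <= t0 + rise)
    down = (t > t0 + rise) & (t <= t0 + rise + fall)
    rates[up] = base + (peak - base) * (t[up] - t0) / rise
    rates[down] = peak - (peak - base) * (t[down] - t0 - rise) / fall
    return RateProfile(rates, {"kind": "triangle", "base": base, "peak": peak,
                               "rise": rise, "fall": fall, "t0": t0})


@dataclass(frozen=True)
class StimulusSchedule:
    """Time-ordered deflection events plus battery timing metadata."""

    events: Tuple[Tuple[str, float], ...]   # (kind "onset"|"offset", start ms)
    rest: float = REST_PERIOD
    metadata: Tuple[Tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        times = [t for _, t in self.events]
        if times != sorted(times):
            raise InvalidParameterError("schedule events must be time-ordered")

    def onsets(self) -> Tuple[float, ...]:
        return tuple(t for kind, t in self.events if kind == "onset")

    def offsets(self) -> Tuple[float, ...]:
        return tuple(t for kind, t in self.events if kind == "offset")


def battery_single(t0: float = 0.0) -> StimulusSchedule:
    """One battery: 500-ms rest, then an onset and an offset 150 ms apart."""
    if t0 < 0:
        raise InvalidParameterError("t0 must be non-negative")
    return StimulusSchedule(
        events=(("onset", t0 + REST_PERIOD), ("offset", t0 + REST_PERIOD + 150.0)),
        metadata=(("separation", 150.0),),
    )


def battery_chain(t0: float = 0.0, n_reps: int = 5, period: float = 100.0,
                  lag: float = 50.0) -> StimulusSchedule:
    """One multi-column battery: rest, then ``n_reps`` onset/offset pairs at 10 Hz.

    Repetition k starts at t0 + rest + k*period; the offset follows its
    onset by ``lag`` ms (half the repetition period, so events are evenly
    interleaved).
    """
    if t0 < 0:
        raise InvalidParameterError("t0 must be non-negative")
    events = []
    for k in range(n_reps):
        start = t0 + REST_PERIOD + k * period
        events.append(("onset", start))
        events.append(("offset", start + lag))
    return StimulusSchedule(events=tuple(events),
                            metadata=(("period", period), ("lag", lag),
                                      ("n_reps", float(n_reps))))


def schedule_to_profile(schedule: StimulusSchedule, duration: float,
                        base: float = BASE_RATE, peak: float = PEAK_RATE) -> RateProfile:
    """Render a schedule as one rate profile.

    Onset events place a (rise 5 ms, fall 30 ms) triangle, offsets the
    mirrored (30, 5) one. Where excursions could overlap the rate is the
    maximum of the active profiles (never a sum); with the standard timings
    triangles never overlap.
    """
    rates = np.full(int(round(duration)), float(base))
    for kind, t in schedule.events:
        rise, fall = (ONSET_RISE, ONSET_FALL) if kind == "onset" else (ONSET_FALL, ONSET_RISE)
        tri = triangle(base, peak, rise, fall, t, duration)
        np.maximum(rates, tri.rates, out=rates)
    return RateProfile(rates, {"kind": "schedule", "base": base, "peak": peak})


@dataclass(frozen=True)
class PoissonSourceArray:
    """``n_sources`` mutually independent Poisson sources sharing one profile."""

    n_sources: int
    profile: RateProfile
    seed: object = 0

    def __post_init__(self) -> None:
        if self.n_sources <= 0:
            raise InvalidParameterError("n_sources must be positive")


def generate_spikes(sources: PoissonSourceArray, duration: Optional[float] = None,
                    dt: float = 1.0, first_id: int = 0,
                    populations: Sequence[PopulationEntry] = ()) -> SpikeRecord:
    """Draw spikes by Bernoulli thinning on the 1-ms grid.

    Per source and per bin, a spike is emitted with probability
    rate(t) * dt; identical seeds give identical records. Source k receives
    global id ``first_id + k``; ``populations`` (if given) is attached to
    the record for decoding.
    """
    if duration is None:
        duration = sources.profile.duration
    n_bins = int(round(duration / dt))
    rates = sources.profile.rates
    if rates.size < n_bins:
        raise InvalidParameterError("rate profile shorter than requested duration")
    p = rates[:n_bins] * (dt / 1000.0)
    if np.any(p >= 1.0):
        raise InvalidParameterError("rate * dt must stay below 1 everywhere")
    rng = np.random.default_rng(sources.seed)
    hit = rng.random((n_bins, sources.n_sources)) < p[:, None]
    t_idx, s_idx = np.nonzero(hit)
    if not populations:
        populations = (("sources", first_id, sources.n_sources),)
    return SpikeRecord.from_events(t_idx * dt, s_idx + first_id, duration,
                                   populations, dt)


def thalamic_drive(model, duration: float, seed,
                   profiles: Optional[Dict[str, RateProfile]] = None,
                   base: float = BASE_RATE) -> SpikeRecord:
    """Drive for every source population of a model, merged into one record.

    ``profiles`` maps population names to rate profiles; unlisted source
    populations fire at the constant ``base`` rate. One independent
    generator seed is spawned per source population, so a population's
    realisation does not depend on which others are modulated.
    """
    sources = model.source_populations()
    seeds = as_seed_sequence(seed).spawn(len(sources))
    entries = model.population_entries()
    times, ids = [], []
    for pop, s in zip(sources, seeds):
        profile = (profiles or {}).get(pop.name) or RateProfile.constant(base, duration)
        rec = generate_spikes(PoissonSourceArray(pop.size, profile, s),
                              duration=duration, first_id=model.offset(pop.name),
                              populations=entries)
        times.append(rec.times)
        ids.append(rec.ids)
    if not times:
        return SpikeRecord.empty(duration, entries)
    return SpikeRecord.from_events(np.concatenate(times), np.concatenate(ids),
                                   duration, entries)
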