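"""The three experimental protocols: balance sweep, response transformation, chain.

Each protocol is a reproducible pipeline over the builder, stimulus and
engine modules, seeded from one master seed that is split into
connectivity, calibration and per-trial stimulus seeds. Protocols that
depend on the thalamocortical weight calibrate it first (pass ``w_tc`` to
reuse a previously calibrated value).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .analysis import PSTH, CountMap, mean_rate, psth, window_counts
from .core import InvalidParameterError, as_seed_sequence
from .engine import SimConfig, run, run_trials
from .network import NetworkModel, build_barrel, build_chain, calibrate_tc_weight
from .records import SpikeRecord
from .stimulus import (BASE_RATE, RateProfile, battery_chain, battery_single,
                       schedule_to_profile, thalamic_drive)

__all__ = [
    "SweepResult",
    "TransformationResult",
    "ChainResult",
    "balance_sweep",
    "response_transformation",
    "chain_experiment",
    "is_evoked",
    "default_b_grid",
    "BATTERY_RUN_MS",
    "CHAIN_RUN_MS",
]

logger = logging.getLogger("barrelsim")

#: Run length for one single-deflection battery: 500-ms rest, onset at 500,
#: offset at 650, offset ramp ends at 685, plus response tail.
BATTERY_RUN_MS = 800.0

#: Run length for one multi-column battery: 500-ms rest plus five
#: onset/offset repetitions at 10 Hz (last offset ramp ends at 985 ms).
CHAIN_RUN_MS = 1000.0


def default_b_grid(n: int = 25, lo: float = 0.1, hi: float = 10.0) -> np.ndarray:
    """Logarithmically spaced balance coefficients resolving the b = 1 transition."""
    return np.geomspace(lo, hi, n)


def _resolve_w_tc(w_tc: Optional[float], seed, scale: float) -> float:
    if w_tc is not None and w_tc > 0:
        return float(w_tc)
    logger.info("calibrating thalamocortical weight (scale=%g)", scale)
    w = calibrate_tc_weight(BASE_RATE, seed=seed, scale=scale)
    logger.info("calibrated thalamocortical weight: %.6f nA", w)
    return w


# -- 1. balance-coefficient sweep -------------------------------------------

@dataclass
class SweepResult:
    """Mean and sd of the L4 excitatory rate per balance coefficient."""

    table: pd.DataFrame                    # columns: b, mean_rate_hz, sd_rate_hz
    trial_rates: Dict[float, np.ndarray]   # per-b per-trial rates
    w_tc: float


def balance_sweep(b_grid: Optional[Sequence[float]] = None, n_trials: int = 10,
                  duration: float = 1000.0, seed=0, scale: float = 1.0,
                  w_tc: Optional[float] = None,
                  i2e_scale: float = 1.0) -> SweepResult:
    """Sweep the balance coefficient under constant 6-Hz thalamic drive.

    For each b the barrel is rebuilt with the same connectivity seed (only
    the inhibitory weight changes) and simulated ``n_trials`` times with
    fresh Poisson seeds; the row reports mean and sd over trials of the
    L4E rate during each run.
    """
    if b_grid is None:
        b_grid = default_b_grid()
    b_grid = np.asarray(b_grid, dtype=float)
    if np.any(b_grid <= 0):
        raise InvalidParameterError("balance coefficients must be positive")
    conn_seed, calib_seed, stim_seed = as_seed_sequence(seed).spawn(3)
    w = _resolve_w_tc(w_tc, calib_seed, scale)
    config = SimConfig(duration=duration)
    per_b_seeds = stim_seed.spawn(len(b_grid))
    rows = []
    trial_rates: Dict[float, np.ndarray] = {}
    for j, b in enumerate(b_grid):
        model = build_barrel(b=float(b), i2e_scale=i2e_scale, w_tc=w,
                             seed=conn_seed, scale=scale)
        records = run_trials(
            model,
            lambda s: thalamic_drive(model, duration, s),
            n_trials, config, base_seed=per_b_seeds[j],
        )
        rates = np.array([mean_rate(r, "L4E", (0.0, duration)) for r in records])
        trial_rates[float(b)] = rates
        rows.append((float(b), rates.mean(), rates.std(ddof=1) if n_trials > 1 else 0.0))
        logger.info("sweep b=%.3f: %.2f +/- %.2f Hz", b, rows[-1][1], rows[-1][2])
    table = pd.DataFrame(rows, columns=["b", "mean_rate_hz", "sd_rate_hz"])
    return SweepResult(table, trial_rates, w)


# -- 2. thalamocortical response transformation ------------------------------

@dataclass
class TransformationResult:
    """Per-(instance, battery) records plus pooled and per-instance PSTHs."""

    records: List[List[SpikeRecord]]
    pooled_psths: Dict[str, PSTH]
    instance_psths: List[PSTH]             # L4E, pooled within each instance
    summary: pd.DataFrame                  # per instance: rates and peaks
    w_tc: float
    onset_time: float = 500.0
    offset_time: float = 650.0


def response_transformation(n_models: int = 10, n_batteries: int = 25, seed=0,
                            scale: float = 1.0, w_tc: Optional[float] = None,
                            b: float = 1.0, i2e_scale: float = 1.5,
                            bin_width: float = 5.0) -> TransformationResult:
    """Deliver single-deflection batteries to independently built barrels.

    Each battery is simulated as an independent 800-ms run with a fresh
    Poisson seed (the 500-ms rest washes out transients, so this is
    equivalent to concatenation). Summary statistics per instance: the
    spontaneous L4E rate (100-500 ms, skipping the initial transient) and
    the peak PSTH rate in the 60 ms after deflection onset and offset.
    """
    if n_models < 1 or n_batteries < 1:
        raise InvalidParameterError("instance and battery counts must be >= 1")
    seeds = as_seed_sequence(seed).spawn(2 + n_models)
    calib_seed, conn_root = seeds[0], seeds[1]
    conn_seeds = conn_root.spawn(n_models)
    w = _resolve_w_tc(w_tc, calib_seed, scale)
    schedule = battery_single(0.0)
    profile = schedule_to_profile(schedule, BATTERY_RUN_MS)
    config = SimConfig(duration=BATTERY_RUN_MS, include_stimulus_in_record=True)
    onset, offset = schedule.onsets()[0], schedule.offsets()[0]

    all_records: List[List[SpikeRecord]] = []
    instance_psths: List[PSTH] = []
    rows = []
    for m in range(n_models):
        model = build_barrel(b=b, i2e_scale=i2e_scale, w_tc=w,
                             seed=conn_seeds[m], scale=scale)
        records = run_trials(
            model,
            lambda s: thalamic_drive(model, BATTERY_RUN_MS, s,
                                     profiles={"thalamus": profile}),
            n_batteries, config, base_seed=seeds[2 + m],
        )
        all_records.append(records)
        inst = psth(records, "L4E", [0.0], bin_width, (0.0, BATTERY_RUN_MS))
        instance_psths.append(inst)
        spont = float(np.mean([mean_rate(r, "L4E", (100.0, onset)) for r in records]))
        rows.append((m, spont,
                     _peak(inst, onset, onset + 60.0),
                     _peak(inst, offset, offset + 60.0)))
    flat = [r for recs in all_records for r in recs]
    pooled = {
        name: psth(flat, name, [0.0], bin_width, (0.0, BATTERY_RUN_MS))
        for name in ("thalamus", "L4E", "L4I")
    }
    summary = pd.DataFrame(rows, columns=["instance", "spontaneous_hz",
                                          "onset_peak_hz", "offset_peak_hz"])
    return TransformationResult(all_records, pooled, instance_psths, summary, w)


def _peak(p: PSTH, t0: float, t1: float) -> float:
    sel = (p.centers >= t0) & (p.centers < t1)
    return float(p.rate[sel].max()) if np.any(sel) else 0.0


# -- 3. lateral propagation through a chain of columns -----------------------

@dataclass
class ChainResult:
    """Battery-aligned PSTHs per population and per-cell post-onset counts."""

    psths: Dict[str, PSTH]
    counts: CountMap                       # summed over all deflection onsets
    onsets: Tuple[float, ...]              # within one battery
    records: List[SpikeRecord]
    w_tc: float
    n_columns: int

    def supragranular_counts(self) -> List[int]:
        """Total L2/3E post-onset spike count per column, proximal to distal."""
        return [int(self.counts.for_population(f"c{k}:L23E").sum())
                for k in range(self.n_columns)]


def chain_experiment(n_columns: int = 5, n_batteries: int = 5, seed=0,
                     scale: float = 1.0, w_tc: Optional[float] = None,
                     b: float = 1.0, i2e_scale: float = 1.5,
                     bin_width: float = 5.0,
                     model: Optional[NetworkModel] = None) -> ChainResult:
    """Drive column 0 of a chain with deflection batteries, the rest at baseline.

    Each battery (500-ms rest + five onset/offset repetitions at 10 Hz) is
    an independent 1-s run. Only column 0's thalamus is modulated; all other
    barreloids fire at the constant 6-Hz baseline. Outputs battery-aligned
    PSTHs for every population and per-cell spike counts summed over 25-ms
    windows following every deflection onset.
    """
    if n_columns < 2:
        raise InvalidParameterError("the chain protocol needs at least two columns")
    conn_seed, calib_seed, stim_seed = as_seed_sequence(seed).spawn(3)
    if model is None:
        w = _resolve_w_tc(w_tc, calib_seed, scale)
        model = build_chain(n_columns=n_columns, b=b, i2e_scale=i2e_scale, w_tc=w,
                            seed=conn_seed, scale=scale)
    else:
        # reuse a prebuilt chain realisation; its provenance wins
        n_columns = int(model.provenance.get("n_columns", n_columns))
        w = float(model.provenance.get("w_tc", w_tc or 0.0))
    schedule = battery_chain(0.0)
    profile = schedule_to_profile(schedule, CHAIN_RUN_MS)
    config = SimConfig(duration=CHAIN_RUN_MS, include_stimulus_in_record=True)
    records = run_trials(
        model,
        lambda s: thalamic_drive(model, CHAIN_RUN_MS, s,
                                 profiles={"c0:thalamus": profile}),
        n_batteries, config, base_seed=stim_seed,
    )
    onsets = schedule.onsets()
    counts = np.zeros(model.n_total, dtype=np.int64)
    for rec in records:
        counts += window_counts(rec, onsets, 25.0).counts
    count_map = CountMap(counts, tuple((t, t + 25.0) for t in onsets),
                         model.population_entries())
    psths = {
        p.name: psth(records, p.name, [0.0], bin_width, (0.0, CHAIN_RUN_MS))
        for p in model.populations
    }
    return ChainResult(psths, count_map, onsets, records, w, n_columns)


def is_evoked(p: PSTH, baseline: Tuple[float, float] = (0.0, 500.0),
              response: Tuple[float, float] = (500.0, 1000.0),
              n_sd: float = 3.0, min_consecutive: int = 2) -> bool:
    """Detect an evoked response in a stimulus-aligned PSTH.

    The response window must exceed the baseline mean by ``n_sd`` baseline
    standard deviations in at least ``min_consecutive`` consecutive bins.
    A genuine deflection response outlasts several 5-ms bins, while
    isolated single-bin exceedances occur by chance in ~1 in 8 null PSTHs
    of this length, so requiring two consecutive bins suppresses false
    positives without biasing against real responses.
    """
    base_sel = (p.centers >= baseline[0]) & (p.centers < baseline[1])
    resp_sel = (p.centers >= response[0]) & (p.centers < response[1])
    base = p.rate[base_sel]
    threshold = base.mean() + n_sd * base.std(ddof=1)
    above = p.rate[resp_sel] > threshold
    run_len = 0
    for flag in above:
        run_len = run_len + 1 if flag else 0
        if run_len >= min_consecutive:
            return True
    return False
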