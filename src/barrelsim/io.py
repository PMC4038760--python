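"""File formats: spike records, flat key-value configs, tables and run manifests.

Spike files are self-describing plain text::

    # barrelsim spikes v1
    # duration_ms 1000
    # dt_ms 1
    # population thalamus 0 285
    # population L4E 285 3471
    500<TAB>312
    ...

Header lines are prefixed ``#``; events follow, one per line as
``time_ms<TAB>neuron_id`` sorted by time then id. Writing then reading a
record reproduces it exactly.

The configuration format is flat ``key = value`` text (``#`` comments);
:func:`default_config` documents every key with the standard model values.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, Union

import numpy as np
import pandas as pd

from .records import SpikeRecord

__all__ = [
    "ParseError",
    "FormatError",
    "read_spikes",
    "write_spikes",
    "default_config",
    "load_config",
    "write_config",
    "write_manifest",
    "write_table",
]

_MAGIC = "# barrelsim spikes v1"


class ParseError(ValueError):
    """A malformed line in a spike or config file (carries the line number)."""


class FormatError(ValueError):
    """A structurally invalid spike file (e.g. unsorted event times)."""


def _fmt_time(t: float) -> str:
    return str(int(t)) if float(t).is_integer() else f"{t:.3f}"


def write_spikes(record: SpikeRecord, path: Union[str, os.PathLike]) -> None:
    with open(path, "w") as fh:
        fh.write(_MAGIC + "\n")
        fh.write(f"# duration_ms {_fmt_time(record.duration)}\n")
        fh.write(f"# dt_ms {_fmt_time(record.dt)}\n")
        for name, start, size in record.populations:
            fh.write(f"# population {name} {start} {size}\n")
        for t, i in zip(record.times, record.ids):
            fh.write(f"{_fmt_time(t)}\t{i}\n")


def read_spikes(path: Union[str, os.PathLike]) -> SpikeRecord:
    duration = None
    dt = 1.0
    populations = []
    times, ids = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                fields = line[1:].split()
                if not fields:
                    continue
                if fields[0] == "duration_ms":
                    duration = float(fields[1])
                elif fields[0] == "dt_ms":
                    dt = float(fields[1])
                elif fields[0] == "population":
                    populations.append((fields[1], int(fields[2]), int(fields[3])))
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 'time<TAB>id', got {line!r}")
            try:
                t = float(parts[0])
                i = int(parts[1])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if t < 0:
                raise ParseError(f"{path}:{lineno}: negative spike time {t}")
            if i < 0:
                raise ParseError(f"{path}:{lineno}: negative neuron id {i}")
            times.append(t)
            ids.append(i)
    if duration is None:
        raise FormatError(f"{path}: missing '# duration_ms' header")
    times_arr = np.asarray(times, dtype=np.float64)
    if times_arr.size and np.any(np.diff(times_arr) < 0):
        raise FormatError(f"{path}: event times are not sorted")
    return SpikeRecord(times_arr, np.asarray(ids, dtype=np.int32), duration, dt,
                       tuple(populations))


# -- configuration -----------------------------------------------------------

def default_config() -> Dict[str, float]:
    """The standard model configuration (all rates Hz, times ms, weights nA)."""
    return {
        # population sizes per column
        "n_l23e": 4507, "n_l23i": 795, "n_l4e": 3471, "n_l4i": 613, "n_thalamus": 285,
        # connectivity
        "p_tc": 0.25, "p_intracortical": 0.1, "p_lateral": 0.1,
        # weights and balance
        "w_e": 0.1, "b": 1.0, "i2e_scale": 1.5,
        "w_interlayer": 0.2, "w_lateral": 0.1,
        "w_tc": -1.0,                # < 0 means: calibrate at run time
        # stimulus
        "rate_base": 6.0, "rate_peak": 30.0,
        "onset_rise": 5.0, "onset_fall": 30.0, "rest_period": 500.0,
        "battery_separation": 150.0, "chain_reps": 5, "chain_period": 100.0,
        # sweep grid (log-spaced)
        "b_min": 0.1, "b_max": 10.0, "n_b": 25,
    }


def load_config(path: Union[str, os.PathLike, None]) -> Dict[str, float]:
    """Defaults overridden by a flat ``key = value`` file (None: pure defaults)."""
    cfg = default_config()
    if path is None:
        return cfg
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParseError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in cfg:
                raise ParseError(f"{path}:{lineno}: unknown configuration key {key!r}")
            try:
                cfg[key] = type(cfg[key])(float(value))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return cfg


def write_config(cfg: Dict[str, float], path: Union[str, os.PathLike]) -> None:
    with open(path, "w") as fh:
        for key, value in cfg.items():
            fh.write(f"{key} = {value}\n")


def write_manifest(path: Union[str, os.PathLike], **entries) -> None:
    """Record the exact parameters and seeds of a run as key=value lines."""
    with open(path, "w") as fh:
        for key, value in entries.items():
            fh.write(f"{key} = {value}\n")


def write_table(df: pd.DataFrame, path: Union[str, os.PathLike]) -> None:
    """Delimited-text table with a header row."""
    df.to_csv(path, sep="\t", index=False)
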