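"""Reading and writing the delimited-text formats the toolkit consumes.

Trace files are CSV with a header naming either a ``time_s`` or ``sample_idx``
column plus a ``force_kg`` or ``force_n`` column (newtons are converted to
kilogram-force with g = 9.80665 m/s^2).  Optional constant metadata columns
(participant, muscle, device, rater, session, trial) are carried into
:attr:`ForceTrace.metadata`.  Measurement tables round-trip losslessly through
:func:`write_measurements` / :func:`read_measurements`.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .model import GRAVITY, TABLE_KEYS, ForceTrace, MeasurementTable, TraceValidationError

__all__ = [
    "read_trace",
    "write_trace",
    "read_measurements",
    "write_measurements",
    "read_measurements_xlsx",
    "TraceParseError",
]

_METADATA_COLUMNS = ("participant", "muscle", "device", "rater", "session", "trial")


class TraceParseError(ValueError):
    """Raised for malformed trace files; carries the offending line number."""


def _parse_csv(path: Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:  # surface the line number pandas found
        raise TraceParseError(f"{path}: {exc}") from exc


def read_trace(
    path: str | Path,
    dialect: str = "custom",
    column_map: Mapping[str, str] | None = None,
    nominal_rate: float | None = None,
) -> ForceTrace:
    """Read a single-trial force trace from a delimited text file.

    Parameters
    ----------
    path
        CSV file with a header row.
    dialect
        Device profile to stamp on the trace (``stable_40hz``,
        ``unstable_100hz``, ``stable_1000hz`` or ``custom``).
    column_map
        Optional mapping from canonical names (``time_s``, ``sample_idx``,
        ``force_kg``, ``force_n``) to the file's column names.
    nominal_rate
        Sampling rate in Hz.  Required when only a sample-index column is
        present (times are synthesised as ``idx / rate``); otherwise defaults
        to the dialect's nominal rate.

    Returns
    -------
    ForceTrace
        Validated trace; times in seconds, force in kilograms.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = _parse_csv(path)
    cmap = dict(column_map or {})

    def col(name: str) -> str | None:
        mapped = cmap.get(name, name)
        return mapped if mapped in df.columns else None

    time_col, idx_col = col("time_s"), col("sample_idx")
    force_kg_col, force_n_col = col("force_kg"), col("force_n")

    bad = df.index[df.isna().any(axis=1)]
    if len(bad):
        # +2: header line plus 1-based numbering
        raise TraceParseError(
            f"{path}: malformed/empty field at line {int(bad[0]) + 2}"
        )

    if time_col is not None:
        times = df[time_col].to_numpy(dtype=float)
    elif idx_col is not None:
        rate = nominal_rate
        if rate is None:
            from .model import DEVICE_PROFILES

            rate = DEVICE_PROFILES.get(dialect)
        if rate is None:
            raise TraceParseError(
                f"{path}: sample-index column requires a nominal_rate to "
                "synthesize times"
            )
        times = df[idx_col].to_numpy(dtype=float) / float(rate)
        nominal_rate = rate
    else:
        raise TraceParseError(f"{path}: no time_s or sample_idx column found")

    if force_kg_col is not None:
        force = df[force_kg_col].to_numpy(dtype=float)
    elif force_n_col is not None:
        force = df[force_n_col].to_numpy(dtype=float) / GRAVITY
    else:
        raise TraceParseError(f"{path}: no force_kg or force_n column found")

    metadata = {
        c: str(df[c].iloc[0]) for c in _METADATA_COLUMNS if c in df.columns
    }
    try:
        return ForceTrace(
            sample_times=times,
            force=force,
            device_profile=dialect,
            nominal_rate=nominal_rate,
            metadata=metadata,
        )
    except TraceValidationError:
        raise


def write_trace(trace: ForceTrace, path: str | Path) -> Path:
    """Write a trace as CSV (time_s, force_kg plus any metadata columns)."""
    path = Path(path)
    df = pd.DataFrame({"time_s": trace.sample_times, "force_kg": trace.force})
    for key, val in trace.metadata.items():
        df[key] = val
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_measurements(path: str | Path) -> MeasurementTable:
    """Read a long-format measurement table from CSV.

    Empty cells become explicit missing values (NaN).  Duplicate key tuples
    and unknown muscle codes raise ``ValueError``.
    """
    df = pd.read_csv(
        path, dtype={k: str for k in TABLE_KEYS}, float_precision="round_trip"
    )
    return MeasurementTable(df)


def write_measurements(table: MeasurementTable, path: str | Path) -> Path:
    """Write a measurement table as CSV with '.' decimals and ISO header names.

    Full float precision is kept (repr round-trip) so write-then-read is the
    identity on valid tables.
    """
    path = Path(path)
    df = table.df.copy()
    # 17 significant digits guarantee binary64 round-trip
    df.to_csv(path, index=False, float_format="%.17g", na_rep="")
    return path


def read_measurements_xlsx(path: str | Path, sheet: int | str = 0) -> MeasurementTable:
    """Optional convenience reader for spreadsheet-format outcome tables.

    Expects the same long-format columns as the CSV reader.  Requires
    ``openpyxl``.
    """
    df = pd.read_excel(path, sheet_name=sheet)
    return MeasurementTable(df)


def measurements_from_string(text: str) -> MeasurementTable:
    """Parse a measurement table from an in-memory CSV string (test helper)."""
    return MeasurementTable(pd.read_csv(_io.StringIO(text), dtype={k: str for k in TABLE_KEYS}))
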