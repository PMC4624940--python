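"""Core data model: force traces, trial sets, and long-format measurement tables.

Forces are stored in kilograms (the native unit of the hand-held and fixed
dynamometers this toolkit targets) and times in seconds with t=0 at the first
recorded sample.  Device sampling profiles describe the three device classes
encountered in practice: a stable 40 Hz hand-held unit, a wireless hand-held
unit streaming at an unstable ~100 Hz, and a fixed laboratory dynamometer at
a stable 1000 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DEVICE_PROFILES",
    "MUSCLE_CODES",
    "ForceTrace",
    "TrialSet",
    "MeasurementTable",
    "TraceValidationError",
    "GRAVITY",
]

#: standard gravity used for newton -> kilogram-force conversion
GRAVITY = 9.80665

#: device sampling profiles and their nominal rates (Hz); ``custom`` has none
DEVICE_PROFILES: dict[str, float | None] = {
    "stable_40hz": 40.0,
    "unstable_100hz": 100.0,
    "stable_1000hz": 1000.0,
    "custom": None,
}

#: lower-limb muscle-group codes: ankle dorsi/plantarflexors, hip
#: abductors/adductors/extensors/flexors, knee extensors/flexors
MUSCLE_CODES = ("ADF", "APF", "HAB", "HAD", "HE", "HF", "KE", "KF")

#: key columns of a long-format measurement table
TABLE_KEYS = ["participant", "muscle", "device", "rater", "session", "metric"]


class TraceValidationError(ValueError):
    """Raised when a force trace violates the data-model invariants."""


@dataclass(frozen=True)
class ForceTrace:
    """A single trial's force–time series.

    Parameters
    ----------
    sample_times
        Sample times in seconds, non-negative and strictly increasing.
    force
        Force in kilograms, same length as ``sample_times``, all finite.
    device_profile
        One of :data:`DEVICE_PROFILES`.
    nominal_rate
        Nominal sampling rate in Hz.  For stable profiles the realised
        sampling intervals must match ``1/nominal_rate`` within
        ``rate_tolerance``; the unstable profile carries no such constraint.
    metadata
        Free-form string map (participant, muscle, device, rater, session,
        trial index, ...).
    rate_tolerance
        Maximum allowed absolute deviation of successive sampling intervals
        from ``1/nominal_rate`` for stable profiles, as a fraction of the
        nominal interval.
    """

    sample_times: np.ndarray
    force: np.ndarray
    device_profile: str = "custom"
    nominal_rate: float | None = None
    metadata: Mapping[str, str] = field(default_factory=dict)
    rate_tolerance: float = 0.01

    def __post_init__(self) -> None:
        t = np.asarray(self.sample_times, dtype=float)
        f = np.asarray(self.force, dtype=float)
        object.__setattr__(self, "sample_times", t)
        object.__setattr__(self, "force", f)
        object.__setattr__(self, "metadata", dict(self.metadata))
        if t.ndim != 1 or f.ndim != 1:
            raise TraceValidationError("sample_times and force must be 1-D")
        if len(t) != len(f):
            raise TraceValidationError(
                f"length mismatch: {len(t)} times vs {len(f)} force samples"
            )
        if len(t) < 2:
            raise TraceValidationError("a force trace needs at least 2 samples")
        if not np.all(np.isfinite(t)):
            raise TraceValidationError("sample times must be finite")
        if not np.all(np.isfinite(f)):
            raise TraceValidationError("force values must be finite")
        if t[0] < 0:
            raise TraceValidationError("sample times must be non-negative")
        dt = np.diff(t)
        if np.any(dt <= 0):
            bad = int(np.argmax(dt <= 0))
            raise TraceValidationError(
                f"sample times must be strictly increasing (violation after "
                f"index {bad}: {t[bad]:.6g} -> {t[bad + 1]:.6g})"
            )
        if self.device_profile not in DEVICE_PROFILES:
            raise TraceValidationError(
                f"unknown device profile {self.device_profile!r}; expected one "
                f"of {sorted(DEVICE_PROFILES)}"
            )
        nominal = self.nominal_rate
        if nominal is None:
            nominal = DEVICE_PROFILES[self.device_profile]
            object.__setattr__(self, "nominal_rate", nominal)
        if self.device_profile.startswith("stable"):
            if nominal is None or nominal <= 0:
                raise TraceValidationError("stable profiles need a nominal_rate")
            interval = 1.0 / nominal
            dev = np.max(np.abs(dt - interval))
            if dev > self.rate_tolerance * interval:
                raise TraceValidationError(
                    f"profile {self.device_profile} requires stable sampling: "
                    f"max interval deviation {dev:.3g}s exceeds tolerance "
                    f"{self.rate_tolerance * interval:.3g}s"
                )

    def __len__(self) -> int:
        return len(self.sample_times)

    @property
    def duration(self) -> float:
        """Span of the trace in seconds."""
        return float(self.sample_times[-1] - self.sample_times[0])

    def is_uniform(self, rel_tol: float = 1e-6) -> bool:
        """True when successive sampling intervals are equal within ``rel_tol``."""
        dt = np.diff(self.sample_times)
        return bool(np.max(np.abs(dt - dt.mean())) <= rel_tol * dt.mean())

    @property
    def sample_rate(self) -> float:
        """Mean realised sampling rate in Hz."""
        return (len(self) - 1) / self.duration

    def with_data(
        self, sample_times: np.ndarray, force: np.ndarray, **overrides
    ) -> "ForceTrace":
        """Return a copy carrying new samples but the same provenance."""
        return replace(self, sample_times=sample_times, force=force, **overrides)


@dataclass(frozen=True)
class TrialSet:
    """The trials (typically two) for one participant x muscle x device x
    rater x session cell.

    All member traces must agree on the key fields present in their metadata.
    """

    trials: tuple[ForceTrace, ...]
    key: Mapping[str, str] = field(default_factory=dict)

    KEY_FIELDS = ("participant", "muscle", "device", "rater", "session")

    def __post_init__(self) -> None:
        trials = tuple(self.trials)
        object.__setattr__(self, "trials", trials)
        object.__setattr__(self, "key", dict(self.key))
        if not trials:
            raise ValueError("TrialSet needs at least one trial")
        for field_name in self.KEY_FIELDS:
            vals = {
                str(tr.metadata[field_name])
                for tr in trials
                if field_name in tr.metadata
            }
            if len(vals) > 1:
                raise ValueError(
                    f"trials disagree on {field_name!r}: {sorted(vals)}"
                )
            if field_name not in self.key and vals:
                self.key[field_name] = vals.pop()

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)


class MeasurementTable:
    """Long-format outcome table keyed by
    (participant, muscle, device, rater, session, metric).

    Thin validated wrapper over a :class:`pandas.DataFrame`.  Values are
    floats; missing outcomes are explicit NaN, never zero.
    """

    def __init__(self, data: pd.DataFrame, validate_muscles: bool = True):
        df = pd.DataFrame(data).copy()
        missing = [c for c in TABLE_KEYS + ["value"] if c not in df.columns]
        if missing:
            raise ValueError(f"measurement table missing columns: {missing}")
        df["session"] = df["session"].astype(int)
        for col in ("participant", "muscle", "device", "rater", "metric"):
            df[col] = df[col].astype(str)
        df["value"] = pd.to_numeric(df["value"], errors="raise")
        if np.any(np.isinf(df["value"].to_numpy(dtype=float))):
            raise ValueError("measurement values must be finite or missing")
        if validate_muscles:
            unknown = sorted(set(df["muscle"]) - set(MUSCLE_CODES))
            if unknown:
                raise ValueError(
                    f"unknown muscle code(s) {unknown}; expected {MUSCLE_CODES}"
                )
        dup = df.duplicated(subset=TABLE_KEYS, keep=False)
        if dup.any():
            first = df.loc[dup, TABLE_KEYS].iloc[0].tolist()
            raise ValueError(f"duplicate key tuple: {tuple(first)}")
        self._df = df[TABLE_KEYS + ["value"]].reset_index(drop=True)

    @property
    def df(self) -> pd.DataFrame:
        """The underlying long-format frame (copy-on-write safe view)."""
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, MeasurementTable):
            return NotImplemented
        a = self._df.sort_values(TABLE_KEYS).reset_index(drop=True)
        b = other._df.sort_values(TABLE_KEYS).reset_index(drop=True)
        return a.equals(b)

    @classmethod
    def from_records(cls, records: Iterable[Mapping], **kw) -> "MeasurementTable":
        return cls(pd.DataFrame(list(records)), **kw)
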