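"""Muscle strength (peak force) and muscle power (rate of force development).

RFD is the change in force over a time interval (Δforce/Δtime) during an
isometric contraction.  Three algorithm families are implemented:

* ``time_to_peak`` — seconds from the first recorded sample to the first
  force maximum;
* ``percent_window`` — slope between the first upward crossings of two force
  thresholds expressed as percentages of the trial's peak force (fixed force
  position, variable duration);
* ``moving_window`` — maximum mean slope over all fixed-length windows slid
  sample-by-sample along the whole trace (fixed duration, variable position).

No contraction-onset detection is performed: every search starts from the
first recorded sample, and the moving-window search naturally ignores an
initial contact transient whenever its slope is lower than the true rise.
All ties are broken to the earliest occurrence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np

from .model import ForceTrace, TrialSet

__all__ = [
    "RfdMethodSpec",
    "StrengthPowerResult",
    "default_battery",
    "peak_force",
    "time_to_peak",
    "rfd_percent_window",
    "rfd_moving_window",
    "compute_battery",
]

PERCENT_WINDOWS = ((5, 95), (10, 90), (15, 85), (20, 80), (25, 75), (30, 70), (35, 65), (40, 60))
MOVING_WINDOWS_MS = (10, 20, 50, 100, 200)


@dataclass(frozen=True)
class RfdMethodSpec:
    """One RFD algorithm variant.

    ``family`` selects the algorithm; ``lo_pct``/``hi_pct`` parameterise the
    percent-of-peak-force family and ``window_ms`` the moving-window family.
    """

    family: Literal["time_to_peak", "percent_window", "moving_window"]
    lo_pct: float | None = None
    hi_pct: float | None = None
    window_ms: float | None = None

    def __post_init__(self) -> None:
        if self.family == "percent_window":
            if self.lo_pct is None or self.hi_pct is None:
                raise ValueError("percent_window needs lo_pct and hi_pct")
            if not (0 < self.lo_pct < self.hi_pct < 100):
                raise ValueError("need 0 < lo < hi < 100")
        elif self.family == "moving_window":
            if self.window_ms is None or self.window_ms <= 0:
                raise ValueError("moving_window needs a positive window_ms")
        elif self.family != "time_to_peak":
            raise ValueError(f"unknown RFD family {self.family!r}")

    @property
    def label(self) -> str:
        if self.family == "time_to_peak":
            return "time_to_peak_s"
        if self.family == "percent_window":
            return f"rfd_pct_{self.lo_pct:g}_{self.hi_pct:g}_kg_per_s"
        return f"rfd_win_{self.window_ms:g}ms_kg_per_s"


def default_battery() -> list[RfdMethodSpec]:
    """The 14 standard variants: time-to-peak, 8 percent windows, 5 moving
    windows (10–200 ms)."""
    specs = [RfdMethodSpec("time_to_peak")]
    specs += [RfdMethodSpec("percent_window", lo_pct=lo, hi_pct=hi) for lo, hi in PERCENT_WINDOWS]
    specs += [RfdMethodSpec("moving_window", window_ms=w) for w in MOVING_WINDOWS_MS]
    return specs


@dataclass
class StrengthPowerResult:
    """Peak force plus all requested RFD variants for one trial set."""

    peak_force_kg: float
    peak_force_time_s: float
    peak_force_trial: int
    per_trial: list[dict[str, float]]
    aggregate: dict[str, float]
    aggregate_rule: str = "max"
    key: dict[str, str] = field(default_factory=dict)


def peak_force(trials: TrialSet) -> tuple[float, int, float]:
    """Highest force sample (kg) over all trials in the set.

    Returns ``(force_kg, trial_index, time_s)``.  Ties go to the earliest
    sample of the lowest-index trial.
    """
    best: tuple[float, int, float] | None = None
    for idx, trace in enumerate(trials):
        i = int(np.argmax(trace.force))  # first maximum within the trial
        cand = (float(trace.force[i]), idx, float(trace.sample_times[i]))
        if best is None or cand[0] > best[0]:
            best = cand
    assert best is not None
    return best


def time_to_peak(trace: ForceTrace) -> float:
    """Seconds from the first sample to the first maximal force sample."""
    i = int(np.argmax(trace.force))
    return float(trace.sample_times[i] - trace.sample_times[0])


def _first_crossing_time(t: np.ndarray, f: np.ndarray, threshold: float) -> float | None:
    """Time of the first upward crossing of ``threshold``, linearly
    interpolated between the bracketing samples.  ``None`` if never reached."""
    above = f >= threshold
    if not above.any():
        return None
    j = int(np.argmax(above))
    if j == 0:
        return float(t[0])
    f0, f1 = f[j - 1], f[j]
    if f1 == f0:
        return float(t[j])
    frac = (threshold - f0) / (f1 - f0)
    return float(t[j - 1] + frac * (t[j] - t[j - 1]))


def rfd_percent_window(trace: ForceTrace, lo_pct: float, hi_pct: float) -> float:
    """RFD between two percent-of-peak-force thresholds (kg/s).

    The thresholds are ``lo_pct``/``hi_pct`` percent of this trial's peak
    force; crossing times are the first upward crossings on the rise to the
    first peak, sub-sample located by linear interpolation.  By construction
    the force change is ``(hi-lo)% * peak``; only the duration varies.

    Returns NaN (a flagged missing value, not an exception) when a threshold
    is never crossed before the first peak or the crossing times coincide.
    """
    if not (0 < lo_pct < hi_pct < 100):
        raise ValueError("need 0 < lo < hi < 100")
    f, t = trace.force, trace.sample_times
    ipk = int(np.argmax(f))
    peak = float(f[ipk])
    rise_t, rise_f = t[: ipk + 1], f[: ipk + 1]
    t_lo = _first_crossing_time(rise_t, rise_f, lo_pct / 100.0 * peak)
    t_hi = _first_crossing_time(rise_t, rise_f, hi_pct / 100.0 * peak)
    if t_lo is None or t_hi is None or t_hi <= t_lo:
        return float("nan")
    return (hi_pct - lo_pct) / 100.0 * peak / (t_hi - t_lo)


def rfd_moving_window(trace: ForceTrace, window_ms: float) -> tuple[float, float]:
    """Peak moving-window RFD (kg/s) and the start time of the best window.

    Slides a window of ``window_ms`` sample-by-sample across the whole trace
    (successive time intervals: samples 1..1+w, 2..2+w, ...) and returns the
    maximum chord slope ``(F[i+w] - F[i]) / (w*Δt)``.  Requires a uniform
    grid; ties go to the earliest window.
    """
    if not trace.is_uniform():
        raise ValueError("moving-window RFD requires a uniform grid; preprocess first")
    dt = float(np.mean(np.diff(trace.sample_times)))
    w = int(round(window_ms / 1000.0 / dt))
    if w < 1:
        raise ValueError(f"window {window_ms} ms is below the sample interval")
    f = trace.force
    if len(f) <= w:
        raise ValueError(
            f"trace of {len(f)} samples is shorter than the {window_ms} ms window"
        )
    diffs = f[w:] - f[:-w]
    i = int(np.argmax(diffs))  # argmax returns the first (earliest) maximum
    return float(diffs[i] / (w * dt)), float(trace.sample_times[i])


def _evaluate(trace: ForceTrace, spec: RfdMethodSpec) -> float:
    if spec.family == "time_to_peak":
        return time_to_peak(trace)
    if spec.family == "percent_window":
        return rfd_percent_window(trace, spec.lo_pct, spec.hi_pct)
    return rfd_moving_window(trace, spec.window_ms)[0]


def compute_battery(
    trials: TrialSet,
    methods: Iterable[RfdMethodSpec] | None = None,
    aggregate: Literal["max", "mean", "best_trial"] = "max",
) -> StrengthPowerResult:
    """Run every requested RFD method on every trial and aggregate.

    ``aggregate`` controls the across-trials summary: ``max`` mirrors the
    peak-force rule (highest value over both trials, the default), ``mean``
    averages, and ``best_trial`` takes every metric from the trial with the
    highest peak force.  For time-to-peak the ``max``/``best_trial`` rules
    use the trial with the higher peak force (a longer time is not "better").
    Flagged missing per-trial values (NaN) propagate without aborting.
    """
    methods = list(methods) if methods is not None else default_battery()
    pf, pf_trial, pf_time = peak_force(trials)
    per_trial: list[dict[str, float]] = []
    for trace in trials:
        row = {spec.label: _evaluate(trace, spec) for spec in methods}
        row["peak_force_kg"] = float(np.max(trace.force))
        per_trial.append(row)

    agg: dict[str, float] = {}
    for spec in methods:
        vals = np.array([row[spec.label] for row in per_trial], dtype=float)
        ok = ~np.isnan(vals)
        if not ok.any():
            agg[spec.label] = float("nan")
        elif spec.family == "time_to_peak" or aggregate == "best_trial":
            v = per_trial[pf_trial][spec.label]
            agg[spec.label] = float(v)
        elif aggregate == "max":
            agg[spec.label] = float(np.max(vals[ok]))
        elif aggregate == "mean":
            agg[spec.label] = float(np.mean(vals[ok]))
        else:
            raise ValueError(f"unknown aggregate rule {aggregate!r}")
    agg["peak_force_kg"] = pf

    return StrengthPowerResult(
        peak_force_kg=pf,
        peak_force_time_s=pf_time,
        peak_force_trial=pf_trial,
        per_trial=per_trial,
        aggregate=agg,
        aggregate_rule=aggregate,
        key=dict(trials.key),
    )
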