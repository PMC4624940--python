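"""Reliability and agreement statistics for paired dynamometry measurements.

Implements the clinimetric battery used to judge test–retest (intra-rater),
inter-rater, and inter-device reliability and concurrent validity:

* ICC(2,1) — two-way random-effects, absolute-agreement, single-measures
  intraclass correlation from the two-way ANOVA mean squares, with the
  Shrout–Fleiss F-based 95% confidence interval;
* SEM — standard error of measurement, ``SD1 * sqrt(1 - ICC)`` where SD1 is
  the standard deviation of the first-session values;
* MDC — minimal detectable change, in two first-class variants because both
  appear in the applied literature: ``1.96*sqrt(2)*SEM`` (ratio 2.7719) and
  ``1.96*SEM`` (ratio 1.96);
* Pearson's r with a Fisher-z 95% CI;
* Lin's concordance correlation coefficient (association penalised for
  deviation from the identity line y = x), Fisher-z CI;
* Bland–Altman 95% limits of agreement, switching to the regression-based
  variant (bias and spread modelled as linear functions of the pair average)
  when the correlation between differences and averages exceeds 0.50 in
  magnitude (proportional bias).

Coefficients are interpreted on the conventional bands excellent (>=0.90),
good (0.75–0.89), moderate (0.50–0.74), poor (<0.50).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import MeasurementTable

__all__ = [
    "PairedSample",
    "ReliabilityResult",
    "AgreementResult",
    "BlandAltmanResult",
    "MethodComparisonSummary",
    "ComparisonDesign",
    "icc_2_1",
    "sem",
    "sem_pct",
    "mdc",
    "pearson_ci",
    "lin_ccc",
    "bland_altman",
    "classify_coefficient",
    "summarize_method_column",
    "run_comparison",
    "round_half_away",
    "MDC_MULTIPLIERS",
]

Z_95 = 1.96
#: MDC/SEM ratio per variant
MDC_MULTIPLIERS = {"sqrt2": Z_95 * math.sqrt(2.0), "plain": Z_95}


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (report convention; Python's round is
    banker's).  Decimal-based so 0.785 -> 0.79 despite binary representation."""
    if np.isnan(x):
        return x
    import decimal

    # quantize away float representation fuzz (0.78499999999999998 == 0.785)
    # before the half-away-from-zero rounding
    d = decimal.Decimal(repr(float(x))).quantize(
        decimal.Decimal(1).scaleb(-(ndigits + 7)), rounding=decimal.ROUND_HALF_EVEN
    )
    d = d.quantize(decimal.Decimal(1).scaleb(-ndigits), rounding=decimal.ROUND_HALF_UP)
    return float(d)


@dataclass(frozen=True)
class PairedSample:
    """Complete per-subject pairs entering a single agreement coefficient."""

    x: np.ndarray
    y: np.ndarray
    subjects: tuple[str, ...] = ()
    label: str = ""

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if np.isnan(x).any() or np.isnan(y).any():
            raise ValueError("pairs must be complete; drop missing values first")

    @property
    def n(self) -> int:
        return len(self.x)

    @classmethod
    def from_xy(cls, x: Sequence[float], y: Sequence[float], label: str = "") -> "PairedSample":
        """Build a paired sample, silently dropping incomplete pairs."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        return cls(x=x[ok], y=y[ok], label=label)


@dataclass
class ReliabilityResult:
    icc: float
    icc_ci: tuple[float, float]
    sem_abs: float
    sem_pct: float
    mdc_abs: float
    mdc_pct: float
    mean_ref: float
    sd1: float
    n: int
    mdc_variant: str = "sqrt2"
    z: float = Z_95


@dataclass
class AgreementResult:
    r: float
    r_ci: tuple[float, float]
    rc: float
    rc_ci: tuple[float, float]
    n: int


@dataclass
class BlandAltmanResult:
    kind: Literal["standard", "regression_based"]
    proportional_bias_r: float
    n: int
    # standard kind
    bias: float | None = None
    loa_low: float | None = None
    loa_high: float | None = None
    # regression-based kind: lines evaluated as intercept + slope * average
    bias_intercept: float | None = None
    bias_slope: float | None = None
    loa_half_width_intercept: float | None = None
    loa_half_width_slope: float | None = None


@dataclass
class MethodComparisonSummary:
    median: float
    iqr_25: float
    iqr_75: float
    n_below_threshold: int
    threshold: float = 0.75
    n: int = 0


def _two_way_mean_squares(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, int, int]:
    """Mean squares of the two-way (subjects x measurements) ANOVA for k=2.

    Returns (MS_rows, MS_cols, MS_error, n, k).
    """
    data = np.column_stack([x, y])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    return ms_rows, ms_cols, ms_err, n, k


def icc_2_1(pairs: PairedSample, ci: float = 0.95) -> tuple[float, tuple[float, float]]:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    Estimate from the two-way ANOVA mean squares::

        ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

    with k=2 measurements per subject.  The confidence interval is the
    Shrout–Fleiss F-based interval with Satterthwaite degrees of freedom.
    The estimate may be negative.
    """
    if pairs.n < 3:
        raise ValueError("ICC needs at least 3 complete pairs")
    ms_r, ms_c, ms_e, n, k = _two_way_mean_squares(pairs.x, pairs.y)
    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    if denom <= 0:
        raise ValueError("zero total variance: ICC undefined")
    icc = (ms_r - ms_e) / denom

    alpha = 1.0 - ci
    if ms_e == 0:  # perfect agreement: interval degenerates at the estimate
        return float(icc), (float(icc), float(icc))
    # Satterthwaite df for the absolute-agreement interval (Shrout–Fleiss /
    # McGraw–Wong)
    fj = ms_c / ms_e
    v_num = (k - 1) * (n - 1) * (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2
    v_den = (n - 1) * k**2 * icc**2 * fj**2 + (n * (1 + (k - 1) * icc) - k * icc) ** 2
    v = v_num / v_den
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (ms_r - f_l * ms_e) / (f_l * (k * ms_c + (k * n - k - n) * ms_e) + n * ms_r)
    upper = n * (f_u * ms_r - ms_e) / (k * ms_c + (k * n - k - n) * ms_e + n * f_u * ms_r)
    lower = min(lower, icc)
    upper = max(upper, icc)
    return float(icc), (float(max(lower, -1.0)), float(min(upper, 1.0)))


def sem(sd1: float, icc: float) -> float:
    """Standard error of measurement: ``SD1 * sqrt(1 - ICC)``.

    SD1 is the standard deviation of the first-session values.  A negative
    ICC is allowed and yields ``sqrt(1 - ICC) > 1``.
    """
    if sd1 < 0:
        raise ValueError("sd1 must be non-negative")
    if not -1.0 <= icc <= 1.0:
        raise ValueError("icc must lie in [-1, 1]")
    return sd1 * math.sqrt(1.0 - icc)


def sem_pct(sd1: float, icc: float, mean_ref: float) -> float:
    """SEM expressed as a percentage of ``mean_ref`` (the session-1 mean)."""
    if mean_ref == 0:
        raise ValueError("percent SEM undefined for zero reference mean")
    return 100.0 * sem(sd1, icc) / abs(mean_ref)


def mdc(sem_value: float, variant: str = "sqrt2") -> float:
    """Minimal detectable change at 95% confidence.

    ``sqrt2`` variant: ``1.96 * sqrt(2) * SEM`` (MDC/SEM = 2.7719);
    ``plain`` variant: ``1.96 * SEM`` (MDC/SEM = 1.96).  Both appear in the
    applied literature, so the variant is explicit in every report.
    """
    if sem_value < 0:
        raise ValueError("sem must be non-negative")
    try:
        return MDC_MULTIPLIERS[variant] * sem_value
    except KeyError:
        raise ValueError(f"unknown MDC variant {variant!r}") from None


def _fisher_ci(r: float, n: int, ci: float = 0.95) -> tuple[float, float]:
    """Fisher z-transform confidence interval for a correlation-type
    coefficient."""
    if n <= 3:  # Fisher variance 1/(n-3) is unbounded: maximally wide CI
        return -1.0, 1.0
    r = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
    z = np.arctanh(r)
    se = 1.0 / math.sqrt(n - 3)
    zcrit = stats.norm.ppf(0.5 + ci / 2.0)
    return float(np.tanh(z - zcrit * se)), float(np.tanh(z + zcrit * se))


def pearson_ci(pairs: PairedSample, ci: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Pearson's r (association irrespective of magnitude differences) with
    a Fisher-z CI."""
    if pairs.n < 3:
        raise ValueError("Pearson correlation needs at least 3 pairs")
    if np.std(pairs.x) == 0 or np.std(pairs.y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r = float(np.corrcoef(pairs.x, pairs.y)[0, 1])
    return r, _fisher_ci(r, pairs.n, ci)


def lin_ccc(pairs: PairedSample, ci: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Lin's concordance correlation coefficient with a Fisher-z CI.

    ``rc = 2 s_xy / (s_x^2 + s_y^2 + (x̄ - ȳ)^2)`` with biased (1/n)
    moments.  Penalises both location and scale shifts from the identity
    line, so ``|rc| <= |r|`` always.
    """
    if pairs.n < 3:
        raise ValueError("concordance correlation needs at least 3 pairs")
    x, y, n = pairs.x, pairs.y, pairs.n
    sx2 = np.var(x)  # biased, 1/n
    sy2 = np.var(y)
    sxy = np.mean((x - x.mean()) * (y - y.mean()))
    denom = sx2 + sy2 + (x.mean() - y.mean()) ** 2
    if denom == 0:
        raise ValueError("degenerate sample: concordance undefined")
    rc = float(2.0 * sxy / denom)
    return rc, _fisher_ci(rc, n, ci)


def bland_altman(
    pairs: PairedSample, proportional_bias_threshold: float = 0.50
) -> BlandAltmanResult:
    """Bland–Altman 95% limits of agreement.

    Differences ``d = x - y`` are examined against averages
    ``a = (x + y)/2``.  When ``|corr(d, a)|`` exceeds the proportional-bias
    threshold (0.50), the regression-based variant is used: the bias line is
    the OLS fit of d on a, and the limits are the bias line plus/minus
    ``1.96 * sqrt(pi/2)`` times the OLS fit of |residual| on a (the
    half-normal correction turning mean absolute residuals into an SD).
    Otherwise the standard limits ``mean(d) ± 1.96 SD(d)`` are reported.
    """
    if pairs.n < 3:
        raise ValueError("Bland–Altman analysis needs at least 3 pairs")
    d = pairs.x - pairs.y
    a = (pairs.x + pairs.y) / 2.0
    if np.std(d) == 0 or np.std(a) == 0:
        prop_r = 0.0
    else:
        prop_r = float(np.corrcoef(d, a)[0, 1])

    if abs(prop_r) <= proportional_bias_threshold:
        bias = float(np.mean(d))
        sd = float(np.std(d, ddof=1))
        return BlandAltmanResult(
            kind="standard",
            proportional_bias_r=prop_r,
            n=pairs.n,
            bias=bias,
            loa_low=bias - Z_95 * sd,
            loa_high=bias + Z_95 * sd,
        )

    slope, intercept = np.polyfit(a, d, 1)
    resid = d - (intercept + slope * a)
    s_slope, s_intercept = np.polyfit(a, np.abs(resid), 1)
    hw_scale = Z_95 * math.sqrt(math.pi / 2.0)
    return BlandAltmanResult(
        kind="regression_based",
        proportional_bias_r=prop_r,
        n=pairs.n,
        bias_intercept=float(intercept),
        bias_slope=float(slope),
        loa_half_width_intercept=float(hw_scale * s_intercept),
        loa_half_width_slope=float(hw_scale * s_slope),
    )


def classify_coefficient(value: float) -> str:
    """Interpretation band for a reliability/validity coefficient.

    Applied to the value rounded to 2 decimals (half away from zero), so a
    coefficient that prints as 0.75 is classified from its printed value:
    excellent >= 0.90, good 0.75–0.89, moderate 0.50–0.74, poor < 0.50.
    """
    if not -1.0 <= value <= 1.0:
        raise ValueError("coefficient must lie in [-1, 1]")
    v = round_half_away(value, 2)
    if v >= 0.90:
        return "excellent"
    if v >= 0.75:
        return "good"
    if v >= 0.50:
        return "moderate"
    return "poor"


def summarize_method_column(
    iccs: Sequence[float], threshold: float = 0.75
) -> MethodComparisonSummary:
    """Summarise one RFD method's per-muscle ICC column.

    Median and 25th/75th percentiles by linear interpolation (quantile
    type 7), count of values strictly below the reliability threshold.
    Reported values are rounded to 2 decimals, half away from zero.
    """
    vals = np.asarray(list(iccs), dtype=float)
    if len(vals) < 2:
        raise ValueError("need at least 2 values to summarise")
    med = float(np.median(vals))
    q25, q75 = (float(q) for q in np.percentile(vals, [25, 75]))  # type 7
    return MethodComparisonSummary(
        median=round_half_away(med),
        iqr_25=round_half_away(q25),
        iqr_75=round_half_away(q75),
        n_below_threshold=int(np.sum(vals < threshold)),
        threshold=threshold,
        n=len(vals),
    )


@dataclass(frozen=True)
class ComparisonDesign:
    """Which factor is paired and which are held fixed in one comparison.

    ``paired_factor`` is one of participant-table key columns (``session``,
    ``rater``, ``device``); ``levels`` names the (x, y) levels to pair, e.g.
    ``("1", "2")`` for test–retest or ``("Lafayette", "KinCom")`` for
    validity against the criterion device.  ``fixed`` filters the table
    before pairing (e.g. ``{"rater": "A"}``).  ``kind`` selects which
    statistics attach: reliability designs report ICC/SEM/MDC (plus R and
    Rc for inter-rater/inter-device), validity adds Bland–Altman.
    """

    paired_factor: str
    levels: tuple[str, str]
    fixed: Mapping[str, str] = field(default_factory=dict)
    kind: Literal["intra_rater", "inter_rater", "inter_device", "validity"] = "intra_rater"
    mdc_variant: str = "sqrt2"

    def __post_init__(self) -> None:
        object.__setattr__(self, "fixed", dict(self.fixed))
        object.__setattr__(self, "levels", tuple(str(l) for l in self.levels))
        if self.paired_factor not in ("session", "rater", "device"):
            raise ValueError("paired_factor must be session, rater, or device")


def run_comparison(
    table: MeasurementTable, design: ComparisonDesign, min_pairs: int = 3
) -> pd.DataFrame:
    """Run the full agreement battery per (muscle, metric) cell of a design.

    Pairing is pairwise complete-case: participants missing either member of
    the pair are dropped and the remaining n is reported.  Cells with fewer
    than ``min_pairs`` complete pairs are flagged (``status`` column) rather
    than fatal.

    Returns a tidy frame with one row per cell: ICC and CI, SEM/MDC in
    absolute units and percent of the first-level mean, Pearson and
    concordance coefficients with CIs where the design calls for them, the
    Bland–Altman kind and limits for validity designs, and the ICC
    interpretation band.
    """
    df = table.df
    for key, val in design.fixed.items():
        df = df[df[key].astype(str) == str(val)]
    lx, ly = design.levels
    col = design.paired_factor
    rows = []
    want_corr = design.kind in ("inter_rater", "inter_device", "validity")
    want_ba = design.kind == "validity"
    for (muscle, metric), cell in df.groupby(["muscle", "metric"], sort=True):
        piv = cell.pivot_table(
            index="participant", columns=col, values="value", aggfunc="first"
        )
        piv.columns = piv.columns.astype(str)
        out: dict = {
            "muscle": muscle,
            "metric": metric,
            "comparison": f"{col}:{lx}-vs-{ly}",
            "kind": design.kind,
        }
        if lx not in piv.columns or ly not in piv.columns:
            out.update(n=0, status="missing_level")
            rows.append(out)
            continue
        pairs = PairedSample.from_xy(
            piv[lx].to_numpy(), piv[ly].to_numpy(), label=f"{muscle}/{metric}"
        )
        out["n"] = pairs.n
        if pairs.n < min_pairs:
            out["status"] = "insufficient_pairs"
            rows.append(out)
            continue
        out["status"] = "ok"
        try:
            icc, (lo, hi) = icc_2_1(pairs)
        except ValueError:
            out["status"] = "degenerate"
            rows.append(out)
            continue
        sd1 = float(np.std(pairs.x, ddof=1))
        mean1 = float(np.mean(pairs.x))
        s_abs = sem(sd1, icc)
        m_abs = mdc(s_abs, design.mdc_variant)
        out.update(
            icc=icc,
            icc_ci_low=lo,
            icc_ci_high=hi,
            icc_band=classify_coefficient(icc),
            sd1=sd1,
            mean_ref=mean1,
            sem_abs=s_abs,
            sem_pct=100.0 * s_abs / abs(mean1) if mean1 != 0 else np.nan,
            mdc_abs=m_abs,
            mdc_pct=100.0 * m_abs / abs(mean1) if mean1 != 0 else np.nan,
            mdc_variant=design.mdc_variant,
        )
        if want_corr:
            try:
                r, r_ci = pearson_ci(pairs)
                rc, rc_ci = lin_ccc(pairs)
                out.update(
                    r=r, r_ci_low=r_ci[0], r_ci_high=r_ci[1],
                    rc=rc, rc_ci_low=rc_ci[0], rc_ci_high=rc_ci[1],
                )
            except ValueError:
                out["status"] = "degenerate_correlation"
        if want_ba:
            ba = bland_altman(pairs)
            out.update(ba_kind=ba.kind, ba_proportional_bias_r=ba.proportional_bias_r)
            if ba.kind == "standard":
                out.update(ba_bias=ba.bias, ba_loa_low=ba.loa_low, ba_loa_high=ba.loa_high)
            else:
                out.update(
                    ba_bias_intercept=ba.bias_intercept,
                    ba_bias_slope=ba.bias_slope,
                    ba_loa_half_width_intercept=ba.loa_half_width_intercept,
                    ba_loa_half_width_slope=ba.loa_half_width_slope,
                )
        rows.append(out)
    return pd.DataFrame(rows)
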