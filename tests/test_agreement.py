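"""Reliability/agreement statistics against hand computations, closed forms,
and an independent reference implementation (pingouin)."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rfdkit.agreement import (
    MDC_MULTIPLIERS,
    ComparisonDesign,
    PairedSample,
    bland_altman,
    classify_coefficient,
    icc_2_1,
    lin_ccc,
    mdc,
    pearson_ci,
    run_comparison,
    sem,
    sem_pct,
    summarize_method_column,
)
from rfdkit.model import MeasurementTable
from rfdkit.reference import (
    REFERENCE_MEDIANS,
    REFERENCE_N_BELOW,
    WORKED_EXAMPLE_CELL,
    reference_icc_table,
    reference_intra_rater_sem_mdc,
    reference_inter_rater_sem_mdc,
)
from rfdkit.synthetic import CohortSpec, simulate_cohort


def icc_2_1_variance_components(x, y):
    """Independent oracle: ICC(2,1) from explicit variance-component
    estimates of the restricted two-way model (hand algebra, no shared code
    with the ANOVA path)."""
    data = np.column_stack([x, y])
    n, k = data.shape
    grand = data.mean()
    ss_rows = k * ((data.mean(axis=1) - grand) ** 2).sum()
    ss_cols = n * ((data.mean(axis=0) - grand) ** 2).sum()
    ss_err = ((data - grand) ** 2).sum() - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    var_r = (msr - mse) / k          # subject variance
    var_c = (msc - mse) / n          # measurement (column) variance
    return var_r / (var_r + var_c + mse)


class TestIcc:
    def test_perfect_agreement(self):
        x = np.arange(10.0)
        icc, (lo, hi) = icc_2_1(PairedSample(x, x.copy()))
        assert icc == pytest.approx(1.0)
        assert lo == hi == icc

    def test_constant_offset_penalised_below_pearson(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = x + 5.0
        icc, _ = icc_2_1(PairedSample(x, y))
        r, _ = pearson_ci(PairedSample(x, y))
        assert r == pytest.approx(1.0)
        assert icc < 1.0

    def test_matches_variance_component_oracle_on_hand_tables(self):
        tables = [
            ([1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 3.0, 5.0]),
            ([10.0, 12.0, 9.0, 15.0], [11.0, 11.5, 10.0, 14.0]),
            ([1.0, 5.0, 2.0, 8.0], [2.0, 4.0, 2.5, 9.0]),
        ]
        for x, y in tables:
            icc, _ = icc_2_1(PairedSample(x, y))
            assert icc == pytest.approx(icc_2_1_variance_components(x, y), abs=1e-10)

    def test_matches_pingouin_estimate_and_ci(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        x = rng.normal(20, 5, 25)
        y = x + rng.normal(1.0, 2.0, 25)
        icc, (lo, hi) = icc_2_1(PairedSample(x, y))
        df = pd.DataFrame({
            "targets": np.r_[np.arange(25), np.arange(25)],
            "raters": ["a"] * 25 + ["b"] * 25,
            "scores": np.r_[x, y],
        })
        res = pg.intraclass_corr(df, "targets", "raters", "scores")
        row = res[res["Type"] == "ICC(A,1)"].iloc[0] if (res["Type"] == "ICC(A,1)").any() \
            else res[res["Type"] == "ICC2"].iloc[0]
        assert icc == pytest.approx(float(row["ICC"]), abs=1e-12)
        ref_lo, ref_hi = row["CI95"] if "CI95" in row else row["CI95%"]
        assert lo == pytest.approx(ref_lo, abs=0.005)
        assert hi == pytest.approx(ref_hi, abs=0.005)

    def test_negative_icc_possible(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = -x + 6.0  # anti-agreement
        icc, _ = icc_2_1(PairedSample(x, y))
        assert icc < 0

    def test_parameter_recovery_at_large_n(self):
        # subject variance 9, error 1 -> theoretical ICC 0.9
        spec = CohortSpec(
            n_subjects=2000, raters=("A",), devices=("D",), muscles=("KE",),
            var_subject=9.0, var_rater=0.0, var_device=0.0,
            var_session=0.0, var_error=1.0, rng_seed=12,
        )
        table, truth = simulate_cohort(spec)
        piv = table.df.pivot_table(index="participant", columns="session", values="value")
        icc, _ = icc_2_1(PairedSample(piv[1].to_numpy(), piv[2].to_numpy()))
        assert truth["theoretical_icc"] == pytest.approx(0.9)
        assert icc == pytest.approx(0.9, abs=0.02)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            icc_2_1(PairedSample([1.0, 2.0], [1.0, 2.0]))


class TestSemMdc:
    def test_perfect_icc_zero_sem(self):
        assert sem(4.92, 1.0) == 0.0

    def test_quarter_unexplained_variance(self):
        assert sem(10.0, 0.75) == pytest.approx(5.0)

    def test_worked_example_cell(self):
        cell = WORKED_EXAMPLE_CELL
        got = sem_pct(cell["sd1"], cell["icc"], cell["mean1"])
        # printed percentage used the unrounded ICC; rounding to 2 decimals
        # moves SEM% by up to ~0.3 points
        assert got == pytest.approx(cell["sem_pct"], abs=0.3)

    def test_mdc_from_printed_sem(self):
        assert mdc(8.62, "sqrt2") == pytest.approx(23.89, abs=0.01)
        assert mdc(6.92, "plain") == pytest.approx(13.56, abs=0.01)
        assert mdc(0.0, "sqrt2") == 0.0 and mdc(0.0, "plain") == 0.0

    def test_negative_icc_inflates_sem(self):
        assert sem(10.0, -0.93) == pytest.approx(10.0 * math.sqrt(1.93))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.001, 100.0), st.sampled_from(["sqrt2", "plain"]))
    def test_mdc_sem_ratio_exact(self, s, variant):
        assert mdc(s, variant) / s == pytest.approx(MDC_MULTIPLIERS[variant], rel=1e-12)

    def test_ratio_constants(self):
        assert MDC_MULTIPLIERS["sqrt2"] == pytest.approx(2.771859, abs=1e-6)
        assert MDC_MULTIPLIERS["plain"] == 1.96


class TestCorrelations:
    def test_linear_transform_gives_unit_pearson(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        r, _ = pearson_ci(PairedSample(x, 2 * x + 3))
        assert r == pytest.approx(1.0)
        r, _ = pearson_ci(PairedSample(x, -x))
        assert r == pytest.approx(-1.0)

    def test_hand_computed_r(self):
        # cov = 3, sx2 = sy2 = 5 (1/n moments cancel) -> r = 3/5
        r, _ = pearson_ci(PairedSample([1, 2, 3, 4], [2, 1, 4, 3]))
        assert r == pytest.approx(0.6, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson_ci(PairedSample([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))

    def test_ccc_identity_line(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        rc, _ = lin_ccc(PairedSample(x, x.copy()))
        assert rc == pytest.approx(1.0)

    def test_ccc_vanishes_with_growing_offset(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        rc_small = lin_ccc(PairedSample(x, x + 1.0))[0]
        rc_large = lin_ccc(PairedSample(x, x + 1000.0))[0]
        assert rc_large < rc_small
        assert rc_large == pytest.approx(0.0, abs=1e-4)
        assert pearson_ci(PairedSample(x, x + 1000.0))[0] == pytest.approx(1.0)

    def test_ccc_moment_oracle(self):
        # sxy=2.5, sx2=1.25, sy2=5, (dmean)^2=6.25 -> rc = 5/12.5 = 0.4
        rc, _ = lin_ccc(PairedSample([1, 2, 3, 4], [2, 4, 6, 8]))
        assert rc == pytest.approx(0.4, abs=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 100_000))
    def test_abs_ccc_never_exceeds_abs_pearson(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 50)
        x = rng.normal(rng.uniform(-10, 10), rng.uniform(0.5, 5), n)
        y = rng.normal(rng.uniform(-10, 10), rng.uniform(0.5, 5), n)
        if np.std(x) == 0 or np.std(y) == 0:
            return
        r, _ = pearson_ci(PairedSample(x, y)) if n >= 3 else (0, None)
        rc, _ = lin_ccc(PairedSample(x, y))
        assert abs(rc) <= abs(r) + 1e-12

    def test_fisher_ci_coverage_bivariate_normal(self):
        # r and rc CIs should cover the truth ~95% of the time at n=50
        rng = np.random.default_rng(2024)
        rho = 0.6
        cov = [[1.0, rho], [rho, 1.0]]
        hits = 0
        reps = 500
        for _ in range(reps):
            xy = rng.multivariate_normal([0, 0], cov, size=50)
            _, (lo, hi) = pearson_ci(PairedSample(xy[:, 0], xy[:, 1]))
            hits += lo <= rho <= hi
        assert hits / reps == pytest.approx(0.95, abs=0.02)


class TestBlandAltman:
    def test_identical_measurements(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = bland_altman(PairedSample(x, x.copy()))
        assert res.kind == "standard"
        assert res.bias == 0.0
        assert res.loa_low == res.loa_high == 0.0

    def test_constant_bias_monte_carlo(self):
        rng = np.random.default_rng(3)
        y = rng.normal(50, 10, 10_000)
        x = y - 2.0 + rng.normal(0, 1.0, 10_000)
        res = bland_altman(PairedSample(x, y))
        assert res.kind == "standard"
        se = 1.0 / math.sqrt(10_000)
        assert res.bias == pytest.approx(-2.0, abs=3 * se)
        assert (res.loa_high - res.loa_low) == pytest.approx(2 * 1.96 * 1.0, rel=0.05)

    def test_proportional_bias_triggers_regression_kind(self):
        a = np.linspace(10, 50, 40)
        rng = np.random.default_rng(1)
        d = 0.5 * a + rng.normal(0, 1.0, 40)  # corr(d, a) >> 0.5
        x = a + d / 2
        y = a - d / 2
        res = bland_altman(PairedSample(x, y))
        assert abs(res.proportional_bias_r) > 0.5
        assert res.kind == "regression_based"
        assert res.bias_slope == pytest.approx(0.5, abs=0.05)

    def test_heteroscedastic_loa_width_grows_with_average(self):
        rng = np.random.default_rng(5)
        a = np.linspace(10, 100, 2000)
        d = 0.3 * a + rng.normal(0, 0.05 * a)
        res = bland_altman(PairedSample(a + d / 2, a - d / 2))
        assert res.kind == "regression_based"
        assert res.loa_half_width_slope > 0


class TestClassification:
    @pytest.mark.parametrize(
        "value, band",
        [
            (0.90, "excellent"), (0.95, "excellent"), (1.0, "excellent"),
            (0.89, "good"), (0.75, "good"), (0.749, "good"),  # rounds to 0.75
            (0.7449, "moderate"), (0.50, "moderate"), (0.74, "moderate"),
            (0.49, "poor"), (0.0, "poor"), (-0.93, "poor"), (-1.0, "poor"),
            (0.895, "excellent"),  # rounds half away from zero to 0.90
        ],
    )
    def test_band_assignment(self, value, band):
        assert classify_coefficient(value) == band

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(-1.0, 1.0))
    def test_partition_of_unit_interval(self, value):
        assert classify_coefficient(value) in {"excellent", "good", "moderate", "poor"}


class TestMethodSummary:
    def test_published_column_medians_and_counts(self):
        table = reference_icc_table()
        for j, col in enumerate(table.columns):
            summary = summarize_method_column(table[col].to_numpy())
            assert summary.median == pytest.approx(REFERENCE_MEDIANS[j], abs=0.005), col
            assert summary.n_below_threshold == REFERENCE_N_BELOW[j], col

    def test_published_iqr_for_time_to_peak(self):
        col = reference_icc_table().iloc[:, 0].to_numpy()
        summary = summarize_method_column(col)
        assert summary.iqr_25 == pytest.approx(0.18)
        assert summary.iqr_75 == pytest.approx(0.68)

    def test_constant_column(self):
        summary = summarize_method_column([0.8] * 8)
        assert summary.median == summary.iqr_25 == summary.iqr_75 == 0.80
        assert summary.n_below_threshold == 0

    def test_iqr_brackets_median(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            vals = rng.uniform(-1, 1, 8)
            s = summarize_method_column(vals)
            assert s.iqr_25 <= s.median <= s.iqr_75


class TestPublishedSemMdcPairs:
    def test_intra_rater_pairs_use_sqrt2_multiplier(self):
        df = reference_intra_rater_sem_mdc()
        recomputed = df["sem_pct"] * MDC_MULTIPLIERS["sqrt2"]
        # printed SEM is rounded to 2 dp, so recomputed MDC can drift by
        # 0.005 * 2.772 ~ 0.014 from the printed value
        assert np.max(np.abs(recomputed - df["mdc_pct"])) <= 0.02

    def test_inter_rater_pairs_use_plain_multiplier(self):
        df = reference_inter_rater_sem_mdc()
        recomputed = df["sem_pct"] * MDC_MULTIPLIERS["plain"]
        assert np.max(np.abs(recomputed - df["mdc_pct"])) <= 0.02


class TestRunComparison:
    def _table_two_devices_identical(self):
        rng = np.random.default_rng(9)
        rows = []
        for i in range(12):
            v = rng.normal(30, 5)
            for device in ("Lafayette", "Hoggan"):
                rows.append(dict(participant=f"P{i:02d}", muscle="KE",
                                 device=device, rater="A", session=1,
                                 metric="peak_force_kg", value=v))
        return MeasurementTable(pd.DataFrame(rows))

    def test_identical_devices_perfect_agreement(self):
        table = self._table_two_devices_identical()
        design = ComparisonDesign(paired_factor="device",
                                  levels=("Lafayette", "Hoggan"),
                                  kind="inter_device")
        report = run_comparison(table, design)
        row = report.iloc[0]
        assert row["icc"] == pytest.approx(1.0)
        assert row["r"] == pytest.approx(1.0)
        assert row["rc"] == pytest.approx(1.0)
        assert row["sem_abs"] == pytest.approx(0.0, abs=1e-9)

    def test_insufficient_pairs_flagged_not_fatal(self):
        rows = [dict(participant="P01", muscle="KE", device="L", rater="A",
                     session=s, metric="peak_force_kg", value=30.0 + s)
                for s in (1, 2)]
        table = MeasurementTable(pd.DataFrame(rows))
        report = run_comparison(table, ComparisonDesign("session", ("1", "2")))
        assert report.iloc[0]["status"] == "insufficient_pairs"

    def test_device_offset_drops_icc_and_ccc_not_pearson(self):
        spec = CohortSpec(n_subjects=40, raters=("A",), sessions=(1,),
                          muscles=("KE",), var_session=0.0, var_error=0.0,
                          var_rater=0.0, var_device=0.0,
                          device_offsets={"Hoggan": 5.0}, rng_seed=21)
        table, _ = simulate_cohort(spec)
        design = ComparisonDesign("device", ("Lafayette", "Hoggan"),
                                  kind="inter_device")
        row = run_comparison(table, design).iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert row["rc"] < 0.9
        assert row["icc"] < 0.9

    def test_heteroscedastic_validity_selects_regression_ba(self):
        rng = np.random.default_rng(17)
        rows = []
        for i in range(40):
            crit = rng.uniform(10, 80)
            hhd = crit + 0.4 * crit + rng.normal(0, 0.02 * crit)
            for device, v in (("KinCom", crit), ("Lafayette", hhd)):
                rows.append(dict(participant=f"P{i:02d}", muscle="KE",
                                 device=device, rater="A", session=1,
                                 metric="rfd_kg_per_s", value=v))
        table = MeasurementTable(pd.DataFrame(rows))
        design = ComparisonDesign("device", ("Lafayette", "KinCom"), kind="validity")
        row = run_comparison(table, design).iloc[0]
        assert row["ba_kind"] == "regression_based"

    def test_ci_coverage_across_simulated_cells(self):
        # known-variance cohorts: the 95% CI should contain the theoretical
        # ICC in at least 93 of 100 cells
        hits = 0
        for rep in range(100):
            spec = CohortSpec(n_subjects=30, raters=("A",), devices=("D",),
                              muscles=("KE",), var_subject=3.0, var_rater=0.0,
                              var_device=0.0, var_session=0.0, var_error=1.0,
                              rng_seed=1000 + rep)
            table, truth = simulate_cohort(spec)
            piv = table.df.pivot_table(index="participant", columns="session",
                                       values="value")
            _, (lo, hi) = icc_2_1(PairedSample(piv[1].to_numpy(), piv[2].to_numpy()))
            hits += lo <= truth["theoretical_icc"] <= hi
        assert hits >= 93
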