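"""Paired ANOVA, normality-adaptive correlations, absolute-agreement ICC and
the cohort validation report."""
import itertools

import numpy as np
import pandas as pd
import pytest

from cogbat import (
    convergent_correlation, icc_absolute_agreement, paired_f, simulate_cohort,
    score_cohort, validation_report,
)
from cogbat.errors import SchemaError
from cogbat.psychometrics import correlation_band, icc_band


class TestPairedF:
    def test_identical_conditions_give_zero_f(self):
        r = paired_f([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert r.f_statistic == 0.0 and r.p_value == 1.0

    def test_hand_worked_fixture_f_equals_t_squared(self):
        # differences [1,1,1,5]: mean 2, sd 2, t = 2 -> F = 4
        r = paired_f([1.0, 1.0, 1.0, 5.0], [0.0, 0.0, 0.0, 0.0])
        assert r.f_statistic == pytest.approx(4.0)

    def test_f_matches_scipy_paired_t_squared(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 20)
        b = rng.normal(0.3, 1, 20)
        from scipy.stats import ttest_rel

        t, p = ttest_rel(a, b)
        r = paired_f(a, b)
        assert r.f_statistic == pytest.approx(t**2)
        assert r.p_value == pytest.approx(p)

    def test_constant_nonzero_difference_is_degenerate(self):
        r = paired_f([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])
        assert np.isinf(r.f_statistic) and r.degenerate


class TestCorrelation:
    def test_identity_is_pearson_one_large(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 30)
        r = convergent_correlation(a, a.copy())
        assert r.coefficient_type == "pearson"
        assert r.estimate == pytest.approx(1.0)
        assert r.band == "large"

    def test_negation_gives_minus_one(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 30)
        r = convergent_correlation(a, -a)
        assert r.estimate == pytest.approx(-1.0)

    def test_heavy_tailed_data_selects_kendall(self):
        rng = np.random.default_rng(3)
        a = rng.lognormal(0, 2.0, 80)
        b = a + rng.lognormal(0, 2.0, 80)
        r = convergent_correlation(a, b)
        assert r.coefficient_type == "kendall_tau"

    def test_kendall_matches_brute_force_pair_counting_on_six_points(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        b = [2.0, 1.0, 4.0, 3.0, 6.0, 5.0]
        conc = disc = 0
        for (i, j) in itertools.combinations(range(6), 2):
            s = (a[j] - a[i]) * (b[j] - b[i])
            conc += s > 0
            disc += s < 0
        tau_oracle = (conc - disc) / 15
        r = convergent_correlation(a, b, force="kendall_tau")
        assert r.estimate == pytest.approx(tau_oracle)

    def test_zero_variance_is_an_error(self):
        with pytest.raises(ZeroDivisionError):
            convergent_correlation([1.0] * 6, [1, 2, 3, 4, 5, 6])

    def test_pearson_equals_cosine_of_centred_vectors(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 25)
        b = 0.5 * a + rng.normal(0, 1, 25)
        r = convergent_correlation(a, b, force="pearson")
        ac, bc = a - a.mean(), b - b.mean()
        cosine = ac @ bc / np.sqrt((ac @ ac) * (bc @ bc))
        assert r.estimate == pytest.approx(cosine, abs=1e-12)


class TestIcc:
    def test_identical_occasions_give_icc_one_excellent(self):
        v = [3.0, 5.0, 9.0, 2.0, 7.0, 4.0]
        r = icc_absolute_agreement(v, v)
        assert r.icc == pytest.approx(1.0)
        assert r.band == "excellent"

    def test_six_subject_fixture_matches_hand_anova_to_1e10(self):
        occ1 = np.array([3.0, 5.0, 9.0, 2.0, 7.0, 4.0])
        occ2 = occ1 + 1.0  # constant shift penalised by absolute agreement
        # independent hand ANOVA
        y = np.column_stack([occ1, occ2])
        n, k = 6, 2
        grand = y.mean()
        msr = k * ((y.mean(1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((y.mean(0) - grand) ** 2).sum() / (k - 1)
        mse = (((y - y.mean(1, keepdims=True) - y.mean(0) + grand) ** 2).sum()
               / ((n - 1) * (k - 1)))
        oracle = (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))
        r = icc_absolute_agreement(occ1, occ2)
        assert r.icc == pytest.approx(oracle, abs=1e-10)

    def test_matches_pingouin_absolute_agreement_single_rater(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        occ1 = rng.normal(10, 3, 12)
        occ2 = occ1 + rng.normal(0.5, 1.5, 12)
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(12), 2),
            "rater": np.tile(["t1", "t2"], 12),
            "y": np.column_stack([occ1, occ2]).ravel(),
        })
        ref = pingouin.intraclass_corr(df, targets="subject", raters="rater",
                                       ratings="y")
        icc2 = float(ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        r = icc_absolute_agreement(occ1, occ2)
        assert r.icc == pytest.approx(icc2, abs=1e-8)

    def test_permuted_retest_has_near_zero_icc_on_average(self):
        rng = np.random.default_rng(6)
        base = rng.normal(0, 1, 20)
        iccs = [
            icc_absolute_agreement(base, rng.permutation(base)).icc
            for _ in range(300)
        ]
        assert abs(np.mean(iccs)) < 0.05

    def test_three_to_one_variance_ratio_recovers_icc_075(self):
        rng = np.random.default_rng(7)
        iccs = []
        for _ in range(300):
            subject = rng.normal(0, np.sqrt(3.0), 40)
            o1 = subject + rng.normal(0, 1.0, 40)
            o2 = subject + rng.normal(0, 1.0, 40)
            iccs.append(icc_absolute_agreement(o1, o2).icc)
        assert np.mean(iccs) == pytest.approx(0.75, abs=0.03)


class TestBands:
    @pytest.mark.parametrize("r,band", [
        (0.05, "none"), (0.1, "small"), (0.29, "small"), (0.3, "medium"),
        (0.49, "medium"), (0.5, "large"), (-0.6, "large"),
    ])
    def test_correlation_bands_at_the_printed_thresholds(self, r, band):
        assert correlation_band(r) == band

    @pytest.mark.parametrize("icc,band", [
        (0.49, "poor"), (0.5, "moderate"), (0.74, "moderate"), (0.75, "good"),
        (0.89, "good"), (0.90, "excellent"), (0.97, "excellent"),
    ])
    def test_icc_bands_at_the_printed_thresholds(self, icc, band):
        assert icc_band(icc) == band


class TestValidationReport:
    def test_missing_columns_raise_a_schema_error_listing_them(self):
        with pytest.raises(SchemaError, match="version"):
            validation_report(pd.DataFrame({"participant": ["a"] * 3,
                                            "task": ["bart"] * 3,
                                            "occasion": ["test"] * 3,
                                            "m": [1.0, 2.0, 3.0]}))

    def test_identical_versions_give_f_zero_and_r_one(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(50, 10, 12)
        rows = []
        for version in ("gamified", "standard"):
            for i, v in enumerate(vals):
                rows.append({"participant": f"p{i}", "task": "bart",
                             "version": version, "occasion": "test",
                             "mean_pumps": v})
        rep = validation_report(pd.DataFrame(rows))
        assert (rep.paired["F"] == 0.0).all()
        assert np.allclose(rep.correlations["estimate"], 1.0)

    def test_stable_cohort_without_occasion_noise_has_icc_one(self):
        logs, _ = simulate_cohort(
            "bart", {"target_pumps_mean": (40.0, 110.0)}, 10, occasions=2,
            seed=1,
        )
        cohort = score_cohort(logs)
        rep = validation_report(cohort)
        assert len(rep.icc) > 0
        assert np.allclose(rep.icc["icc"].dropna(), 1.0)
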