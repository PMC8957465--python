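"""Inferential stage: special functions, tests, agreement summaries."""

import math

import numpy as np
import pytest
from scipy import integrate, special, stats as sps

from arthromri.cohort import MethodModel, default_cohort_spec, make_cohort
from arthromri.stats import (ContingencyTable, DegenerateDataError,
                             agreement_summary, chi2_df1_p_value,
                             detection_rate_comparison, f_p_value,
                             one_way_anova, paired_t_test,
                             regularized_incomplete_beta,
                             student_t_p_two_sided)


class TestIncompleteBeta:
    @pytest.mark.parametrize("a,b", [(0.5, 0.5), (1, 3), (2.5, 7.5), (40, 0.5),
                                     (100, 100)])
    def test_matches_scipy_betainc(self, a, b):
        for x in (0.0, 1e-6, 0.1, 0.3, 0.5, 0.7, 0.9, 1 - 1e-6, 1.0):
            ours = regularized_incomplete_beta(a, b, x)
            ref = special.betainc(a, b, x)
            assert ours == pytest.approx(ref, rel=1e-10, abs=1e-14)

    def test_symmetry(self):
        assert regularized_incomplete_beta(2, 5, 0.3) == pytest.approx(
            1 - regularized_incomplete_beta(5, 2, 0.7), rel=1e-12)


class TestTailProbabilities:
    def test_t_matches_quadrature(self, rng):
        for _ in range(10):
            t = float(rng.uniform(-4, 4))
            df = int(rng.integers(2, 60))
            density = lambda x: (
                math.gamma((df + 1) / 2)
                / (math.sqrt(df * math.pi) * math.gamma(df / 2))
                * (1 + x * x / df) ** (-(df + 1) / 2)
            )
            tail, _ = integrate.quad(density, abs(t), np.inf)
            assert student_t_p_two_sided(t, df) == pytest.approx(
                2 * tail, abs=1e-6)

    def test_f_matches_scipy(self, rng):
        for _ in range(10):
            f = float(rng.uniform(0.1, 8))
            d1, d2 = int(rng.integers(1, 10)), int(rng.integers(2, 50))
            assert f_p_value(f, d1, d2) == pytest.approx(
                sps.f.sf(f, d1, d2), rel=1e-9)

    def test_chi2_df1_matches_scipy(self):
        for x in (0.0, 0.5, 3.841, 8.333, 20.0):
            assert chi2_df1_p_value(x) == pytest.approx(
                sps.chi2.sf(x, 1), rel=1e-10, abs=1e-300)


class TestPairedT:
    def test_no_change_gives_p_one(self):
        r = paired_t_test([3.0, 4.0, 5.0], [3.0, 4.0, 5.0])
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_hand_example(self):
        r = paired_t_test([10, 12, 14], [9, 10, 12])
        assert r.statistic == pytest.approx(5.0, rel=1e-12)
        assert r.df == 2
        assert r.p_value == pytest.approx(sps.ttest_rel([10, 12, 14],
                                                        [9, 10, 12]).pvalue,
                                          rel=1e-9)

    def test_matches_scipy_on_random_inputs(self, rng):
        for _ in range(10):
            pre = rng.normal(10, 2, 25)
            post = pre - rng.normal(0.5, 1, 25)
            ours = paired_t_test(pre, post)
            ref = sps.ttest_rel(pre, post)
            assert ours.statistic == pytest.approx(ref.statistic, rel=1e-10)
            assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_degenerate_constant_shift(self):
        with pytest.raises(DegenerateDataError):
            paired_t_test([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])


class TestAnova:
    def test_equal_means_f_zero(self):
        r = one_way_anova([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_hand_example(self):
        r = one_way_anova([[1, 2, 3], [4, 5, 6]])
        assert r.statistic == pytest.approx(13.5, rel=1e-12)
        assert r.df == (1, 4)

    def test_two_group_f_equals_t_squared(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.8, 1, 15)
        f = one_way_anova([a, b])
        t = sps.ttest_ind(a, b)
        assert f.statistic == pytest.approx(t.statistic**2, rel=1e-10)
        assert f.p_value == pytest.approx(t.pvalue, rel=1e-9)

    def test_degenerate_zero_within_variance(self):
        with pytest.raises(DegenerateDataError):
            one_way_anova([[2.0, 2.0], [3.0, 3.0]])


class TestDetectionRate:
    def test_identical_raters_statistic_zero(self):
        grades = [0, 1, 1, 2, 3, 1]
        r, table = detection_rate_comparison(grades, grades, 1)
        assert r.statistic == 0.0 and r.p_value == 1.0
        assert table.a == table.c

    def test_hand_table(self):
        method = [1] * 30 + [0] * 70
        pathology = [1] * 50 + [0] * 50
        r, table = detection_rate_comparison(method, pathology, 1)
        assert (table.a, table.b, table.c, table.d) == (30, 70, 50, 50)
        assert r.statistic == pytest.approx(200 * 2000**2 /
                                            (100 * 100 * 80 * 120), rel=1e-12)
        assert r.statistic == pytest.approx(8.333, abs=5e-4)
        assert r.p_value == pytest.approx(sps.chi2.sf(r.statistic, 1),
                                          rel=1e-9)

    def test_symmetric_in_rater_roles(self, rng):
        m = rng.integers(0, 4, 60)
        p = rng.integers(0, 4, 60)
        r1, _ = detection_rate_comparison(m, p, 2)
        r2, _ = detection_rate_comparison(p, m, 2)
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)

    def test_absent_level_is_degenerate(self):
        with pytest.raises(DegenerateDataError, match="absent"):
            detection_rate_comparison([0, 1, 1], [1, 0, 1], 3)

    def test_nan_pairs_dropped(self):
        m = [1.0, np.nan, 0.0, 1.0]
        p = [1.0, 2.0, np.nan, 0.0]
        r, table = detection_rate_comparison(m, p, 1)
        assert table.n == 4  # 2 joints x 2 raters

    def test_yates_shrinks_statistic(self):
        method = [1] * 30 + [0] * 70
        pathology = [1] * 50 + [0] * 50
        plain, _ = detection_rate_comparison(method, pathology, 1)
        corrected, _ = detection_rate_comparison(method, pathology, 1,
                                                 yates=True)
        assert corrected.statistic < plain.statistic


class TestAgreementSummary:
    def test_pathology_counts_match_printed_table(self, default_cohort):
        summary = agreement_summary(default_cohort, "synovial_hyperplasia")
        assert summary["counts"]["pathology"].tolist() == [15, 50, 27, 54]

    def test_counts_conserve_assessments(self, default_cohort):
        for lesion, total in [("effusion", 110),
                              ("synovial_hyperplasia", 146),
                              ("hemosiderin", 148)]:
            summary = agreement_summary(default_cohort, lesion)
            for arm in summary["counts"].columns:
                assert summary["counts"][arm].sum() == total

    def test_exact_arm_never_significant(self):
        spec = default_cohort_spec(
            seed=4, arm_models={"conventional_mri": MethodModel("exact"),
                                "canny_mri": MethodModel("exact")})
        cohort = make_cohort(spec)
        summary = agreement_summary(cohort, "hemosiderin")
        for result in summary["tests"].values():
            assert result is not None
            assert result.statistic == 0.0 and result.p_value == 1.0

    def test_unknown_lesion_rejected(self, default_cohort):
        with pytest.raises(ValueError, match="lesion"):
            agreement_summary(default_cohort, "osteophyte")


class TestContainers:
    def test_contingency_rejects_negative(self):
        with pytest.raises(ValueError):
            ContingencyTable(a=-1, b=2, c=3, d=4, level=1)

    def test_p_value_bounds_enforced(self):
        from arthromri.stats import TestResult

        with pytest.raises(ValueError):
            TestResult(1.0, 1, 1.5, "bad", 3)
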