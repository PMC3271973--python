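"""Group pooling, t tests, ANOVA with Bonferroni post-hocs, correlation."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from seroscreen import (
    anova_bonferroni,
    fold_change,
    pearson_r2,
    pool_summaries,
    ttest_raw,
    welch_t_from_summaries,
)
from seroscreen.cohorts import SERUM_CASE_GROUPS, SERUM_CONTROL_GROUPS, SERUM_GROUPS


def summaries(values):
    v = np.asarray(values, dtype=float)
    return len(v), v.mean(), v.std(ddof=1)


class TestPoolSummaries:
    def test_published_case_groups_pool_to_reported_mean(self):
        groups = [
            (SERUM_GROUPS[g].n, SERUM_GROUPS[g].mean, SERUM_GROUPS[g].sd)
            for g in SERUM_CASE_GROUPS
        ]
        n, mean, sd = pool_summaries(groups)
        assert n == 72
        assert round(mean, 2) == 1344.09

    def test_single_group_is_identity(self):
        assert pool_summaries([(10, 5.0, 2.0)]) == (10, 5.0, 2.0)

    def test_matches_concatenated_raw_moments(self, rng):
        a = rng.normal(10, 3, size=17)
        b = rng.normal(40, 9, size=23)
        n, mean, sd = pool_summaries([summaries(a), summaries(b)])
        concat = np.concatenate([a, b])
        assert n == len(concat)
        assert mean == pytest.approx(concat.mean(), abs=1e-10)
        assert sd == pytest.approx(concat.std(ddof=1), abs=1e-10)

    def test_associativity(self, rng):
        gs = [summaries(rng.normal(m, 2, size=n)) for m, n in [(5, 8), (9, 12), (2, 6)]]
        ab = pool_summaries(gs[:2])
        nested = pool_summaries([ab, gs[2]])
        flat = pool_summaries(gs)
        assert nested[1] == pytest.approx(flat[1], abs=1e-10)
        assert nested[2] == pytest.approx(flat[2], abs=1e-10)

    def test_n1_group_without_sd_is_allowed(self):
        n, mean, sd = pool_summaries([(1, 4.0, None), (1, 8.0, None)])
        assert n == 2 and mean == 6.0
        assert sd == pytest.approx(np.std([4.0, 8.0], ddof=1))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pool_summaries([])


class TestWelchFromSummaries:
    def test_identical_summaries_give_null_result(self):
        res = welch_t_from_summaries(5.0, 2.0, 10, 5.0, 2.0, 10)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_published_cohort_bound(self):
        ctrl = pool_summaries(
            [(SERUM_GROUPS[g].n, SERUM_GROUPS[g].mean, SERUM_GROUPS[g].sd) for g in SERUM_CONTROL_GROUPS]
        )
        case = pool_summaries(
            [(SERUM_GROUPS[g].n, SERUM_GROUPS[g].mean, SERUM_GROUPS[g].sd) for g in SERUM_CASE_GROUPS]
        )
        res = welch_t_from_summaries(case[1], case[2], case[0], ctrl[1], ctrl[2], ctrl[0])
        assert res.p <= 5e-5

    def test_agrees_with_raw_welch_test(self, rng):
        a = rng.lognormal(6, 0.8, size=14)
        b = rng.lognormal(6.4, 0.6, size=19)
        from_raw = ttest_raw(a, b, variant="welch")
        from_sum = welch_t_from_summaries(*(summaries(a)[i] for i in (1, 2, 0)),
                                          *(summaries(b)[i] for i in (1, 2, 0)))
        assert from_sum.statistic == pytest.approx(from_raw.statistic, abs=1e-10)
        assert from_sum.p == pytest.approx(from_raw.p, abs=1e-10)

    def test_degenerate_zero_variance_conventions(self):
        assert welch_t_from_summaries(3.0, 0.0, 5, 3.0, 0.0, 5).p == 1.0
        res = welch_t_from_summaries(3.0, 0.0, 5, 4.0, 0.0, 5)
        assert res.p == 0.0 and res.note is not None


class TestTtestRaw:
    def test_group_against_itself_is_null(self, rng):
        a = rng.normal(size=10)
        res = ttest_raw(a, a)
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_pooled_t_squared_equals_anova_f(self, rng):
        a = rng.normal(0, 1, size=9)
        b = rng.normal(1, 2, size=13)
        t = ttest_raw(a, b, variant="pooled")
        overall, _ = anova_bonferroni({"a": a, "b": b})
        assert t.statistic**2 == pytest.approx(overall.statistic, rel=1e-10)

    def test_agrees_with_permutation_oracle(self, rng):
        a = rng.normal(0.0, 1.0, size=10)
        b = rng.normal(0.8, 1.0, size=10)
        observed = ttest_raw(a, b, variant="pooled")
        pooled = np.concatenate([a, b])
        n1, n = len(a), len(pooled)
        total, ss_total = pooled.sum(), (pooled**2).sum()
        draws = 200_000
        idx = np.argsort(rng.random((draws, n)), axis=1)[:, :n1]
        s1 = pooled[idx].sum(axis=1)
        m1, m2 = s1 / n1, (total - s1) / (n - n1)
        ss_within = ss_total - n1 * m1**2 - (n - n1) * m2**2
        t_perm = (m1 - m2) / np.sqrt(ss_within / (n - 2) * (1 / n1 + 1 / (n - n1)))
        p_perm = np.mean(np.abs(t_perm) >= abs(observed.statistic) - 1e-12)
        assert observed.p == pytest.approx(p_perm, abs=0.02)

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            ttest_raw([1.0], [2.0, 3.0])


class TestAnovaBonferroni:
    def test_identical_groups_are_degenerate(self):
        groups = {k: [2.0, 2.0, 2.0] for k in "abc"}
        overall, pairwise = anova_bonferroni(groups)
        assert overall.statistic == 0.0 and overall.p == 1.0
        assert all(t.adjusted_p == 1.0 for t in pairwise)

    def test_f_matches_sum_of_squares_oracle(self, rng):
        groups = {
            "a": rng.normal(0, 1, size=11),
            "b": rng.normal(1, 1.5, size=8),
            "c": rng.normal(2, 0.7, size=14),
        }
        overall, _ = anova_bonferroni(groups)
        concat = np.concatenate(list(groups.values()))
        grand = concat.mean()
        ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
        ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
        k, n = len(groups), len(concat)
        f = (ss_between / (k - 1)) / (ss_within / (n - k))
        assert overall.statistic == pytest.approx(f, abs=1e-10)
        assert overall.p == pytest.approx(sps.f.sf(f, k - 1, n - k), abs=1e-12)

    def test_bonferroni_bounds(self, rng):
        groups = {k: rng.normal(i, 1, size=7) for i, k in enumerate("abcd")}
        _, pairwise = anova_bonferroni(groups)
        assert len(pairwise) == 6
        for t in pairwise:
            assert t.p <= t.adjusted_p <= 1.0
            assert t.adjusted_p == pytest.approx(min(1.0, t.p * 6))


class TestFoldChange:
    def test_published_malignant_vs_benign_ratio_rounds_to_three(self):
        ratio = fold_change(1344.09, SERUM_GROUPS["Benign"].mean)
        assert ratio == pytest.approx(3.406, abs=1e-3)
        assert round(ratio) == 3

    def test_equal_means_are_unit_ratio(self):
        assert fold_change(7.7, 7.7) == 1.0

    def test_reciprocal_identity(self):
        assert fold_change(3.0, 8.0) * fold_change(8.0, 3.0) == pytest.approx(1.0)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            fold_change(1.0, 0.0)


class TestPearsonR2:
    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        assert pearson_r2(x, 2 * x + 1) == pytest.approx(1.0)

    def test_null_mean_matches_theory(self, rng):
        # under independence E[r^2] = 1/(n-1)
        n, reps = 20, 3000
        x = rng.normal(size=n)
        vals = [pearson_r2(x, rng.permutation(x)) for _ in range(reps)]
        assert np.mean(vals) == pytest.approx(1 / (n - 1), rel=0.15)

    def test_affine_invariance(self, rng):
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        assert pearson_r2(x, y) == pytest.approx(pearson_r2(3 * x - 7, -0.5 * y + 2))

    def test_zero_variance_reported_missing(self):
        assert math.isnan(pearson_r2([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))
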