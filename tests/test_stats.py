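"""Hand-implemented tests vs permutation oracles and scipy cross-checks."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from pbodyquant.stats import (
    mann_whitney_u,
    pearson_correlation,
    permutation_oracle,
    steel_dwass,
    student_t_two_tailed,
)


class TestStudentT:
    def test_identical_samples(self):
        res = student_t_two_tailed([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        assert res.pvalue == 1.0

    def test_separation_limit(self):
        x = np.array([1.0, 2.0, 3.0])
        res = student_t_two_tailed(x, x + 1000.0)
        assert res.pvalue < 1e-6

    def test_zero_variance_conventions(self):
        same = student_t_two_tailed([2.0, 2.0], [2.0, 2.0])
        assert same.pvalue == 1.0
        apart = student_t_two_tailed([2.0, 2.0], [3.0, 3.0])
        assert apart.pvalue == 0.0
        assert any("degenerate" in n for n in apart.notes)

    def test_matches_scipy_cross_check(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 8), rng.normal(0.5, 1.2, 11)
        ours = student_t_two_tailed(x, y)
        ref = sps.ttest_ind(x, y, equal_var=True)
        assert ours.statistic == pytest.approx(ref.statistic)
        assert ours.pvalue == pytest.approx(ref.pvalue)
        ours_w = student_t_two_tailed(x, y, welch=True)
        ref_w = sps.ttest_ind(x, y, equal_var=False)
        assert ours_w.pvalue == pytest.approx(ref_w.pvalue)

    def test_symmetric_under_group_swap(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=6), rng.normal(size=9)
        assert student_t_two_tailed(x, y).pvalue == pytest.approx(
            student_t_two_tailed(y, x).pvalue
        )

    def test_agrees_with_exhaustive_permutation_midrange(self):
        # moderately separated groups, where the permutation distribution
        # (20 splits) can actually be matched by the t tail
        x, y = [-1.71, 0.13, 0.18], [2.68, 0.32, 1.52]
        p_t = student_t_two_tailed(x, y).pvalue
        p_perm = permutation_oracle(
            lambda a, b: student_t_two_tailed(a, b).statistic, x, y
        )
        assert abs(p_t - p_perm) < 0.02


class TestMannWhitney:
    def test_exact_small_sample_example(self):
        res = mann_whitney_u([1.0, 2.0], [3.0, 4.0])
        assert res.statistic == 0.0
        assert res.pvalue == pytest.approx(1.0 / 3.0)
        assert "exact" in res.notes

    def test_exact_matches_full_enumeration(self):
        # independent oracle: enumerate all rank assignments directly
        rng = np.random.default_rng(2)
        x, y = rng.normal(0, 1, 5), rng.normal(1, 1, 6)
        res = mann_whitney_u(x, y)
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)
        nx = len(x)
        mu = nx * len(y) / 2.0
        obs = abs(ranks[:nx].sum() - nx * (nx + 1) / 2 - mu)
        count = total = 0
        for combo in itertools.combinations(range(len(pooled)), nx):
            u = ranks[list(combo)].sum() - nx * (nx + 1) / 2
            total += 1
            count += abs(u - mu) >= obs - 1e-12
        assert res.pvalue == pytest.approx(count / total)

    def test_complete_ties_give_central_u(self):
        res = mann_whitney_u([5.0] * 4, [5.0] * 6)
        assert res.statistic == 4 * 6 / 2.0
        assert res.pvalue == 1.0

    def test_asymptotic_close_to_exact_at_6_plus_6(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(0, 1, 6), rng.normal(0.8, 1, 6)
        exact = mann_whitney_u(x, y, method="exact").pvalue
        approx = mann_whitney_u(x, y, method="asymptotic").pvalue
        assert abs(exact - approx) < 0.01

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        x, y = rng.uniform(1, 5, 7), rng.uniform(2, 6, 8)
        a = mann_whitney_u(x, y)
        b = mann_whitney_u(np.exp(x), np.exp(y))
        assert a.statistic == b.statistic
        assert a.pvalue == b.pvalue


class TestPearson:
    def test_perfect_correlation(self):
        x = np.arange(5.0)
        assert pearson_correlation(x, 3 * x + 1)[0] == pytest.approx(1.0)

    def test_orthogonal_contrasts_zero(self):
        r, p = pearson_correlation([-1.0, 0.0, 1.0], [1.0, -2.0, 1.0])
        assert r == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_t_transform_tail_frozen_values(self):
        # r=0.46: the t transform gives p ≈ 9.4e-16 at n=274 and ≈ 6.2e-7
        # at n=107 (a sample size consistent with a printed P ≈ 6.5e-7)
        def p_for(n, r=0.46):
            x = np.linspace(-1, 1, n)
            resid = np.sin(np.arange(n))  # arbitrary, made orthogonal below
            resid = resid - resid.mean()
            resid -= (resid @ (x - x.mean())) / ((x - x.mean()) @ (x - x.mean())) * (
                x - x.mean()
            )
            xs = (x - x.mean()) / np.std(x)
            rs = resid / np.std(resid)
            y = r * xs + math.sqrt(1 - r * r) * rs
            rr, pp = pearson_correlation(x, y)
            assert rr == pytest.approx(r, abs=1e-12)
            return pp

        assert p_for(274) == pytest.approx(9.404e-16, rel=0.01)
        assert p_for(107) == pytest.approx(6.205e-7, rel=0.01)

    def test_matches_scipy_cross_check(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=40), rng.normal(size=40)
        r, p = pearson_correlation(x, y)
        ref = sps.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestSteelDwass:
    def test_identical_groups_null(self):
        g = {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0], "c": [1.0, 2.0, 3.0]}
        for res in steel_dwass(g):
            assert res.pvalue >= 0.99

    def test_shifted_group_flagged(self):
        rng = np.random.default_rng(6)
        base = rng.normal(0, 1, 30)
        g = {"a": base, "b": rng.normal(0, 1, 30), "c": rng.normal(0, 1, 30) + 5.0}
        table = {(r.group_a, r.group_b): r.pvalue for r in steel_dwass(g)}
        assert table[("a", "c")] < 0.0005
        assert table[("b", "c")] < 0.0005
        assert table[("a", "b")] > 0.05

    def test_asymptotic_close_to_permutation_small_n(self):
        g = {"a": [1.0, 2.0, 3.0, 4.0], "b": [1.1, 2.1, 3.05, 4.05],
             "c": [9.0, 10.0, 11.0, 12.0]}
        asym = {(r.group_a, r.group_b): r.pvalue for r in steel_dwass(g)}
        perm = {
            (r.group_a, r.group_b): r.pvalue
            for r in steel_dwass(g, method="permutation", n_resamples=100_000, seed=42)
        }
        for pair in asym:
            assert abs(asym[pair] - perm[pair]) < 0.05

    def test_rank_based_hence_monotone_invariant(self):
        rng = np.random.default_rng(7)
        g = {k: rng.uniform(1, 10, 8) for k in "abc"}
        h = {k: np.log(v) for k, v in g.items()}
        pa = [r.pvalue for r in steel_dwass(g)]
        pb = [r.pvalue for r in steel_dwass(h)]
        assert pa == pytest.approx(pb)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            steel_dwass({"a": [1.0], "b": [1.0, 2.0], "c": [1.0, 2.0]})
    def test_two_groups_rejected(self):
        with pytest.raises(ValueError):
            steel_dwass({"a": [1.0, 2.0], "b": [1.0, 2.0]})


class TestPermutationOracle:
    def test_exhaustive_enumeration_count(self):
        # C(8,4)=70 splits: a statistic that records how often it is called
        calls = []

        def stat(a, b):
            calls.append(1)
            return float(np.mean(a) - np.mean(b))

        permutation_oracle(stat, [1.0, 2.0, 3.0, 4.0], [5.0, 6.0, 7.0, 8.0])
        assert len(calls) == 70 + 1  # one observed + 70 enumerated

    def test_monte_carlo_p_bounded_below(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(0, 1, 10), rng.normal(10, 1, 10)
        p = permutation_oracle(
            lambda a, b: float(np.mean(a) - np.mean(b)), x, y,
            n_resamples=500, seed=1, exhaustive_limit=10,
        )
        assert 1.0 / 501.0 <= p <= 1.0
        assert p == pytest.approx(1.0 / 501.0)

    def test_oracle_reproduces_t_p_for_normal_data(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(0, 1, 10), rng.normal(0.6, 1, 10)
        p_t = student_t_two_tailed(x, y).pvalue
        p_perm = permutation_oracle(
            lambda a, b: student_t_two_tailed(a, b).statistic, x, y,
            n_resamples=10_000, seed=2, exhaustive_limit=10,
        )
        assert abs(p_t - p_perm) < 0.02


class TestNullCalibration:
    def test_type_one_error_rates(self):
        rng = np.random.default_rng(10)
        rej_t = rej_m = 0
        reps = 1000
        for _ in range(reps):
            x, y = rng.normal(0, 1, 10), rng.normal(0, 1, 10)
            rej_t += student_t_two_tailed(x, y).pvalue < 0.05
            rej_m += mann_whitney_u(x, y).pvalue < 0.05
        assert rej_t / reps == pytest.approx(0.05, abs=0.02)
        assert rej_m / reps == pytest.approx(0.05, abs=0.02)

    def test_steel_dwass_familywise_error_bounded(self):
        rng = np.random.default_rng(11)
        reps, hits = 1000, 0
        for _ in range(reps):
            g = {k: rng.normal(0, 1, 10) for k in "abc"}
            hits += min(r.pvalue for r in steel_dwass(g)) < 0.05
        assert hits / reps <= 0.07
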