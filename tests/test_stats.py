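"""Permutation ANOVA, Holm, Kruskal-Wallis, two-way ANOVA, regression."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from copebuoy import (
    holm_bonferroni,
    kruskal_wallis,
    length_lipid_regression,
    permutation_anova,
    two_way_anova,
)
from copebuoy.stats import attach_holm, count_stratified_arrangements


class TestPermutationAnova:
    def test_exhaustive_two_groups_worked_example(self):
        """{1,2} vs {10,11}: 2 of the 6 label arrangements reach the
        observed |mean difference|, so the exact p is 1/3."""
        res = permutation_anova([1, 2, 10, 11], ["5 m", "5 m", "20 m", "20 m"])
        assert res.exact
        assert res.iterations == 6
        assert res.p_raw == pytest.approx(2 / 6, abs=1e-12)

    def test_constant_response_degenerates(self):
        res = permutation_anova([3.0] * 8, ["a"] * 4 + ["b"] * 4)
        assert res.F_obs == 0.0
        assert res.p_raw == 1.0

    def test_determinism_under_seed(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=40)
        depth = np.repeat(["a", "b"], 20)
        date = np.tile(np.repeat(["d1", "d2"], 10), 2)
        r1 = permutation_anova(y, depth, date, iterations=300, seed=7)
        r2 = permutation_anova(y, depth, date, iterations=300, seed=7)
        assert r1.p_raw == r2.p_raw and r1.F_obs == r2.F_obs

    def test_single_depth_level_raises(self):
        with pytest.raises(ValueError):
            permutation_anova([1, 2, 3], ["a", "a", "a"])

    def test_stratum_without_contrast_dropped(self, caplog):
        y = [1.0, 2.0, 10.0, 11.0, 5.0, 6.0]
        depth = ["a", "a", "b", "b", "a", "a"]
        date = ["d1", "d1", "d1", "d1", "d2", "d2"]
        with caplog.at_level("WARNING"):
            res = permutation_anova(y, depth, date)
        assert res.dropped_strata == ("d2",)
        assert res.n == 4

    def test_exhaustive_and_monte_carlo_agree(self):
        """Same dataset through both paths: binomial-error agreement."""
        rng = np.random.default_rng(5)
        y = np.concatenate([rng.normal(0, 1, 5), rng.normal(1.5, 1, 5)])
        depth = np.repeat(["a", "b"], 5)
        exact = permutation_anova(y, depth)  # C(10,5)=252 arrangements
        assert exact.exact
        mc = permutation_anova(y, depth, iterations=4000, seed=11,
                               exhaustive_limit=10)
        assert not mc.exact
        se = np.sqrt(exact.p_raw * (1 - exact.p_raw) / 4000)
        assert abs(mc.p_raw - exact.p_raw) < 4 * se + 1e-3

    def test_arrangement_counting(self):
        depth = np.array([0, 0, 1, 1])
        date = np.array([0, 0, 0, 0])
        assert count_stratified_arrangements(depth, date) == 6
        date2 = np.array([0, 0, 1, 1])
        depth2 = np.array([0, 1, 0, 1])
        assert count_stratified_arrangements(depth2, date2) == 4

    def test_covariate_absorbs_date_shift(self):
        """A pure date effect with no depth effect stays non-significant."""
        rng = np.random.default_rng(21)
        n = 30
        date = np.tile(np.repeat(["d1", "d2"], n // 2), 2)[: 2 * n]
        depth = np.repeat(["a", "b"], n)
        shift = np.where(date == "d2", 10.0, 0.0)
        y = rng.normal(0, 1, 2 * n) + shift
        res = permutation_anova(y, depth, date, iterations=800, seed=3)
        assert res.p_raw > 0.05

    def test_power_monotone_in_effect_size(self):
        """Rejection rate grows with the depth effect (sweep test)."""
        rng = np.random.default_rng(17)
        rates = []
        for effect in (0.0, 0.8, 2.0):
            hits = 0
            for rep in range(40):
                y = np.concatenate([
                    rng.normal(0, 1, 12), rng.normal(effect, 1, 12)])
                res = permutation_anova(
                    y, np.repeat(["a", "b"], 12), iterations=400,
                    seed=int(rng.integers(2**31)), exhaustive_limit=10)
                hits += res.p_raw <= 0.05
            rates.append(hits / 40)
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] > rates[0]


class TestHolm:
    def test_hand_step_down_example(self):
        assert holm_bonferroni([0.01, 0.04, 0.03]) == pytest.approx(
            [0.03, 0.06, 0.06])

    def test_single_p_unchanged(self):
        assert holm_bonferroni([0.2]) == [0.2]

    def test_all_ones(self):
        assert holm_bonferroni([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(0.001, 1.0, size=9)
        ours = holm_bonferroni(p)
        _, theirs, _, _ = multipletests(p, method="holm")
        assert ours == pytest.approx(theirs, rel=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_bonferroni([0.0, 0.5])

    def test_attach_holm_preserves_order_and_monotonicity(self):
        res = [permutation_anova([1, 2, 10, 11], ["a", "a", "b", "b"])
               for _ in range(3)]
        adjusted = attach_holm(res)
        for r in adjusted:
            assert r.p_adjusted >= r.p_raw


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=12))
def test_holm_properties(ps):
    adj = holm_bonferroni(ps)
    assert all(0 < a <= 1 for a in adj)
    assert all(a >= p - 1e-15 for a, p in zip(adj, ps))
    # order-preserving on the sorted scale
    order = np.argsort(ps)
    assert np.all(np.diff(np.asarray(adj)[order]) >= -1e-15)


class TestKruskalWallis:
    def test_worked_example(self):
        res = kruskal_wallis([[1, 2], [3, 4]])
        assert res.H == pytest.approx(2.4, abs=1e-12)
        assert res.df == 1
        assert not res.tie_corrected

    def test_full_ties(self):
        res = kruskal_wallis([[5, 5], [5, 5]])
        assert res.H == 0.0 and res.p == 1.0

    def test_group_order_symmetry(self, rng):
        a, b, c = rng.normal(size=8), rng.normal(size=5), rng.normal(size=7)
        h1 = kruskal_wallis([a, b, c]).H
        h2 = kruskal_wallis([c, a, b]).H
        assert h1 == pytest.approx(h2, rel=1e-12)

    def test_matches_scipy_with_ties(self, rng):
        from scipy.stats import kruskal

        a = rng.integers(0, 5, size=12).astype(float)
        b = rng.integers(0, 5, size=9).astype(float)
        ours = kruskal_wallis([a, b])
        ref_h, ref_p = kruskal(a, b)
        assert ours.H == pytest.approx(ref_h, rel=1e-12)
        assert ours.p == pytest.approx(ref_p, rel=1e-9)

    def test_tie_free_equals_uncorrected_formula(self, rng):
        a = rng.permutation(np.arange(1.0, 16.0))
        groups = [a[:5], a[5:9], a[9:]]
        ours = kruskal_wallis(groups)
        n = 15
        ranks = {v: i + 1 for i, v in enumerate(sorted(a))}
        h = 12 / (n * (n + 1)) * sum(
            len(g) * np.mean([ranks[v] for v in g]) ** 2 for g in groups
        ) - 3 * (n + 1)
        assert ours.H == pytest.approx(h, abs=1e-12)
        assert not ours.tie_corrected

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2], []])


class TestTwoWayAnova:
    def test_stage_dominates_depth_null(self, rng):
        """C4/C5-style data: huge stage effect, nil depth effect."""
        n = 40
        stage = np.repeat(["C4", "C5"], 2 * n)
        depth = np.tile(np.repeat(["a", "b"], n), 2)
        y = np.where(stage == "C5", 10.0, 0.0) + rng.normal(0, 0.5, 4 * n)
        out = two_way_anova(y, depth, stage)
        assert out["stage"]["F"] > 100
        assert out["stage"]["p"] < 1e-6
        assert out["depth"]["p"] > 0.05

    def test_balanced_design_matches_marginal(self, rng):
        """With balance, sequential SS for depth is order-independent and
        equals the statsmodels marginal (type II) value."""
        import pandas as pd
        from statsmodels.formula.api import ols
        from statsmodels.stats.anova import anova_lm

        n = 12
        stage = np.repeat(["C4", "C5"], 2 * n)
        depth = np.tile(np.repeat(["a", "b"], n), 2)
        y = rng.normal(0, 1, 4 * n) + (depth == "b") * 0.7
        out = two_way_anova(y, depth, stage)
        df = pd.DataFrame({"y": y, "depth": depth, "stage": stage})
        t2 = anova_lm(ols("y ~ C(depth) + C(stage)", df).fit(), typ=2)
        assert out["depth"]["F"] == pytest.approx(
            float(t2.loc["C(depth)", "F"]), rel=1e-9)

    def test_zero_variance_response(self):
        out = two_way_anova([1.0] * 8, ["a", "b"] * 4, ["x"] * 4 + ["y"] * 4)
        assert out["depth"]["F"] == 0.0 and out["stage"]["F"] == 0.0

    def test_single_level_factor_rejected(self):
        with pytest.raises(ValueError):
            two_way_anova([1, 2, 3, 4], ["a"] * 4, ["x", "x", "y", "y"])


class TestRegression:
    def test_perfectly_linear(self):
        x = np.arange(10.0)
        fit = length_lipid_regression(x, 2.0 * x + 1.0)
        assert fit["r_squared"] == pytest.approx(1.0)
        assert fit["slope"] == pytest.approx(2.0)

    def test_null_simulation_p_uniform(self, rng):
        """Independent noise: R^2 near zero, p roughly uniform."""
        ps = []
        for _ in range(200):
            x = rng.normal(size=50)
            y = rng.normal(size=50)
            fit = length_lipid_regression(x, y)
            ps.append(fit["p"])
        ps = np.asarray(ps)
        assert np.mean(ps < 0.05) < 0.12
        assert 0.3 < np.mean(ps) < 0.7

    def test_slope_recovery_within_3_se(self, rng):
        x = rng.uniform(0.5, 3.5, size=200)
        y = 0.8 * x + rng.normal(0, 0.3, size=200)
        fit = length_lipid_regression(x, y)
        assert abs(fit["slope"] - 0.8) < 3 * fit["stderr"]

    def test_zero_length_variance_rejected(self):
        with pytest.raises(ValueError):
            length_lipid_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
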