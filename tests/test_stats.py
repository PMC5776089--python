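import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from weaklink.stats import (
    friedman_exact_p,
    friedman_per_node,
    friedman_statistic,
    mauchly_test,
    percent_change,
    profile_analysis,
    split_nodes_by_change,
)


class TestPercentChange:
    def test_flat_and_doubled(self):
        t = pd.DataFrame({"Task": [2.0, 3.0], "Stim": [2.0, 6.0]},
                         index=["a", "b"])
        out = percent_change(t, "Task")
        assert out.loc["a", "Stim"] == 100.0
        assert out.loc["b", "Stim"] == 200.0
        assert (out["Task"] == 100.0).all()

    def test_zero_baseline_flagged(self):
        t = pd.DataFrame({"Task": [0.0], "Stim": [1.0]}, index=["a"])
        out = percent_change(t, "Task")
        assert out.loc["a"].isna().all()

    def test_unknown_baseline_rejected(self):
        with pytest.raises(ValueError):
            percent_change(pd.DataFrame({"A": [1.0]}), "B")


def friedman_brute_force_p(x):
    """Independent oracle: enumerate every per-subject rank permutation and
    compute the tie-corrected statistic from the raw formula each time."""
    x = np.asarray(x, float)
    n, k = x.shape
    base_ranks = [sps.rankdata(row) for row in x]
    ties = sum((np.unique(r, return_counts=True)[1] ** 3
                - np.unique(r, return_counts=True)[1]).sum() for r in base_ranks)
    c = 1 - ties / (n * k * (k**2 - 1))

    def stat(rank_rows):
        col = np.sum(rank_rows, axis=0)
        s = 12 / (n * k * (k + 1)) * (col**2).sum() - 3 * n * (k + 1)
        return s / c if c > 0 else 0.0

    observed = stat(np.array(base_ranks))
    hits = total = 0
    for combo in itertools.product(
        *[set(itertools.permutations(r)) for r in base_ranks]
    ):
        total += 1
        if stat(np.array(combo)) >= observed - 1e-9:
            hits += 1
    return hits / total


class TestFriedman:
    def test_identical_columns(self):
        x = np.tile([[1.0, 1.0, 1.0]], (6, 1))
        assert friedman_statistic(x) == 0.0
        assert friedman_exact_p(x) == 1.0

    def test_strictly_ordered_rows_statistic(self):
        # ranks 1,2,3 in every row: chi2 = 12n/(k(k+1)) * sum (Rbar - 2)^2 = 2n
        rng = np.random.default_rng(0)
        x = np.sort(rng.standard_normal((10, 3)), axis=1)
        assert friedman_statistic(x) == pytest.approx(20.0)

    def test_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            x = rng.standard_normal((12, 4))
            stat, _ = sps.friedmanchisquare(*x.T)
            assert friedman_statistic(x) == pytest.approx(stat, abs=1e-10)

    @pytest.mark.parametrize("n", [3, 4, 5, 6])
    def test_exact_p_matches_brute_force(self, n):
        rng = np.random.default_rng(n)
        x = rng.standard_normal((n, 3))
        assert friedman_exact_p(x) == pytest.approx(friedman_brute_force_p(x))

    def test_exact_p_with_ties(self):
        x = np.array([[1.0, 1.0, 2.0], [2.0, 1.0, 1.0],
                      [1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        assert friedman_exact_p(x) == pytest.approx(friedman_brute_force_p(x))

    def test_monotone_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((8, 3))
        y = np.exp(3 * x) - 5  # strictly increasing transform
        assert friedman_statistic(y) == pytest.approx(friedman_statistic(x))

    def test_per_node_bonferroni_and_skip(self):
        rng = np.random.default_rng(3)
        good = rng.standard_normal((21, 3))
        bad = good.copy()
        bad[0, 0] = np.nan
        with pytest.warns(RuntimeWarning, match="missing"):
            out = friedman_per_node({"good": good, "bad": bad},
                                    n_nodes_for_correction=23)
        assert list(out.index) == ["good"]
        row = out.loc["good"]
        assert row.p_bonferroni == min(1.0, row.p * 23)
        assert row.method == "chi2"  # 6^21 arrangements: asymptotic branch


class TestSplitNodes:
    def test_all_increased(self):
        t = pd.DataFrame({"Task": [1.0, 1.0], "Stim": [2.0, 3.0]},
                         index=["a", "b"])
        inc, rest = split_nodes_by_change(t, ("Stim", "Task"))
        assert inc == ["a", "b"] and rest == []

    def test_tie_goes_to_unchanged_group(self):
        t = pd.DataFrame({"Task": [1.0], "Stim": [1.0]}, index=["a"])
        inc, rest = split_nodes_by_change(t, ("Stim", "Task"))
        assert inc == [] and rest == ["a"]

    def test_matches_elementwise_comparison(self):
        rng = np.random.default_rng(4)
        t = pd.DataFrame({"Task": rng.random(20), "Stim": rng.random(20)},
                         index=[f"n{i}" for i in range(20)])
        inc, rest = split_nodes_by_change(t, ("Stim", "Task"))
        for name in t.index:
            expected_inc = t.loc[name, "Stim"] > t.loc[name, "Task"]
            assert (name in inc) == expected_inc


class TestMauchly:
    def _data_with_exact_cov(self, cov, n=40, seed=0):
        """Sample whose empirical covariance equals `cov` exactly."""
        rng = np.random.default_rng(seed)
        k = cov.shape[0]
        x = rng.standard_normal((n, k))
        x -= x.mean(axis=0)
        s = np.cov(x, rowvar=False, ddof=1)
        white = np.linalg.cholesky(np.linalg.inv(s))
        color = np.linalg.cholesky(cov)
        return x @ white @ color.T

    def test_compound_symmetry_gives_w_one(self):
        cov = 0.4 * np.ones((3, 3)) + 0.6 * np.eye(3)
        x = self._data_with_exact_cov(cov)
        w, p = mauchly_test(x)
        assert w == pytest.approx(1.0, abs=1e-10)
        assert p == pytest.approx(1.0, abs=1e-10)

    def test_w_in_unit_interval(self):
        rng = np.random.default_rng(5)
        for seed in range(10):
            x = rng.standard_normal((15, 4)) * [1.0, 2.0, 0.5, 1.5]
            w, p = mauchly_test(x)
            assert 0 < w <= 1 + 1e-12
            assert 0 <= p <= 1

    def test_detects_strong_autoregressive_structure(self):
        rng = np.random.default_rng(6)
        cov = np.array([[1.0, 0.9, 0.81], [0.9, 1.0, 0.9], [0.81, 0.9, 1.0]])
        x = rng.multivariate_normal(np.zeros(3), cov, size=100)
        _, p = mauchly_test(x)
        assert p < 0.05

    def test_shape_requirements(self):
        with pytest.raises(ValueError):
            mauchly_test(np.zeros((10, 2)))
        with pytest.raises(ValueError):
            mauchly_test(np.zeros((3, 4)))


class TestProfileAnalysis:
    def test_parallel_profiles_give_zero_interaction(self):
        base = np.array([1.0, 3.0, 2.0])
        offsets = np.array([0.0, 1.0, 2.0, 5.0, -1.0, 0.5])
        x = base[None, :] + offsets[:, None]
        res = profile_analysis(x, ["g1"] * 3 + ["g2"] * 3)
        assert res.f_interaction == pytest.approx(0.0, abs=1e-20)

    def test_two_conditions_equal_squared_t_on_differences(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal((14, 2))
        group = np.array(["a"] * 7 + ["b"] * 7)
        res = profile_analysis(x, group)
        diffs = x[:, 1] - x[:, 0]
        t, _ = sps.ttest_ind(diffs[group == "a"], diffs[group == "b"])
        assert res.f_interaction == pytest.approx(t**2, rel=1e-10)

    def test_constant_profile_shift_invariance(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal((10, 3))
        group = ["a"] * 5 + ["b"] * 5
        res1 = profile_analysis(x, group)
        res2 = profile_analysis(x + np.array([5.0, -2.0, 9.0])[None, :]
                                + rng.standard_normal((10, 1)), group)
        # adding any constant condition profile or per-case offset leaves
        # the parallelism F untouched only for the per-case offsets; the
        # condition profile shifts both groups equally so F is unchanged too
        assert res2.f_interaction == pytest.approx(res1.f_interaction, rel=1e-10)

    def test_matches_pingouin_mixed_anova(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(9)
        x = rng.standard_normal((12, 3)) + np.array([0.5, 0.0, -0.5])
        group = np.array(["a"] * 5 + ["b"] * 7)
        res = profile_analysis(x, group)
        df = pd.DataFrame({
            "dv": x.ravel(),
            "within": list(np.tile(["c1", "c2", "c3"], 12)),
            "subject": np.repeat(np.arange(12), 3),
            "group": np.repeat(group, 3),
        })
        aov = pingouin.mixed_anova(df, dv="dv", within="within",
                                   subject="subject", between="group")
        inter = aov[aov["Source"] == "Interaction"].iloc[0]
        p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
        assert res.f_interaction == pytest.approx(inter["F"], rel=1e-8)
        assert res.p_interaction == pytest.approx(inter[p_col], rel=1e-8)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            profile_analysis(np.zeros((3, 3)), ["a", "a", "b"])

    def test_more_than_two_groups_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            profile_analysis(np.zeros((6, 3)), ["a", "a", "b", "b", "c", "c"])
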