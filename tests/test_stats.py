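"""Statistical battery vs independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from stskit.stats import (
    StatsError,
    bh_adjust,
    correlation_screen,
    dunn_test,
    group_comparison,
    kruskal_wallis,
    linear_fit,
    logistic_fit,
    pearson,
    smd,
)


# ---------------------------------------------------------------------------
# independent oracles

def bh_bruteforce(p, m=None):
    """Literal min-over-tail definition of the BH step-up adjustment."""
    p = np.asarray(p, dtype=float)
    k = len(p)
    m = k if m is None else m
    order = np.argsort(p, kind="stable")
    ranks = np.empty(k, dtype=int)
    ranks[order] = np.arange(1, k + 1)
    out = np.empty(k)
    for i in range(k):
        tail = [m * p[j] / ranks[j] for j in range(k) if ranks[j] >= ranks[i]]
        out[i] = min(1.0, min(tail))
    return out


def average_ranks(pooled):
    """Mid-ranks computed via sorting, independently of scipy.rankdata."""
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(len(pooled))
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def kw_oracle(groups):
    """Tie-corrected H from the defining rank-sum formula."""
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = average_ranks(pooled)
    H = 0.0
    start = 0
    for g in groups:
        rsum = ranks[start:start + len(g)].sum()
        H += rsum**2 / len(g)
        start += len(g)
    H = 12.0 / (N * (N + 1)) * H - 3 * (N + 1)
    from collections import Counter

    ties = sum(t**3 - t for t in Counter(pooled.tolist()).values())
    return H / (1.0 - ties / (N**3 - N))


def dunn_oracle(groups):
    """Pairwise Dunn z from the defining formula, Counter-based ties."""
    from collections import Counter

    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = average_ranks(pooled)
    means, sizes, start = [], [], 0
    for g in groups:
        means.append(ranks[start:start + len(g)].mean())
        sizes.append(len(g))
        start += len(g)
    ties = sum(t**3 - t for t in Counter(pooled.tolist()).values())
    A = N * (N + 1) / 12.0 - ties / (12.0 * (N - 1))
    out = {}
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            out[(i, j)] = (means[i] - means[j]) / np.sqrt(
                A * (1.0 / sizes[i] + 1.0 / sizes[j]))
    return out


def logit_newton_oracle(X, y, iters=200):
    """Plain Newton-Raphson on the logistic log-likelihood."""
    beta = np.zeros(X.shape[1])
    for _ in range(iters):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1 - mu)
        grad = X.T @ (y - mu)
        hess = X.T @ (X * W[:, None])
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-12:
            break
    return beta


# ---------------------------------------------------------------------------

class TestPearson:
    def test_exact_linear_relation_gives_r_one(self):
        x = np.arange(10.0)
        r, p, n = pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert n == 10

    def test_constant_variable_rejected(self):
        with pytest.raises(StatsError, match="variance"):
            pearson(np.arange(5.0), np.ones(5))

    def test_matches_covariance_formula_oracle(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        r, _, _ = pearson(x, y)
        oracle = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_symmetry_and_positive_affine_invariance(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        r_xy, _, _ = pearson(x, y)
        r_yx, _, _ = pearson(y, x)
        r_aff, _, _ = pearson(3.0 * x + 7.0, 0.5 * y - 2.0)
        assert r_xy == pytest.approx(r_yx, abs=1e-12)
        assert r_xy == pytest.approx(r_aff, abs=1e-10)

    def test_missing_values_dropped_pairwise(self):
        x = np.array([1.0, 2, 3, np.nan, 5])
        y = np.array([2.0, 4, 6, 8, np.nan])
        r, _, n = pearson(x, y)
        assert n == 3
        assert r == pytest.approx(1.0)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.037], m=1), [0.037])

    def test_hand_worked_step_up_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04], m=4),
                                   [0.04, 0.04, 0.04, 0.04])

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_matches_bruteforce_definition(self, p):
        np.testing.assert_allclose(bh_adjust(p), bh_bruteforce(p), atol=1e-12)

    def test_matches_statsmodels_when_family_equals_tests(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        p = rng.uniform(size=40)
        _, sm_adj, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_adjust(p), sm_adj, atol=1e-12)

    def test_external_family_size_scales_adjustment(self):
        base = bh_adjust([0.01, 0.02], m=2)
        wider = bh_adjust([0.01, 0.02], m=21)
        np.testing.assert_allclose(wider, np.minimum(1, base * 21 / 2), atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(StatsError):
            bh_adjust([0.5, 1.2])


class TestCorrelationScreen:
    def _table(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        age = rng.normal(40, 15, n)
        time = 8 + 0.08 * age + rng.normal(0, 1.0, n)  # planted strong link
        return pd.DataFrame({
            "age": age, "time": time,
            "noise1": rng.normal(size=n), "noise2": rng.normal(size=n),
        })

    def test_planted_pair_discovered_nulls_not(self):
        table = self._table()
        pairs = [("time", "age"), ("time", "noise1"), ("time", "noise2"),
                 ("age", "noise1"), ("age", "noise2"), ("noise1", "noise2")]
        results = correlation_screen(table, pairs, m=21)
        by_pair = {(r.x_name, r.y_name): r for r in results}
        assert by_pair[("time", "age")].p_adj < 0.05
        nulls = [r for r in results if "noise" in r.y_name and r.x_name != "age"
                 or (r.x_name, r.y_name) == ("noise1", "noise2")]
        assert all(r.family_size == 21 for r in results)

    def test_unknown_variable_rejected(self):
        with pytest.raises(StatsError, match="unknown variable"):
            correlation_screen(self._table(), [("time", "nope")])

    def test_identical_tests_get_identical_adjustment(self):
        table = self._table()
        results = correlation_screen(table, [("time", "age"), ("time", "age")])
        assert results[0].p_adj == results[1].p_adj


class TestKruskalWallis:
    def test_identical_group_multisets_give_zero(self):
        H, _ = kruskal_wallis([np.array([1.0, 2, 3]), np.array([3.0, 1, 2])])
        assert H == pytest.approx(0.0, abs=1e-12)

    def test_matches_rank_formula_oracle_on_small_groups(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            groups = [rng.integers(0, 8, size=rng.integers(3, 9)).astype(float)
                      for _ in range(3)]
            if np.all(np.concatenate(groups) == np.concatenate(groups)[0]):
                continue
            H, _ = kruskal_wallis(groups)
            assert H == pytest.approx(kw_oracle(groups), abs=1e-9)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(22)
        groups = [rng.normal(loc=i, size=10) for i in range(3)]
        H1, _ = kruskal_wallis(groups)
        H2, _ = kruskal_wallis(groups[::-1])
        assert H1 == pytest.approx(H2, abs=1e-12)

    def test_all_identical_values_rejected(self):
        with pytest.raises(StatsError, match="identical"):
            kruskal_wallis([np.ones(4), np.ones(5)])


class TestDunn:
    def test_identical_groups_give_zero_z_unit_p(self):
        g = np.array([1.0, 2, 3, 4])
        rows = dunn_test([g, g.copy()])
        _, _, z, p_raw, p_adj = rows[0]
        assert z == pytest.approx(0.0, abs=1e-12)
        assert p_raw == pytest.approx(1.0)

    def test_matches_formula_oracle_on_four_groups(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            groups = [rng.integers(0, 12, size=rng.integers(4, 10)).astype(float)
                      for _ in range(4)]
            if np.all(np.concatenate(groups) == np.concatenate(groups)[0]):
                continue
            rows = dunn_test(groups)
            oracle = dunn_oracle(groups)
            for (i, j), (a, b, z, _, _) in zip(oracle, rows):
                assert z == pytest.approx(oracle[(i, j)], abs=1e-9)

    def test_antisymmetric_under_pair_reversal(self):
        rng = np.random.default_rng(32)
        g1, g2 = rng.normal(0, 1, 12), rng.normal(1, 1, 9)
        z_fwd = dunn_test([g1, g2])[0][2]
        z_rev = dunn_test([g2, g1])[0][2]
        assert z_fwd == pytest.approx(-z_rev, abs=1e-12)

    def test_adjusted_p_never_below_raw(self):
        rng = np.random.default_rng(33)
        groups = [rng.normal(i * 0.3, 1, 15) for i in range(4)]
        for _, _, _, p_raw, p_adj in dunn_test(groups):
            assert p_adj >= p_raw - 1e-15

    def test_group_comparison_wrapper(self):
        rng = np.random.default_rng(34)
        values = np.concatenate([rng.normal(0, 1, 30), rng.normal(2, 1, 30)])
        labels = ["a"] * 30 + ["b"] * 30
        res = group_comparison(values, labels)
        assert res.p_global < 0.01
        assert len(res.pairwise) == 1


class TestRegression:
    def test_exact_linear_data_recovered(self):
        x = np.arange(20.0)
        res = linear_fit(3 + 2 * x, pd.DataFrame({"x": x}))
        name, beta, lo, hi, p = res.term("x")
        assert beta == pytest.approx(2.0, abs=1e-10)
        assert lo <= beta <= hi

    def test_intercept_only_model_gives_mean(self):
        y = np.array([1.0, 2.0, 6.0])
        res = linear_fit(y, pd.DataFrame(index=range(3)))
        assert res.term("const")[1] == pytest.approx(y.mean())

    def test_simple_regression_slope_matches_closed_form(self):
        rng = np.random.default_rng(41)
        x = rng.normal(size=50)
        y = 1.5 * x + rng.normal(size=50)
        res = linear_fit(y, pd.DataFrame({"x": x}))
        closed = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert res.term("x")[1] == pytest.approx(closed, abs=1e-10)

    def test_ols_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(42)
        X = rng.normal(size=(100, 3))
        y = X @ [1.0, -2.0, 0.5] + rng.normal(size=100)
        res = linear_fit(y, pd.DataFrame(X, columns=["a", "b", "c"]))
        Xd = np.column_stack([np.ones(100), X])
        oracle = np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
        fitted = [res.term(n)[1] for n in ("const", "a", "b", "c")]
        np.testing.assert_allclose(fitted, oracle, atol=1e-8)

    def test_collinear_design_rejected(self):
        x = np.arange(10.0)
        with pytest.raises(StatsError, match="collinear"):
            linear_fit(x, pd.DataFrame({"a": x, "b": 2 * x}))

    def test_logistic_matches_newton_oracle(self):
        rng = np.random.default_rng(43)
        X = rng.normal(size=(300, 2))
        eta = 0.3 + 0.8 * X[:, 0] - 0.5 * X[:, 1]
        y = (rng.uniform(size=300) < 1 / (1 + np.exp(-eta))).astype(float)
        res = logistic_fit(y, pd.DataFrame(X, columns=["a", "b"]))
        Xd = np.column_stack([np.ones(300), X])
        oracle = logit_newton_oracle(Xd, y)
        fitted = [res.term(n)[1] for n in ("const", "a", "b")]
        np.testing.assert_allclose(fitted, oracle, atol=1e-6)

    def test_logistic_null_predictor_near_zero(self):
        rng = np.random.default_rng(44)
        x = rng.normal(size=2000)
        y = rng.integers(0, 2, size=2000).astype(float)
        res = logistic_fit(y, pd.DataFrame({"x": x}))
        name, beta, lo, hi, p = res.term("x")
        assert abs(beta) < 0.15
        assert lo < 0 < hi

    def test_single_class_outcome_rejected(self):
        with pytest.raises(StatsError, match="single class"):
            logistic_fit(np.ones(10), pd.DataFrame({"x": np.arange(10.0)}))

    def test_perfect_separation_rejected(self):
        x = np.arange(20.0)
        y = (x > 9.5).astype(float)
        with pytest.raises(StatsError):
            logistic_fit(y, pd.DataFrame({"x": x}))


class TestSMD:
    def test_identical_groups_negligible(self):
        g = np.array([1.0, 2, 3, 4])
        res = smd(g, g.copy())
        assert res.smd == pytest.approx(0.0)
        assert res.negligible

    def test_continuous_formula_example(self):
        rng = np.random.default_rng(51)
        a = rng.normal(10, 4, 100000)
        b = rng.normal(12, 4, 100000)
        res = smd(a, b)
        assert res.smd == pytest.approx(-0.5, abs=0.02)

    def test_binary_formula_example(self):
        # proportions 0.58 vs 0.53 -> SMD ~ 0.10 by the binary formula
        a = np.repeat([1.0, 0.0], [58, 42])
        b = np.repeat([1.0, 0.0], [53, 47])
        res = smd(a, b, kind="binary")
        oracle = (0.58 - 0.53) / np.sqrt((0.58 * 0.42 + 0.53 * 0.47) / 2)
        assert res.smd == pytest.approx(oracle, abs=1e-12)
        assert res.smd == pytest.approx(0.10, abs=0.005)

    def test_ci_contains_estimate(self):
        rng = np.random.default_rng(52)
        res = smd(rng.normal(0, 1, 50), rng.normal(0.3, 1, 60))
        assert res.ci_low <= res.smd <= res.ci_high

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(StatsError, match="pooled SD"):
            smd(np.ones(5), np.ones(5))
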