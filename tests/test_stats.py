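"""Statistics: each procedure is checked against an independent formula oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from telecare.stats import (
    DegenerateStatisticError,
    cohens_d,
    fleiss_kappa,
    holm_bonferroni,
    ols_cluster_robust,
    proportion_with_attribute,
    spearman_test,
)

from conftest import make_call

import datetime


# ---------------------------------------------------------------------------
# Independent oracles (textbook formulas, no statsmodels/scipy)

def fleiss_kappa_oracle(table):
    table = np.asarray(table, dtype=float)
    n_items, _ = table.shape
    n = table[0].sum()
    p_j = table.sum(axis=0) / (n_items * n)
    p_i = ((table**2).sum(axis=1) - n) / (n * (n - 1))
    p_bar, p_e = p_i.mean(), (p_j**2).sum()
    return (p_bar - p_e) / (1 - p_e)


def holm_oracle(ps):
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    adjusted = [0.0] * m
    running = 0.0
    for k, i in enumerate(order):
        running = max(running, (m - k) * ps[i])
        adjusted[i] = min(1.0, running)
    return adjusted


def midrank(values):
    values = list(values)
    ranks = [0.0] * len(values)
    for i, v in enumerate(values):
        smaller = sum(1 for w in values if w < v)
        ties = sum(1 for w in values if w == v)
        ranks[i] = smaller + (ties + 1) / 2
    return ranks


def cluster_sandwich_oracle(y, X, clusters):
    """CR1 sandwich expanded term by term."""
    y, X = np.asarray(y, float), np.asarray(X, float)
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    u = y - X @ beta
    bread = np.linalg.inv(X.T @ X)
    meat = np.zeros((X.shape[1], X.shape[1]))
    for c in set(clusters):
        mask = np.asarray(clusters) == c
        score = X[mask].T @ u[mask]
        meat += np.outer(score, score)
    G, (N, K) = len(set(clusters)), X.shape
    correction = G / (G - 1) * (N - 1) / (N - K)
    return beta, np.sqrt(np.diag(correction * bread @ meat @ bread))


# ---------------------------------------------------------------------------

class TestFleissKappa:
    def test_unanimous_agreement(self):
        table = np.zeros((5, 3))
        table[:, 1] = 3
        table[0, 1], table[0, 0] = 0, 3
        res = fleiss_kappa(table, n_raters=3)
        assert res.kappa == pytest.approx(1.0)

    def test_complete_disagreement_two_raters(self):
        # P_bar = 0, P_e = 0.5 -> kappa = -1
        res = fleiss_kappa(np.array([[1, 1], [1, 1]]), n_raters=2)
        assert res.kappa == pytest.approx(-1.0)

    def test_matches_textbook_formula_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            table = rng.multinomial(3, [0.5, 0.3, 0.2], size=10)
            res = fleiss_kappa(table, n_raters=3)
            assert res.kappa == pytest.approx(fleiss_kappa_oracle(table), abs=1e-12)

    def test_invariant_to_category_relabeling(self):
        rng = np.random.default_rng(1)
        table = rng.multinomial(4, [0.4, 0.4, 0.2], size=8)
        shuffled = table[:, [2, 0, 1]]
        assert fleiss_kappa(table, 4).kappa == pytest.approx(fleiss_kappa(shuffled, 4).kappa, abs=1e-12)

    def test_single_category_degenerate(self):
        table = np.zeros((4, 2))
        table[:, 0] = 3
        with pytest.raises(DegenerateStatisticError):
            fleiss_kappa(table, n_raters=3)


class TestClusteredOLS:
    def test_constant_groups_exact_fit(self):
        res = ols_cluster_robust([2, 2, 2, 5, 5, 5], [0, 0, 0, 1, 1, 1], ["a", "b", "c", "a", "b", "c"])
        assert res.estimate == pytest.approx(3.0)
        assert res.se_clustered == pytest.approx(0.0, abs=1e-10)

    def test_estimate_is_group_mean_difference(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=40)
        g = rng.integers(0, 2, size=40)
        g[:2] = [0, 1]
        cl = rng.integers(0, 8, size=40)
        res = ols_cluster_robust(y, g, cl)
        assert res.estimate == pytest.approx(y[g == 1].mean() - y[g == 0].mean(), abs=1e-10)

    def test_three_cluster_toy_matches_hand_sandwich(self):
        y = [1.0, 2.0, 3.0, 5.0, 6.0, 4.0]
        g = [0, 1, 0, 1, 0, 1]
        cl = ["p1", "p1", "p2", "p2", "p3", "p3"]
        res = ols_cluster_robust(y, g, cl)
        X = np.column_stack([np.ones(6), g])
        beta, se = cluster_sandwich_oracle(y, X, cl)
        assert res.estimate == pytest.approx(beta[1], abs=1e-10)
        assert res.se_clustered == pytest.approx(se[1], abs=1e-10)

    def test_singleton_clusters_reduce_to_hc1(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=12)
        g = np.r_[np.zeros(6, int), np.ones(6, int)]
        res = ols_cluster_robust(y, g, cluster_ids=list(range(12)))
        # HC1 oracle: White estimator with N/(N-K) ... CR1 with G=N gives
        # N/(N-1)*(N-1)/(N-K) = N/(N-K), the HC1 scaling
        X = np.column_stack([np.ones(12), g])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        u = y - X @ beta
        bread = np.linalg.inv(X.T @ X)
        meat = X.T @ np.diag(u**2) @ X
        hc1 = np.sqrt(np.diag(12 / (12 - 2) * bread @ meat @ bread))
        assert res.se_clustered == pytest.approx(hc1[1], abs=1e-10)

    def test_group_mean_identity_reproduces_difference(self):
        # groups constructed with means 17.5 (n=49) and 10.1 (n=80)
        focused = np.full(49, 17.5)
        focused[0:2] = [16.5, 18.5]
        other = np.full(80, 10.1)
        other[0:2] = [9.1, 11.1]
        y = np.r_[other, focused]
        g = np.r_[np.zeros(80, int), np.ones(49, int)]
        cl = np.arange(129) % 25
        res = ols_cluster_robust(y, g, cl)
        assert res.estimate == pytest.approx(7.4, abs=1e-9)
        assert res.ci_low <= res.estimate <= res.ci_high

    def test_single_cluster_returns_estimate_without_inference(self):
        with pytest.warns(UserWarning, match="fewer than 2 clusters"):
            res = ols_cluster_robust([1.0, 2.0, 3.0, 4.0], [0, 0, 1, 1], ["a"] * 4)
        assert res.estimate == pytest.approx(2.0)
        assert math.isnan(res.se_clustered)


class TestHolm:
    def test_single_p_unchanged(self):
        assert holm_bonferroni([0.03]).adjusted == (0.03,)

    def test_step_down_example(self):
        assert holm_bonferroni([0.01, 0.02, 0.04]).adjusted == pytest.approx((0.03, 0.04, 0.04))

    def test_empty_input(self):
        assert holm_bonferroni([]).adjusted == ()

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=10), st.randoms())
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_dominance_and_permutation_equivariance(self, ps, rnd):
        result = holm_bonferroni(ps)
        assert all(a >= p for a, p in zip(result.adjusted, result.raw))
        assert result.adjusted == pytest.approx(holm_oracle(ps), abs=1e-12)
        perm = list(range(len(ps)))
        rnd.shuffle(perm)
        permuted = holm_bonferroni([ps[i] for i in perm]).adjusted
        assert permuted == pytest.approx(tuple(result.adjusted[i] for i in perm), abs=1e-12)


class TestSpearman:
    def test_monotone_relations(self):
        x = [1, 2, 3, 4, 5]
        assert spearman_test(x, [2, 4, 9, 16, 30]).rho == pytest.approx(1.0)
        assert spearman_test(x, [5, 4, 3, 2, 1]).rho == pytest.approx(-1.0)

    def test_ties_use_midranks(self):
        x = [1, 2, 2, 3, 4, 5]
        y = [3, 1, 4, 4, 6, 5]
        res = spearman_test(x, y)
        rx, ry = midrank(x), midrank(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert res.rho == pytest.approx(oracle, abs=1e-10)
        # t-approximation p-value
        t = res.rho * math.sqrt((6 - 2) / (1 - res.rho**2))
        from scipy.stats import t as tdist

        assert res.p_value == pytest.approx(2 * tdist.sf(abs(t), 4), abs=1e-10)

    def test_constant_input_degenerate(self):
        with pytest.raises(DegenerateStatisticError):
            spearman_test([1, 1, 1], [1, 2, 3])


class TestCohensD:
    def test_identical_groups(self):
        assert cohens_d([1, 2, 3], [1, 2, 3]).d == 0.0

    def test_textbook_example(self):
        res = cohens_d([1, 2, 3], [3, 4, 5])
        assert res.d == pytest.approx(-2.0)
        assert res.group_sds == (1.0, 1.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=10), rng.normal(1, 2, size=14)
        assert cohens_d(a, b).d == pytest.approx(-cohens_d(b, a).d, abs=1e-12)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=20), rng.normal(0.5, 1.5, size=25)
        expected = pingouin.compute_effsize(a, b, eftype="cohen")
        assert cohens_d(a, b).d == pytest.approx(expected, abs=1e-10)

    def test_zero_pooled_sd_unequal_means(self):
        assert cohens_d([1, 1], [2, 2]).d == -math.inf


class TestAttributeProportion:
    def make_group(self, n_with, n_without):
        day = datetime.date(2015, 1, 1)
        calls = [
            make_call(f"w{i}", "A", day, {"symptom_checking": 3}, attrs={"symptom_checking": ["frequency"]})
            for i in range(n_with)
        ]
        calls += [make_call(f"o{i}", "A", day, {"symptom_checking": 3}) for i in range(n_without)]
        return calls

    def test_extremes_and_forced_count(self):
        assert proportion_with_attribute(self.make_group(0, 5), {"frequency"}) == 0.0
        assert proportion_with_attribute(self.make_group(4, 0), {"frequency"}) == 1.0
        assert proportion_with_attribute(self.make_group(3, 5), {"frequency"}) == 0.375
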