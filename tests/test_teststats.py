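import warnings
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy.stats import rankdata

from permaxt import (
    ConfigurationError,
    DegenerateFeatureWarning,
    ExpressionMatrix,
    Outcome,
    compute_stats,
    cox_rank_score_stat,
    cox_score_stat,
    make_context,
    pearson_stat,
    spearman_stat,
    tstat,
    wilcoxon_stat,
)
from permaxt.teststats import scalar_statistic


def _ctx(outcome):
    return make_context(outcome)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def oracle_pooled_t(x, g):
    """Textbook pooled-variance two-sample t, written independently."""
    x = np.asarray(x, float)
    a = x[np.asarray(g) == 1]
    b = x[np.asarray(g) == 0]
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    return (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))


def oracle_logrank_chi2(time, event, g):
    """Standard log-rank chi-square via 2x2 tables at each event time.

    Valid comparison when all event times are distinct (d_j = 1), where the
    hypergeometric and Breslow variances coincide.
    """
    time, event, g = (np.asarray(a) for a in (time, event, g))
    O_minus_E = 0.0
    V = 0.0
    for tj in np.unique(time[event == 1]):
        at_risk = time >= tj
        n_j = at_risk.sum()
        n1_j = (at_risk & (g == 1)).sum()
        d_j = ((time == tj) & (event == 1)).sum()
        d1_j = ((time == tj) & (event == 1) & (g == 1)).sum()
        O_minus_E += d1_j - d_j * n1_j / n_j
        V += d_j * (n1_j / n_j) * (1 - n1_j / n_j) * (n_j - d_j) / (n_j - 1)
    return O_minus_E**2 / V


# ---------------------------------------------------------------------------
# t statistic
# ---------------------------------------------------------------------------

class TestTstat:
    def test_textbook_value(self):
        ctx = _ctx(Outcome.binary([0, 0, 1, 1]))
        x = np.array([1.0, 2.0, 3.0, 4.0])
        expected = oracle_pooled_t(x, [0, 0, 1, 1])
        assert tstat(x, ctx) == pytest.approx(expected)
        assert tstat(x, ctx) == pytest.approx(2.8284271247461903)

    def test_equal_means_zero(self):
        ctx = _ctx(Outcome.binary([0, 0, 1, 1]))
        assert tstat(np.array([1.0, 3.0, 1.0, 3.0]), ctx) == 0.0

    def test_label_swap_negates(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(10)
        g = np.array([0, 1, 0, 1, 0, 1, 0, 1, 0, 1])
        a = tstat(x, _ctx(Outcome.binary(g)))
        b = tstat(x, _ctx(Outcome.binary(1 - g)))
        assert a == pytest.approx(-b)

    def test_constant_feature_degenerate(self):
        ctx = _ctx(Outcome.binary([0, 0, 1, 1]))
        with pytest.warns(DegenerateFeatureWarning):
            assert tstat(np.ones(4), ctx) == 0.0

    @given(hnp.arrays(np.float64, 8,
                      elements=st.floats(-50, 50, allow_nan=False)))
    @settings(max_examples=50, deadline=None)
    def test_matches_oracle_random(self, x):
        g = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        ctx = _ctx(Outcome.binary(g))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DegenerateFeatureWarning)
            got = tstat(x, ctx)
        a, b = x[g == 1], x[g == 0]
        sp2 = (a.var(ddof=1) * 3 + b.var(ddof=1) * 3) / 6
        if sp2 <= 0:
            assert got == 0.0
        else:
            assert got == pytest.approx(oracle_pooled_t(x, g), rel=1e-10)


# ---------------------------------------------------------------------------
# Wilcoxon
# ---------------------------------------------------------------------------

class TestWilcoxon:
    def test_maximal_separation_matches_enumeration(self):
        # x = (1,2,3,10,20,30) with group 1 = three largest: enumeration of
        # all 20 rank-sum assignments shows the observed value is maximal.
        x = np.array([1.0, 2.0, 3.0, 10.0, 20.0, 30.0])
        g = np.array([0, 0, 0, 1, 1, 1])
        ctx = _ctx(Outcome.binary(g))
        got = wilcoxon_stat(x, ctx)
        r = rankdata(x)
        ew = 3 * 7 / 2
        var = 9 / 30 * ((r - r.mean()) ** 2).sum()
        enumerated = [(r[list(c)].sum() - ew) / np.sqrt(var)
                      for c in combinations(range(6), 3)]
        assert got == pytest.approx(max(enumerated))
        assert got == pytest.approx(1.9639610121239315)

    def test_monotone_invariance(self):
        g = np.array([0, 1, 0, 1, 1, 0, 1, 0])
        rng = np.random.default_rng(3)
        x = rng.standard_normal(8)
        ctx = _ctx(Outcome.binary(g))
        assert wilcoxon_stat(x, ctx) == pytest.approx(
            wilcoxon_stat(np.exp(x), ctx))

    def test_constant_degenerate(self):
        ctx = _ctx(Outcome.binary([0, 0, 1, 1]))
        with pytest.warns(DegenerateFeatureWarning):
            assert wilcoxon_stat(np.full(4, 2.0), ctx) == 0.0

    def test_label_swap_negates(self):
        g = np.array([0, 1, 0, 1, 1, 0])
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0])
        a = wilcoxon_stat(x, _ctx(Outcome.binary(g)))
        b = wilcoxon_stat(x, _ctx(Outcome.binary(1 - g)))
        assert a == pytest.approx(-b)

    def test_ties_use_midranks(self):
        # tie-corrected variance: compare against direct permutation moments
        x = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 3.0])
        g = np.array([0, 1, 0, 1, 0, 1])
        ctx = _ctx(Outcome.binary(g))
        r = rankdata(x)
        Ws = [r[list(c)].sum() for c in combinations(range(6), 3)]
        Ws = np.array(Ws)
        got = wilcoxon_stat(x, ctx)
        expected = (r[g == 1].sum() - Ws.mean()) / Ws.std(ddof=0)
        assert got == pytest.approx(expected, rel=1e-10)


# ---------------------------------------------------------------------------
# Pearson / Spearman
# ---------------------------------------------------------------------------

class TestPearson:
    def test_oracle_value(self):
        ctx = _ctx(Outcome.quantitative([1.0, 3.0, 2.0, 5.0, 4.0]))
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        # r = 0.8 -> t = 0.8*sqrt(3)/sqrt(0.36)
        assert pearson_stat(x, ctx) == pytest.approx(2.3094010767585034)

    def test_perfect_correlation_clamped(self):
        x = np.arange(10.0)
        ctx = _ctx(Outcome.quantitative(2 * x + 1))
        val = pearson_stat(x, ctx)
        assert val >= np.sqrt(8) / np.sqrt(1e-12) * 0.99
        assert val > 0

    def test_orthogonal_zero(self):
        ctx = _ctx(Outcome.quantitative([-1.0, 0.0, 1.0]))
        assert pearson_stat(np.array([1.0, -2.0, 1.0]), ctx) == pytest.approx(0.0)

    def test_constant_outcome_config_error(self):
        ctx = _ctx(Outcome.quantitative([2.0, 2.0, 2.0]))
        with pytest.raises(ConfigurationError):
            pearson_stat(np.array([1.0, 2.0, 3.0]), ctx)

    def test_negated_outcome_negates(self):
        rng = np.random.default_rng(5)
        x, y = rng.standard_normal(9), rng.standard_normal(9)
        a = pearson_stat(x, _ctx(Outcome.quantitative(y)))
        b = pearson_stat(x, _ctx(Outcome.quantitative(-y)))
        assert a == pytest.approx(-b)


class TestSpearman:
    def test_oracle_value(self):
        ctx = _ctx(Outcome.quantitative([1.0, 3.0, 2.0, 5.0, 4.0]))
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        # rank correlation 0.8, same t-form as the Pearson fixture
        assert spearman_stat(x, ctx) == pytest.approx(2.3094010767585034)

    def test_monotone_invariance_both_sides(self):
        rng = np.random.default_rng(11)
        x, y = rng.standard_normal(12), rng.standard_normal(12)
        a = spearman_stat(x, _ctx(Outcome.quantitative(y)))
        b = spearman_stat(np.exp(x), _ctx(Outcome.quantitative(y**3)))
        assert a == pytest.approx(b)

    def test_perfect_rank_correlation(self):
        x = np.arange(8.0)
        ctx = _ctx(Outcome.quantitative(np.exp(x)))
        assert spearman_stat(x, ctx) > 1e5


# ---------------------------------------------------------------------------
# Cox score / rank score
# ---------------------------------------------------------------------------

class TestCoxScore:
    def test_constant_x_zero(self, survival_outcome):
        ctx = _ctx(survival_outcome)
        with pytest.warns(DegenerateFeatureWarning):
            assert cox_score_stat(np.ones(10), ctx) == 0.0

    def test_binary_equals_logrank(self, survival_outcome):
        ctx = _ctx(survival_outcome)
        x = np.array([0.0, 1, 0, 1, 1, 0, 0, 1, 0, 1])
        expected = oracle_logrank_chi2(survival_outcome.time,
                                       survival_outcome.event, x)
        assert cox_score_stat(x, ctx) == pytest.approx(expected, rel=1e-10)

    def test_affine_invariance(self, survival_outcome):
        ctx = _ctx(survival_outcome)
        rng = np.random.default_rng(9)
        x = rng.standard_normal(10)
        assert cox_score_stat(x, ctx) == pytest.approx(
            cox_score_stat(3.5 * x - 2.0, ctx), rel=1e-10)

    def test_nonnegative(self, survival_outcome):
        ctx = _ctx(survival_outcome)
        rng = np.random.default_rng(13)
        for _ in range(20):
            assert cox_score_stat(rng.standard_normal(10), ctx) >= 0.0

    def test_tied_event_times_breslow(self):
        # two events share a time; scalar loop handles the tie directly
        o = Outcome.survival([2.0, 2.0, 3.0, 5.0, 5.0, 7.0],
                             [1, 1, 0, 1, 0, 1])
        ctx = _ctx(o)
        x = np.array([0.2, -1.0, 0.5, 1.5, -0.3, 0.9])
        m = ExpressionMatrix(x[None, :], ["g"], [f"s{i}" for i in range(6)])
        vec = compute_stats(m, ctx, "coxscore")
        assert vec[0] == pytest.approx(cox_score_stat(x, ctx), rel=1e-10)


class TestCoxRankScore:
    def test_monotone_invariance(self, survival_outcome):
        ctx = _ctx(survival_outcome)
        rng = np.random.default_rng(21)
        x = rng.standard_normal(10)
        assert cox_rank_score_stat(x, ctx) == pytest.approx(
            cox_rank_score_stat(np.exp(x), ctx), rel=1e-10)

    def test_equals_score_on_ranks(self, survival_outcome):
        ctx = _ctx(survival_outcome)
        x = rankdata(np.random.default_rng(2).standard_normal(10))
        assert cox_rank_score_stat(x, ctx) == pytest.approx(
            cox_score_stat(x, ctx), rel=1e-12)

    def test_outlier_robustness(self, survival_outcome):
        ctx = _ctx(survival_outcome)
        rng = np.random.default_rng(17)
        x = rng.standard_normal(10)
        x_out = x.copy()
        x_out[np.argmax(x)] += 100.0  # inflate the max: ranks unchanged
        assert cox_rank_score_stat(x, ctx) == pytest.approx(
            cox_rank_score_stat(x_out, ctx), rel=1e-10)
        assert cox_score_stat(x, ctx) != pytest.approx(
            cox_score_stat(x_out, ctx), rel=1e-3)


# ---------------------------------------------------------------------------
# vectorized computation
# ---------------------------------------------------------------------------

STAT_OUTCOMES = [
    ("ttest", "binary"), ("wilcoxon", "binary"),
    ("pearson", "quantitative"), ("spearman", "quantitative"),
    ("coxscore", "survival"), ("coxrankscore", "survival"),
]


def _outcome_for(kind, n, rng):
    if kind == "binary":
        g = np.r_[np.zeros(n // 2, int), np.ones(n - n // 2, int)]
        return Outcome.binary(rng.permutation(g))
    if kind == "quantitative":
        return Outcome.quantitative(rng.standard_normal(n))
    e = rng.integers(0, 2, n)
    e[rng.integers(n)] = 1
    return Outcome.survival(rng.exponential(size=n) + 0.01, e)


class TestComputeStats:
    @pytest.mark.parametrize("statistic,kind", STAT_OUTCOMES)
    def test_matches_scalar_loop(self, statistic, kind):
        rng = np.random.default_rng(31)
        n, K = 15, 100
        X = rng.standard_normal((K, n))
        m = ExpressionMatrix(X, [f"g{i}" for i in range(K)],
                             [f"s{i}" for i in range(n)])
        ctx = _ctx(_outcome_for(kind, n, rng))
        vec = compute_stats(m, ctx, statistic)
        fn = scalar_statistic(statistic)
        scalar = np.array([fn(X[k], ctx) for k in range(K)])
        np.testing.assert_allclose(vec, scalar, rtol=1e-10, atol=1e-12)

    @pytest.mark.parametrize("statistic,kind", STAT_OUTCOMES)
    def test_single_feature_equals_scalar(self, statistic, kind):
        rng = np.random.default_rng(37)
        n = 12
        x = rng.standard_normal(n)
        m = ExpressionMatrix(x[None, :], ["g0"], [f"s{i}" for i in range(n)])
        ctx = _ctx(_outcome_for(kind, n, rng))
        vec = compute_stats(m, ctx, statistic)
        assert vec.shape == (1,)
        assert vec[0] == pytest.approx(scalar_statistic(statistic)(x, ctx),
                                       rel=1e-10)

    def test_duplicated_rows_duplicated_stats(self, binary_outcome):
        rng = np.random.default_rng(41)
        x = rng.standard_normal(8)
        m = ExpressionMatrix(np.vstack([x, x]), ["a", "b"],
                             [f"s{i}" for i in range(8)])
        vec = compute_stats(m, _ctx(binary_outcome), "ttest")
        assert vec[0] == vec[1]

    def test_incompatible_pairing_rejected(self, small_matrix, binary_outcome):
        with pytest.raises(ConfigurationError):
            compute_stats(small_matrix, _ctx(binary_outcome), "pearson")

    @pytest.mark.parametrize("statistic,kind", STAT_OUTCOMES)
    def test_sample_order_invariance(self, statistic, kind):
        # jointly permuting samples of x and outcome leaves every statistic fixed
        rng = np.random.default_rng(43)
        n = 14
        x = rng.standard_normal(n)
        outcome = _outcome_for(kind, n, rng)
        perm = rng.permutation(n)
        fn = scalar_statistic(statistic)
        a = fn(x, _ctx(outcome))
        b = fn(x[perm], _ctx(outcome.take(perm)))
        assert a == pytest.approx(b, rel=1e-9)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_property_joint_permutation_invariance_ttest(self, seed):
        rng = np.random.default_rng(seed)
        n = 10
        x = rng.standard_normal(n)
        g = np.r_[np.zeros(5, int), np.ones(5, int)]
        outcome = Outcome.binary(rng.permutation(g))
        perm = rng.permutation(n)
        a = tstat(x, _ctx(outcome))
        b = tstat(x[perm], _ctx(outcome.take(perm)))
        assert a == pytest.approx(b, rel=1e-9, abs=1e-12)
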