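"""The six marginal association statistics.

Each statistic maps one feature vector ``x`` (length n) plus an outcome to
a scalar.  The signed statistics (ttest, wilcoxon, pearson, spearman) use
the critical region {|T| > xi}; the Cox score statistics are reported on
the chi-square scale U^2/V with region {T > xi}.

Scalar operations (:func:`tstat`, :func:`wilcoxon_stat`, ...) are written
as plain per-feature code and serve as the reference path; the engine uses
:func:`compute_stats`, a vectorized implementation over all K features that
must agree with the scalar loop to 1e-10 relative tolerance.

Outcome-side quantities that are reusable across features (group indicator,
centered outcome, risk-set bookkeeping from the sorted survival times) live
in :class:`StatContext` and are computed once per outcome (hence once per
permutation replicate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import rankdata

from .datamodel_io import (
    ConfigurationError,
    ExpressionMatrix,
    Outcome,
    STATISTIC_OUTCOME_KIND,
)

__all__ = [
    "DegenerateFeatureWarning",
    "StatContext",
    "make_context",
    "tstat",
    "wilcoxon_stat",
    "pearson_stat",
    "spearman_stat",
    "cox_score_stat",
    "cox_rank_score_stat",
    "compute_stats",
    "STATISTIC_COMPARISON_SCALE",
    "comparison_scale",
    "requires_rank_transform",
]

#: Guard against division by zero when |r| = 1 in the correlation t-form.
_CORR_EPS = 1e-12

#: Comparison scale used for permutation indicator counts: absolute value
#: for the signed statistics, identity for the (nonnegative) Cox tests.
STATISTIC_COMPARISON_SCALE = {
    "ttest": "abs",
    "wilcoxon": "abs",
    "pearson": "abs",
    "spearman": "abs",
    "coxscore": "identity",
    "coxrankscore": "identity",
}

#: Statistics that operate on midranks of the feature vector.
_RANK_X = frozenset({"wilcoxon", "spearman", "coxrankscore"})


class DegenerateFeatureWarning(UserWarning):
    """A feature was constant (or otherwise uninformative); its statistic
    is reported as 0 instead of aborting the run."""


def requires_rank_transform(statistic: str) -> bool:
    return statistic in _RANK_X


def comparison_scale(statistic: str, values: np.ndarray) -> np.ndarray:
    """Map statistics onto the scale used for all permutation comparisons."""
    if STATISTIC_COMPARISON_SCALE[statistic] == "abs":
        return np.abs(values)
    return np.asarray(values)


# ---------------------------------------------------------------------------
# outcome-side precomputation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StatContext:
    """Outcome plus outcome-only precomputed quantities.

    The precomputed content never depends on expression values, so one
    context is shared by all K features of a replicate.
    """

    outcome: Outcome
    # binary
    group: Optional[np.ndarray] = None
    n0: int = 0
    n1: int = 0
    # quantitative: centered outcome and its sum of squares, same for ranks
    y_centered: Optional[np.ndarray] = None
    ss_y: float = 0.0
    ry_centered: Optional[np.ndarray] = None
    ss_ry: float = 0.0
    # survival: samples sorted by descending time; per distinct event time
    # the inclusive risk-set boundary index, event count, and the sorted
    # positions of the events themselves
    order: Optional[np.ndarray] = None
    risk_boundary: Optional[np.ndarray] = None
    d: Optional[np.ndarray] = None
    event_pos: Optional[np.ndarray] = None
    event_group_starts: Optional[np.ndarray] = None

    @property
    def n(self) -> int:
        return self.outcome.n


def make_context(outcome: Outcome) -> StatContext:
    """Build the per-outcome :class:`StatContext`."""
    if outcome.kind == "binary":
        g = outcome.group.astype(np.float64)
        return StatContext(outcome=outcome, group=g,
                           n0=int(outcome.n - g.sum()), n1=int(g.sum()))
    if outcome.kind == "quantitative":
        y = outcome.y
        yc = y - y.mean()
        ry = rankdata(y, method="average")
        ryc = ry - ry.mean()
        return StatContext(outcome=outcome, y_centered=yc,
                           ss_y=float(yc @ yc), ry_centered=ryc,
                           ss_ry=float(ryc @ ryc))
    # survival: Breslow risk-set bookkeeping.  Samples sorted by descending
    # time so the risk set at event time t is a prefix of the sorted order
    # (censoring ties at an event time remain at risk).
    t, e = outcome.time, outcome.event
    order = np.argsort(-t, kind="stable")
    ts, es = t[order], e[order]
    event_pos = np.flatnonzero(es == 1)
    etimes = ts[event_pos]                       # non-increasing
    starts = np.flatnonzero(np.r_[True, etimes[1:] != etimes[:-1]])
    distinct = etimes[starts]
    counts = np.diff(np.r_[starts, len(etimes)])
    # inclusive index of the last sample with time >= each distinct event time
    boundary = np.searchsorted(-ts, -distinct, side="right") - 1
    return StatContext(outcome=outcome, order=order, risk_boundary=boundary,
                       d=counts.astype(np.float64), event_pos=event_pos,
                       event_group_starts=starts)


def _require_kind(ctx: StatContext, kind: str, statistic: str) -> None:
    if ctx.outcome.kind != kind:
        raise ConfigurationError(
            f"{statistic} requires a {kind} outcome, got {ctx.outcome.kind!r}"
        )


def _degenerate(statistic: str) -> float:
    warnings.warn(f"constant feature: {statistic} reported as 0",
                  DegenerateFeatureWarning, stacklevel=3)
    return 0.0


# ---------------------------------------------------------------------------
# scalar reference implementations
# ---------------------------------------------------------------------------

def tstat(x: np.ndarray, ctx: StatContext) -> float:
    """Pooled-variance two-sample t statistic, group 1 minus group 0."""
    _require_kind(ctx, "binary", "ttest")
    x = np.asarray(x, dtype=float)
    g = ctx.outcome.group
    x0, x1 = x[g == 0], x[g == 1]
    n0, n1 = len(x0), len(x1)
    sp2 = (((x0 - x0.mean()) ** 2).sum() + ((x1 - x1.mean()) ** 2).sum()) / (n0 + n1 - 2)
    if sp2 <= 0:
        return _degenerate("ttest")
    return float((x1.mean() - x0.mean()) / np.sqrt(sp2 * (1.0 / n0 + 1.0 / n1)))


def wilcoxon_stat(x: np.ndarray, ctx: StatContext) -> float:
    """Standardized Wilcoxon rank sum of group 1, midranks, tie-corrected
    permutation variance."""
    _require_kind(ctx, "binary", "wilcoxon")
    x = np.asarray(x, dtype=float)
    g = ctx.outcome.group
    r = rankdata(x, method="average")
    n, n1 = len(x), int(g.sum())
    n0 = n - n1
    W = r[g == 1].sum()
    EW = n1 * (n + 1) / 2.0
    # permutation variance of W with ties: n0*n1/(n*(n-1)) * sum (r - rbar)^2
    var = n0 * n1 / (n * (n - 1.0)) * ((r - r.mean()) ** 2).sum()
    if var <= 0:
        return _degenerate("wilcoxon")
    return float((W - EW) / np.sqrt(var))


def pearson_stat(x: np.ndarray, ctx: StatContext) -> float:
    """Pearson correlation mapped through r*sqrt(n-2)/sqrt(max(1-r^2, eps))."""
    _require_kind(ctx, "quantitative", "pearson")
    x = np.asarray(x, dtype=float)
    y = ctx.outcome.y
    n = len(x)
    if n < 3:
        raise ConfigurationError("pearson needs n >= 3")
    yc = y - y.mean()
    ss_y = yc @ yc
    if ss_y <= 0:
        raise ConfigurationError("constant quantitative outcome")
    xc = x - x.mean()
    ss_x = xc @ xc
    if ss_x <= 0:
        return _degenerate("pearson")
    r = (xc @ yc) / np.sqrt(ss_x * ss_y)
    return float(r * np.sqrt(n - 2) / np.sqrt(max(1.0 - r * r, _CORR_EPS)))


def spearman_stat(x: np.ndarray, ctx: StatContext) -> float:
    """:func:`pearson_stat` on midranks of x and midranks of y."""
    _require_kind(ctx, "quantitative", "spearman")
    x = np.asarray(x, dtype=float)
    rank_ctx = make_context(Outcome.quantitative(
        rankdata(ctx.outcome.y, method="average")))
    return pearson_stat(rankdata(x, method="average"), rank_ctx)


def _cox_score_uv(x: np.ndarray, ctx: StatContext) -> tuple[float, float]:
    """Breslow-ties Cox partial-likelihood score U and variance V at beta=0,
    computed by a plain loop over distinct event times."""
    t, e = ctx.outcome.time, ctx.outcome.event
    U = 0.0
    V = 0.0
    for tj in np.unique(t[e == 1]):
        at_risk = x[t >= tj]
        events = x[(t == tj) & (e == 1)]
        dj = len(events)
        m = at_risk.mean()
        U += events.sum() - dj * m
        V += dj * ((at_risk - m) ** 2).mean()
    return U, V


def cox_score_stat(x: np.ndarray, ctx: StatContext) -> float:
    """Chi-square-scale Cox score statistic T = U^2 / V (Breslow ties)."""
    _require_kind(ctx, "survival", "coxscore")
    x = np.asarray(x, dtype=float)
    U, V = _cox_score_uv(x, ctx)
    if V <= 0:
        return _degenerate("coxscore")
    return float(U * U / V)


def cox_rank_score_stat(x: np.ndarray, ctx: StatContext) -> float:
    """:func:`cox_score_stat` on the midranks of x."""
    _require_kind(ctx, "survival", "coxrankscore")
    return cox_score_stat(rankdata(np.asarray(x, dtype=float),
                                   method="average"), ctx)


_SCALAR = {
    "ttest": tstat,
    "wilcoxon": wilcoxon_stat,
    "pearson": pearson_stat,
    "spearman": spearman_stat,
    "coxscore": cox_score_stat,
    "coxrankscore": cox_rank_score_stat,
}


# ---------------------------------------------------------------------------
# vectorized computation over all K features
# ---------------------------------------------------------------------------

def _vec_ttest(X: np.ndarray, ctx: StatContext) -> tuple[np.ndarray, np.ndarray]:
    g = ctx.group
    n0, n1 = ctx.n0, ctx.n1
    s1 = X @ g
    s0 = X.sum(axis=1) - s1
    m1, m0 = s1 / n1, s0 / n0
    sq = (X * X).sum(axis=1)
    sq1 = (X * X) @ g
    sq0 = sq - sq1
    sp2 = (sq1 - n1 * m1 * m1 + sq0 - n0 * m0 * m0) / (n0 + n1 - 2)
    degenerate = sp2 <= 0
    denom = np.sqrt(np.where(degenerate, 1.0, sp2) * (1.0 / n0 + 1.0 / n1))
    T = np.where(degenerate, 0.0, (m1 - m0) / denom)
    return T, degenerate


def _vec_wilcoxon(XR: np.ndarray, ctx: StatContext) -> tuple[np.ndarray, np.ndarray]:
    # XR holds midranks of each feature row
    g = ctx.group
    n = ctx.n
    n0, n1 = ctx.n0, ctx.n1
    W = XR @ g
    EW = n1 * (n + 1) / 2.0
    rc = XR - XR.mean(axis=1, keepdims=True)
    var = n0 * n1 / (n * (n - 1.0)) * (rc * rc).sum(axis=1)
    degenerate = var <= 0
    T = np.where(degenerate, 0.0, (W - EW) / np.sqrt(np.where(degenerate, 1.0, var)))
    return T, degenerate


def _vec_corr(X: np.ndarray, yc: np.ndarray, ss_y: float) -> tuple[np.ndarray, np.ndarray]:
    n = X.shape[1]
    if n < 3:
        raise ConfigurationError("correlation statistics need n >= 3")
    if ss_y <= 0:
        raise ConfigurationError("constant quantitative outcome")
    xc = X - X.mean(axis=1, keepdims=True)
    ss_x = (xc * xc).sum(axis=1)
    degenerate = ss_x <= 0
    r = (xc @ yc) / np.sqrt(np.where(degenerate, 1.0, ss_x) * ss_y)
    r = np.where(degenerate, 0.0, r)
    T = r * np.sqrt(n - 2) / np.sqrt(np.maximum(1.0 - r * r, _CORR_EPS))
    return T, degenerate


def _vec_cox(X: np.ndarray, ctx: StatContext) -> tuple[np.ndarray, np.ndarray]:
    Xs = X[:, ctx.order]
    cs1 = np.cumsum(Xs, axis=1)
    cs2 = np.cumsum(Xs * Xs, axis=1)
    nj = (ctx.risk_boundary + 1).astype(np.float64)
    S1 = cs1[:, ctx.risk_boundary]
    S2 = cs2[:, ctx.risk_boundary]
    mean = S1 / nj
    # event covariate sums per distinct event time
    Ev = Xs[:, ctx.event_pos]
    Ej = np.add.reduceat(Ev, ctx.event_group_starts, axis=1)
    d = ctx.d
    U = (Ej - d * mean).sum(axis=1)
    V = (d * (S2 / nj - mean * mean)).sum(axis=1)
    degenerate = V <= 1e-300
    T = np.where(degenerate, 0.0, U * U / np.where(degenerate, 1.0, V))
    return T, degenerate


def _compute_stats_array(
    X: np.ndarray, ctx: StatContext, statistic: str, *, pre_ranked: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized statistics for a raw (K, n) array.

    ``pre_ranked=True`` promises that rows of ``X`` are already midranks,
    letting the permutation engine rank the matrix once instead of once per
    replicate (ranks of a feature do not change when the outcome is
    shuffled).  Returns (statistics, degenerate mask).
    """
    if statistic not in STATISTIC_OUTCOME_KIND:
        raise ConfigurationError(f"unknown statistic {statistic!r}")
    _require_kind(ctx, STATISTIC_OUTCOME_KIND[statistic], statistic)
    if X.ndim != 2 or X.shape[1] != ctx.n:
        raise ConfigurationError(
            f"expression matrix has {X.shape[1] if X.ndim == 2 else '?'} samples, "
            f"outcome has {ctx.n}"
        )
    if requires_rank_transform(statistic) and not pre_ranked:
        X = rankdata(X, method="average", axis=1)
    if statistic == "ttest":
        return _vec_ttest(X, ctx)
    if statistic == "wilcoxon":
        return _vec_wilcoxon(X, ctx)
    if statistic == "pearson":
        return _vec_corr(X, ctx.y_centered, ctx.ss_y)
    if statistic == "spearman":
        return _vec_corr(X, ctx.ry_centered, ctx.ss_ry)
    return _vec_cox(X, ctx)


def compute_stats(X: ExpressionMatrix, ctx: StatContext, statistic: str) -> np.ndarray:
    """Per-feature statistics for all K features of an expression matrix.

    Equivalent (to 1e-10 relative tolerance) to mapping the scalar
    operation over features; degenerate features yield 0 and a single
    :class:`DegenerateFeatureWarning`.
    """
    T, degenerate = _compute_stats_array(np.asarray(X.values, dtype=float),
                                         ctx, statistic)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} degenerate feature(s) reported as 0",
            DegenerateFeatureWarning, stacklevel=2,
        )
    return T


def scalar_statistic(statistic: str):
    """Look up the scalar reference implementation by name."""
    try:
        return _SCALAR[statistic]
    except KeyError:
        raise ConfigurationError(f"unknown statistic {statistic!r}") from None
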