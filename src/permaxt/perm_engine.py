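"""Single-step maxT permutation procedure.

Given observed statistics T_1..T_K, the engine draws B random shuffles of
the outcome vector (one shuffle per replicate, shared by every feature),
recomputes all K statistics under each shuffle, and from the replicate
values derives

* unadjusted p_k   = B^-1 sum_b I[ c(T*_bk) >= c(T_k) ]
* adjusted   p~_k  = B^-1 sum_b I[ max_j c(T*_bj) >= c(T_k) ]
* critical value xi = empirical (1-alpha) order-statistic of the B maxima,

where c is the comparison scale (absolute value for the signed statistics,
identity for the chi-square-scale Cox statistics).  Comparisons use >= so a
p-value of exactly 0 is attainable; set ``conservative=True`` in the config
for the (count+1)/(B+1) variant.

Memory stays O(K + B): per-feature exceedance counters and the B maxima are
retained, never the full B x K matrix.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import rankdata

from .datamodel_io import (
    ConfigurationError,
    ExpressionMatrix,
    Outcome,
    PermutationConfig,
    PermutationResult,
)
from .teststats import (
    _compute_stats_array,
    comparison_scale,
    make_context,
    requires_rank_transform,
)

__all__ = [
    "permute_outcome",
    "unadjusted_pvalues",
    "adjusted_pvalues",
    "critical_value",
    "run_permutation",
    "fdr_adjust",
]


def permute_outcome(outcome: Outcome, rng: np.random.Generator) -> Outcome:
    """Uniformly random rearrangement of the n outcome units.

    Survival (time, event) pairs move as one unit; the expression matrix is
    never touched.
    """
    return outcome.take(rng.permutation(outcome.n))


def unadjusted_pvalues(T_obs: np.ndarray, T_null: np.ndarray, *,
                       statistic: str = "ttest") -> np.ndarray:
    """p_k from an explicit (B, K) replicate matrix.

    Provided for small problems and testing; :func:`run_permutation`
    accumulates the same counts in a streaming loop.
    """
    c_obs = comparison_scale(statistic, np.asarray(T_obs, dtype=float))
    c_null = comparison_scale(statistic, np.asarray(T_null, dtype=float))
    if c_null.ndim != 2 or c_null.shape[1] != c_obs.shape[0]:
        raise ConfigurationError(
            f"T_null shape {c_null.shape} incompatible with K={c_obs.shape[0]}"
        )
    return (c_null >= c_obs[None, :]).mean(axis=0)


def adjusted_pvalues(T_obs: np.ndarray, max_null: np.ndarray, *,
                     statistic: str = "ttest") -> np.ndarray:
    """maxT-adjusted p~_k from the per-replicate maxima."""
    c_obs = comparison_scale(statistic, np.asarray(T_obs, dtype=float))
    max_null = np.asarray(max_null, dtype=float)
    if max_null.ndim != 1:
        raise ConfigurationError("max_null must be a 1-D vector of B maxima")
    B = max_null.shape[0]
    # count of maxima >= c via the sorted vector
    srt = np.sort(max_null)
    return (B - np.searchsorted(srt, c_obs, side="left")) / B


def critical_value(max_null: np.ndarray, alpha: float) -> float:
    """Empirical (1-alpha) quantile of the maxima as an order statistic:
    the ceil(B*(1-alpha))-th smallest value."""
    if not (0.0 < alpha < 1.0):
        raise ConfigurationError("alpha must lie in (0, 1)")
    max_null = np.asarray(max_null, dtype=float)
    B = max_null.shape[0]
    if B < 1:
        raise ConfigurationError("need at least one replicate")
    idx = min(math.ceil(B * (1.0 - alpha)), B) - 1
    return float(np.sort(max_null)[idx])


def run_permutation(
    X: ExpressionMatrix, outcome: Outcome, config: PermutationConfig
) -> PermutationResult:
    """Full maxT run: observed statistics, B permutation replicates,
    p-values and critical value.  Fully reproducible from ``config.seed``."""
    config.check_outcome(outcome)
    if outcome.n != X.n_samples:
        raise ConfigurationError(
            f"outcome has {outcome.n} samples, expression matrix {X.n_samples}"
        )
    statistic = config.statistic
    values = np.asarray(X.values, dtype=float)
    # Feature ranks are invariant under outcome shuffles, so rank once.
    if requires_rank_transform(statistic):
        values = rankdata(values, method="average", axis=1)

    ctx = make_context(outcome)
    T_obs, _ = _compute_stats_array(values, ctx, statistic, pre_ranked=True)
    c_obs = comparison_scale(statistic, T_obs)

    rng = np.random.default_rng(config.seed)
    B = config.B
    exceed = np.zeros(X.n_features, dtype=np.int64)
    max_null = np.empty(B, dtype=float)
    for b in range(B):
        perm_outcome = permute_outcome(outcome, rng)
        ctx_b = make_context(perm_outcome)
        T_b, _ = _compute_stats_array(values, ctx_b, statistic, pre_ranked=True)
        c_b = comparison_scale(statistic, T_b)
        exceed += c_b >= c_obs
        max_null[b] = c_b.max()

    if config.conservative:
        p_unadj = (exceed + 1) / (B + 1)
        exceed_max = (max_null[None, :] >= c_obs[:, None]).sum(axis=1)
        p_adj = (exceed_max + 1) / (B + 1)
    else:
        p_unadj = exceed / B
        p_adj = adjusted_pvalues(T_obs, max_null, statistic=statistic)
    xi = critical_value(max_null, config.alpha)
    return PermutationResult(
        feature_ids=X.feature_ids,
        T_obs=T_obs,
        p_unadj=p_unadj,
        p_adj=np.maximum(p_adj, p_unadj),
        max_null=max_null,
        xi=xi,
        config=config,
    )


def fdr_adjust(p_unadj: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (monotone, capped at 1)."""
    p = np.asarray(p_unadj, dtype=float)
    if p.ndim != 1:
        raise ConfigurationError("p-values must form a 1-D vector")
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ConfigurationError("p-values must lie in [0, 1]")
    K = p.shape[0]
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * K / np.arange(1, K + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(K)
    out[order] = adjusted
    return out
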