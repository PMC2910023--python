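"""Synthetic-data generators mirroring the published simulation designs.

The null designs are: n x K iid standard-normal expression, Bernoulli(0.5)
binary groups, standard-normal quantitative outcomes, and exponential
survival with independent exponential censoring tuned to a target expected
censoring rate (default 0.3).  Signal injection (``n_signal > 0``) is an
extension for power/recovery testing and defaults to off, so the null
designs are reproduced exactly.

All generators are deterministic functions of (parameters, seed).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .datamodel_io import (
    ConfigurationError,
    ExpressionMatrix,
    Outcome,
    write_expression,
)

__all__ = [
    "SimDesign",
    "simulate_expression",
    "simulate_binary_outcome",
    "simulate_quantitative_outcome",
    "simulate_survival_outcome",
    "simulate_dataset",
    "write_dataset",
]

DEFAULT_CENSOR_RATE = 0.3


@dataclass(frozen=True)
class SimDesign:
    """Parameters of one synthetic dataset."""

    n: int
    K: int
    outcome_kind: str = "binary"
    censor_rate: float = DEFAULT_CENSOR_RATE
    n_signal: int = 0
    effect_size: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2 or self.K < 1:
            raise ConfigurationError("need n >= 2 and K >= 1")
        if self.outcome_kind not in ("binary", "quantitative", "survival"):
            raise ConfigurationError(f"unknown outcome kind {self.outcome_kind!r}")
        if not (0.0 <= self.censor_rate < 1.0):
            raise ConfigurationError("censor_rate must lie in [0, 1)")
        if not (0 <= self.n_signal <= self.K):
            raise ConfigurationError("need 0 <= n_signal <= K")
        if self.n_signal > 0 and self.effect_size == 0.0:
            raise ConfigurationError("signal features need a nonzero effect size")


def _feature_ids(K: int) -> list[str]:
    return [f"f{i:06d}" for i in range(1, K + 1)]


def _sample_ids(n: int) -> list[str]:
    return [f"s{i:04d}" for i in range(1, n + 1)]


def simulate_expression(n: int, K: int, seed: int = 0) -> ExpressionMatrix:
    """K x n matrix of iid N(0, 1) entries with synthetic identifiers."""
    rng = np.random.default_rng(seed)
    return ExpressionMatrix(values=_expr_values(rng, n, K),
                            feature_ids=_feature_ids(K),
                            sample_ids=_sample_ids(n))


def _expr_values(rng: np.random.Generator, n: int, K: int) -> np.ndarray:
    return rng.standard_normal((K, n))


def simulate_binary_outcome(n: int, seed: int = 0) -> Outcome:
    """iid Bernoulli(0.5) group labels; redrawn if a group comes out empty
    (probability 2^(1-n)), so both groups are always populated."""
    rng = np.random.default_rng(seed)
    return Outcome.binary(_binary_labels(rng, n))


def _binary_labels(rng: np.random.Generator, n: int) -> np.ndarray:
    while True:
        g = rng.integers(0, 2, size=n)
        if 0 < g.sum() < n:
            return g


def simulate_quantitative_outcome(n: int, seed: int = 0) -> Outcome:
    """iid N(0, 1) outcomes."""
    if n < 3:
        raise ConfigurationError("quantitative designs need n >= 3")
    rng = np.random.default_rng(seed)
    return Outcome.quantitative(rng.standard_normal(n))


def simulate_survival_outcome(n: int, censor_rate: float = DEFAULT_CENSOR_RATE,
                              seed: int = 0) -> Outcome:
    """Event times Y0 ~ Exp(1), censoring C ~ Exp(c) independent with
    c = censor_rate / (1 - censor_rate), so P(censored) = c/(1+c) equals
    ``censor_rate`` exactly.  Observed time = min(Y0, C), event = I[Y0 < C].
    ``censor_rate=0`` gives C = +inf (all events)."""
    if not (0.0 <= censor_rate < 1.0):
        raise ConfigurationError("censor_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    y0 = rng.standard_exponential(n)
    time, event = _censor(rng, y0, censor_rate)
    return Outcome.survival(time, event)


def _censor(rng: np.random.Generator, y0: np.ndarray,
            censor_rate: float) -> tuple[np.ndarray, np.ndarray]:
    if censor_rate == 0.0:
        return y0, np.ones(len(y0), dtype=int)
    c_rate = censor_rate / (1.0 - censor_rate)
    C = rng.standard_exponential(len(y0)) / c_rate
    time = np.minimum(y0, C)
    event = (y0 < C).astype(int)
    return time, event


def simulate_dataset(design: SimDesign) -> tuple[ExpressionMatrix, Outcome, list[str]]:
    """Expression matrix + outcome + ground-truth signal feature ids.

    Under the null (``n_signal=0``) the outcome is independent of every
    feature.  With signal, the designated features drive the outcome:

    * binary — signal features are mean-shifted by ``effect_size`` in group 1;
    * quantitative — y = effect_size * (mean of signal features) + N(0, 1);
    * survival — event hazard exp(effect_size * mean of signal features),
      sampled by inverse transform, then censored as in the null design.
    """
    ss = np.random.SeedSequence(design.seed)
    rng_x, rng_y = (np.random.default_rng(c) for c in ss.spawn(2))
    values = _expr_values(rng_x, design.n, design.K)
    feature_ids = _feature_ids(design.K)

    if design.n_signal > 0:
        signal_idx = np.sort(rng_y.choice(design.K, size=design.n_signal,
                                          replace=False))
    else:
        signal_idx = np.array([], dtype=int)
    signal_ids = [feature_ids[i] for i in signal_idx]
    lp = values[signal_idx].mean(axis=0) if len(signal_idx) else np.zeros(design.n)

    if design.outcome_kind == "binary":
        g = _binary_labels(rng_y, design.n)
        if len(signal_idx):
            values = values.copy()
            values[np.ix_(signal_idx, np.flatnonzero(g == 1))] += design.effect_size
        outcome = Outcome.binary(g)
    elif design.outcome_kind == "quantitative":
        noise = rng_y.standard_normal(design.n)
        outcome = Outcome.quantitative(design.effect_size * lp + noise)
    else:
        # inverse-transform exponential with per-sample rate exp(effect * lp)
        y0 = rng_y.standard_exponential(design.n) / np.exp(design.effect_size * lp)
        time, event = _censor(rng_y, y0, design.censor_rate)
        outcome = Outcome.survival(time, event)

    matrix = ExpressionMatrix(values=values, feature_ids=feature_ids,
                              sample_ids=_sample_ids(design.n))
    return matrix, outcome, signal_ids


def write_dataset(design: SimDesign, outdir: str) -> dict[str, str]:
    """Fixture writer: emit expression.tsv, phenotype.tsv and truth.txt in
    the package's TSV dialect; returns the written paths."""
    matrix, outcome, signal_ids = simulate_dataset(design)
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "expression": os.path.join(outdir, "expression.tsv"),
        "phenotype": os.path.join(outdir, "phenotype.tsv"),
        "truth": os.path.join(outdir, "truth.txt"),
    }
    write_expression(matrix, paths["expression"])
    with open(paths["phenotype"], "w", encoding="utf-8") as fh:
        if outcome.kind == "binary":
            fh.write("sample\tgroup\n")
            for s, g in zip(matrix.sample_ids, outcome.group):
                fh.write(f"{s}\t{int(g)}\n")
        elif outcome.kind == "quantitative":
            fh.write("sample\ty\n")
            for s, y in zip(matrix.sample_ids, outcome.y):
                fh.write(f"{s}\t{format(y, '.17g')}\n")
        else:
            fh.write("sample\ttime\tevent\n")
            for s, t, e in zip(matrix.sample_ids, outcome.time, outcome.event):
                fh.write(f"{s}\t{format(t, '.17g')}\t{int(e)}\n")
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        for fid in signal_ids:
            fh.write(fid + "\n")
    return paths
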