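"""Domain types and TSV readers/writers.

File dialect is strict TSV: UTF-8, tab separated, ``.`` decimal separator,
no quoting.  Expression matrices are stored features-as-rows with a header
line of sample identifiers.  Sample alignment between phenotype and
expression files is always by identifier, never by file order.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ConfigurationError",
    "ExpressionMatrix",
    "Outcome",
    "PermutationConfig",
    "PermutationResult",
    "ResultTable",
    "STATISTIC_OUTCOME_KIND",
    "read_expression",
    "write_expression",
    "read_phenotype",
    "read_annotation",
    "write_results",
    "format_pvalue",
]


class FormatError(ValueError):
    """A file violates the TSV contract (duplicates, missing or bad cells)."""


class ConfigurationError(ValueError):
    """Inconsistent analysis configuration (e.g. statistic/outcome mismatch)."""


#: Which outcome kind each statistic requires.
STATISTIC_OUTCOME_KIND: Mapping[str, str] = {
    "ttest": "binary",
    "wilcoxon": "binary",
    "pearson": "quantitative",
    "spearman": "quantitative",
    "coxscore": "survival",
    "coxrankscore": "survival",
}


# ---------------------------------------------------------------------------
# core types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionMatrix:
    """A K-feature x n-sample real-valued expression matrix.

    Parameters
    ----------
    values : ndarray of shape (K, n)
        Complete (no missing entries) real matrix, features as rows.
    feature_ids : sequence of K unique strings
    sample_ids : sequence of n unique strings
    """

    values: np.ndarray
    feature_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise FormatError("expression values must be a 2-D matrix")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "feature_ids", tuple(str(f) for f in self.feature_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        K, n = values.shape
        if K < 1:
            raise FormatError("expression matrix needs at least one feature")
        if n < 2:
            raise FormatError("expression matrix needs at least two samples")
        if len(self.feature_ids) != K:
            raise FormatError(f"{len(self.feature_ids)} feature ids for {K} rows")
        if len(self.sample_ids) != n:
            raise FormatError(f"{len(self.sample_ids)} sample ids for {n} columns")
        for name, ids in (("feature", self.feature_ids), ("sample", self.sample_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise FormatError(f"duplicate {name} id {dup!r}")
        if not np.isfinite(values).all():
            k, j = np.argwhere(~np.isfinite(values))[0]
            raise FormatError(
                f"non-finite expression value at feature {self.feature_ids[k]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class Outcome:
    """Tagged union over binary group labels, quantitative values, or
    right-censored survival pairs ``(time, event)`` with event=1 meaning the
    event was observed."""

    kind: Literal["binary", "quantitative", "survival"]
    group: Optional[np.ndarray] = None
    y: Optional[np.ndarray] = None
    time: Optional[np.ndarray] = None
    event: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.kind == "binary":
            g = np.asarray(self.group)
            if not np.isin(g, (0, 1)).all():
                bad = g[~np.isin(g, (0, 1))][0]
                raise ConfigurationError(f"binary group label {bad!r} outside {{0,1}}")
            g = g.astype(np.int8)
            if g.min() == g.max():
                raise ConfigurationError("binary outcome needs both groups non-empty")
            object.__setattr__(self, "group", g)
        elif self.kind == "quantitative":
            y = np.asarray(self.y, dtype=float)
            if not np.isfinite(y).all():
                raise ConfigurationError("quantitative outcome has non-finite values")
            object.__setattr__(self, "y", y)
        elif self.kind == "survival":
            t = np.asarray(self.time, dtype=float)
            e = np.asarray(self.event)
            if not np.isin(e, (0, 1)).all():
                raise ConfigurationError("event indicators must lie in {0,1}")
            e = e.astype(np.int8)
            if t.shape != e.shape:
                raise ConfigurationError("time and event lengths differ")
            if not (np.isfinite(t).all() and (t > 0).all()):
                raise ConfigurationError("survival times must be finite and > 0")
            if e.sum() == 0:
                raise ConfigurationError("survival outcome needs at least one event")
            object.__setattr__(self, "time", t)
            object.__setattr__(self, "event", e)
        else:
            raise ConfigurationError(f"unknown outcome kind {self.kind!r}")

    # convenience constructors -------------------------------------------------
    @classmethod
    def binary(cls, group: Sequence[int]) -> "Outcome":
        return cls(kind="binary", group=np.asarray(group))

    @classmethod
    def quantitative(cls, y: Sequence[float]) -> "Outcome":
        return cls(kind="quantitative", y=np.asarray(y, dtype=float))

    @classmethod
    def survival(cls, time: Sequence[float], event: Sequence[int]) -> "Outcome":
        return cls(kind="survival", time=np.asarray(time, dtype=float),
                   event=np.asarray(event))

    @property
    def n(self) -> int:
        if self.kind == "binary":
            return len(self.group)
        if self.kind == "quantitative":
            return len(self.y)
        return len(self.time)

    def take(self, index: np.ndarray) -> "Outcome":
        """Reorder samples.  Survival (time, event) pairs move as one unit."""
        if self.kind == "binary":
            return Outcome(kind="binary", group=self.group[index])
        if self.kind == "quantitative":
            return Outcome(kind="quantitative", y=self.y[index])
        return Outcome(kind="survival", time=self.time[index],
                       event=self.event[index])


@dataclass(frozen=True)
class PermutationConfig:
    """Configuration of one maxT permutation run.

    ``conservative=True`` switches the p-value estimator to
    ``(count + 1) / (B + 1)``; the default matches the plain
    count-over-B definition under which p = 0 is attainable.
    """

    statistic: str
    B: int
    alpha: float = 0.05
    seed: int = 0
    conservative: bool = False

    def __post_init__(self) -> None:
        if self.statistic not in STATISTIC_OUTCOME_KIND:
            raise ConfigurationError(
                f"unknown statistic {self.statistic!r}; choose from "
                f"{sorted(STATISTIC_OUTCOME_KIND)}"
            )
        if not (isinstance(self.B, (int, np.integer)) and self.B >= 1):
            raise ConfigurationError("B must be a positive integer")
        if not (0.0 < self.alpha < 1.0):
            raise ConfigurationError("alpha must lie in (0, 1)")
        if not (isinstance(self.seed, (int, np.integer)) and self.seed >= 0):
            raise ConfigurationError("seed must be a nonnegative integer")

    def check_outcome(self, outcome: Outcome) -> None:
        required = STATISTIC_OUTCOME_KIND[self.statistic]
        if outcome.kind != required:
            raise ConfigurationError(
                f"statistic {self.statistic!r} requires a {required} outcome, "
                f"got {outcome.kind!r}"
            )


@dataclass(frozen=True)
class PermutationResult:
    """Observed statistics and permutation p-values for one run.

    ``T_obs`` is on the statistic's reporting scale (signed z/t scale for
    ttest/wilcoxon/pearson/spearman, chi-square scale for the Cox tests);
    ``max_null`` holds per-replicate maxima on the comparison scale and
    ``xi`` the empirical critical value at level alpha.
    """

    feature_ids: tuple[str, ...]
    T_obs: np.ndarray
    p_unadj: np.ndarray
    p_adj: np.ndarray
    max_null: np.ndarray
    xi: float
    config: PermutationConfig

    def __post_init__(self) -> None:
        K = len(self.feature_ids)
        for name in ("T_obs", "p_unadj", "p_adj"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (K,):
                raise ConfigurationError(f"{name} must have length {K}")
            object.__setattr__(self, name, arr)
        object.__setattr__(self, "max_null",
                           np.asarray(self.max_null, dtype=float))
        if (self.p_adj + 1e-12 < self.p_unadj).any():
            raise ConfigurationError("adjusted p-values cannot be below unadjusted")


@dataclass
class ResultTable:
    """Sorted, optionally annotated result rows mirroring the published
    output layout: feature, T, p_unadj, p_adj, symbol, description."""

    frame: pd.DataFrame = field(default_factory=pd.DataFrame)

    COLUMNS = ("feature", "T", "p_unadj", "p_adj", "symbol", "description")

    def __len__(self) -> int:
        return len(self.frame)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _first_duplicate(ids: Sequence[str]) -> Optional[str]:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


def _read_tsv(path) -> pd.DataFrame:
    # keep_default_na=False so sentinel strings like "NA" surface as parse
    # errors with coordinates instead of silently becoming NaN
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                       na_values=[])


def read_expression(path) -> ExpressionMatrix:
    """Load a features-as-rows TSV expression matrix.

    First header field names the feature-id column; remaining header fields
    are sample ids.  Every data cell must parse as a finite real.
    """
    df = _read_tsv(path)
    if df.shape[1] < 3:
        raise FormatError(f"{path}: need a feature-id column and >= 2 samples")
    feature_ids = df.iloc[:, 0].tolist()
    sample_ids = [str(c) for c in df.columns[1:]]
    for name, ids in (("feature", feature_ids), ("sample", sample_ids)):
        dup = _first_duplicate(ids)
        if dup is not None:
            raise FormatError(f"{path}: duplicate {name} id {dup!r}")
    cells = df.iloc[:, 1:]
    numeric = cells.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().to_numpy())
    if bad.size:
        i, j = bad[0]
        raise FormatError(
            f"{path}: cell {cells.iat[i, j]!r} at feature {feature_ids[i]!r}, "
            f"sample {sample_ids[j]!r} is not a finite number"
        )
    # numpy's string->float conversion is correctly rounded; pandas'
    # to_numeric fast path can be off by one ULP, breaking round-trips
    values = cells.to_numpy().astype(np.float64)
    if not np.isfinite(values).all():
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise FormatError(
            f"{path}: non-finite value at feature {feature_ids[i]!r}, "
            f"sample {sample_ids[j]!r}"
        )
    return ExpressionMatrix(values=values, feature_ids=feature_ids,
                            sample_ids=sample_ids)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    """Write a matrix in the format accepted by :func:`read_expression`.

    Floats are printed with 17 significant digits so that a read/write
    round-trip is value-exact.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("feature\t" + "\t".join(matrix.sample_ids) + "\n")
        for fid, row in zip(matrix.feature_ids, matrix.values):
            fh.write(fid + "\t" + "\t".join(format(v, ".17g") for v in row) + "\n")


def read_phenotype(
    path,
    kind: str,
    *,
    sample_col: str = "sample",
    group_col: str = "group",
    value_col: str = "y",
    time_col: str = "time",
    event_col: str = "event",
    expression: Optional[ExpressionMatrix] = None,
) -> Outcome:
    """Load a phenotype TSV as an :class:`Outcome` of the requested kind.

    When ``expression`` is given, rows are re-ordered to that matrix's
    sample order; the sample sets must then match exactly.
    """
    if kind not in ("binary", "quantitative", "survival"):
        raise ConfigurationError(f"unknown outcome kind {kind!r}")
    df = _read_tsv(path)
    needed = {"binary": [sample_col, group_col],
              "quantitative": [sample_col, value_col],
              "survival": [sample_col, time_col, event_col]}[kind]
    for col in needed:
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    samples = df[sample_col].tolist()
    dup = _first_duplicate(samples)
    if dup is not None:
        raise FormatError(f"{path}: duplicate sample id {dup!r}")

    if expression is not None:
        have, want = set(samples), set(expression.sample_ids)
        if have != want:
            missing = sorted(want - have)
            extra = sorted(have - want)
            raise FormatError(
                f"{path}: sample sets differ from expression matrix "
                f"(missing: {missing}, unexpected: {extra})"
            )
        df = df.set_index(sample_col).loc[list(expression.sample_ids)].reset_index()

    def numeric(col: str) -> np.ndarray:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            i = int(vals.isna().to_numpy().argmax())
            raise FormatError(
                f"{path}: value {df[col].iat[i]!r} in column {col!r} "
                f"(sample {df[sample_col].iat[i]!r}) is not numeric"
            )
        return df[col].to_numpy().astype(np.float64)

    try:
        if kind == "binary":
            g = numeric(group_col)
            if not np.isin(g, (0.0, 1.0)).all():
                bad = g[~np.isin(g, (0.0, 1.0))][0]
                raise FormatError(f"{path}: group value {bad:g} outside {{0,1}}")
            return Outcome.binary(g.astype(int))
        if kind == "quantitative":
            return Outcome.quantitative(numeric(value_col))
        e = numeric(event_col)
        if not np.isin(e, (0.0, 1.0)).all():
            bad = e[~np.isin(e, (0.0, 1.0))][0]
            raise FormatError(f"{path}: event value {bad:g} outside {{0,1}}")
        return Outcome.survival(numeric(time_col), e.astype(int))
    except ConfigurationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def read_annotation(path) -> dict[str, tuple[str, str]]:
    """Load a feature annotation TSV with columns feature, symbol, description."""
    df = _read_tsv(path)
    if df.shape[1] < 3:
        raise FormatError(f"{path}: annotation needs feature, symbol, description")
    out: dict[str, tuple[str, str]] = {}
    for fid, sym, desc in zip(df.iloc[:, 0], df.iloc[:, 1], df.iloc[:, 2]):
        out[str(fid)] = (str(sym), str(desc))
    return out


# ---------------------------------------------------------------------------
# result writer
# ---------------------------------------------------------------------------

def format_pvalue(p: float) -> str:
    """4 significant digits; exact zero printed as ``0e+00``."""
    if p == 0:
        return "0e+00"
    return format(p, ".4g")


def write_results(
    result: PermutationResult,
    annotation: Optional[Mapping[str, tuple[str, str]]] = None,
    path=None,
    top: Optional[float] = None,
) -> ResultTable:
    """Assemble (and optionally write) the sorted result table.

    Rows are sorted by adjusted p ascending, ties broken by \\|T\\|
    descending, then feature id.  With ``top`` given, only rows with
    ``p_adj <= top`` are emitted.  Annotation gaps produce blank
    symbol/description cells and a single warning.
    """
    annotation = annotation or {}
    ids = result.feature_ids
    if annotation:
        missing = [f for f in ids if f not in annotation]
        if missing:
            warnings.warn(
                f"annotation missing for {len(missing)} of {len(ids)} features "
                f"(first: {missing[0]!r}); emitting blanks",
                stacklevel=2,
            )
    symbols = [annotation.get(f, ("", ""))[0] for f in ids]
    descriptions = [annotation.get(f, ("", ""))[1] for f in ids]
    frame = pd.DataFrame({
        "feature": ids,
        "T": result.T_obs,
        "p_unadj": result.p_unadj,
        "p_adj": result.p_adj,
        "symbol": symbols,
        "description": descriptions,
    })
    frame["_absT"] = np.abs(frame["T"])
    frame = frame.sort_values(
        by=["p_adj", "_absT", "feature"], ascending=[True, False, True],
        kind="mergesort",
    ).drop(columns="_absT").reset_index(drop=True)
    if top is not None:
        frame = frame[frame["p_adj"] <= top].reset_index(drop=True)
    table = ResultTable(frame=frame)
    if path is not None:
        out = frame.copy()
        out["T"] = [format(t, ".6g") for t in out["T"]]
        out["p_unadj"] = [format_pvalue(p) for p in out["p_unadj"]]
        out["p_adj"] = [format_pvalue(p) for p in out["p_adj"]]
        out.to_csv(path, sep="\t", index=False)
    return table


def file_digest(path) -> str:
    """SHA-256 hex digest of a file, for run manifests."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
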