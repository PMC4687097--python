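"""Ranking Phase I predictions by CYP activity and abundance.

The likelihood that a predicted transformation actually occurs is estimated
from the enzymes that can catalyse it: a product is more likely the more
abundant and active its catalysing CYPs are, and the more of them there
are.  The score of a prediction is

    score = sum_k (average activity_k) * (average abundance_k)

over the catalysing CYP subfamilies *k* for which liver activity/abundance
data are available; enzymes without data are skipped and flagged.

Activity (pmol substrate/min/mg protein) and abundance (pmol CYP/mg
protein) are collated from multiple published hepatocyte studies into
enzymes x studies matrices and made comparable by: imputing missing values
from row averages, min-max scaling each study column to [0, 1], quantile
normalisation across studies, and iterating the imputation until the
imputed entries converge (relative tolerance 0.1 %).  Row averages of the
converged matrices, normalised to sum to one over the nine major hepatic
CYPs (1A2, 2A6, 2B6, 2C8, 2C9, 2C19, 2D6, 2E1, 3A4), give the per-CYP
statistics used by the score.  A pre-normalised statistics table is
packaged with the module.

Phase II conjugates are not scored (transferase activity/abundance data are
too sparse); they are reported with a null score.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EnzymeDataMatrix",
    "EnzymeStats",
    "ScoredPrediction",
    "ConvergenceError",
    "minmax_scale_columns",
    "quantile_normalize",
    "normalize_matrix",
    "summarize",
    "load_packaged_stats",
    "score",
    "rank",
]

CYP_PANEL = ("1A2", "2A6", "2B6", "2C8", "2C9", "2C19", "2D6", "2E1", "3A4")


class ConvergenceError(RuntimeError):
    pass


@dataclass
class EnzymeDataMatrix:
    """Enzymes x studies data matrix with explicit missingness.

    ``data`` holds raw nonnegative values with NaN for missing cells;
    ``kind`` is "activity" or "abundance".
    """

    data: pd.DataFrame
    kind: str
    units: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("activity", "abundance"):
            raise ValueError(f"kind must be 'activity' or 'abundance', got {self.kind!r}")
        empty = self.data.index[self.data.isna().all(axis=1)]
        if len(empty):
            import warnings

            warnings.warn(
                f"dropping enzymes with no observed values: {list(empty)}", stacklevel=2
            )
            self.data = self.data.drop(index=empty)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()


def minmax_scale_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Scale each study column to [0, 1]: (a_ij - a_j,min) / (a_j,max - a_j,min).

    Constant columns scale to all-zero.
    """
    lo = df.min(axis=0)
    span = (df.max(axis=0) - lo).replace(0, np.nan)
    return ((df - lo) / span).fillna(0.0)


def quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Force every column to the same distribution (mean of sorted columns).

    Tied values within a column receive the mean of the reference
    distribution over their tied ranks.
    """
    arr = df.to_numpy(dtype=float)
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    n = arr.shape[0]
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="stable")
        ranks = np.empty(n, dtype=int)
        ranks[order] = np.arange(n)
        # average the reference over tied spans
        col_sorted = col[order]
        value = np.empty(n)
        start = 0
        while start < n:
            stop = start
            while stop + 1 < n and col_sorted[stop + 1] == col_sorted[start]:
                stop += 1
            value[start : stop + 1] = reference[start : stop + 1].mean()
            start = stop + 1
        out[:, j] = value[ranks]
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def normalize_matrix(
    m: EnzymeDataMatrix, tol: float = 1e-3, max_iter: int = 200
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Impute, scale and quantile-normalise a raw enzymes x studies matrix.

    Missing cells start at their row average; each pass min-max scales the
    columns, quantile-normalises across studies, and re-estimates the
    missing cells from the row means of the normalised matrix.  Iteration
    stops when the largest relative change over imputed entries drops below
    *tol* (default 0.1 %).  Returns (normalised matrix, imputed-cell values).
    """
    raw = m.data
    mask = raw.isna()
    X = raw.copy()
    row_means = raw.mean(axis=1)
    for i in X.index:
        X.loc[i, mask.loc[i]] = row_means[i]
    prev: pd.DataFrame | None = None
    for _ in range(max_iter):
        Q = quantile_normalize(minmax_scale_columns(X))
        if not mask.to_numpy().any():
            return Q, Q.where(mask)
        est = Q.mean(axis=1)
        X = Q.copy()
        for i in X.index:
            X.loc[i, mask.loc[i]] = est[i]
        current = X.where(mask)
        if prev is not None:
            num = (current - prev).abs()
            den = prev.abs().clip(lower=1e-12)
            delta = (num / den).max().max()
            if delta < tol:
                return X, current
        prev = current
    raise ConvergenceError(
        f"imputation did not converge within {max_iter} iterations (tol={tol})"
    )


@dataclass
class EnzymeStats:
    """Per-CYP summary: sum-normalised average plus descriptive min/max.

    ``table`` is indexed by enzyme token with columns
    (abundance_avg, abundance_min, abundance_max,
     activity_avg, activity_min, activity_max).
    The averages of each kind sum to 1 over the panel; the min/max columns
    describe the per-row spread of the converged normalised matrices and
    are carried as metadata only.
    """

    table: pd.DataFrame

    def has_data(self, enzyme: str) -> bool:
        return enzyme in self.table.index

    def average(self, kind: str, enzyme: str) -> float:
        return float(self.table.loc[enzyme, f"{kind}_avg"])

    @property
    def enzymes(self) -> tuple[str, ...]:
        return tuple(self.table.index)


def summarize(norm_activity: pd.DataFrame, norm_abundance: pd.DataFrame) -> EnzymeStats:
    """Row-average the normalised matrices and sum-normalise the averages."""
    if list(norm_activity.index) != list(norm_abundance.index):
        raise ValueError("activity and abundance matrices must share enzyme rows")
    cols = {}
    for kind, df in (("abundance", norm_abundance), ("activity", norm_activity)):
        avg = df.mean(axis=1)
        total = avg.sum()
        if total <= 0:
            raise ValueError(f"{kind}: averages sum to zero, cannot normalise")
        cols[f"{kind}_avg"] = avg / total
        cols[f"{kind}_min"] = df.min(axis=1)
        cols[f"{kind}_max"] = df.max(axis=1)
    return EnzymeStats(pd.DataFrame(cols))


@functools.lru_cache(maxsize=1)
def load_packaged_stats() -> EnzymeStats:
    """Normalised activity/abundance statistics for the 9-CYP liver panel."""
    with resources.files("proximal.data").joinpath("cyp_stats.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", index_col="cyp", dtype={"cyp": str})
    return EnzymeStats(df)


@dataclass(frozen=True)
class ScoreResult:
    value: float
    used: tuple[str, ...]
    missing: tuple[str, ...]

    @property
    def reported(self) -> float:
        """Score rounded (half-even) to 4 decimals, as printed in reports."""
        return float(np.round(self.value, 4))


def score(enzymes: Iterable[str], stats: EnzymeStats | None = None) -> ScoreResult:
    """Sum of (average activity x average abundance) over enzymes with data.

    Enzymes absent from the statistics table (e.g. 1A1, 1B1, 2C18, 3A5, for
    which liver data are unavailable) contribute nothing and are reported in
    ``missing``.
    """
    if stats is None:
        stats = load_packaged_stats()
    used, missing = [], []
    total = 0.0
    for e in sorted(set(enzymes)):
        if stats.has_data(e):
            used.append(e)
            total += stats.average("activity", e) * stats.average("abundance", e)
        else:
            missing.append(e)
    return ScoreResult(value=total, used=tuple(used), missing=tuple(missing))


@dataclass(frozen=True)
class ScoredPrediction:
    id: str
    enzymes: tuple[str, ...]
    score: float  # full precision
    reported_score: float  # rounded to 4 decimals
    rank: int
    enzymes_without_data: tuple[str, ...] = ()


def rank(
    items: Sequence[tuple[str, Iterable[str]]], stats: EnzymeStats | None = None
) -> list[ScoredPrediction]:
    """Score and ordinally rank predictions.

    *items* are (id, enzyme set) pairs.  Output is sorted by descending
    score with ties kept in input order (stable), ranks 1..n.
    """
    if stats is None:
        stats = load_packaged_stats()
    scored = []
    for pos, (pid, enzymes) in enumerate(items):
        res = score(enzymes, stats)
        scored.append((pos, pid, tuple(sorted(set(enzymes))), res))
    scored.sort(key=lambda t: (-t[3].value, t[0]))
    return [
        ScoredPrediction(
            id=pid,
            enzymes=enz,
            score=res.value,
            reported_score=res.reported,
            rank=k + 1,
            enzymes_without_data=res.missing,
        )
        for k, (pos, pid, enz, res) in enumerate(scored)
    ]
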