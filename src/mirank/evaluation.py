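"""Scoring a ranked miRNA list against a disease annotation set.

Provides cumulative annotation-ratio curves (fraction of gold-standard
miRNAs among the top k, as a function of k), upper-tail hypergeometric
overlap tests for fixed top lists, and the differential-expression t-test
baseline ranking used for method comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import AnnotationSet, ExpressionMatrix

__all__ = [
    "CumulativeCurve",
    "OverlapTest",
    "cumulative_ratio",
    "hypergeom_overlap",
    "hypergeom_upper_tail",
    "de_ttest_rank",
]


@dataclass
class CumulativeCurve:
    """ratio[k-1] = |top-k of the ranking  ∩  annotated| / k."""

    k: np.ndarray
    ratio: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.k, "ratio": self.ratio}).set_index("k")

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    def at(self, k: int) -> float:
        return float(self.ratio[k - 1])


@dataclass
class OverlapTest:
    """Upper-tail hypergeometric test of a top list against an annotation.

    Drawing n of M items of which K are annotated, p = P(X >= x) for the
    observed x annotated items in the top list.
    """

    M: int
    K: int
    n: int
    x: int
    p: float


def cumulative_ratio(ranked_ids: Sequence[str], annotation: AnnotationSet) -> CumulativeCurve:
    """Cumulative fraction of annotated miRNAs along a ranking."""
    ids = list(ranked_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("ranked list contains duplicates")
    hits = np.array([1.0 if m in annotation else 0.0 for m in ids])
    k = np.arange(1, len(ids) + 1)
    return CumulativeCurve(k, np.cumsum(hits) / k)


def hypergeom_upper_tail(x, M: int, K: int, n: int) -> np.ndarray:
    """P(X >= x) for X ~ Hypergeometric(M, K, n), vectorized over x.

    Evaluated in log-space so magnitudes far below 1e-40 remain exact in
    double precision."""
    x = np.atleast_1d(np.asarray(x, dtype=int))
    with np.errstate(divide="ignore"):
        p = np.exp(stats.hypergeom.logsf(x - 1, M, K, n))
    p = np.where(x <= 0, 1.0, p)
    return np.minimum(p, 1.0)


def hypergeom_overlap(M: int, K: int, n: int, x: int) -> OverlapTest:
    """Upper-tail hypergeometric test of x annotated items among a top-n
    list drawn from a universe of M with K annotated."""
    if not (0 <= K <= M and 0 <= n <= M):
        raise ValueError("need 0 <= K <= M and 0 <= n <= M")
    if not (0 <= x <= min(K, n)):
        raise ValueError("need 0 <= x <= min(K, n)")
    p = float(hypergeom_upper_tail(x, M, K, n)[0])
    return OverlapTest(M, K, n, x, p)


def de_ttest_rank(tumor: ExpressionMatrix, normal: ExpressionMatrix) -> list[str]:
    """Differential-expression baseline: rank miRNAs by Welch t-test p-value.

    Tumor and normal matrices must share entity ids; each group needs at
    least two samples. Returns ids in ascending p-value order (ties broken
    by id for determinism).
    """
    if set(tumor.entity_ids) != set(normal.entity_ids):
        raise ValueError("tumor and normal matrices must share entity ids")
    if len(tumor.sample_ids) < 2 or len(normal.sample_ids) < 2:
        raise ValueError("each group needs at least 2 samples")
    ids = tumor.entity_ids
    X = tumor.values
    Y = normal.data.loc[ids].to_numpy()
    res = stats.ttest_ind(X, Y, axis=1, equal_var=False)
    p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)  # zero-variance ties
    order = sorted(range(len(ids)), key=lambda i: (p[i], ids[i]))
    return [ids[i] for i in order]
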