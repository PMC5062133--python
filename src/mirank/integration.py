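"""Bidirectional order-statistics rank aggregation of the three features.

Each feature is converted to a ranking ratio in (0, 1] in both sort
directions. For a given miRNA the N = 3 ratios are treated as candidate
upper bounds on the order statistics of N independent Uniform(0, 1)
variables; the Q statistic is the joint probability

    Q(r_1, ..., r_N) = P(U_(1) <= r_(1), ..., U_(N) <= r_(N))

with the ratios sorted ascending. A miRNA that ranks uniformly well on all
features has uniformly small descending ratios, hence a small Q. Q is
evaluated with the recursive solution of Stuart et al. for this joint CDF.

Two Q values are computed per miRNA: Q1 from descending ratios (relevance:
small means good everywhere) and Q2 from ascending ratios (irrelevance:
large means not-bad everywhere). Ranking Q1 ascending gives R_Q1, ranking
Q2 descending gives R_Q2, and the final score is R_Q = R_Q1 + R_Q2, ranked
ascending. Summing the two directions damps miRNAs whose good Q1 is driven
by a single feature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .features import FeatureTable

__all__ = [
    "ranking_ratio",
    "q_statistic",
    "IntegrationResult",
    "integrate",
    "integrate_average_ratio",
    "integrate_inverse_normal",
]


def ranking_ratio(values: Sequence[float], direction: str = "descending") -> np.ndarray:
    """Rank values in the requested direction and divide ranks by M.

    Rank 1 is best for the chosen direction; ties get the average of the
    tied ranks. Ratios therefore lie in (0, 1]: 1/M for the unique best
    value, 1 for the unique worst.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValueError("values must be a non-empty 1-D vector")
    if direction == "descending":
        ranks = rankdata(-v, method="average")
    elif direction == "ascending":
        ranks = rankdata(v, method="average")
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return ranks / v.size


def q_statistic(ratios: Sequence[float]) -> float:
    """Joint CDF of uniform order statistics at the sorted ratios.

    Returns P(U_(k) <= r_(k) for all k) for N iid Uniform(0,1) variables,
    where r_(1) <= ... <= r_(N) are the sorted inputs, via the recursion

        V_0 = 1,  V_k = sum_{i=1..k} (-1)^(i-1) V_{k-i} r_(N-k+1)^i / i!,
        Q = N! * V_N.

    Works for any N >= 1; N=1 reduces to r and N=2 to 2 r1 r2 - r1^2.
    """
    r = np.sort(np.asarray(ratios, dtype=float))
    if r.size == 0:
        raise ValueError("need at least one ratio")
    if (r < 0).any() or (r > 1).any():
        raise ValueError("ratios must lie in [0, 1]")
    N = r.size
    V = np.zeros(N + 1)
    V[0] = 1.0
    for k in range(1, N + 1):
        rk = r[N - k]  # r_(N-k+1) in 1-based indexing
        acc = 0.0
        for i in range(1, k + 1):
            acc += (-1) ** (i - 1) * V[k - i] * rk**i / math.factorial(i)
        V[k] = acc
    q = math.factorial(N) * V[N]
    # recursion is exact; clipping only guards against last-bit float noise
    return float(min(max(q, 0.0), 1.0))


def _q_rows(ratio_matrix: np.ndarray) -> np.ndarray:
    """Q statistic of each row of an (M, N) ratio matrix."""
    return np.array([q_statistic(row) for row in ratio_matrix])


@dataclass
class IntegrationResult:
    """Full output of the bidirectional order-statistics integration."""

    mirna_ids: list[str]
    q1: np.ndarray  # relevance Q per miRNA (descending ratios)
    q2: np.ndarray  # irrelevance Q per miRNA (ascending ratios)
    rq1: np.ndarray  # rank of q1, ascending (average ties)
    rq2: np.ndarray  # rank of q2, descending (average ties)
    rq: np.ndarray  # rq1 + rq2, the final score (smaller = higher priority)
    final_rank: np.ndarray  # permutation of 1..M sorting rq ascending

    def ranked_ids(self) -> list[str]:
        order = np.argsort(self.final_rank)
        return [self.mirna_ids[i] for i in order]

    def to_frame(self, features: FeatureTable | None = None) -> pd.DataFrame:
        cols = {"mirna": self.mirna_ids}
        if features is not None:
            cols.update({"a": features.a, "c": features.c, "t": features.t})
        cols.update(
            {
                "q1": self.q1,
                "q2": self.q2,
                "rq1": self.rq1,
                "rq2": self.rq2,
                "rq": self.rq,
                "final_rank": self.final_rank,
            }
        )
        return pd.DataFrame(cols).set_index("mirna")

    def to_tsv(self, path: str | Path, features: FeatureTable | None = None) -> None:
        self.to_frame(features).to_csv(path, sep="\t")


def integrate(features: FeatureTable) -> IntegrationResult:
    """Run the full bidirectional Q integration on a feature table."""
    if features.M < 2:
        raise ValueError("need at least 2 miRNAs to integrate")
    cols = (features.a, features.c, features.t.astype(float))
    RD = np.column_stack([ranking_ratio(v, "descending") for v in cols])
    RI = np.column_stack([ranking_ratio(v, "ascending") for v in cols])
    q1 = _q_rows(RD)
    q2 = _q_rows(RI)
    rq1 = rankdata(q1, method="average")
    rq2 = rankdata(-q2, method="average")
    rq = rq1 + rq2
    # deterministic final order: smaller rq, then smaller rq1, then id
    order = np.lexsort((np.asarray(features.mirna_ids, dtype=object), rq1, rq))
    final_rank = np.empty(features.M, dtype=int)
    final_rank[order] = np.arange(1, features.M + 1)
    return IntegrationResult(list(features.mirna_ids), q1, q2, rq1, rq2, rq, final_rank)


def _priority_series(mirna_ids: list[str], score: np.ndarray, ascending: bool) -> pd.Series:
    """Scores indexed by miRNA, sorted best-first with id tie-breaks."""
    s = pd.Series(score, index=pd.Index(mirna_ids, name="mirna"), name="score")
    return s.sort_index().sort_values(ascending=ascending, kind="stable")


def integrate_average_ratio(
    features: FeatureTable, weights: Sequence[float] = (1.0, 1.0, 1.0)
) -> pd.Series:
    """Baseline integrator: weighted mean of descending ranking ratios.

    Returns scores sorted ascending (best first). Equal weights give the
    plain average (RD_1 + RD_2 + RD_3) / 3.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (3,) or (w < 0).any() or w.sum() == 0:
        raise ValueError("weights must be 3 non-negative reals with positive sum")
    cols = (features.a, features.c, features.t.astype(float))
    RD = np.column_stack([ranking_ratio(v, "descending") for v in cols])
    score = RD @ w / w.sum()
    return _priority_series(features.mirna_ids, score, ascending=True)


def integrate_inverse_normal(features: FeatureTable) -> pd.Series:
    """Baseline integrator: mean of inverse-normal transformed ranks.

    The descending rank of each feature is mapped to u' = (rank - 0.5)/M
    and then to z = Phi^{-1}(1 - u'), so the top-ranked value gets the most
    positive z. Scores (mean z over the three features) are sorted
    descending (best first).
    """
    M = features.M
    cols = (features.a, features.c, features.t.astype(float))
    zs = []
    for v in cols:
        ranks = ranking_ratio(v, "descending") * M  # average-tie ranks
        u = (ranks - 0.5) / M
        zs.append(norm.ppf(1.0 - u))
    score = np.mean(zs, axis=0)
    return _priority_series(features.mirna_ids, score, ascending=False)
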