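"""Per-miRNA features: mean expression, mean |PCC| with all genes, target count.

The three features quantify, respectively, how abundantly a miRNA is
expressed in tumor samples, how strongly its expression co-varies with the
transcriptome as a whole, and how many genes it is predicted to target by
sequence complementarity. Highly expressed, highly connected, highly
correlated miRNAs are the candidates most likely to drive network-wide
expression changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import InteractionSet, PairedDataset

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureTable",
    "mean_expression",
    "mean_abs_correlation",
    "target_count",
    "build_feature_table",
]


@dataclass
class FeatureTable:
    """Per-miRNA feature triplet over a universe of M miRNAs.

    a : mean tumor expression; c : mean absolute Pearson correlation with
    all retained genes, in [0, 1]; t : number of distinct predicted target
    genes, a non-negative integer.
    """

    mirna_ids: list[str]
    a: np.ndarray
    c: np.ndarray
    t: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        self.t = np.asarray(self.t, dtype=int)
        M = len(self.mirna_ids)
        if not (len(self.a) == len(self.c) == len(self.t) == M):
            raise ValueError("feature vectors must all have length M")
        if M == 0:
            raise ValueError("empty feature table")
        if ((self.c < -1e-12) | (self.c > 1 + 1e-12)).any():
            raise ValueError("c entries must lie in [0, 1]")
        if (self.t < 0).any():
            raise ValueError("t entries must be non-negative")
        self.c = np.clip(self.c, 0.0, 1.0)

    @property
    def M(self) -> int:
        return len(self.mirna_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mirna": self.mirna_ids, "a": self.a, "c": self.c, "t": self.t}
        ).set_index("mirna")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("mirna\ta\tc\tt\n")
            for m, a, c, t in zip(self.mirna_ids, self.a, self.c, self.t):
                fh.write(f"{m}\t{repr(float(a))}\t{repr(float(c))}\t{int(t)}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureTable":
        df = pd.read_csv(path, sep="\t", dtype={"mirna": str}, float_precision="round_trip")
        return cls(list(df["mirna"]), df["a"].to_numpy(), df["c"].to_numpy(), df["t"].to_numpy())


def mean_expression(dataset: PairedDataset) -> np.ndarray:
    """Mean expression of each miRNA over all tumor samples (feature F1)."""
    if dataset.n_samples < 1:
        raise ValueError("need at least one sample")
    return dataset.mirna.values.mean(axis=1)


def mean_abs_correlation(dataset: PairedDataset) -> np.ndarray:
    """Mean absolute Pearson correlation of each miRNA with all genes (F2).

    Genes with zero variance across samples have undefined PCC and are
    excluded globally, so every miRNA is averaged over the same gene
    universe. A zero-variance miRNA gets c_i = 0 with a warning.
    """
    n = dataset.n_samples
    if n < 3:
        raise ValueError("need at least 3 samples for correlation")
    X = dataset.mirna.values  # (M, n)
    Y = dataset.genes.values  # (G, n)

    Yc = Y - Y.mean(axis=1, keepdims=True)
    y_sd = np.sqrt((Yc**2).sum(axis=1))
    keep = y_sd > 0
    if not keep.any():
        raise ValueError("all genes have zero variance across samples")
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.warning("excluded %d zero-variance genes from F2", n_excluded)
    Yz = Yc[keep] / y_sd[keep, None]

    Xc = X - X.mean(axis=1, keepdims=True)
    x_sd = np.sqrt((Xc**2).sum(axis=1))
    flat = x_sd == 0
    if flat.any():
        logger.warning("%d zero-variance miRNAs assigned c=0", int(flat.sum()))
    x_sd_safe = np.where(flat, 1.0, x_sd)
    Xz = Xc / x_sd_safe[:, None]

    # correlation matrix of unit-norm centered rows is a plain inner product
    corr = Xz @ Yz.T
    c = np.abs(np.clip(corr, -1.0, 1.0)).mean(axis=1)
    c[flat] = 0.0
    return c


def target_count(mirna_ids: list[str], interactions: InteractionSet) -> np.ndarray:
    """Number of distinct predicted target genes per miRNA (F3).

    Depends only on the interaction table; miRNAs absent from it get 0.
    """
    counts: dict[str, set[str]] = {}
    for m, g in interactions.pairs:
        counts.setdefault(m, set()).add(g)
    return np.array([len(counts.get(m, ())) for m in mirna_ids], dtype=int)


def build_feature_table(dataset: PairedDataset, interactions: InteractionSet) -> FeatureTable:
    """Compute all three features over the dataset's miRNA id order."""
    ids = dataset.mirna.entity_ids
    return FeatureTable(
        mirna_ids=ids,
        a=mean_expression(dataset),
        c=mean_abs_correlation(dataset),
        t=target_count(ids, interactions),
    )
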