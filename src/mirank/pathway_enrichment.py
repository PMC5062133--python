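"""Per-miRNA related-gene sets and hypergeometric pathway enrichment.

The related-gene set of a miRNA is the union of (a) the genes whose
expression is most strongly correlated with the miRNA (top fraction of
|PCC|, default 1%) and (b) its experimentally validated targets. Each
gene-set in a collection is then tested for over-representation of the
related genes with an upper-tail hypergeometric test; p-values are
corrected per miRNA across sets by the Benjamini-Hochberg step-up
procedure, with q < 0.05 flagged as significant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .data_io import GeneSetCollection, InteractionSet, PairedDataset, normalize_id
from .evaluation import hypergeom_overlap

logger = logging.getLogger(__name__)

__all__ = ["EnrichmentRow", "related_genes", "enrich", "enrichment_frame"]

SIGNIFICANCE_Q = 0.05


@dataclass
class EnrichmentRow:
    mirna_id: str
    set_name: str
    overlap: int
    set_size: int
    query_size: int
    background_size: int
    p: float
    q: float
    significant: bool


def related_genes(
    mirna_id: str,
    dataset: PairedDataset,
    validated: InteractionSet | None = None,
    fraction: float = 0.01,
) -> set[str]:
    """Genes related to a miRNA: top-|PCC| fraction union validated targets.

    The correlation cutoff keeps the ceil(fraction * G) genes with largest
    absolute Pearson correlation to the miRNA; genes tied with the cutoff
    value are all included, so the result is deterministic.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    mid = normalize_id(mirna_id)
    if mid not in dataset.mirna.data.index:
        raise KeyError(f"miRNA {mirna_id!r} absent from expression matrix")
    x = dataset.mirna.data.loc[mid].to_numpy()
    Y = dataset.genes.values
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=1, keepdims=True)
    x_sd = np.sqrt((xc**2).sum())
    y_sd = np.sqrt((Yc**2).sum(axis=1))
    denom = np.where((y_sd > 0) & (x_sd > 0), y_sd * x_sd, np.inf)
    abs_pcc = np.abs(Yc @ xc) / denom  # zero-variance rows score 0
    G = len(abs_pcc)
    k = math.ceil(fraction * G)
    cutoff = np.sort(abs_pcc)[::-1][k - 1]
    top = {g for g, r in zip(dataset.genes.entity_ids, abs_pcc) if r >= cutoff}
    if validated is not None:
        top |= validated.targets_of(mid)
    return top


def enrich(query: set[str], collection: GeneSetCollection) -> list[EnrichmentRow]:
    """Hypergeometric over-representation of a gene query in every set.

    Query genes outside the collection background are dropped with a
    warning. BH correction runs across all sets of the collection for this
    single query; rows come back sorted by (p, set name).
    """
    if not collection.background:
        raise ValueError("empty enrichment background")
    q_in = {normalize_id(g) for g in query}
    outside = q_in - collection.background
    if outside:
        logger.warning("dropped %d query genes outside the background", len(outside))
    q_in &= collection.background
    M = len(collection.background)
    n = len(q_in)
    names = sorted(collection.sets)
    pvals = []
    meta = []
    for name in names:
        members = collection.sets[name]
        x = len(q_in & members)
        pvals.append(hypergeom_overlap(M, len(members), n, x).p)
        meta.append((name, x, len(members)))
    if pvals:
        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    else:
        qvals = []
    rows = [
        EnrichmentRow(
            mirna_id="",
            set_name=name,
            overlap=x,
            set_size=size,
            query_size=n,
            background_size=M,
            p=float(p),
            q=float(qv),
            significant=bool(qv < SIGNIFICANCE_Q),
        )
        for (name, x, size), p, qv in zip(meta, pvals, qvals)
    ]
    rows.sort(key=lambda r: (r.p, r.set_name))
    return rows


def enrichment_frame(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in rows])


def write_enrichment(rows: Sequence[EnrichmentRow], path: str | Path) -> None:
    enrichment_frame(rows).to_csv(path, sep="\t", index=False)
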