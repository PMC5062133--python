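"""Readers, writers and validated in-memory containers for all external formats.

Every downstream module consumes only the typed objects defined here:
expression matrices (entities x samples), interaction sets, disease
annotation sets, GMT gene-set collections and clinical tables. All files
are UTF-8, tab-delimited text.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "PairedDataset",
    "InteractionSet",
    "AnnotationSet",
    "GeneSetCollection",
    "ClinicalTable",
    "normalize_id",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_interactions",
    "write_interactions",
    "read_gmt",
    "write_gmt",
    "read_annotation",
    "write_annotation",
    "read_clinical",
    "write_clinical",
    "align_paired",
]


def normalize_id(identifier: str) -> str:
    """Normalize a miRNA/gene identifier.

    Lowercase, strip surrounding whitespace, and drop a leading ``hsa-``
    species prefix so that mature-miRNA names from different sources
    (``hsa-miR-21`` vs ``miR-21``) compare equal. After normalization,
    matching is exact string equality; no mature<->precursor mapping is
    attempted.
    """
    s = identifier.strip().lower()
    if s.startswith("hsa-"):
        s = s[4:]
    return s


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Expression values for entities (miRNAs or genes) across samples.

    ``data`` is entities x samples with unique, normalized entity ids as the
    index and unique sample ids as the columns. Rows containing missing
    values are dropped at construction and counted via ``n_dropped``.
    """

    data: pd.DataFrame
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise ValueError("expression matrix is empty")
        idx = pd.Index([normalize_id(str(e)) for e in self.data.index])
        cols = pd.Index([str(c).strip() for c in self.data.columns])
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate entity ids: {dups[:5]}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        data = self.data.copy()
        data.index, data.columns = idx, cols
        mask = data.isna().any(axis=1)
        if mask.any():
            self.n_dropped = int(mask.sum())
            logger.warning("dropped %d entity rows with missing values", self.n_dropped)
            data = data.loc[~mask]
            if data.shape[0] == 0:
                raise ValueError("all rows contained missing values")
        self.data = data.astype(float)

    @property
    def entity_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)])


@dataclass
class ClinicalTable:
    """Per-sample survival record: time in days and a binary event flag
    (1 = deceased, 0 = right-censored)."""

    data: pd.DataFrame  # index: sample_id; columns: time, event

    def __post_init__(self) -> None:
        df = self.data.copy()
        df.index = pd.Index([str(s).strip() for s in df.index])
        if df.index.has_duplicates:
            raise ValueError("duplicate sample ids in clinical table")
        if not {"time", "event"} <= set(df.columns):
            raise ValueError("clinical table needs 'time' and 'event' columns")
        df["time"] = df["time"].astype(float)
        df["event"] = df["event"].astype(int)
        if (df["time"] < 0).any():
            raise ValueError("negative survival time")
        if not df["event"].isin((0, 1)).all():
            raise ValueError("event flag must be 0 or 1")
        self.data = df[["time", "event"]]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def subset(self, sample_ids: Iterable[str]) -> "ClinicalTable":
        keep = [s for s in sample_ids if s in self.data.index]
        return ClinicalTable(self.data.loc[keep])


@dataclass
class PairedDataset:
    """miRNA and gene expression over an identical, identically ordered
    sample axis, with an optional clinical table restricted to those samples."""

    mirna: ExpressionMatrix
    genes: ExpressionMatrix
    clinical: Optional[ClinicalTable] = None

    def __post_init__(self) -> None:
        if self.mirna.sample_ids != self.genes.sample_ids:
            raise ValueError(
                "miRNA and gene matrices have different sample axes; "
                "use align_paired() first"
            )
        if self.clinical is not None:
            extra = set(self.clinical.sample_ids) - set(self.mirna.sample_ids)
            if extra:
                raise ValueError(f"clinical samples absent from expression: {sorted(extra)[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return self.mirna.sample_ids

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class InteractionSet:
    """Deduplicated set of predicted or validated (miRNA, gene) pairs."""

    pairs: frozenset[tuple[str, str]]
    source_tags: Optional[Mapping[tuple[str, str], str]] = None

    def __post_init__(self) -> None:
        for m, g in self.pairs:
            if not m or not g:
                raise ValueError("empty identifier in interaction pair")
        self.pairs = frozenset(self.pairs)

    def targets_of(self, mirna_id: str) -> set[str]:
        m = normalize_id(mirna_id)
        return {g for mi, g in self.pairs if mi == m}

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class AnnotationSet:
    """Disease-associated miRNA ids (the gold-standard role)."""

    disease_label: str
    mirna_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.disease_label:
            raise ValueError("annotation set needs a non-empty disease label")
        self.mirna_ids = frozenset(normalize_id(m) for m in self.mirna_ids)

    def __contains__(self, mirna_id: str) -> bool:
        return normalize_id(mirna_id) in self.mirna_ids


@dataclass
class GeneSetCollection:
    """Named gene sets over a declared background universe for enrichment."""

    sets: dict[str, frozenset[str]]
    background: frozenset[str]

    def __post_init__(self) -> None:
        self.background = frozenset(normalize_id(g) for g in self.background)
        norm = {}
        for name, members in self.sets.items():
            if name in norm:
                raise ValueError(f"duplicate gene-set name {name!r}")
            norm[name] = frozenset(normalize_id(g) for g in members)
        for name, members in norm.items():
            if not members <= self.background:
                raise ValueError(f"gene set {name!r} has members outside the background")
        self.sets = norm

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_expression_matrix(path: str | Path, transform: str = "none") -> ExpressionMatrix:
    """Read a tab-separated entities x samples matrix.

    First column holds entity ids, the header row holds sample ids.
    ``transform='log2_plus1'`` applies log2(x+1), the usual variance
    stabilization for RNA-Seq counts; ``'none'`` reads values as-is.
    """
    if transform not in ("none", "log2_plus1"):
        raise ValueError(f"unknown transform {transform!r}")
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty file")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: no data rows/columns")
    try:
        # numpy's strtod parse is correctly rounded, so repr round-trips
        numeric = pd.DataFrame(
            df.to_numpy(dtype=float), index=df.index, columns=df.columns
        )
    except (TypeError, ValueError):
        coerced = df.apply(pd.to_numeric, errors="coerce")
        bad = coerced.isna() & df.notna()
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}"
        ) from None
    if transform == "log2_plus1":
        if (numeric < 0).to_numpy().any():
            raise ValueError(f"{path}: negative value under log2_plus1 transform")
        numeric = np.log2(numeric + 1.0)
    return ExpressionMatrix(numeric)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write TSV at full float precision (round-trips losslessly)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(["id"] + matrix.sample_ids) + "\n")
        for eid, row in zip(matrix.entity_ids, matrix.values):
            fh.write(eid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_interactions(paths: Sequence[str | Path]) -> InteractionSet:
    """Read two-column (miRNA, gene) TSV files and union them.

    Duplicate pairs, within and across files, are removed (set semantics).
    """
    pairs: set[tuple[str, str]] = set()
    tags: dict[tuple[str, str], str] = {}
    for path in paths:
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                fields = line.split("\t")
                if len(fields) != 2 or not fields[0].strip() or not fields[1].strip():
                    raise ValueError(f"{path}:{lineno}: malformed interaction line {line!r}")
                pair = (normalize_id(fields[0]), normalize_id(fields[1]))
                pairs.add(pair)
                tags.setdefault(pair, path.name)
    return InteractionSet(frozenset(pairs), tags)


def write_interactions(interactions: InteractionSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for m, g in sorted(interactions.pairs):
            fh.write(f"{m}\t{g}\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (set name, description, members...).

    The background universe is the union of all member genes, the default
    enrichment universe when none is supplied externally.
    """
    sets: dict[str, frozenset[str]] = {}
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line with fewer than 3 fields")
            name = fields[0].strip()
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            members = frozenset(normalize_id(g) for g in fields[2:] if g.strip())
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets[name] = members
    background = frozenset().union(*sets.values()) if sets else frozenset()
    return GeneSetCollection(sets, background)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(collection.sets):
            members = sorted(collection.sets[name])
            fh.write("\t".join([name, "na"] + members) + "\n")


def read_annotation(path: str | Path, disease_label: str = "disease") -> AnnotationSet:
    """Read a one-column list of disease-associated miRNA ids."""
    ids: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            token = line.strip()
            if token:
                ids.add(normalize_id(token))
    return AnnotationSet(disease_label, frozenset(ids))


def write_annotation(annotation: AnnotationSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for m in sorted(annotation.mirna_ids):
            fh.write(m + "\n")


def read_clinical(path: str | Path) -> ClinicalTable:
    """Read a 3-column TSV: sample id, survival time in days, event flag."""
    df = pd.read_csv(path, sep="\t", dtype={0: str}, float_precision="round_trip")
    if df.shape[1] != 3:
        raise ValueError(f"{path}: clinical table must have exactly 3 columns")
    df.columns = ["sample_id", "time", "event"]
    df = df.set_index("sample_id")
    return ClinicalTable(df)


def write_clinical(clinical: ClinicalTable, path: str | Path) -> None:
    df = clinical.data.copy()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\ttime_days\tevent\n")
        for sid, row in df.iterrows():
            fh.write(f"{sid}\t{repr(float(row['time']))}\t{int(row['event'])}\n")


def align_paired(
    mirna: ExpressionMatrix,
    genes: ExpressionMatrix,
    clinical: Optional[ClinicalTable] = None,
) -> PairedDataset:
    """Align two expression matrices on their shared samples.

    Columns are reordered to the sorted intersection of sample ids, which
    makes alignment idempotent and independent of the input column order.
    Clinical records for samples outside the intersection are dropped.
    """
    common = sorted(set(mirna.sample_ids) & set(genes.sample_ids))
    if not common:
        raise ValueError("no samples shared between miRNA and gene matrices")
    n_lost = max(len(mirna.sample_ids), len(genes.sample_ids)) - len(common)
    if n_lost:
        logger.info("alignment dropped up to %d unshared samples", n_lost)
    clin = clinical.subset(common) if clinical is not None else None
    return PairedDataset(mirna.subset_samples(common), genes.subset_samples(common), clin)
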