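"""Synthetic paired-expression fixtures with planted driver miRNAs.

The generator emulates the study conditions the pipeline is built for: a
tumor cohort with paired miRNA and gene expression, a predicted-interaction
table, a disease annotation list, gene-set collections and clinical
follow-up. A configurable subset of "driver" miRNAs is planted with the
three signals the prioritization method exploits:

* elevated mean expression (``driver_expr_shift`` noise-SD units),
* many predicted targets (``driver_target_count`` vs the background count),
* a shared latent factor (loading ``driver_corr``) injected into each
  driver and its target genes, producing genuine |PCC| signal; the loading
  sign is randomized per gene, so only the absolute correlation carries it.

Survival times are exponential with proportional hazards: samples in the
top decile of the first driver's expression have their hazard multiplied
by ``survival_effect``. Censoring is an independent exponential calibrated
to the requested censoring fraction. All randomness flows from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import (
    AnnotationSet,
    ClinicalTable,
    ExpressionMatrix,
    GeneSetCollection,
    InteractionSet,
    PairedDataset,
    write_annotation,
    write_clinical,
    write_expression_matrix,
    write_gmt,
    write_interactions,
)

__all__ = ["SyntheticConfig", "SyntheticBundle", "generate", "write_bundle", "null_config"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters. Defaults are the strong planted-signal cohort:
    a 100-sample tumor set with 200 miRNAs of which 10 are drivers, a
    3-SD expression elevation, 50 vs 5 predicted targets, latent-factor
    loading 0.8, a 3x hazard for driver-high samples and ~30% censoring."""

    n_samples: int = 100
    n_genes: int = 1000
    n_mirnas: int = 200
    n_drivers: int = 10
    driver_expr_shift: float = 3.0
    driver_target_count: int = 50
    background_target_count: int = 5
    driver_corr: float = 0.8
    noise_sd: float = 1.0
    survival_effect: float = 3.0
    censor_rate: float = 0.3
    baseline_hazard: float = 1.0 / 500.0  # per day; mean survival 500 days
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_drivers > self.n_mirnas:
            raise ValueError("n_drivers must not exceed n_mirnas")
        if not 0 <= self.driver_corr < 1:
            raise ValueError("driver_corr must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must be in [0, 1)")
        for name in ("n_samples", "n_genes", "n_mirnas", "n_drivers"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.driver_target_count > self.n_genes or self.background_target_count > self.n_genes:
            raise ValueError("target counts cannot exceed n_genes")


def null_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """Signal-free configuration: drivers are exchangeable with background
    (no expression shift, no correlation, equal target counts)."""
    return SyntheticConfig(
        driver_expr_shift=0.0,
        driver_corr=0.0,
        driver_target_count=5,
        background_target_count=5,
        survival_effect=1.0,
        seed=seed,
        **overrides,
    )


@dataclass
class SyntheticBundle:
    dataset: PairedDataset
    interactions: InteractionSet
    annotation: AnnotationSet
    gene_sets: GeneSetCollection
    truth: list[str]


def generate(config: SyntheticConfig) -> SyntheticBundle:
    """Generate a fully reproducible synthetic cohort from the config."""
    rng = np.random.default_rng(config.seed)
    c = config
    mirna_ids = [f"mir-{i:04d}" for i in range(c.n_mirnas)]
    gene_ids = [f"gene-{i:05d}" for i in range(c.n_genes)]
    sample_ids = [f"sample-{j:04d}" for j in range(c.n_samples)]
    drivers = mirna_ids[: c.n_drivers]

    # interaction table: drivers get many targets, background miRNAs few
    pairs: set[tuple[str, str]] = set()
    driver_targets: dict[str, np.ndarray] = {}
    for i, m in enumerate(mirna_ids):
        k = c.driver_target_count if i < c.n_drivers else c.background_target_count
        targets = rng.choice(c.n_genes, size=k, replace=False)
        if i < c.n_drivers:
            driver_targets[m] = targets
        for g in targets:
            pairs.add((m, gene_ids[g]))

    # expression: per-entity baseline means, iid noise, shared latent factor
    # per driver injected into that driver and its target genes
    # between-entity baseline spread is half the within-sample noise, so a
    # shift in noise-SD units translates into clear between-miRNA signal
    mirna_base = rng.normal(5.0, 0.5, size=c.n_mirnas)
    gene_base = rng.normal(5.0, 0.5, size=c.n_genes)
    mirna_base[: c.n_drivers] += c.driver_expr_shift * c.noise_sd

    M = mirna_base[:, None] + c.noise_sd * rng.normal(size=(c.n_mirnas, c.n_samples))
    G = gene_base[:, None] + c.noise_sd * rng.normal(size=(c.n_genes, c.n_samples))

    rho = c.driver_corr
    mix = np.sqrt(1.0 - rho**2)
    claimed = np.zeros(c.n_genes, dtype=bool)
    for i, m in enumerate(drivers):
        z = rng.normal(size=c.n_samples)
        eps = rng.normal(size=c.n_samples)
        M[i] = mirna_base[i] + c.noise_sd * (rho * z + mix * eps)
        for g in driver_targets[m]:
            if claimed[g]:
                continue  # genes shared between drivers follow the first
            claimed[g] = True
            sign = rng.choice((-1.0, 1.0))
            eps_g = rng.normal(size=c.n_samples)
            G[g] = gene_base[g] + c.noise_sd * (sign * rho * z + mix * eps_g)

    mirna_expr = ExpressionMatrix(pd.DataFrame(M, index=mirna_ids, columns=sample_ids))
    gene_expr = ExpressionMatrix(pd.DataFrame(G, index=gene_ids, columns=sample_ids))

    # survival: hazard multiplied for the top decile of the first driver
    hazard = np.full(c.n_samples, c.baseline_hazard)
    n_high = max(1, int(np.ceil(0.10 * c.n_samples)))
    high = np.argsort(M[0])[::-1][:n_high]
    hazard[high] *= c.survival_effect
    event_t = rng.exponential(1.0 / hazard)
    if c.censor_rate > 0:
        lam_c = c.baseline_hazard * c.censor_rate / (1.0 - c.censor_rate)
        censor_t = rng.exponential(1.0 / lam_c, size=c.n_samples)
    else:
        censor_t = np.full(c.n_samples, np.inf)
    observed = np.minimum(event_t, censor_t)
    event = (event_t <= censor_t).astype(int)
    clinical = ClinicalTable(
        pd.DataFrame({"time": observed, "event": event}, index=sample_ids)
    )

    dataset = PairedDataset(mirna_expr, gene_expr, clinical)
    annotation = AnnotationSet("synthetic-disease", frozenset(drivers))

    # gene sets: one set per driver, its targets padded with random genes,
    # plus an equal number of purely random sets; background = all genes
    sets: dict[str, frozenset[str]] = {}
    pad_size = min(20, max(2, c.n_genes // 5))
    rand_lo = min(max(5, c.n_genes // 33), c.n_genes)
    rand_hi = max(rand_lo + 1, min(c.n_genes, c.n_genes // 12))
    for i, m in enumerate(drivers):
        pad = rng.choice(c.n_genes, size=pad_size, replace=False)
        members = {gene_ids[g] for g in driver_targets[m]} | {gene_ids[g] for g in pad}
        sets[f"driverset-{i:02d}"] = frozenset(members)
    for j in range(c.n_drivers):
        size = int(rng.integers(rand_lo, rand_hi))
        members = rng.choice(c.n_genes, size=size, replace=False)
        sets[f"randomset-{j:02d}"] = frozenset(gene_ids[g] for g in members)
    gene_sets = GeneSetCollection(sets, frozenset(gene_ids))

    return SyntheticBundle(dataset, InteractionSet(frozenset(pairs)), annotation, gene_sets, list(drivers))


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Write every fixture of the bundle in the standard text formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mirna": outdir / "mirna_expression.tsv",
        "genes": outdir / "gene_expression.tsv",
        "interactions": outdir / "interactions.tsv",
        "annotation": outdir / "annotation.tsv",
        "gene_sets": outdir / "gene_sets.gmt",
        "clinical": outdir / "clinical.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_expression_matrix(bundle.dataset.mirna, paths["mirna"])
    write_expression_matrix(bundle.dataset.genes, paths["genes"])
    write_interactions(bundle.interactions, paths["interactions"])
    write_annotation(bundle.annotation, paths["annotation"])
    write_gmt(bundle.gene_sets, paths["gene_sets"])
    write_clinical(bundle.dataset.clinical, paths["clinical"])
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        for m in bundle.truth:
            fh.write(m + "\n")
    return paths
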