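import numpy as np
import pandas as pd
import pytest

from mirank.data_io import (
    ClinicalTable,
    ExpressionMatrix,
    InteractionSet,
    PairedDataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def make_paired(mirna_values, gene_values, mirna_ids=None, gene_ids=None, clinical=None):
    """Build a PairedDataset from plain arrays with generated ids."""
    mirna_values = np.asarray(mirna_values, dtype=float)
    gene_values = np.asarray(gene_values, dtype=float)
    n = mirna_values.shape[1]
    samples = [f"s{j}" for j in range(n)]
    mirna_ids = mirna_ids or [f"mir-{i}" for i in range(mirna_values.shape[0])]
    gene_ids = gene_ids or [f"g{i}" for i in range(gene_values.shape[0])]
    m = ExpressionMatrix(pd.DataFrame(mirna_values, index=mirna_ids, columns=samples))
    g = ExpressionMatrix(pd.DataFrame(gene_values, index=gene_ids, columns=samples))
    return PairedDataset(m, g, clinical)


@pytest.fixture
def small_dataset(rng):
    """15-sample, 50-gene, 6-miRNA random dataset for correlation oracles."""
    return make_paired(rng.normal(5, 2, (6, 15)), rng.normal(3, 1.5, (50, 15)))


@pytest.fixture
def toy_interactions():
    return InteractionSet(
        frozenset({("mir-0", "g0"), ("mir-0", "g1"), ("mir-1", "g1")})
    )


@pytest.fixture
def toy_clinical():
    times = [30, 60, 90, 120, 150, 180, 210, 240, 270, 300]
    events = [1, 1, 0, 1, 1, 0, 1, 1, 1, 0]
    idx = [f"s{j}" for j in range(10)]
    return ClinicalTable(pd.DataFrame({"time": times, "event": events}, index=idx))
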