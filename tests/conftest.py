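import numpy as np
import pytest

from mirlassonet.io import (
    CASE,
    CONTROL,
    Config,
    EdgeList,
    ExpressionMatrix,
    TextRelevanceRecord,
    TextRelevanceTable,
)
from mirlassonet.synth import SynthConfig, generate_all


@pytest.fixture
def small_expr() -> ExpressionMatrix:
    """3 genes x 4 samples, 2 control / 2 case."""
    rng = np.random.default_rng(0)
    return ExpressionMatrix(
        gene_ids=["GA", "GB", "GC"],
        sample_ids=["s1", "s2", "s3", "s4"],
        values=rng.standard_normal((3, 4)),
        group_labels=[CONTROL, CONTROL, CASE, CASE],
    )


@pytest.fixture
def relevance_table() -> TextRelevanceTable:
    return TextRelevanceTable(records=[
        TextRelevanceRecord("D", "G1", 0.5, 12),
        TextRelevanceRecord("D", "G2", 0.0, 50),
        TextRelevanceRecord("D", "G3", 0.9, 10),
        TextRelevanceRecord("E", "G4", 0.4, 30),
    ])


@pytest.fixture
def default_config() -> Config:
    return Config()


@pytest.fixture(scope="session")
def small_synth():
    """A reduced synthetic bundle for fast unit tests (full defaults are
    exercised in the acceptance suite)."""
    cfg = SynthConfig(n_genes=200, n_mirnas=15, n_diseases=3,
                      targets_per_mirna=20, n_samples_per_group=6, seed=5)
    return generate_all(cfg)


@pytest.fixture(scope="session")
def benchmark_runs():
    """Full pipeline on generator defaults over 10 seeds, with and without
    PPI propagation; returns (data, with_indirect, without_indirect) tuples."""
    import warnings
    from mirlassonet.pipeline import run_pipeline

    runs = []
    for seed in range(1, 11):
        data = generate_all(SynthConfig(seed=seed))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with_ind = run_pipeline(data.expression, data.text,
                                    data.direct_targets, data.ppi, data.gold,
                                    use_indirect=True)
            without_ind = run_pipeline(data.expression, data.text,
                                       data.direct_targets, data.ppi, data.gold,
                                       use_indirect=False)
        runs.append((data, with_ind, without_ind))
    return runs


def random_edge_lists(rng, n_genes=50, n_mirnas=4, ppi_p=0.15, target_p=0.2):
    """Random PPI + direct-target instance for oracle comparisons."""
    genes = [f"G{i}" for i in range(n_genes)]
    mirnas = [f"M{j}" for j in range(n_mirnas)]
    ppi_pairs = [
        (genes[i], genes[j])
        for i in range(n_genes)
        for j in range(i + 1, n_genes)
        if rng.random() < ppi_p
    ]
    direct_pairs = [
        (m, g) for m in mirnas for g in genes if rng.random() < target_p
    ]
    return (
        EdgeList.from_pairs(ppi_pairs, directed=False),
        EdgeList.from_pairs(direct_pairs, directed=True),
        genes,
        mirnas,
    )
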