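import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from cosed.io import ReplicatePairMatrix
from cosed.simulate import ExperimentConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_experiment():
    """One modest simulated experiment shared across read-only tests."""
    config = ExperimentConfig(n_proteins=300, seed=7)
    tables, sequences, truth = simulate_experiment(config)
    return config, tables, sequences, truth


def make_matrix(control: dict, sample: dict) -> ReplicatePairMatrix:
    """Build a ReplicatePairMatrix from {gene: [per-pair intensities]} dicts."""
    genes = sorted(control)
    n_pairs = len(next(iter(control.values())))
    pairs = [str(i + 1) for i in range(n_pairs)]
    data = pd.DataFrame(
        0.0,
        index=pd.Index(genes, name="gene"),
        columns=pd.MultiIndex.from_product([pairs, ["control", "sample"]]),
    )
    for gene in genes:
        for j, pair in enumerate(pairs):
            data.loc[gene, (pair, "control")] = control[gene][j]
            data.loc[gene, (pair, "sample")] = sample[gene][j]
    return ReplicatePairMatrix(data)


@pytest.fixture
def tiny_matrix():
    """Three genes x three pairs with known detection patterns."""
    control = {
        "geneA": [100.0, 100.0, 100.0],
        "geneB": [100.0, 100.0, 100.0],
        "geneC": [0.0, 0.0, 0.0],
    }
    sample = {
        "geneA": [200.0, 210.0, 190.0],
        "geneB": [0.0, 150.0, 160.0],
        "geneC": [50.0, 60.0, 0.0],
    }
    return make_matrix(control, sample)
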