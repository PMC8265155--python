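"""Shared fixtures: synthetic cohorts at the sizes the analyses need.

The expensive fixtures (clustered cohorts) are session-scoped so the whole
suite fits one generation + clustering pass per cohort.
"""

import numpy as np
import pytest

import multisep as ms


@pytest.fixture(scope="session")
def bench_data():
    """Default benchmark cohort: 400 lines x 200 genes, 5+5 planted pairs."""
    ds, truth = ms.generate_dataset(seed=3)
    models, failures = ms.cluster_all_genes(ds.expression, seed=3)
    assert not failures
    return ds, truth, models


@pytest.fixture(scope="session")
def null_data():
    """Null cohort (no planted pairs) sized for calibration checks."""
    params = ms.GeneratorParams(
        n_lines=300, n_genes=60, n_crispr_pairs=0, n_mutation_pairs=0
    )
    ds, truth = ms.generate_dataset(params, seed=11)
    models, failures = ms.cluster_all_genes(ds.expression, seed=11)
    assert not failures
    return ds, truth, models


@pytest.fixture(scope="session")
def small_data():
    """Tiny cohort for I/O, CLI and annotation tests."""
    params = ms.GeneratorParams(
        n_lines=80, n_genes=16, n_tissues=3, fixed_tissue_size=20,
        n_crispr_pairs=2, n_mutation_pairs=2, weak_fraction=0.2,
    )
    return ms.generate_dataset(params, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
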