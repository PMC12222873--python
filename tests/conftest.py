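import warnings

import numpy as np
import pytest

from gamhap import (
    SimConfig,
    SliceSpec,
    build_genome_model,
    build_segregation_tables,
    emit_dataset,
)


@pytest.fixture(scope="session")
def default_dataset():
    """Medium simulated dataset at default geometry, shared across tests."""
    cfg = SimConfig(chrom_sizes={"chr1": 10_000_000, "chr2": 8_000_000}, seed=42)
    model = build_genome_model(cfg)
    spec = SliceSpec(slices_per_sample=3)
    table, truth = emit_dataset(model, spec, 200, seed=42, depth=100)
    return model, spec, table, truth


@pytest.fixture(scope="session")
def default_segregation(default_dataset):
    _, _, table, _ = default_dataset
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_segregation_tables(table)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
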