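"""Shared fixtures: seeded RNGs and a session-scoped synthetic experiment."""

import numpy as np
import pytest

from poolscreen.snp_pipeline import prepare_gene_context
from poolscreen.synthetic_data import make_toy_genome


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_genome():
    return make_toy_genome(n_genes=40, mean_gene_length=900, seed=7)


@pytest.fixture(scope="session")
def toy_context(toy_genome):
    return prepare_gene_context(toy_genome.features, toy_genome.sequence)
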