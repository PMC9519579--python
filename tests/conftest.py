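"""Shared fixtures: small seeded simulated studies reused across test modules."""

import numpy as np
import pytest

from content import SimConfig, simulate_study
from content.decompose import center_scale


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A miniature study: 3 genes, 6 contexts, 80 SNPs, pool of 120."""
    return SimConfig(
        n_genes=3, n_contexts=6, n_snps_per_gene=80,
        sample_size_range=(60, 120), h2_shared=0.3, h2_specific=0.1,
        frac_contexts_with_specific=1.0, seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def small_preprocessed(small_study):
    panel, truth, study = small_study
    return panel, truth, center_scale(study).expression


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
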