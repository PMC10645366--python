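"""Shared fixtures: small simulated datasets reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from u1seq.synthetic_data import (
    DEConfig,
    SimConfig,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_dataset():
    """Compact six-strain dataset with planted effects."""
    return simulate_dataset(SimConfig(seed=101, n_genes=120))


@pytest.fixture(scope="session")
def null_dataset():
    """2000-gene dataset with no planted expression effects."""
    cfg = SimConfig(seed=202, n_genes=2000, de=DEConfig(fraction_affected={}))
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def powered_dataset():
    """1000-gene dataset with planted |log2FC| = 2 effects."""
    return simulate_dataset(SimConfig(seed=303, n_genes=1000))


@pytest.fixture(scope="session")
def apa_dataset():
    """Dataset sized for ~100 two-polyA-site genes at >=20x UTR depth."""
    return simulate_dataset(SimConfig(seed=404, n_genes=250))


@pytest.fixture()
def rng():
    return np.random.default_rng(9)
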