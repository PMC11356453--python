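from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from flavotype.synthetic_data import (ExprSimConfig, FamilySimConfig,
                                      make_reference, simulate_expression,
                                      simulate_family)

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50,
                              deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def dfr_anchor():
    return make_reference("DFR")


@pytest.fixture(scope="session")
def fls_anchor():
    return make_reference("FLS")


@pytest.fixture(scope="session")
def small_dfr_family():
    """30 simulated DFR homologs with planted N/D/A residues."""
    cfg = FamilySimConfig(family="DFR", n_sequences=30, seed=7)
    return simulate_family(cfg)


@pytest.fixture(scope="session")
def small_fls_family():
    cfg = FamilySimConfig(
        family="FLS", n_sequences=30, seed=7,
        planted_anchor_residues={"H": 1 / 3, "F": 1 / 3, "Y": 1 / 3})
    return simulate_family(cfg)


@pytest.fixture(scope="session")
def small_expression_sim():
    cfg = ExprSimConfig(n_species=4, samples_per_species=10, rho=0.9, seed=5)
    return simulate_expression(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
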