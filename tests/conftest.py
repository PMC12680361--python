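"""Shared fixtures: small substrates and kinetic setups.

Everything is generated programmatically; sizes are kept small so the
whole suite runs on one CPU in minutes.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from lignosacc import (
    CocktailConfig,
    Composition,
    KineticParams,
    SubstrateConfig,
)


@pytest.fixture
def toy_composition() -> Composition:
    return Composition(
        pct_cellulose=0.5,
        pct_hemicellulose=0.25,
        pct_lignin=0.2,
        pct_acetate=0.02,
        sample_id="toy",
    )


@pytest.fixture
def toy_config(toy_composition) -> SubstrateConfig:
    """Small shielded microfibril: 18 chains x 20 bonds."""
    return SubstrateConfig(
        composition=toy_composition,
        mode_code=3,
        length_fibril=20,
        CF_cellu=0.5,
        CF_hemi=0.4,
        r_ca_cellu=0.5,
        r_ca_hemi=0.5,
        mu_defect=0.3,
        N_defect=0.5,
    )


@pytest.fixture
def free_config(toy_composition) -> SubstrateConfig:
    return SubstrateConfig(
        composition=toy_composition,
        mode_code=3,
        length_fibril=20,
        CF_cellu=0.5,
        CF_hemi=0.4,
        r_ca_cellu=0.5,
        r_ca_hemi=0.5,
        free_floating=True,
    )


@pytest.fixture
def cellulose_only() -> Composition:
    return Composition(pct_cellulose=0.8, sample_id="pure")


@pytest.fixture
def small_cocktail() -> CocktailConfig:
    """Cocktail scaled to the small test substrates (enzyme:substrate
    ratio of the full-size system)."""
    return CocktailConfig(total_enz_molecules=12)


@pytest.fixture
def default_params() -> KineticParams:
    return KineticParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
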