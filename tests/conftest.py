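"""Shared fixtures: a small synthetic reference and study for fast tests."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from amplipair import assign, synth

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=100,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_spec() -> synth.ReferenceSpec:
    """Short-gene reference spec: 5 genera x 2 species, 300 bp genes."""
    return synth.ReferenceSpec(
        n_genera=5,
        species_per_genus=2,
        gene_length=300,
        subregion=(60, 180),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_reference(small_spec):
    return synth.generate_reference(small_spec)


@pytest.fixture(scope="session")
def small_db(small_reference) -> assign.ReferenceDB:
    records, lineages = small_reference
    return assign.ReferenceDB(records, lineages)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240316)
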