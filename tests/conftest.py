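"""Shared fixtures: small synthetic datasets reused across test modules."""

import numpy as np
import pytest

from evoconverge.simulate import (
    SimulationDesign,
    generate_dataset,
    generate_reference,
)


@pytest.fixture(scope="session")
def small_design():
    return SimulationDesign(n_genes=120, master_seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_design):
    """(reference, mutations, truth, coverage, growth) for a 120-gene design."""
    return generate_dataset(small_design)


@pytest.fixture(scope="session")
def small_reference(small_dataset):
    return small_dataset[0]


@pytest.fixture(scope="session")
def null_design():
    """Pure-null study conditions: no planted structure of any kind."""
    return SimulationDesign(
        n_genes=120,
        master_seed=7,
        n_convergent=0,
        n_hotspot=0,
        n_ancestral=0,
        n_het_loci=0,
        n_ref_discrepancies=0,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def calibration_reference():
    """A full-size (2000-gene) reference shared by the calibration studies."""
    design = SimulationDesign(
        n_genes=2000,
        master_seed=11,
        n_convergent=0,
        n_hotspot=0,
        n_ancestral=0,
        n_het_loci=0,
        n_ref_discrepancies=0,
    )
    return design, generate_reference(design)
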