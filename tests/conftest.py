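import numpy as np
import pytest

from tcspred.synthetic_fixtures import (
    SimulationSpec,
    simulate_feature_table,
    write_fixture,
)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """A complete synthetic fixture directory shared across tests."""
    d = tmp_path_factory.mktemp("fixture")
    write_fixture(d, SimulationSpec(seed=11, coupling=0.8, n_genomes=6,
                                    n_background_proteins=8,
                                    protein_length=80,
                                    n_species=26, msa_length=80),
                  n_pos=3, n_neg=5)
    return d


@pytest.fixture(scope="session")
def separable_table():
    """Feature table that is separable by construction (5-sigma shift)."""
    return simulate_feature_table(
        SimulationSpec(seed=1, n_pairs=200, class_separation=5.0, imbalance=0.25))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
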