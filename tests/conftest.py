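import numpy as np
import pytest

from molsde.mol_data import FixtureSpec, MoleculeBatch, make_fixtures
from molsde.nets import NetworkConfig, ScoreModel
from molsde.sde import DiffusionSpec


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def spec():
    return DiffusionSpec()


@pytest.fixture(scope="session")
def fixture_molecules():
    return make_fixtures(FixtureSpec(count_per_template=10, jitter_std=0.02, seed=7))


@pytest.fixture(scope="session")
def fixture_batch(fixture_molecules):
    return MoleculeBatch.from_molecules(fixture_molecules)


@pytest.fixture(scope="session")
def tiny_config():
    return NetworkConfig(l_h=1, l_r=1, l_a=1, k_power=2, heads=2, hidden=16)


@pytest.fixture(scope="session")
def small_model(spec):
    cfg = NetworkConfig(l_h=2, l_r=2, l_a=2, k_power=2, heads=2, hidden=32)
    return ScoreModel(cfg, k=5, spec=spec, seed=0)
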