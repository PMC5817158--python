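import numpy as np
import pytest

from macroniche.compositional import PCL, Composition, CompositionSet, closure
from macroniche.simulate import preset, simulate_study


@pytest.fixture
def barycentre() -> Composition:
    return closure((1, 1, 1))


@pytest.fixture
def two_point_set() -> CompositionSet:
    return CompositionSet.from_compositions(
        [closure((0.5, 0.3, 0.2)), closure((0.2, 0.3, 0.5))]
    )


@pytest.fixture
def random_set() -> CompositionSet:
    rng = np.random.default_rng(2024)
    raw = rng.dirichlet(np.ones(3) * 2.0, size=25)
    return CompositionSet(PCL, raw)


@pytest.fixture(scope="session")
def noisy_study():
    """A default-scenario synthetic scat study with moderate Dirichlet noise."""
    return simulate_study(preset("natural-vs-anthropogenic", seed=11))


@pytest.fixture(scope="session")
def noisefree_study():
    cfg = preset("natural-vs-anthropogenic", seed=7, n_populations=8)
    cfg.dirichlet_concentration = np.inf
    return simulate_study(cfg)
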