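import numpy as np
import pytest

from gramconf.fixtures import (FixtureSpec, generate_point_clouds,
                               generate_toy_molecules, worked_examples)


@pytest.fixture(scope="session")
def point_clouds():
    """50 random point clouds, 4-12 atoms, reproducible."""
    return generate_point_clouds(
        FixtureSpec(kind="point_cloud", n_molecules=50, min_atoms=4,
                    max_atoms=12, seed=11))


@pytest.fixture(scope="session")
def toy_molecules():
    """20 idealized-geometry tree molecules with explicit hydrogens."""
    return generate_toy_molecules(
        FixtureSpec(n_molecules=20, min_atoms=3, max_atoms=9, seed=7))


@pytest.fixture(scope="session")
def examples():
    return worked_examples()


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
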