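import numpy as np
import pytest

import trajscope as ts


@pytest.fixture(scope="session")
def helix10():
    return ts.make_toy_protein(10, "helix")


@pytest.fixture(scope="session")
def helix10_ca(helix10):
    return ts.select_atoms(helix10, "name CA")


@pytest.fixture(scope="session")
def helix60():
    return ts.make_toy_protein(60, "helix")


@pytest.fixture(scope="session")
def helix60_ca(helix60):
    return ts.select_atoms(helix60, "name CA")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_trajectory(structure, frames):
    return ts.Trajectory(topology=structure, frames=np.asarray(frames, float))


@pytest.fixture(scope="session")
def correlated_ensemble(helix60):
    """Gaussian ensemble with a planted 0.8 block between residues 1-5 and 6-10."""
    spec = ts.EnsembleSpec(
        reference=helix60, sigma=0.5,
        correlation_blocks=[([1, 2, 3, 4, 5], [6, 7, 8, 9, 10], 0.8)],
        n_frames=5000, seed=31)
    return ts.make_gaussian_ensemble(spec)
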