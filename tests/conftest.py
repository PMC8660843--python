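import numpy as np
import pytest

import lhcquench as lq


@pytest.fixture(scope="session")
def two_basin():
    """Planted 2-basin ensemble (500 frames) with its truth labels."""
    spec = lq.make_basin_spec(n_clusters=2, n_frames=500, n_residues=20, seed=11)
    return lq.generate_ensemble(spec)


@pytest.fixture(scope="session")
def two_basin_features(two_basin):
    ensemble, _ = two_basin
    quads = lq.standard_dihedral_quadruples(ensemble)
    return lq.compute_dihedrals(ensemble, quads)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
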