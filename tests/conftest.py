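import logging

import numpy as np
import pytest

import gmmrefine as g

logging.getLogger("gmmrefine").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def helix():
    return g.make_peptide(12, kind="helix")


@pytest.fixture(scope="session")
def helix_topo(helix):
    return g.compile_topology(helix)


@pytest.fixture(scope="session")
def helix_h(helix):
    return g.add_hydrogens(helix)


@pytest.fixture(scope="session")
def rna5():
    return g.make_rna(5)


@pytest.fixture(scope="session")
def rna5_topo(rna5):
    return g.compile_topology(rna5)


@pytest.fixture(scope="session")
def suite_library():
    return g.SuiteLibrary.default()


@pytest.fixture(scope="session")
def rama_fit_full():
    """Full-size boundary-penalized fit of the default 5-peak histogram."""
    hist = g.make_rama_histogram(step=4.0)
    gmm = g.fit_rama_gmm(hist, n_components=2500, seed=1)
    return hist, gmm


@pytest.fixture(scope="session")
def rama_gmm_small():
    """Moderate-size fitted Ramachandran surface shared across tests."""
    hist = g.make_rama_histogram(step=4.0)
    return hist, g.fit_rama_gmm(hist, n_components=600, n_rounds=2,
                                seed=1, rmsd_tol=0.05)


@pytest.fixture(scope="session")
def leu_rotamer_gmm():
    hist = g.make_rotamer_histogram("LEU", 2)
    return hist, g.fit_rotamer_gmm(hist, "LEU", n_components=10, n_iter=80)


def rigid_transform(coords, seed=0):
    rng = np.random.default_rng(seed)
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
    t = rng.normal(scale=5.0, size=3)
    return coords @ R.T + t
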