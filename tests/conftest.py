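import numpy as np
import pytest

import cagescreen as cs


@pytest.fixture(scope="session")
def blocks():
    """Built-in 6 coordinating + 4 core block library, as a label map."""
    coords, cores = cs.default_blocks()
    return {b.label: b for b in [*coords, *cores]}


@pytest.fixture(scope="session")
def block_lists():
    return cs.default_blocks()


@pytest.fixture(scope="session")
def ligand_5b4(blocks):
    """One embedded ligand, shared across tests (embedding is the slow step)."""
    return cs.build_ligand_structure(cs.LigandSpec.from_id("5B4"), blocks, seed=42)


@pytest.fixture
def ideal():
    return cs.ideal_cage()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_rigid_motion(rng):
    """A uniformly random proper rotation + translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    return rot, rng.uniform(-20, 20, size=3)


def transform_cage(cage, rot, trans):
    moved = cage.copy()
    moved.coords = cage.coords @ rot.T + trans
    return moved


def tls_plane_oracle(points):
    """Independent total-least-squares plane fit via the covariance
    eigenproblem (not the SVD route the implementation uses).

    Returns (normal, centroid, rss of perpendicular distances).
    """
    pts = np.asarray(points, float)
    c = pts.mean(axis=0)
    cov = (pts - c).T @ (pts - c)
    w, v = np.linalg.eigh(cov)
    normal = v[:, 0]
    d = (pts - c) @ normal
    return normal, c, float(np.sum(d**2))
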