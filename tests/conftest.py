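import numpy as np
import pytest

from absaxs import (make_toy_antibody, make_conformer, debye_profile,
                    default_q_grid)
from absaxs.structure import StructureModel


@pytest.fixture(scope="session")
def q_grid():
    return default_q_grid()


@pytest.fixture(scope="session")
def closed_model():
    return make_toy_antibody()


@pytest.fixture(scope="session")
def open_model(closed_model):
    return make_conformer(closed_model, "open", seed=1)


@pytest.fixture(scope="session")
def extended_model(closed_model):
    return make_conformer(closed_model, "extended", seed=1)


@pytest.fixture(scope="session")
def closed_profile(closed_model, q_grid):
    return debye_profile(closed_model, q_grid)


@pytest.fixture(scope="session")
def open_profile(open_model, q_grid):
    return debye_profile(open_model, q_grid)


def make_sphere_model(radius=50.0, spacing=5.0):
    """Cubic-lattice bead filling of a solid sphere (analytic oracle body).

    A lattice (rather than random) filling keeps the coarse-grained density
    uniform, so the Debye profile tracks the continuous sphere form factor
    up to the lattice's own diffraction scale (q ~ 2 pi / spacing, far above
    the window tested).
    """
    ax = np.arange(-radius, radius + spacing, spacing)
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    pts = pts[np.sum(pts ** 2, axis=1) <= radius ** 2]
    n = pts.shape[0]
    return StructureModel(pts, np.ones(n), np.full(n, "protein", dtype=object),
                          np.full(n, "A", dtype=object), np.arange(1, n + 1),
                          np.full(n, "body", dtype=object))


def make_random_sphere_model(n=400, radius=30.0, seed=3):
    """Random bead filling (for paths that only need some 3-D body)."""
    rng = np.random.default_rng(seed)
    pts = np.empty((0, 3))
    while pts.shape[0] < n:
        cand = rng.uniform(-1, 1, size=(2 * n, 3))
        pts = np.vstack([pts, cand[np.sum(cand ** 2, axis=1) <= 1.0]])
    pts = pts[:n] * radius
    return StructureModel(pts, np.ones(n), np.full(n, "protein", dtype=object),
                          np.full(n, "A", dtype=object), np.arange(1, n + 1),
                          np.full(n, "body", dtype=object))


@pytest.fixture(scope="session")
def sphere_model():
    return make_sphere_model()


@pytest.fixture(scope="session")
def sphere_profile(sphere_model, q_grid):
    return debye_profile(sphere_model, q_grid)
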