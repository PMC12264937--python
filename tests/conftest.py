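import numpy as np
import pytest

from caml import (
    PointCloud,
    make_c60,
    make_complex_from_facets,
    rips_filtration,
)


@pytest.fixture(scope="session")
def c60_cloud():
    return make_c60()


@pytest.fixture(scope="session")
def c60_filtration(c60_cloud):
    return rips_filtration(c60_cloud, max_dim=3, cap=3.0)


@pytest.fixture
def hollow_triangle():
    return make_complex_from_facets([(1, 2), (2, 3), (1, 3)])


@pytest.fixture
def equilateral_cloud():
    # permutation-symmetric coordinates: all pairwise distances are the
    # *identical* float sqrt(2), so diameter ties are exact
    return PointCloud(np.eye(3), ["C", "C", "C"])


def random_complex(rng: np.random.Generator, n_vertices: int):
    """Random small complex from a handful of random candidate facets."""
    n_facets = int(rng.integers(1, 5))
    facets = []
    for _ in range(n_facets):
        size = int(rng.integers(1, min(n_vertices, 4) + 1))
        facets.append(tuple(rng.choice(n_vertices, size=size, replace=False)))
    return make_complex_from_facets(facets, vertices=range(n_vertices))


def random_rips(rng: np.random.Generator, n_points: int, max_dim: int = 3):
    """Random point cloud in a unit-ish box with a mid-scale cap."""
    pts = PointCloud(rng.random((n_points, 3)) * 2.0, ["C"] * n_points)
    cap = float(rng.uniform(0.8, 2.5))
    return rips_filtration(pts, max_dim=max_dim, cap=cap)
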