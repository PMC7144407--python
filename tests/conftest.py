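import numpy as np
import pytest

from regnets import (
    ProjectionGeometry,
    build_operator,
    get_filter,
    svd_decompose,
)


def random_system(rng, m, d, rank=None):
    """A random system with controllable numerical rank."""
    a = rng.standard_normal((m, d))
    if rank is not None and rank < min(m, d):
        import scipy.linalg

        v, s, ut = scipy.linalg.svd(a, full_matrices=False)
        s[rank:] = 0.0
        a = (v * s) @ ut
    return svd_decompose(a)


def diagonal_system(diag):
    """System for a (padded) diagonal matrix; singular vectors are canonical."""
    diag = np.asarray(diag, dtype=float)
    return svd_decompose(np.diag(diag))


@pytest.fixture(scope="session")
def tsvd():
    return get_filter("tsvd")


@pytest.fixture(scope="session")
def tikhonov():
    return get_filter("tikhonov")


@pytest.fixture(scope="session")
def small_geometry():
    """A 16x16 tomography geometry small enough for per-test SVDs."""
    return ProjectionGeometry(
        grid_n=16, n_angles=8, n_offsets=24, kb_shape=7.0, kb_support=0.4
    )


@pytest.fixture(scope="session")
def small_system(small_geometry):
    return svd_decompose(build_operator(small_geometry))
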