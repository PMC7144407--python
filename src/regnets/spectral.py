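"""Finite-dimensional spectral machinery for linear inverse problems.

Everything here is phrased through the singular system of a real m x d
matrix A = sum_n sigma_n v_n u_n^T: spectral functions f(A*A), filter-based
regularized inverses B_alpha = g_alpha(A*A) A*, fractional powers
(A*A)^mu omega (source elements), and the orthogonal projector onto the
numerical kernel of A.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import scipy.linalg
import scipy.sparse as sparse

from .filters import FilterSpec

__all__ = [
    "SpectralSystem",
    "svd_decompose",
    "singular_values",
    "apply_spectral_function",
    "apply_regularizer",
    "source_element",
    "kernel_projector",
]


@dataclass
class SpectralSystem:
    """A matrix together with its full singular system.

    ``matrix`` is the m x d forward operator (dense or scipy sparse);
    ``domain_basis`` holds the right singular vectors u_n (d x k columns),
    ``range_basis`` the left singular vectors v_n (m x k columns), and
    ``singular_values`` the non-increasing sigma_n, so that
    A u_n = sigma_n v_n.  Singular values at or below
    ``rank_tol * sigma_1`` are treated as numerically zero (part of the
    kernel), together with the orthogonal complement of all retained u_n
    when d > k.
    """

    matrix: object
    singular_values: np.ndarray
    domain_basis: np.ndarray
    range_basis: np.ndarray
    rank_tol: float = 1e-10

    @property
    def m(self) -> int:
        return self.matrix.shape[0]

    @property
    def d(self) -> int:
        return self.matrix.shape[1]

    @property
    def sigma1(self) -> float:
        return float(self.singular_values[0]) if self.singular_values.size else 0.0

    @property
    def kernel_threshold(self) -> float:
        return self.rank_tol * self.sigma1

    @property
    def positive_mask(self) -> np.ndarray:
        """Mask of singular triplets above the numerical-kernel threshold."""
        return self.singular_values > self.kernel_threshold

    @property
    def rank(self) -> int:
        return int(self.positive_mask.sum())

    def matvec(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(self.matrix @ x)

    def rmatvec(self, y: np.ndarray) -> np.ndarray:
        return np.asarray(self.matrix.T @ y)

    def pinv_apply(self, y: np.ndarray) -> np.ndarray:
        """Minimum-norm least-squares solution A^+ y via the singular system."""
        pos = self.positive_mask
        u = self.domain_basis[:, pos]
        v = self.range_basis[:, pos]
        s = self.singular_values[pos]
        return u @ ((v.T @ y) / s)


def svd_decompose(matrix, rank_tol: float = 1e-10) -> SpectralSystem:
    """Compute the full singular system of a dense or sparse matrix.

    The decomposition always retains min(m, d) triplets, including
    numerically-zero singular values; those at or below ``rank_tol * sigma_1``
    are flagged as kernel directions by the returned system.
    """
    if not 0 < rank_tol < 1:
        raise ValueError("rank_tol must lie in (0, 1)")
    dense = matrix.toarray() if sparse.issparse(matrix) else np.asarray(matrix, float)
    if not np.all(np.isfinite(dense)):
        bad = np.argwhere(~np.isfinite(dense))[0]
        raise ValueError(f"matrix has a non-finite entry at index {tuple(bad)}")
    v, s, ut = scipy.linalg.svd(dense, full_matrices=False)
    return SpectralSystem(
        matrix=matrix,
        singular_values=s,
        domain_basis=ut.T,
        range_basis=v,
        rank_tol=rank_tol,
    )


def singular_values(matrix) -> np.ndarray:
    """All singular values of a (possibly sparse) matrix, non-increasing.

    Goes through the eigenvalues of the smaller Gram matrix, which is far
    cheaper than a full SVD when only the spectrum is needed (e.g. for
    counting retained TSVD components of a large sparse projector).
    """
    m, d = matrix.shape
    if m <= d:
        gram = matrix @ matrix.T
    else:
        gram = matrix.T @ matrix
    gram = gram.toarray() if sparse.issparse(gram) else np.asarray(gram, float)
    ev = scipy.linalg.eigvalsh(gram)
    return np.sqrt(np.maximum(ev, 0.0))[::-1]


def _check_domain(system: SpectralSystem, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape != (system.d,):
        raise ValueError(f"expected domain vector of dimension {system.d}, got {x.shape}")
    return x


def apply_spectral_function(
    system: SpectralSystem, f: Callable[[np.ndarray], np.ndarray], x: np.ndarray
) -> np.ndarray:
    """Apply f(A*A) to a domain vector through the singular system.

    Returns sum_n f(sigma_n^2) <u_n, x> u_n plus f(0) times the component of
    x orthogonal to all retained u_n (the part of the kernel not spanned by
    stored triplets).
    """
    x = _check_domain(system, x)
    lam = system.singular_values**2
    vals = np.asarray(f(lam), dtype=float)
    if vals.shape != lam.shape:  # scalar (non-vectorized) callable
        vals = np.array([float(f(l)) for l in lam])
    if not np.all(np.isfinite(vals)):
        bad = lam[~np.isfinite(vals)][0]
        raise ValueError(f"spectral function is non-finite at eigenvalue {bad!r}")
    f0 = float(f(0.0))
    if not np.isfinite(f0):
        raise ValueError("spectral function is non-finite at eigenvalue 0.0")
    u = system.domain_basis
    coeff = u.T @ x
    return u @ (vals * coeff) + f0 * (x - u @ coeff)


def apply_regularizer(
    system: SpectralSystem, filter_spec: FilterSpec, alpha: float, y: np.ndarray
) -> np.ndarray:
    """Regularized inverse B_alpha y = g_alpha(A*A) A* y.

    Spectrally: sum_n g_alpha(sigma_n^2) sigma_n <y, v_n> u_n.  For the TSVD
    filter this is exactly sum_{sigma_n^2 >= alpha} <y, v_n>/sigma_n u_n.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    y = np.asarray(y, dtype=float)
    if y.shape != (system.m,):
        raise ValueError(f"expected data vector of dimension {system.m}, got {y.shape}")
    s = system.singular_values
    g = np.asarray(filter_spec(s**2, alpha), dtype=float)
    coeff = g * s * (system.range_basis.T @ y)
    return system.domain_basis @ coeff


def source_element(system: SpectralSystem, mu: float, omega: np.ndarray) -> np.ndarray:
    """The source element (A*A)^mu omega.

    For mu = 0 this is omega itself (the kernel component is preserved);
    for mu > 0 the kernel component is annihilated.
    """
    if mu < 0:
        raise ValueError("mu must be non-negative")
    omega = _check_domain(system, omega)
    if mu == 0:
        return omega.copy()
    u = system.domain_basis
    s2mu = system.singular_values ** (2.0 * mu)
    return u @ (s2mu * (u.T @ omega))


def kernel_projector(system: SpectralSystem, x: np.ndarray) -> np.ndarray:
    """Orthogonal projection of x onto the numerical kernel of A.

    The numerical kernel is spanned by domain-basis vectors with
    sigma_n <= rank_tol * sigma_1 together with the orthogonal complement of
    all retained u_n (nontrivial when d > min(m, d)).
    """
    x = _check_domain(system, x)
    pos = system.positive_mask
    u = system.domain_basis[:, pos]
    return x - u @ (u.T @ x)
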