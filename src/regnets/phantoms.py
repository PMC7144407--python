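"""Seeded Shepp-Logan-style phantoms, sinogram simulation and dataset assembly.

Phantoms are random superpositions of constant-intensity ellipses: one
enclosing high-intensity "skull" ellipse plus a handful of interior ellipses
of mixed sign, evaluated at the blob-grid centers so that the coefficient
vector doubles as an N x N image.  Data are simulated as y = A c + delta*xi
with xi_j i.i.d. Gaussian of standard deviation ||A c||_inf, so delta is a
relative noise level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from ._utils import derive_seed, image_to_vec, vec_to_image
from .filters import FilterSpec
from .radon import ProjectionGeometry
from .spectral import SpectralSystem, apply_regularizer

__all__ = [
    "Ellipse",
    "Phantom",
    "Sinogram",
    "Dataset",
    "generate_phantom",
    "simulate_data",
    "make_dataset",
]


@dataclass(frozen=True)
class Ellipse:
    center: Tuple[float, float]
    semi_axes: Tuple[float, float]
    rotation: float
    intensity: float

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        dx, dy = x - self.center[0], y - self.center[1]
        xr = c * dx + s * dy
        yr = -s * dx + c * dy
        return (xr / self.semi_axes[0]) ** 2 + (yr / self.semi_axes[1]) ** 2 <= 1.0


@dataclass
class Phantom:
    """An ellipse phantom and its coefficient image on the blob grid."""

    ellipses: List[Ellipse]
    coefficients: np.ndarray
    seed: int

    @property
    def vector(self) -> np.ndarray:
        return image_to_vec(self.coefficients)


@dataclass
class Sinogram:
    """Simulated data vector with its noise metadata (angle-major layout)."""

    data: np.ndarray
    noise_level: float
    noise_seed: int
    clean_reference: Optional[np.ndarray] = None
    n_angles: Optional[int] = None
    n_offsets: Optional[int] = None

    def as_image(self) -> np.ndarray:
        if self.n_angles is None or self.n_offsets is None:
            raise ValueError("sinogram carries no geometry metadata")
        return self.data.reshape(self.n_angles, self.n_offsets)


def _random_ellipses(rng: np.random.Generator, n_ellipses: int) -> List[Ellipse]:
    ellipses = []
    # enclosing "skull" ring at fixed high intensity
    skull_axes = tuple(rng.uniform(0.55, 0.72, size=2))
    ellipses.append(
        Ellipse(
            center=tuple(rng.uniform(-0.05, 0.05, size=2)),
            semi_axes=skull_axes,
            rotation=float(rng.uniform(0, np.pi)),
            intensity=1.0,
        )
    )
    for _ in range(n_ellipses - 1):
        r = 0.75 * np.sqrt(rng.uniform())
        phi = rng.uniform(0, 2 * np.pi)
        center = (r * np.cos(phi), r * np.sin(phi))
        max_axis = min(0.6, 0.98 - float(np.hypot(*center)))
        lo = min(0.05, max_axis / 2)
        axes = tuple(rng.uniform(lo, max(max_axis, lo + 1e-3), size=2))
        intensity = float(rng.uniform(0.1, 1.0) * rng.choice([-1.0, 1.0]))
        ellipses.append(
            Ellipse(center, axes, float(rng.uniform(0, np.pi)), intensity)
        )
    return ellipses


def generate_phantom(
    seed: int,
    geometry: ProjectionGeometry,
    complexity: Tuple[int, int] = (5, 12),
) -> Phantom:
    """Generate a random Shepp-Logan-style phantom, deterministic per seed.

    ``complexity`` bounds the total ellipse count (inclusive).  Coefficients
    are the ellipse-sum evaluated at the grid centers.
    """
    if seed < 0:
        raise ValueError("seed must be non-negative")
    rng = np.random.default_rng(seed)
    lo, hi = complexity
    n_ellipses = int(rng.integers(lo, hi + 1))
    ellipses = _random_ellipses(rng, n_ellipses)
    centers = geometry.grid_centers()
    x, y = centers[:, 0], centers[:, 1]
    coeff = np.zeros(geometry.n_coeff)
    for e in ellipses:
        coeff += e.intensity * e.contains(x, y)
    return Phantom(ellipses, vec_to_image(coeff, geometry.grid_n), seed)


def simulate_data(
    system: SpectralSystem,
    phantom: Phantom,
    delta: float = 0.0,
    noise_seed: int = 0,
    geometry: Optional[ProjectionGeometry] = None,
) -> Sinogram:
    """Simulate y = A c + delta * xi, with xi_j ~ ||A c||_inf * N(0, 1)."""
    c = phantom.vector
    if c.shape != (system.d,):
        raise ValueError(
            f"phantom has {c.size} coefficients, operator expects {system.d}"
        )
    clean = system.matvec(c)
    if delta > 0:
        scale = float(np.max(np.abs(clean)))
        xi = np.random.default_rng(noise_seed).standard_normal(system.m) * scale
        data = clean + delta * xi
    else:
        data = clean.copy()
    return Sinogram(
        data=data,
        noise_level=float(delta),
        noise_seed=int(noise_seed),
        clean_reference=clean,
        n_angles=geometry.n_angles if geometry else None,
        n_offsets=geometry.n_offsets if geometry else None,
    )


@dataclass
class Dataset:
    """Index-aligned pairs (B_alpha y^(k) as image, ground-truth c^(k) as image)."""

    inputs: np.ndarray  # (n, grid_n, grid_n)
    targets: np.ndarray  # (n, grid_n, grid_n)
    alpha: float
    seed: int
    delta: float
    phantom_seeds: np.ndarray = field(default=None)

    def __len__(self) -> int:
        return self.inputs.shape[0]


def make_dataset(
    system: SpectralSystem,
    filter_spec: FilterSpec,
    alpha: float,
    n_samples: int,
    seed: int,
    delta_train: float = 0.0,
    *,
    geometry: ProjectionGeometry,
    complexity: Tuple[int, int] = (5, 12),
) -> Dataset:
    """Assemble a paired training/evaluation set of regularized reconstructions.

    Each input is B_alpha y^(k) reshaped to the image grid, each target the
    phantom coefficients c^(k).  Noise-free data (delta_train = 0) is the
    default training condition; per-sample phantom and noise seeds are
    derived from the master seed by counters.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    n = geometry.grid_n
    inputs = np.empty((n_samples, n, n))
    targets = np.empty((n_samples, n, n))
    phantom_seeds = np.empty(n_samples, dtype=np.int64)
    for k in range(n_samples):
        pseed = derive_seed(seed, 0, k)
        nseed = derive_seed(seed, 1, k)
        phantom = generate_phantom(pseed, geometry, complexity)
        sino = simulate_data(system, phantom, delta_train, nseed, geometry)
        b = apply_regularizer(system, filter_spec, alpha, sino.data)
        inputs[k] = vec_to_image(b, n)
        targets[k] = phantom.coefficients
        phantom_seeds[k] = pseed
    return Dataset(inputs, targets, float(alpha), int(seed), float(delta_train), phantom_seeds)
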