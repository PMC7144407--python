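"""Regularizing spectral filters and empirical qualification estimation.

A regularizing filter is a family g_alpha : [0, ||A*A||] -> R with
(i) sup over alpha and lambda of |lambda * g_alpha(lambda)| finite, and
(ii) g_alpha(lambda) -> 1/lambda pointwise for lambda > 0 as alpha -> 0.
It induces the regularized inverse B_alpha = g_alpha(A*A) A*.

The *qualification* mu0 of a filter is the largest smoothness order mu such
that sup_lambda lambda^mu |1 - lambda g_alpha(lambda)| <= C alpha^mu holds
uniformly in alpha for all mu <= mu0.  Tikhonov has mu0 = 1; truncated SVD
has infinite qualification.  `estimate_qualification` certifies these orders
numerically from the filter values alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict

import numpy as np

__all__ = [
    "FilterSpec",
    "tikhonov_filter",
    "tsvd_filter",
    "get_filter",
    "QualificationReport",
    "estimate_qualification",
]


def tikhonov_filter(lam, alpha: float):
    """Tikhonov filter g_alpha(lambda) = 1 / (lambda + alpha)."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    lam = np.asarray(lam, dtype=float)
    out = 1.0 / (lam + alpha)
    return out if out.ndim else float(out)


def tsvd_filter(lam, alpha: float):
    """Truncated-SVD filter: 0 for lambda < alpha, 1/lambda for lambda >= alpha.

    The cutoff is inclusive (lambda >= alpha is retained).
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    lam = np.asarray(lam, dtype=float)
    with np.errstate(divide="ignore"):
        out = np.where(lam >= alpha, 1.0 / np.where(lam > 0, lam, 1.0), 0.0)
    # lam == 0 only retained if alpha <= 0, which is excluded; keep exact zeros
    out = np.where(lam == 0.0, 0.0, out)
    return out if out.ndim else float(out)


@dataclass
class FilterSpec:
    """A named regularizing filter with its declared qualification.

    Parameters
    ----------
    name:
        Identifier, e.g. ``"tikhonov"`` or ``"tsvd"``.
    g:
        Vectorized map ``(lambda, alpha) -> g_alpha(lambda)``.
    declared_qualification:
        The analytically known qualification order (``np.inf`` for TSVD).
    stability_bound:
        Known uniform bound on ``sup |lambda * g_alpha(lambda)|``.
    """

    name: str
    g: Callable[..., np.ndarray]
    declared_qualification: float
    stability_bound: float = 1.0

    def __call__(self, lam, alpha: float):
        return self.g(lam, alpha)


_FILTERS: Dict[str, FilterSpec] = {
    "tikhonov": FilterSpec("tikhonov", tikhonov_filter, 1.0, 1.0),
    "tsvd": FilterSpec("tsvd", tsvd_filter, np.inf, 1.0),
}


def get_filter(name: str) -> FilterSpec:
    """Look up a built-in filter by name ("tikhonov" | "tsvd")."""
    try:
        return _FILTERS[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown filter {name!r}; available: {sorted(_FILTERS)}"
        ) from None


def _lambda_grid(lam_max: float, n: int = 2048) -> np.ndarray:
    # the supremum of lambda^mu * alpha/(lambda+alpha) migrates toward 0 with
    # alpha, so the grid is logarithmic down to 1e-12 * lam_max, plus 0 itself
    grid = np.geomspace(1e-12 * lam_max, lam_max, n)
    return np.concatenate([[0.0], grid])


@dataclass
class QualificationReport:
    """Outcome of the empirical qualification scan."""

    qualification: float
    capped: bool
    mu_grid: np.ndarray
    ratios: Dict[float, np.ndarray] = field(repr=False)
    slopes: Dict[float, float] = field(default_factory=dict)
    bounded: Dict[float, bool] = field(default_factory=dict)


def estimate_qualification(
    filter_spec: FilterSpec,
    mu_grid,
    alpha_grid,
    lam_max: float,
    *,
    bounded_factor: float = 3.0,
    divergence_slope: float = -0.1,
    n_lambda: int = 2048,
) -> QualificationReport:
    """Estimate the qualification order of a filter on a (mu, alpha) grid.

    For each mu the scan computes

        r(mu, alpha) = sup_lambda lambda^mu |1 - lambda g_alpha(lambda)| / alpha^mu

    over a dense lambda grid in [0, lam_max].  A mu is declared *bounded* when
    r varies by less than ``bounded_factor`` across the alpha grid, and
    *divergent* when the log-log slope of r versus alpha is below
    ``divergence_slope``.  The estimate is the largest bounded mu; it is
    ``capped`` when every tested mu is bounded (infinite qualification cannot
    be distinguished from "bounded up to the grid maximum").
    """
    mu_grid = np.sort(np.asarray(mu_grid, dtype=float))
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    if mu_grid.size == 0 or alpha_grid.size == 0:
        raise ValueError("mu_grid and alpha_grid must be non-empty")
    if np.any(mu_grid <= 0):
        raise ValueError("qualification orders mu must be positive")
    alpha_grid = np.sort(alpha_grid)[::-1]  # decreasing
    span = alpha_grid[0] / alpha_grid[-1]
    if span < 1e5:
        raise ValueError("alpha_grid must span at least 5 decades")

    lam = _lambda_grid(lam_max, n_lambda)
    # Def 2(i) stability check on the same grids
    sup_stab = 0.0
    residuals = np.empty((alpha_grid.size, lam.size))
    for i, alpha in enumerate(alpha_grid):
        g = np.asarray(filter_spec(lam, alpha), dtype=float)
        if not np.all(np.isfinite(g)):
            raise ValueError(f"filter {filter_spec.name} non-finite at alpha={alpha}")
        sup_stab = max(sup_stab, float(np.max(np.abs(lam * g))))
        res = np.abs(1.0 - lam * g)
        res[res < 100 * np.finfo(float).eps] = 0.0  # rounding noise in lam * (1/lam)
        residuals[i] = res
    if sup_stab > 10.0 * max(filter_spec.stability_bound, 1.0):
        raise ValueError(
            f"filter {filter_spec.name} violates the uniform stability bound: "
            f"sup |lambda g| = {sup_stab:.3g}"
        )

    ratios: Dict[float, np.ndarray] = {}
    slopes: Dict[float, float] = {}
    bounded: Dict[float, bool] = {}
    for mu in mu_grid:
        r = np.array(
            [
                np.max(lam**mu * residuals[i]) / alpha**mu
                for i, alpha in enumerate(alpha_grid)
            ]
        )
        ratios[float(mu)] = r
        pos = r > 0
        if pos.sum() >= 2:
            slope = np.polyfit(np.log(alpha_grid[pos]), np.log(r[pos]), 1)[0]
        else:
            slope = 0.0
        slopes[float(mu)] = float(slope)
        rp = r[pos]
        factor = float(rp.max() / rp.min()) if rp.size else 1.0
        bounded[float(mu)] = factor < bounded_factor

    best = None
    for mu in mu_grid:
        larger = mu_grid[mu_grid > mu]
        if bounded[float(mu)] and all(
            slopes[float(m)] < divergence_slope for m in larger
        ):
            best = float(mu)
    if best is None:
        raise ValueError(
            f"no tested mu is bounded for filter {filter_spec.name}; "
            "grid too coarse or filter not regularizing"
        )
    capped = bool(bounded[float(mu_grid[-1])])
    return QualificationReport(
        qualification=float(mu_grid[-1]) if capped else best,
        capped=capped,
        mu_grid=mu_grid,
        ratios=ratios,
        slopes=slopes,
        bounded=bounded,
    )
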