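"""Small shared helpers: canonical vector/image reshape and seed derivation."""

from __future__ import annotations

import numpy as np

__all__ = ["vec_to_image", "image_to_vec", "derive_seed"]


def vec_to_image(x: np.ndarray, grid_n: int) -> np.ndarray:
    """Reshape a coefficient vector of length grid_n**2 to a grid image (row-major).

    This is the single canonical reshape used everywhere networks meet
    spectral vectors.
    """
    x = np.asarray(x)
    if x.size != grid_n * grid_n:
        raise ValueError(f"vector of size {x.size} is not a {grid_n}x{grid_n} image")
    return x.reshape(grid_n, grid_n)


def image_to_vec(img: np.ndarray) -> np.ndarray:
    """Flatten a grid image to a coefficient vector (row-major)."""
    return np.asarray(img).reshape(-1)


def derive_seed(master: int, *counters: int) -> int:
    """Counter-based child seed below 2**31, deterministic in (master, counters)."""
    ss = np.random.SeedSequence([int(master), *[int(c) for c in counters]])
    return int(ss.generate_state(1)[0] % (2**31))
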