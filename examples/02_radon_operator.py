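"""The sparse-view Radon operator in a Kaiser-Bessel blob basis.

Assembles a reduced-scale projector (32x32 blob grid, 10 angles, 48 offsets),
checks the analytic blob projection against numerical quadrature, and looks
at the singular spectrum that makes this problem ill-posed: far fewer data
than unknowns, a wide spread of singular values, and a large null space.
"""

import numpy as np
from scipy.integrate import quad

from regnets import ProjectionGeometry, build_operator, kb_profile, kb_radon_profile, singular_values

geometry = ProjectionGeometry(grid_n=32, n_angles=10, n_offsets=48, kb_support=0.22)
print(f"geometry: {geometry.grid_n}x{geometry.grid_n} blobs, "
      f"{geometry.n_angles} angles x {geometry.n_offsets} offsets")

# the closed-form blob projection equals the line integral of the blob
s = geometry.kb_support / 3
tmax = np.sqrt(geometry.kb_support**2 - s**2)
ref, _ = quad(lambda t: kb_profile(np.hypot(s, t), geometry.kb_shape, geometry.kb_support),
              -tmax, tmax)
closed = kb_radon_profile(s, geometry.kb_shape, geometry.kb_support)
print(f"projection at s = a/3: closed form {closed:.10f}, quadrature {ref:.10f}")

A = build_operator(geometry)
print(f"operator shape {A.shape}, {A.nnz} nonzeros "
      f"({100 * A.nnz / (A.shape[0] * A.shape[1]):.1f}% dense)")

sv = singular_values(A)
retained = int(np.sum(sv**2 >= 1.0))
print(f"sigma_1 = {sv[0]:.3f}, sigma_min = {sv[sv > 1e-10 * sv[0]].min():.2e}")
print(f"numerical rank {np.sum(sv > 1e-10 * sv[0])} of {A.shape[1]} unknowns "
      f"-> null space dimension {A.shape[1] - np.sum(sv > 1e-10 * sv[0])}")
print(f"truncated SVD at alpha = 1 would retain {retained} components")
# Everything in the null space is invisible to the data: no linear method can
# recover it, which is exactly the gap the trained networks fill.
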