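"""Convergence-rate verification on a toy diagonal system.

Under the source condition x = (A*A)^mu w and the a-priori rule
alpha = delta^(2/(2mu+1)), the reconstruction error of a filter with
qualification >= mu decays like delta^(2mu/(2mu+1)).  This script fits that
exponent empirically for Tikhonov regularization at mu = 1/2 and mu = 1, and
evaluates the term-by-term error bound

  ||R_alpha(y_d) - x|| <= delta (1+L)||B_alpha|| + C rho alpha^mu
                          + d_alpha(x; rho, mu) + mixing term.
"""

import numpy as np

from regnets import (
    RegNetModel,
    distance_function,
    empirical_rate,
    error_bound_terms,
    get_filter,
    source_element,
    svd_decompose,
)

system = svd_decompose(np.diag(1.0 / np.arange(1, 201)))
tik = get_filter("tikhonov")
factory = lambda alpha: RegNetModel(system=system, filter=tik, alpha=alpha, mode="plain")

for mu in (0.5, 1.0):
    x = source_element(system, mu, system.domain_basis[:, 0])
    report = empirical_rate(
        system, factory, x, mu, np.geomspace(1e-1, 1e-6, 11),
        replicates=11, seed=1, noise="worst_case",
    )
    print(f"mu = {mu}: fitted slope {report.slope:.3f}, "
          f"theory 2mu/(2mu+1) = {report.expected_slope:.3f}")

# the distance function is zero exactly on the source set ...
w = system.domain_basis[:, 0]
x = source_element(system, 1.0, w)
print("d_alpha on a source element:",
      f"{distance_function(system, None, x, rho_src=1.0, mu=1.0).value:.2e}")

# ... and the error bound dominates the realized error
model = factory(0.01)
delta = 1e-3
y = system.matvec(x) + delta * system.range_basis[:, 5]
terms = error_bound_terms(system, model, x, y, delta=delta, rho_src=1.0, mu=1.0, C=1.0)
print(f"true error {terms['true_error']:.3e} <= bound {terms['total_bound']:.3e} "
      f"(noise {terms['noise_term']:.1e}, approx {terms['approximation_term']:.1e})")
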