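# Methods

## Problem and model

The package addresses linear ill-posed inverse problems `y_delta = A x + z`,
`||z|| <= delta`, in finite dimensions, through the composition

    R_alpha = (Id + N_theta(alpha)) ∘ B_alpha,

where `B_alpha = g_alpha(A*A) A*` is a classical filter-based regularization
of the Moore–Penrose inverse and `N_theta(alpha)` is a trained,
band-projected network.  Two filters are built in: Tikhonov
(`g_alpha = 1/(lambda+alpha)`) and truncated SVD (`0` below the cutoff
`lambda < alpha`, `1/lambda` above, cutoff inclusive).  Three reconstruction
modes exist:

* **plain** — `N = 0`: the classical regularizer.
* **continued_svd** (TSVD only) — the network output is projected onto the
  orthogonal complement of the retained singular directions, so retained
  coefficients of `B_alpha y` pass through exactly and the network
  extrapolates the truncated ones from them.
* **null_space** (TSVD only) — the network output is projected onto the
  numerical kernel of `A`; the addition is invisible to the operator
  (`||A * addition|| <= rank_tol * sigma_1 * ||addition||`).

The theory module certifies the quantities that drive convergence analysis:
filter qualification, the source-condition distance function, a four-term
error bound, and empirical convergence rates.

## Spectral conventions

All spectral computations run in double precision.  `svd_decompose` keeps
the full singular system (min(m, d) triplets); singular values at or below
`rank_tol * sigma_1` (default `rank_tol = 1e-10`) are treated as numerically
zero.  The *numerical kernel* is the span of those directions **plus** the
orthogonal complement of all retained right singular vectors (nontrivial
when d > m).  For TSVD, `(Id - B_alpha A)` is exactly the orthogonal
projector onto `{u_n : sigma_n^2 < alpha}` plus that complement, which is why
the continued-SVD band defaults to the full complement (`kernel_band =
"complement"`); the variant that restricts to stored directions with
`0 < sigma_n^2 < alpha` is available as `kernel_band = "band"`.

## Qualification estimation

`estimate_qualification` computes, per smoothness order mu,

    r(mu, alpha) = sup_lambda lambda^mu |1 - lambda g_alpha(lambda)| / alpha^mu

over a lambda-grid of 2048 logarithmically spaced points in
`[1e-12 * lambda_max, lambda_max]` plus `lambda = 0` (the supremum migrates
toward 0 as alpha shrinks).  A mu is *bounded* when r varies by less than a
factor 3 across an alpha-grid spanning at least five decades, *divergent*
when the log–log slope of r versus alpha is below −0.1; both thresholds were
validated against the closed forms for Tikhonov (`r` constant for mu <= 1,
slope `mu − 1` beyond) and TSVD (`r <= 1` for every mu).  Residuals
`|1 − lambda g|` below 100 machine epsilons are clamped to zero: they are
rounding noise of `lambda * (1/lambda)` and would otherwise be amplified by
`alpha^{-mu}`.  The reported qualification is the largest bounded mu; when
every tested mu is bounded the estimate is *capped* at the grid maximum
(infinite qualification is indistinguishable from "bounded up to the grid").

## Distance function

`d_alpha(x; rho, mu) = inf { ||r − (A*A)^mu w|| : ||w|| <= rho }` with
`r = x − N_theta(B_alpha A x)` is solved exactly in the singular basis.  The
unconstrained coefficients are `w_n = <u_n, r> / sigma_n^{2mu}`; if their
norm exceeds rho, the constrained minimizer lies on the sphere and solves the
secular equation `||w(nu)|| = rho`, `w(nu)_n = sigma_n^{2mu} <u_n, r> /
(sigma_n^{4mu} + nu)`, which is strictly decreasing in nu; it is bracketed by
doubling and solved with Brent's method to relative 1e-12.  The component of
r orthogonal to `ran((A*A)^mu)` (kernel directions) cannot be matched by any
w and contributes irreducibly — exact in finite dimensions.

## Rate verification

`empirical_rate` applies the a-priori rule `alpha = c * delta^{2/(2mu+1)}`
(c = 1 by default; the fitted slope is insensitive to c) over a delta-grid
of at least four points, records the median error over >= 11 seeded
replicates, and fits the log–log slope by least squares.

One numerical subtlety is documented here because it shapes the default
probes.  The `O(delta^{2mu/(2mu+1)})` bound is a *worst-case* statement.  On
a finite spectrum (the standard toy system `sigma_n = 1/n`, d = 200), an
isotropically random source element and isotropic noise spread their mass
over the whole spectrum; each term of the error then decays with a diluted,
non-canonical exponent in the pre-asymptotic window where alpha sweeps
through the spectrum, and the fitted slope lands between 1/2 and 2mu/(2mu+1).
The sharp rate is therefore verified with a *sharpness probe*: the source
element concentrated on the leading singular direction (`w = u_1`) and a
random-sign perturbation of size delta along the data direction attaining
`||B_alpha||` (`noise="worst_case"`).  With that construction the fitted
slopes on the toy system are 0.56 for mu = 1/2 (theory 0.5) and 0.66 for
mu = 1 (theory 2/3).  Isotropic noise (`noise="gaussian"`) and noise-free
runs remain available.

## Networks and training

No deep-learning framework is used: the networks are implemented in numpy
with hand-written backward passes.  The default architecture is an
encoder–decoder with skip connections (U-net style, without residual
connection): two 3x3 conv + ReLU blocks per scale, 2x2 average-pool
downsampling, nearest-neighbour upsampling, channel concatenation, and a
final 1x1 convolution; 2 scales and 8 base channels at the reduced
experiment scale (channel count doubles per scale).  Network arithmetic runs
in single precision for speed; every projection onto spectral bands is done
in double precision.  Backward passes are verified against finite
differences in the test suite (in a double-precision instance).

Training minimizes the mean absolute error between ground-truth coefficients
`c^(k)` and the full reconstruction `R_alpha(y^(k)) = b^(k) + P U_theta(b^(k))`,
where `b^(k) = B_alpha y^(k)` is precomputed and `P` is the fixed band
projector of the mode; only network parameters are free, so the loss
gradient enters the network through `P` alone.  The optimizer is stochastic
gradient descent with learning rate 0.05 and momentum 0.99; training data
are noise-free (`delta_train = 0`).  The reported loss is the per-sample l1
norm averaged over the batch; the update uses the per-pixel mean gradient of
the same objective (a constant rescaling of the summed-l1 gradient), which
keeps update magnitudes independent of image size at the stated learning
rate.  Epoch count and batch size default to 60 and 8 at the reduced scale.
Per-alpha runs are independent, each with its own regenerated dataset
(inputs `B_alpha y` depend on alpha) and a counter-derived seed.

## Synthetic phantoms and noise

Phantoms are random superpositions of 5–12 constant-intensity ellipses: one
enclosing "skull" ellipse (semi-axes 0.55–0.72, intensity 1) plus interior
ellipses with centers in the disk of radius 0.75, semi-axes 0.05–0.6
(clamped so the support stays inside the unit square) and intensities of
magnitude 0.1–1 with random sign.  Coefficients are the ellipse-sum
evaluated at the blob-grid centers, so the coefficient vector doubles as the
image.  Data are simulated as `y = A c + delta * xi` with
`xi_j ~ ||A c||_inf * N(0, 1)`, i.e. delta is a relative noise level;
evaluation uses delta in {0.02, 0.05}.  All randomness flows from a master
seed through counter-based children (`SeedSequence`), so every dataset,
noise draw and training run is exactly reproducible.

What the generator does *not* emulate: anatomical texture, scanner physics
(beam hardening, scatter, detector blur), correlated noise, and phantoms
outside the ellipse family.  Passing tests therefore demonstrate the
mechanism — learned completion of invisible spectral components under a
known operator — not clinical reconstruction quality.

## Radon operator discretization

The unknown density on `[-1,1]^2` is expanded in order-0 Kaiser–Bessel
blobs (shape rho = 7, support a = 0.055 at full scale, about four pixels) on
an N x N Cartesian grid; the forward matrix entry for (angle k, offset j,
blob i) is the analytic blob projection evaluated at
`s_j − <x_i, omega_k>`,

    p(s) = 2 a sinh(rho sqrt(1 − (s/a)^2)) / (rho I0(rho)),  |s| <= a,

validated against adaptive quadrature of the blob along lines to relative
1e-8 in the test suite.  Rows are angle-major; entries beyond the blob
support are structurally zero, so the matrix is sparse.  Grid and offset
endpoint conventions are explicit parameters: the defaults
(endpoint-inclusive blob grid on [-1,1], cell-midpoint offsets on
[-3/2, 3/2]) were frozen by validating the operator's singular spectrum —
at full scale (N = 128, 30 angles, 200 offsets) truncated SVD at alpha = 1
retains 796 components under this convention; the other three variants give
788–793.  At the reduced experiment scale (N = 32, 10 angles, 48 offsets)
the blob support is widened to a = 0.22 to keep the same ~4-pixel footprint
relative to the coarser grid.

## Experiment protocol and problem sizes

The end-to-end comparison runs at a reduced scale chosen so the whole
protocol (operator + SVD + 12 training runs + evaluation) completes in
minutes on one CPU: 32x32 grid, 10 angles, 48 offsets, 100 training and 25
test phantoms, 10 validation phantoms for the alpha choice, six alpha values
placed at fixed retained-count fractions (0.95, 0.8, 0.6, 0.4, 0.25, 0.12)
of the numerical rank.  Reconstructions and ground truths are min–max
rescaled to [0, 1] *independently* before computing MSE/MAE (a shared-scale
variant is a flag); constant images rescale to zeros with a warning.  The
operating alpha of each method is the MSE-minimizer on the validation set,
ties broken toward stronger regularization.  Every artifact embeds the
configuration hash and master seed.

## Known limitations

* Only explicit-SVD operators: no matrix-free projectors, no
  filtered-backprojection baselines, fan/cone-beam geometries, or iterative
  filters (Landweber, iterated Tikhonov).
* The admissible sets actually learned by trained networks are not
  characterized; the adaptedness check (`check_adaptedness`) certifies the
  convergence condition empirically on probes, not analytically.
* The empirical Lipschitz estimate (maximum ratio over 200 seeded probe
  pairs) is a lower bound on the true constant; it serves as a uniform-bound
  certificate across the alpha family, not an exact constant.
* Reduced-scale training (100 samples, small networks) shows the qualitative
  method ordering; absolute error values at full scale would differ.
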