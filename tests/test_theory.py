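import numpy as np
import pytest
from scipy.optimize import minimize

from regnets import (
    CallableNetwork,
    RegNetModel,
    ZeroNetwork,
    distance_function,
    empirical_rate,
    error_bound_terms,
    get_filter,
    nullspace_network_apply,
    source_element,
    svd_decompose,
)
from conftest import diagonal_system, random_system


def brute_force_distance(system, r, rho, mu):
    """Constrained minimization oracle via SLSQP from several starts."""
    pos = system.positive_mask
    u = system.domain_basis[:, pos]
    s2mu = system.singular_values[pos] ** (2 * mu)

    def objective(w):
        return np.linalg.norm(r - u @ (s2mu * w))

    cons = [{"type": "ineq", "fun": lambda w: rho**2 - w @ w}]
    best = np.inf
    for seed in range(4):
        w0 = np.random.default_rng(seed).standard_normal(u.shape[1]) * rho / 10
        res = minimize(objective, w0, constraints=cons, method="SLSQP",
                       options={"maxiter": 500, "ftol": 1e-14})
        best = min(best, objective(res.x * min(1.0, rho / max(np.linalg.norm(res.x), 1e-300))))
    return best


def projected_gradient_distance(system, r, rho, mu, iters=60):
    """Second oracle: naive bisection on the Lagrange multiplier.

    The KKT conditions give w(nu)_n = s_n^{2mu} <u_n, r> / (s_n^{4mu} + nu)
    with ||w(nu)|| monotone decreasing in nu; pure-python bisection, no
    library root-finder.  (A plain projected-gradient iteration stalls on
    these spectra: the condition number scales like (s_max/s_min)^{4mu}.)
    """
    pos = system.positive_mask
    u = system.domain_basis[:, pos]
    s2mu = system.singular_values[pos] ** (2 * mu)
    coeff = u.T @ r

    def w_of(nu):
        return s2mu * coeff / (s2mu**2 + nu)

    w = coeff / s2mu
    if np.linalg.norm(w) > rho:
        lo, hi = 0.0, 1.0
        while np.linalg.norm(w_of(hi)) > rho:
            hi *= 4.0
        for _ in range(iters):
            mid = 0.5 * (lo + hi)
            if np.linalg.norm(w_of(mid)) > rho:
                lo = mid
            else:
                hi = mid
        w = w_of(0.5 * (lo + hi))
        w *= rho / np.linalg.norm(w)  # land exactly on the sphere
    return float(np.linalg.norm(r - u @ (s2mu * w)))


class TestDistanceFunction:
    def test_zero_input(self):
        system = diagonal_system([2.0, 1.0])
        res = distance_function(system, None, np.zeros(2), rho_src=1.0, mu=1.0)
        assert res.value == 0.0
        assert np.all(res.minimizer == 0.0)

    def test_source_element_has_zero_distance(self):
        rng = np.random.default_rng(0)
        system = random_system(rng, 6, 6)
        w0 = rng.standard_normal(6)
        w0 *= 0.5 / np.linalg.norm(w0)
        x = source_element(system, 1.0, w0)
        res = distance_function(system, None, x, rho_src=1.0, mu=1.0)
        assert res.value < 1e-10
        assert not res.constraint_active
        assert np.linalg.norm(res.minimizer) <= 1.0 + 1e-10

    @pytest.mark.parametrize("mu", [0.5, 1.0])
    def test_matches_two_independent_oracles(self, mu):
        rng = np.random.default_rng(1)
        for trial in range(20):
            d = int(rng.integers(3, 9))
            system = random_system(rng, d + 1, d)
            x = rng.standard_normal(d) * 2
            rho = float(rng.uniform(0.1, 2.0))
            res = distance_function(system, None, x, rho_src=rho, mu=mu)
            ref1 = brute_force_distance(system, x, rho, mu)
            ref2 = projected_gradient_distance(system, x, rho, mu)
            floor = 1e-6 * np.linalg.norm(x)  # oracle convergence floor
            assert res.value == pytest.approx(ref1, rel=2e-6, abs=floor)
            assert res.value == pytest.approx(ref2, rel=2e-6, abs=floor)
            # certified optimality structure
            assert np.linalg.norm(res.minimizer) <= rho * (1 + 1e-10)
            recon = res.residual - source_element(system, mu, res.minimizer)
            assert res.value == pytest.approx(np.linalg.norm(recon), abs=1e-10)

    def test_monotone_in_radius(self):
        rng = np.random.default_rng(2)
        system = random_system(rng, 5, 5)
        x = rng.standard_normal(5)
        rhos = [0.1, 0.3, 1.0, 3.0, 10.0]
        vals = [distance_function(system, None, x, r, 1.0).value for r in rhos]
        assert np.all(np.diff(vals) <= 1e-12)

    def test_kernel_component_is_irreducible(self):
        system = diagonal_system([1.0, 0.0])
        x = np.array([0.0, 3.0])  # pure kernel direction
        res = distance_function(system, None, x, rho_src=100.0, mu=1.0)
        assert res.value == pytest.approx(3.0)

    def test_nullspace_model_decay_rate(self, tsvd):
        # with a constant null-space network and x = (Id+N)(A*A)^mu w,
        # d_alpha(x) = O(alpha^mu)  (bounded by L*C*alpha^mu)
        rng = np.random.default_rng(3)
        system = random_system(rng, 6, 9, rank=5)
        net = CallableNetwork(lambda img: np.tanh(img))
        w = rng.standard_normal(9)
        w *= 0.8 / np.linalg.norm(w)
        mu = 1.0
        z = source_element(system, mu, w)
        x = z + nullspace_network_apply(system, net, z)
        lam1 = system.sigma1**2
        alphas = lam1 * np.array([1e-1, 1e-2, 1e-3, 1e-4])
        for alpha in alphas:
            model = RegNetModel(system=system, filter=tsvd, alpha=alpha,
                                network=net, mode="null_space")
            res = distance_function(system, model, x, rho_src=1.0, mu=mu)
            assert res.value <= 1.0 * 1.0 * alpha**mu + 1e-9  # L = C = 1 here


class TestErrorBound:
    def test_reduces_to_approximation_term(self, tsvd):
        # delta = 0, zero network, x in the source set: distance and mixing
        # vanish and the bound is C rho alpha^mu
        rng = np.random.default_rng(4)
        system = random_system(rng, 6, 6)
        w = rng.standard_normal(6)
        w *= 0.9 / np.linalg.norm(w)
        x = source_element(system, 1.0, w)
        model = RegNetModel(system=system, filter=tsvd, alpha=0.1 * system.sigma1**2,
                            network=ZeroNetwork(), mode="continued_svd")
        terms = error_bound_terms(system, model, x, system.matvec(x),
                                  delta=0.0, rho_src=1.0, mu=1.0, C=1.0)
        assert terms["noise_term"] == 0.0
        assert terms["distance_term"] < 1e-9
        assert terms["mixing_term"] < 1e-12
        assert terms["total_bound"] == pytest.approx(1.0 * 1.0 * model.alpha, rel=1e-9)
        assert terms["true_error"] <= terms["total_bound"] + 1e-9

    def test_mixing_term_vanishes_for_continued_svd(self, tsvd):
        rng = np.random.default_rng(5)
        system = random_system(rng, 7, 10, rank=6)
        net = CallableNetwork(lambda img: np.cos(img))
        alpha = float(system.singular_values[3] ** 2)
        model = RegNetModel(system=system, filter=tsvd, alpha=alpha,
                            network=net, mode="continued_svd")
        x = rng.standard_normal(10)
        terms = error_bound_terms(system, model, x, system.matvec(x),
                                  delta=0.0, rho_src=1.0, mu=1.0, C=1.0,
                                  lipschitz=1.0)
        assert terms["mixing_term"] <= 1e-12

    def test_bound_dominates_error_on_random_instances(self, tsvd):
        rng = np.random.default_rng(6)
        count = 0
        for trial in range(50):
            d = int(rng.integers(4, 9))
            system = random_system(rng, d, d + 2, rank=d - 1)
            net = CallableNetwork(lambda img: np.tanh(img))
            # 1-Lipschitz network
            alpha = float(rng.choice(system.singular_values[: d - 1]) ** 2)
            model = RegNetModel(system=system, filter=tsvd, alpha=alpha,
                                network=net, mode="null_space")
            x = rng.standard_normal(d + 2)
            delta = float(rng.uniform(0.001, 0.1))
            noise = rng.standard_normal(d)
            y = system.matvec(x) + delta * noise / np.linalg.norm(noise)
            terms = error_bound_terms(system, model, x, y, delta=delta,
                                      rho_src=1.0, mu=1.0, C=1.0, lipschitz=1.0)
            assert terms["true_error"] <= terms["total_bound"] * (1 + 1e-9)
            count += 1
        assert count == 50

    def test_misfit_precondition(self, tsvd):
        system = diagonal_system([1.0, 1.0])
        model = RegNetModel(system=system, filter=tsvd, alpha=0.5, mode="plain")
        x = np.array([1.0, 1.0])
        with pytest.raises(ValueError, match="delta"):
            error_bound_terms(system, model, x, system.matvec(x) + 1.0,
                              delta=0.01, rho_src=1.0, mu=1.0, C=1.0)


def _toy_rate_system(d=200):
    return svd_decompose(np.diag(1.0 / np.arange(1, d + 1)))


class TestEmpiricalRate:
    @pytest.mark.parametrize("mu,expected", [(0.5, 0.5), (1.0, 2.0 / 3.0)])
    def test_tikhonov_source_condition_rate(self, mu, expected):
        # source element concentrated on the leading singular direction and
        # worst-case-aligned noise: the sharp delta^{2mu/(2mu+1)} rate shows
        system = _toy_rate_system()
        tik = get_filter("tikhonov")
        w = system.domain_basis[:, 0].copy()
        x = source_element(system, mu, w)
        factory = lambda alpha: RegNetModel(system=system, filter=tik,
                                            alpha=alpha, mode="plain")
        report = empirical_rate(system, factory, x, mu,
                                np.geomspace(1e-1, 1e-6, 11), replicates=11,
                                seed=1, noise="worst_case")
        assert report.expected_slope == pytest.approx(expected)
        assert abs(report.slope - report.expected_slope) <= 0.08

    def test_zero_noise_errors_monotone(self):
        system = _toy_rate_system(60)
        tik = get_filter("tikhonov")
        rng = np.random.default_rng(8)
        x = source_element(system, 1.0, rng.standard_normal(60))
        factory = lambda alpha: RegNetModel(system=system, filter=tik,
                                            alpha=alpha, mode="plain")
        report = empirical_rate(system, factory, x, 1.0,
                                np.geomspace(1e-1, 1e-5, 6), noise="none")
        assert np.all(np.diff(report.errors) <= 0)  # decreasing with delta

    def test_short_grid_rejected(self):
        system = _toy_rate_system(10)
        tik = get_filter("tikhonov")
        factory = lambda alpha: RegNetModel(system=system, filter=tik,
                                            alpha=alpha, mode="plain")
        with pytest.raises(ValueError, match="4"):
            empirical_rate(system, factory, np.ones(10), 1.0, [1e-1, 1e-2, 1e-3])


def test_regnet_convergence_with_adapted_networks(tsvd):
    """TSVD RegNets with a constant null-space network and alpha = delta^{2/3}
    converge to x = (Id+N)z along decreasing noise levels."""
    rng = np.random.default_rng(9)
    system = random_system(rng, 20, 32, rank=16)
    net = CallableNetwork(lambda img: np.tanh(img))
    z = system.pinv_apply(system.matvec(rng.standard_normal(32)))
    x = z + nullspace_network_apply(system, net, z)
    deltas = np.geomspace(1e-1, 1e-6, 6)
    errors = []
    for delta in deltas:
        alpha = delta ** (2.0 / 3.0) * system.sigma1**2
        model = RegNetModel(system=system, filter=tsvd, alpha=alpha,
                            network=net, mode="null_space")
        noise = rng.standard_normal(20)
        y = system.matvec(x) + delta * noise / np.linalg.norm(noise)
        from regnets import regnet_reconstruct

        errors.append(np.linalg.norm(regnet_reconstruct(model, y) - x))
    errors = np.array(errors)
    assert np.all(np.diff(errors[2:]) < 0) or errors[-1] < errors[2]
    assert errors[-1] <= 1e-3 * np.linalg.norm(x)
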