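import numpy as np
import pytest

from regnets import (
    CallableNetwork,
    RegNetModel,
    ZeroNetwork,
    apply_regularizer,
    check_adaptedness,
    continued_svd_reconstruct,
    kernel_projector,
    nullspace_network_apply,
    nullspace_svd_reconstruct,
    regnet_reconstruct,
    svd_decompose,
)
from conftest import diagonal_system, random_system


class TestNullspaceNetworkApply:
    def test_zero_network(self):
        rng = np.random.default_rng(0)
        system = random_system(rng, 5, 9, rank=4)
        out = nullspace_network_apply(system, ZeroNetwork(), rng.standard_normal(9))
        assert np.all(out == 0)

    def test_full_rank_square(self):
        rng = np.random.default_rng(1)
        system = random_system(rng, 9, 9)
        net = CallableNetwork(lambda img: img + 1.0)
        out = nullspace_network_apply(system, net, rng.standard_normal(9))
        assert np.linalg.norm(out) < 1e-9

    def test_coordinate_kernel(self):
        system = diagonal_system([1.0, 0.0])
        net = CallableNetwork(lambda img: np.full_like(img, 3.0))
        out = nullspace_network_apply(system, net, np.array([1.0, 2.0]))
        assert out[0] == pytest.approx(0.0, abs=1e-12)

    def test_output_invisible_to_operator(self):
        rng = np.random.default_rng(2)
        system = random_system(rng, 4, 9, rank=3)
        net = CallableNetwork(lambda img: np.sin(img))
        x = rng.standard_normal(9)
        out = nullspace_network_apply(system, net, x)
        netout = np.sin(x)
        assert np.linalg.norm(system.matvec(out)) <= 1e-8 * system.sigma1 * np.linalg.norm(netout)


class TestModeDispatch:
    def test_plain_equals_apply_regularizer(self, tsvd):
        rng = np.random.default_rng(3)
        system = random_system(rng, 6, 9, rank=5)
        model = RegNetModel(system=system, filter=tsvd, alpha=0.1, mode="plain")
        y = rng.standard_normal(6)
        assert np.array_equal(
            regnet_reconstruct(model, y), apply_regularizer(system, tsvd, 0.1, y)
        )

    def test_zero_network_reduces_to_filter(self, tsvd):
        rng = np.random.default_rng(4)
        system = random_system(rng, 6, 9, rank=5)
        for mode, fn in [
            ("continued_svd", continued_svd_reconstruct),
            ("null_space", nullspace_svd_reconstruct),
        ]:
            model = RegNetModel(system=system, filter=tsvd, alpha=0.1,
                                network=ZeroNetwork(), mode=mode)
            y = rng.standard_normal(6)
            assert np.allclose(fn(model, y), apply_regularizer(system, tsvd, 0.1, y))

    def test_manual_two_step_composition(self, tsvd):
        rng = np.random.default_rng(5)
        system = random_system(rng, 5, 9, rank=4)
        net = CallableNetwork(lambda img: img**2)
        model = RegNetModel(system=system, filter=tsvd, alpha=0.05,
                            network=net, mode="null_space")
        y = rng.standard_normal(5)
        b = apply_regularizer(system, tsvd, 0.05, y)
        manual = b + kernel_projector(system, (b**2))
        assert np.array_equal(regnet_reconstruct(model, y), manual)

    def test_non_tsvd_mode_rejected(self, tikhonov):
        system = diagonal_system([2.0, 1.0])
        with pytest.raises(ValueError, match="TSVD"):
            RegNetModel(system=system, filter=tikhonov, alpha=0.1, mode="continued_svd")

    def test_unknown_mode_rejected(self, tsvd):
        system = diagonal_system([2.0, 1.0])
        with pytest.raises(ValueError, match="mode"):
            RegNetModel(system=system, filter=tsvd, alpha=0.1, mode="landweber")


class TestContinuedSvd:
    def test_retained_coefficients_untouched(self, tsvd):
        rng = np.random.default_rng(6)
        system = random_system(rng, 8, 12, rank=6)
        alpha = float(np.median(system.singular_values[:6]) ** 2)
        net = CallableNetwork(lambda img: np.cos(img) + img)
        model = RegNetModel(system=system, filter=tsvd, alpha=alpha,
                            network=net, mode="continued_svd")
        y = rng.standard_normal(8)
        b = apply_regularizer(system, tsvd, alpha, y)
        out = regnet_reconstruct(model, y)
        u = system.domain_basis
        for n in np.flatnonzero(model.retained_mask):
            assert abs(u[:, n] @ out - u[:, n] @ b) < 1e-12

    def test_hand_enumerated_diagonal_case(self, tsvd):
        # A = diag(2, 1, 0.1), alpha = 0.5: retained sigma^2 = {4, 1},
        # truncated band = {0.01}.  With U(x) = x + 1 the added component is
        # (<B y, e3> + 1) e3 = e3 since B y has no e3 part.
        system = diagonal_system([2.0, 1.0, 0.1])
        net = CallableNetwork(lambda img: img + 1.0)
        model = RegNetModel(system=system, filter=tsvd, alpha=0.5,
                            network=net, mode="continued_svd")
        y = np.array([2.0, 3.0, 5.0])
        b = apply_regularizer(system, tsvd, 0.5, y)
        out = regnet_reconstruct(model, y)
        u = system.domain_basis
        # hand evaluation of the continued-SVD sum
        expected = b.copy()
        uy = net(b.reshape(1, -1)).ravel()
        for n in range(3):
            if system.singular_values[n] ** 2 < 0.5:
                expected += (u[:, n] @ uy) * u[:, n]
        assert np.allclose(out, expected, atol=1e-14)
        assert abs(np.abs(out - b).sum() - 1.0) < 1e-12  # exactly the e3 unit addition

    def test_band_variant_excludes_numerical_kernel(self, tsvd):
        rng = np.random.default_rng(7)
        system = random_system(rng, 6, 10, rank=5)
        alpha = float(system.singular_values[2] ** 2) * 0.99
        net = CallableNetwork(lambda img: np.ones_like(img))
        y = rng.standard_normal(6)
        full = RegNetModel(system=system, filter=tsvd, alpha=alpha, network=net,
                           mode="continued_svd", kernel_band="complement")
        band = RegNetModel(system=system, filter=tsvd, alpha=alpha, network=net,
                           mode="continued_svd", kernel_band="band")
        add_full = regnet_reconstruct(full, y) - apply_regularizer(system, tsvd, alpha, y)
        add_band = regnet_reconstruct(band, y) - apply_regularizer(system, tsvd, alpha, y)
        # the band addition is visible to A, the kernel part is not
        assert np.linalg.norm(kernel_projector(system, add_band)) < 1e-10
        assert np.linalg.norm(add_full) >= np.linalg.norm(add_band) - 1e-12


class TestNullspaceMode:
    def test_added_component_annihilated(self, tsvd):
        rng = np.random.default_rng(8)
        system = random_system(rng, 7, 12, rank=5)
        alpha = float(system.singular_values[3] ** 2)
        net = CallableNetwork(lambda img: img + np.sin(img))
        model = RegNetModel(system=system, filter=tsvd, alpha=alpha,
                            network=net, mode="null_space")
        y = rng.standard_normal(7)
        b = apply_regularizer(system, tsvd, alpha, y)
        added = regnet_reconstruct(model, y) - b
        assert np.linalg.norm(system.matvec(added)) <= 1e-8 * system.sigma1 * np.linalg.norm(added)

    def test_full_rank_adds_nothing(self, tsvd):
        rng = np.random.default_rng(9)
        system = random_system(rng, 6, 6)
        net = CallableNetwork(lambda img: np.ones_like(img))
        model = RegNetModel(system=system, filter=tsvd, alpha=0.5,
                            network=net, mode="null_space")
        y = rng.standard_normal(6)
        assert np.allclose(
            regnet_reconstruct(model, y), apply_regularizer(system, tsvd, 0.5, y)
        )


class TestTheorem42Condition:
    def test_balpha_a_annihilates_continued_svd_addition(self, tsvd):
        """For TSVD the added band lies in ran(Id - B_alpha A), so
        B_alpha A applied to the addition is zero to machine precision."""
        rng = np.random.default_rng(10)
        for trial in range(10):
            system = random_system(rng, 7, 10, rank=6)
            alpha = float(rng.choice(system.singular_values[:6]) ** 2) * 0.9
            net = CallableNetwork(lambda img: np.tanh(img) + 0.5)
            model = RegNetModel(system=system, filter=tsvd, alpha=alpha,
                                network=net, mode="continued_svd")
            x = rng.standard_normal(10)
            b = apply_regularizer(system, tsvd, alpha, system.matvec(x))
            added = model.network_addition(b)
            term = apply_regularizer(system, tsvd, alpha, system.matvec(added))
            assert np.linalg.norm(term) <= 1e-12 * max(1.0, np.linalg.norm(added))


class TestAdaptedness:
    def _tsvd_models(self, system, tsvd, alphas, net_for_alpha):
        return [
            RegNetModel(system=system, filter=tsvd, alpha=a,
                        network=net_for_alpha(a), mode="null_space")
            for a in alphas
        ]

    def test_zero_networks_zero_error(self, tsvd):
        rng = np.random.default_rng(11)
        system = random_system(rng, 6, 9, rank=5)
        alphas = [1e-1, 1e-2, 1e-3]
        models = self._tsvd_models(system, tsvd, alphas, lambda a: ZeroNetwork())
        probe = system.pinv_apply(system.matvec(rng.standard_normal(9)))
        report = check_adaptedness(models, lambda z: np.zeros_like(z), [probe])
        assert report.adapted
        assert np.all(report.errors == 0)

    def test_constant_null_space_network_is_adapted(self, tsvd):
        rng = np.random.default_rng(12)
        system = random_system(rng, 6, 9, rank=5)
        u_fn = lambda img: np.tanh(img)
        net = CallableNetwork(u_fn)
        smin2 = float(np.min(system.singular_values[system.positive_mask]) ** 2)
        alphas = list(np.geomspace(0.5 * system.sigma1**2, 1e-4 * smin2, 6))
        models = self._tsvd_models(system, tsvd, alphas, lambda a: net)
        reference = lambda z: nullspace_network_apply(system, net, z)
        probe = system.pinv_apply(system.matvec(rng.standard_normal(9)))
        report = check_adaptedness(models, reference, [probe], tol=1e-5)
        assert report.adapted
        assert report.errors[0, -1] < report.errors[0, 0]

    def test_diverging_scale_flagged_not_adapted(self, tsvd):
        rng = np.random.default_rng(13)
        system = random_system(rng, 6, 9, rank=5)
        alphas = list(np.geomspace(1e-1, 1e-6, 5) * system.sigma1**2)

        def net_for_alpha(a):
            return CallableNetwork(lambda img, a=a: img / a)

        models = self._tsvd_models(system, tsvd, alphas, net_for_alpha)
        probe = system.pinv_apply(system.matvec(rng.standard_normal(9)))
        report = check_adaptedness(models, lambda z: np.zeros_like(z), [probe], tol=1e-5)
        assert not report.adapted

    def test_kernel_probe_rejected(self, tsvd):
        rng = np.random.default_rng(14)
        system = random_system(rng, 5, 9, rank=4)
        models = self._tsvd_models(
            system, tsvd, [1e-1, 1e-2, 1e-3], lambda a: ZeroNetwork()
        )
        kernel_vec = kernel_projector(system, rng.standard_normal(9))
        with pytest.raises(ValueError, match="kernel"):
            check_adaptedness(models, lambda z: np.zeros_like(z), [kernel_vec])
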