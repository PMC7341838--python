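"""Cumulant contractions, ensemble formulas, signal synthesis and DKI fit."""
import math

import numpy as np
import pytest

from axondiff import cumulants as cm
from axondiff import walk as wk

Z = np.array([0.0, 0.0, 1.0])
X = np.array([1.0, 0.0, 0.0])


def gaussian_record(variances: tuple[float, float, float], t: float = 10.0,
                    n: int = 200000, seed: int = 0) -> wk.MomentRecord:
    """Exact-moment record of a zero-mean Gaussian displacement field."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, 3)) * np.sqrt(variances)
    return record_from_displacements(x, t)


def record_from_displacements(x: np.ndarray, t: float) -> wk.MomentRecord:
    n = x.shape[0]
    m2 = np.array([
        (x[:, 0] ** 2).sum(), (x[:, 1] ** 2).sum(), (x[:, 2] ** 2).sum(),
        (x[:, 0] * x[:, 1]).sum(), (x[:, 0] * x[:, 2]).sum(),
        (x[:, 1] * x[:, 2]).sum(),
    ])
    m4 = np.array([
        (x[:, 0] ** e[0] * x[:, 1] ** e[1] * x[:, 2] ** e[2]).sum()
        for e in wk.M4_EXPONENTS
    ])
    return wk.MomentRecord(
        t=np.array([t]), W=np.array([float(n)]),
        m2=m2[None, :], m4=m4[None, :], n_walkers=n,
    )


def analytic_record(m2_diag, t=10.0):
    """Record with exact Gaussian population moments, no sampling noise."""
    vx, vy, vz = m2_diag
    m2 = np.array([vx, vy, vz, 0.0, 0.0, 0.0])
    m4 = np.zeros(15)
    var = {0: vx, 1: vy, 2: vz}
    for i, (a, b, c) in enumerate(wk.M4_EXPONENTS):
        exps = (a, b, c)
        if sorted(exps) == [0, 0, 4]:
            ax = exps.index(4)
            m4[i] = 3 * var[ax] ** 2
        elif sorted(exps) == [0, 2, 2]:
            axes = [j for j, e in enumerate(exps) if e == 2]
            m4[i] = var[axes[0]] * var[axes[1]]
        # odd-exponent monomials vanish for a centered Gaussian
    return wk.MomentRecord(
        t=np.array([t]), W=np.array([1.0]), m2=m2[None, :], m4=m4[None, :],
        n_walkers=1,
    )


class TestContractions:
    def test_diagonal_tensor_along_axes(self):
        t = 10.0
        rec = analytic_record((2 * t * 1.0, 2 * t * 1.0, 2 * t * 2.0), t)
        assert cm.apparent_D(rec, Z, t) == pytest.approx(2.0, abs=1e-12)
        assert cm.apparent_D(rec, X, t) == pytest.approx(1.0, abs=1e-12)

    def test_oblique_direction_interpolates(self):
        t = 10.0
        rec = analytic_record((2 * t, 2 * t, 4 * t), t)
        n45 = np.array([math.sin(math.pi / 4), 0.0, math.cos(math.pi / 4)])
        assert cm.apparent_D(rec, n45, t) == pytest.approx(1.5, abs=1e-12)

    def test_gaussian_kurtosis_zero_analytic(self):
        t = 5.0
        rec = analytic_record((2 * t, 2 * t, 2 * t), t)
        for n in (Z, X, np.array([0.6, 0.0, 0.8])):
            assert cm.apparent_K(rec, n, t) == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_kurtosis_zero_sampled(self):
        rec = gaussian_record((20.0, 20.0, 20.0), seed=1)
        se = cm.apparent_K_se(rec, Z, 10.0)
        assert abs(cm.apparent_K(rec, Z, 10.0)) < 3 * se

    def test_two_variance_mixture_kurtosis(self):
        # equal mixture of 1d Gaussians with variances {2t, 4t} along z:
        # K = 3 Var(D) / Dbar^2 = 3 * 0.25 / 2.25 = 1/3
        t = 10.0
        rng = np.random.default_rng(2)
        n = 400000
        sigma = np.where(rng.uniform(size=n) < 0.5, math.sqrt(2 * t), math.sqrt(4 * t))
        x = np.zeros((n, 3))
        x[:, 2] = rng.standard_normal(n) * sigma
        rec = record_from_displacements(x, t)
        assert cm.apparent_K(rec, Z, t) == pytest.approx(1.0 / 3.0, abs=0.02)

    def test_two_point_displacement_kurtosis_floor(self):
        # symmetric +-a displacement: Bernoulli fourth moment gives K = -2
        t = 1.0
        n = 1000
        x = np.zeros((n, 3))
        x[: n // 2, 2] = 1.3
        x[n // 2 :, 2] = -1.3
        rec = record_from_displacements(x, t)
        assert cm.apparent_K(rec, Z, t) == pytest.approx(-2.0, abs=1e-12)

    def test_non_unit_direction_rejected(self):
        rec = analytic_record((1.0, 1.0, 1.0), 1.0)
        with pytest.raises(ValueError):
            cm.apparent_D(rec, np.array([0.0, 0.0, 2.0]), 1.0)
        with pytest.raises(ValueError):
            cm.apparent_D(rec, Z, 99.0)  # unsampled time


class TestReflectDirection:
    def test_z_axis_fixed(self):
        assert np.allclose(cm.reflect_direction(Z), Z)

    def test_x_axis_flips(self):
        assert np.allclose(cm.reflect_direction(X), -X)

    def test_oblique_preserves_polar_angle(self):
        n = np.array([math.sin(math.pi / 4), 0.0, math.cos(math.pi / 4)])
        r = cm.reflect_direction(n)
        assert np.allclose(r, [-math.sin(math.pi / 4), 0.0, math.cos(math.pi / 4)])
        assert r @ Z == pytest.approx(n @ Z, abs=1e-12)
        assert np.linalg.norm(r) == pytest.approx(1.0, abs=1e-12)


def toy_axons(t=np.array([10.0, 20.0])):
    a1 = cm.AxonCumulants(t=t, D=np.full(t.size, 1.0), K=np.zeros(t.size), f=0.5)
    a2 = cm.AxonCumulants(t=t, D=np.full(t.size, 2.0), K=np.zeros(t.size), f=0.5)
    return [a1, a2]


class TestEnsemble:
    def test_single_axon_identity(self):
        t = np.array([10.0])
        a = cm.AxonCumulants(t=t, D=np.array([1.7]), K=np.array([0.3]), f=1.0)
        assert cm.ensemble_D([a])[0] == pytest.approx(1.7)
        K, Ki, Kx = cm.ensemble_K([a])
        assert K[0] == pytest.approx(0.3)
        assert Ki[0] == pytest.approx(0.0)

    def test_half_half_mixture(self):
        axons = toy_axons()
        assert np.allclose(cm.ensemble_D(axons), 1.5)
        K, K_inter, K_intra = cm.ensemble_K(axons)
        assert np.allclose(K, 1.0 / 3.0)
        assert np.allclose(K_inter, 1.0 / 3.0)
        assert np.allclose(K_intra, 0.0)

    def test_identical_compartments_zero_kurtosis(self):
        t = np.array([10.0])
        axons = [
            cm.AxonCumulants(t=t, D=np.array([1.2]), K=np.array([0.0]), f=0.25)
            for _ in range(4)
        ]
        K, _, _ = cm.ensemble_K(axons)
        assert K[0] == pytest.approx(0.0, abs=1e-14)

    def test_nonnegative_when_all_axon_kurtoses_nonnegative(self):
        rng = np.random.default_rng(7)
        t = np.array([10.0, 30.0])
        f = rng.dirichlet(np.ones(8))
        axons = [
            cm.AxonCumulants(t=t, D=rng.uniform(0.5, 2.5, t.size),
                             K=rng.uniform(0.0, 1.0, t.size), f=fi)
            for fi in f
        ]
        K, _, _ = cm.ensemble_K(axons)
        assert np.all(K >= 0)

    def test_fraction_mismatch_rejected(self):
        axons = toy_axons()
        axons[0].f = 0.4
        with pytest.raises(ValueError):
            cm.ensemble_D(axons)

    def test_taylor_coefficients_of_log_signal(self):
        # D and K from the ensemble formulas must equal the O(b) and O(b^2)
        # coefficients of -ln S(b); Richardson-extrapolated finite
        # differences at b -> 0 are the independent oracle
        rng = np.random.default_rng(11)
        t = np.array([20.0])
        f = rng.dirichlet(np.ones(6))
        axons = [
            cm.AxonCumulants(t=t, D=rng.uniform(0.8, 2.2, 1),
                             K=rng.uniform(0.0, 0.8, 1), f=fi)
            for fi in f
        ]
        D = cm.ensemble_D(axons)[0]
        K = cm.ensemble_K(axons)[0][0]

        def logS(b):
            return math.log(cm.synthesize_signal(axons, [b]).S[0, 0]) if b else 0.0

        def derivs(b0):
            f1, f2, f3 = logS(b0), logS(2 * b0), logS(3 * b0)
            first = -(3 * f1 - 1.5 * f2 + f3 / 3) / b0
            second = (-5 * f1 + 4 * f2 - f3) / b0**2
            return first, second

        # Richardson extrapolation of the O(b^2) one-sided differences
        (d_h, k_h), (d_h2, k_h2) = derivs(1e-3), derivs(5e-4)
        first = (4 * d_h2 - d_h) / 3
        second = (4 * k_h2 - k_h) / 3
        assert first == pytest.approx(D, rel=1e-6)
        assert 3.0 * second / D**2 == pytest.approx(K, rel=1e-6)


class TestSignals:
    def test_b_zero_normalization(self):
        sig = cm.synthesize_signal(toy_axons(), [0.0, 1.0])
        assert np.allclose(sig.S[0], 1.0)

    def test_single_gaussian_is_pure_exponential(self):
        t = np.array([10.0])
        a = cm.AxonCumulants(t=t, D=np.array([1.5]), K=np.array([0.0]), f=1.0)
        b = np.array([0.0, 0.5, 1.0, 2.0])
        sig = cm.synthesize_signal([a], b)
        assert np.allclose(np.log(sig.S[:, 0]), -b * 1.5, atol=1e-14)

    def test_two_axon_closed_form(self):
        sig = cm.synthesize_signal(toy_axons(), [1.0])
        expected = 0.5 * math.exp(-1.0) + 0.5 * math.exp(-2.0)
        assert sig.S[0, 0] == pytest.approx(expected, abs=1e-14)

    def test_monotonicity_warning_at_large_b(self):
        t = np.array([10.0])
        a = cm.AxonCumulants(t=t, D=np.array([2.0]), K=np.array([1.0]), f=1.0)
        with pytest.warns(UserWarning, match="monotonicity"):
            cm.synthesize_signal([a], [2.0])


class TestDkiWlls:
    B_PROTOCOL = np.array([0.0, 0.4, 1.0, 1.5])

    def test_single_gaussian_k_zero(self):
        t = np.array([10.0])
        a = cm.AxonCumulants(t=t, D=np.array([1.5]), K=np.array([0.0]), f=1.0)
        sig = cm.synthesize_signal([a], self.B_PROTOCOL)
        D, K = cm.fit_dki_wlls(sig)
        assert D[0] == pytest.approx(1.5, abs=1e-10)
        assert K[0] == pytest.approx(0.0, abs=1e-10)

    def test_recovers_ensemble_cumulants_small_spread(self):
        t = np.array([20.0])
        axons = [
            cm.AxonCumulants(t=t, D=np.array([d]), K=np.array([0.1]), f=0.25)
            for d in (1.40, 1.45, 1.50, 1.55)
        ]
        sig = cm.synthesize_signal(axons, self.B_PROTOCOL)
        D, K = cm.fit_dki_wlls(sig)
        assert D[0] == pytest.approx(cm.ensemble_D(axons)[0], rel=0.01)
        assert K[0] == pytest.approx(cm.ensemble_K(axons)[0][0], rel=0.05)

    def test_ten_axon_truncation_error_bounds(self):
        rng = np.random.default_rng(13)
        t = np.array([20.0, 40.0])
        f = rng.dirichlet(np.ones(10))
        axons = [
            cm.AxonCumulants(t=t, D=rng.uniform(1.2, 1.8, t.size),
                             K=rng.uniform(0.0, 0.4, t.size), f=fi)
            for fi in f
        ]
        sig = cm.synthesize_signal(axons, self.B_PROTOCOL)
        D, K = cm.fit_dki_wlls(sig)
        D_ref = cm.ensemble_D(axons)
        K_ref = cm.ensemble_K(axons)[0]
        assert np.all(np.abs(D / D_ref - 1) < 0.02)
        assert np.all(np.abs(K - K_ref) < 0.05 * np.maximum(K_ref, 0.1))

    def test_insufficient_b_values_rejected(self):
        t = np.array([10.0])
        a = cm.AxonCumulants(t=t, D=np.array([1.5]), K=np.array([0.0]), f=1.0)
        with pytest.raises(ValueError):
            cm.fit_dki_wlls(cm.synthesize_signal([a], [0.0, 1.0]))


class TestDispersionProjection:
    @pytest.mark.parametrize("kappa", [15.4, 4.7, 1.65])
    def test_gaussian_stick_projection_scales_with_cos2(self, kappa):
        # an ideal stick (free 1d diffusion along its axis) dispersed by a
        # Watson distribution: D(z) / D(axis) -> <cos^2 psi>
        from axondiff.substrate import watson_mean_cos2

        t = 10.0
        D0 = 2.0
        rec = analytic_record((1e-12, 1e-12, 2 * D0 * t), t)
        axons = cm.dispersed_ensemble([rec], [1.0], kappa, n_draws=4000, seed=5)
        D = cm.ensemble_D(axons)[0]
        per_draw = np.array([a.D[0] for a in axons])
        se = per_draw.std() / math.sqrt(per_draw.size)
        assert abs(D - D0 * watson_mean_cos2(kappa)) < 3 * se
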