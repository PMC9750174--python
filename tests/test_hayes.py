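"""Thin-layer elastic model: kernel, correction factor, inversion, RMSE."""

import numpy as np
import pytest

from indentmap._layer import kappa_solve, layer_compliance
from indentmap.hayes import (
    HERTZ_KAPPA,
    ExtrapolationError,
    HayesIndentation,
    HayesInput,
    KappaTable,
    contact_radius,
    fit_ramp_rmse,
    hayes_force,
    instantaneous_modulus,
    kappa,
)
from indentmap.simulate import simulate_relaxation_curve


class TestContactRadius:
    @pytest.mark.parametrize("R,w0,a", [(150, 6, 30.0), (150, 13.5, 45.0), (150, 0, 0.0)])
    def test_hertzian_values(self, R, w0, a):
        assert contact_radius(R, w0) == pytest.approx(a)

    def test_depth_beyond_radius_raises(self):
        with pytest.raises(ValueError, match="indenter radius"):
            contact_radius(150.0, 150.0)


class TestLayerKernel:
    def test_compliance_matches_boundary_value_solution(self):
        """Independent oracle: solve the layer elasticity equations per
        Hankel mode with a Love stress function and compare the surface
        compliance weight against the closed form used by the solver."""
        import sympy as sp

        z, lam, nu, G = sp.symbols("z lam nu G", positive=True)
        A, B, C, D, p, h = sp.symbols("A B C D p h")
        f = (A + B * z) * sp.exp(-lam * z) + (C + D * z) * sp.exp(lam * z)
        fp, fpp, fppp = (sp.diff(f, z, k) for k in (1, 2, 3))
        u_r = lam * fp / (2 * G)
        u_z = ((1 - 2 * nu) * fpp - 2 * (1 - nu) * lam**2 * f) / (2 * G)
        s_zz = (1 - nu) * fppp - (2 - nu) * lam**2 * fp
        s_rz = lam * (nu * fpp + (1 - nu) * lam**2 * f)
        sol = sp.solve(
            [sp.Eq(s_rz.subs(z, 0), 0), sp.Eq(s_zz.subs(z, 0), -p),
             sp.Eq(u_r.subs(z, h), 0), sp.Eq(u_z.subs(z, h), 0)],
            [A, B, C, D], dict=True)[0]
        uz0 = sp.simplify(u_z.subs(z, 0).subs(sol))
        E = 2 * G * (1 + nu)
        w_bvp = sp.lambdify((lam, h, nu),
                            sp.simplify(uz0 / (2 * (1 - nu**2) * p / (E * lam))),
                            "numpy")
        for nu_ in (0.3, 0.45, 0.5 - 1e-9):
            for x in (0.05, 0.3, 1.0, 3.0, 8.0):
                assert layer_compliance(x, nu_) == pytest.approx(
                    float(w_bvp(x, 1.0, nu_)), rel=1e-9)

    def test_halfspace_limit(self):
        assert layer_compliance(25.0, 0.5) == pytest.approx(1.0, abs=1e-12)


class TestKappa:
    def test_hertz_limit(self):
        assert kappa(1e-6, 0.5) == pytest.approx(HERTZ_KAPPA, rel=0.01)
        assert kappa_solve(1e-4, 0.5) == pytest.approx(HERTZ_KAPPA, rel=1e-4)

    def test_monotone_in_aspect(self):
        k1, k05 = kappa(1.0, 0.5), kappa(0.5, 0.5)
        assert k1 > k05 > HERTZ_KAPPA

    def test_monotone_in_nu(self):
        assert kappa(1.0, 0.5) > kappa(1.0, 0.4) > kappa(1.0, 0.3)

    def test_table_agrees_with_solver_off_nodes(self):
        """Interpolated kappa vs the direct contact solver at aspect ratios
        that are not table nodes (2% band, nu = 0.5)."""
        rng = np.random.default_rng(42)
        for aspect in np.exp(rng.uniform(np.log(0.2), np.log(2.0), 8)):
            assert kappa(aspect, 0.5) == pytest.approx(
                kappa_solve(float(aspect), 0.5), rel=0.02)

    def test_incompressible_thin_layer_scaling(self):
        """For nu=0.5 the confined-layer stiffening grows ~ (a/h)^3."""
        k4, k2 = kappa_solve(4.0, 0.5), kappa_solve(2.0, 0.5)
        assert 2.0 < (k4 - HERTZ_KAPPA) / (k2 - HERTZ_KAPPA) < 8.5

    def test_out_of_range_aspect_raises(self):
        with pytest.raises(ExtrapolationError):
            kappa(50.0, 0.5)

    def test_table_shape_validation(self):
        with pytest.raises(ValueError, match="shape"):
            KappaTable(np.array([0.1, 1.0]), np.array([0.5]), np.ones((3, 1)))


class TestInversion:
    def test_hertz_oracle_thick_layer(self):
        """Half-space limit: force from the Hertz closed form recovers E."""
        E_true, R, w0, h = 10.0, 150.0, 6.0, 1e4
        P = 4.0 / 3.0 * E_true / (1 - 0.5**2) * np.sqrt(R) * w0**1.5 * 1e-6
        res = instantaneous_modulus(HayesInput(P=P, w0=w0, h=h, R=R, nu=0.5))
        assert res.E == pytest.approx(E_true, rel=0.01)

    def test_hertz_kappa_algebraic_identity(self):
        """With kappa forced to 2/3: E = 3 P (1-nu^2) / (4 a w0)."""
        P, w0, h, R, nu = 0.05, 10.0, 50.0, 150.0, 0.5
        res = instantaneous_modulus(HayesInput(P, w0, h, R, nu),
                                    kappa_fn=lambda a, n: HERTZ_KAPPA)
        a = contact_radius(R, w0)
        assert res.E == pytest.approx(3 * P * (1 - nu**2) / (4 * a * w0) * 1e6,
                                      rel=1e-12)

    def test_forward_inverse_round_trip_single(self):
        E, h = 12.0, 50.0
        c = simulate_relaxation_curve(E, h)
        res = HayesIndentation(c, h).fit()
        assert res.contact.E == pytest.approx(E, rel=0.02)

    def test_nonpositive_force_rejected(self):
        with pytest.raises(ValueError, match="force"):
            HayesInput(P=0.0, w0=10.0, h=50.0)

    def test_ignoring_correction_biases_thin_layers_high(self):
        """A Hertz analysis of a thin bonded layer overestimates E."""
        E, h = 12.0, 40.0  # aspect ~ 0.87 at 20% strain
        c = simulate_relaxation_curve(E, h)
        corrected = HayesIndentation(c, h).fit().contact.E
        naive = HayesIndentation(c, h,
                                 kappa_fn=lambda a, n: HERTZ_KAPPA).fit().contact.E
        assert naive > corrected * 1.5

    def test_modulus_independent_of_thickness(self):
        """Recovered E shows no thickness correlation when true E is fixed
        (the decoupling the site-specific thickness correction buys).
        Run at generator-default measurement noise: with exact arithmetic a
        correlation coefficient would only measure the shape of the ~0.05%
        numerical residual, not the decoupling."""
        rng = np.random.default_rng(7)
        hs = rng.uniform(35.0, 95.0, 100)
        Es = [HayesIndentation(
                  simulate_relaxation_curve(12.0, h, noise=0.047,
                                            sample_noise=0.001, rng=rng),
                  h).fit().contact.E
              for h in hs]
        r = np.corrcoef(hs, Es)[0, 1]
        assert abs(r) < 0.2
        # and the recovered values scatter around the true modulus
        assert np.mean(Es) == pytest.approx(12.0, rel=0.02)


class TestRampRMSE:
    def test_noiseless_self_consistency(self):
        c = simulate_relaxation_curve(12.0, 50.0)
        res = HayesIndentation(c, 50.0).fit()
        assert res.contact.rmse < 1e-6

    def test_multiplicative_noise_sets_rmse_scale(self):
        """2% per-sample force noise puts the apparent-modulus RMSE at
        ~0.02 E (averaged over 100 simulated records)."""
        E, h = 12.0, 50.0
        rng = np.random.default_rng(3)
        vals = []
        for _ in range(100):
            c = simulate_relaxation_curve(E, h, sample_noise=0.02, rng=rng)
            vals.append(fit_ramp_rmse(c, h, E_fit=E))
        assert np.mean(vals) == pytest.approx(0.02 * E, rel=0.15)

    def test_too_few_ramp_points_raises(self):
        from indentmap.curves import CurveMeta, IndentationCurve

        t = np.array([0.0, 0.4, 0.8, 1.0, 20.0, 91.0])
        w = np.array([0.0, 8.0, 16.0, 20.0, 20.0, 20.0])
        F = np.array([0.0, 0.02, 0.05, 0.06, 0.04, 0.03])
        c = IndentationCurve(t, w, F, CurveMeta())
        with pytest.raises(ValueError, match="5 usable ramp points"):
            fit_ramp_rmse(c, 50.0, E_fit=10.0)


def test_parameter_recovery_sweep():
    """Noiseless forward simulation then inversion over the modulus and
    thickness grid recovers E within 2% everywhere."""
    for E in (2.0, 5.0, 10.0, 20.0, 40.0):
        for h in (35.0, 50.0, 70.0, 100.0):
            c = simulate_relaxation_curve(E, h)
            res = HayesIndentation(c, h).fit()
            assert res.contact.E == pytest.approx(E, rel=0.02), (E, h)


def test_summary_reports_fit(capsys):
    c = simulate_relaxation_curve(12.0, 50.0)
    res = HayesIndentation(c, 50.0).fit()
    text = res.summary()
    assert "E (instantaneous)" in text and "12.0" in text
    assert res.params["E_MPa"] == res.contact.E
    # predict() reproduces the forward force at the fitted modulus
    w = np.array([5.0, 10.0])
    assert np.allclose(res.predict(w), hayes_force(res.contact.E, w, 50.0))
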