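"""SAXS form factors, chi-square fitting and Debye-equation scattering."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import integrate
from scipy.special import j1

from fapkit.helix import AtomicModel, HelicalParams
from fapkit.saxs import (
    CylinderParams,
    HydrationConfig,
    SAXSCurve,
    atomic_debye_intensity,
    cross_section_report,
    debye_chain_ff,
    elliptical_cylinder_ff,
    excess_scattering_lengths,
    fit_cylinder_model,
    fit_scale_offset,
    hydration_shell,
    model_intensity,
    read_saxs,
)
from fapkit.synth import synth_helical_trace, synth_saxs_curve


class TestChainFormFactor:
    def test_normalized_at_zero(self):
        assert debye_chain_ff(np.array([0.0]), Rg=3.0)[0] == pytest.approx(1.0)

    def test_closed_form_at_x_equals_one(self):
        # P = 2(e^-1 - 1 + 1)/1 = 2/e
        assert debye_chain_ff(np.array([1.0]), Rg=1.0)[0] == pytest.approx(
            2 * np.exp(-1), rel=1e-12
        )

    def test_large_x_asymptote(self):
        q = np.array([200.0])
        x = (q * 1.0) ** 2
        assert (debye_chain_ff(q, Rg=1.0) * x)[0] == pytest.approx(2.0, rel=1e-3)

    def test_small_x_series_matches_expm1_oracle(self):
        # cancellation-free reference: P = 2 (expm1(-x) + x) / x^2
        x = np.array([1e-6, 1e-4, 9.9e-3, 1.01e-2, 0.1])
        q = np.sqrt(x)  # Rg = 1
        want = 2 * (np.expm1(-x) + x) / x**2
        assert np.allclose(debye_chain_ff(q, Rg=1.0), want, rtol=1e-10)

    def test_guinier_limit_recovers_rg(self):
        """-3 d ln I / d(q^2) -> Rg^2 for q Rg <= 0.3."""
        Rg = 3.0
        q = np.linspace(0.01, 0.1, 20)  # q*Rg <= 0.3
        P = debye_chain_ff(q, Rg)
        slope = np.polyfit(q**2, np.log(P), 1)[0]
        assert -3 * slope == pytest.approx(Rg**2, rel=0.01)


class TestCylinderFormFactor:
    def test_normalized_at_zero(self):
        assert elliptical_cylinder_ff(np.array([0.0]), R=1.7, eps=3.3)[0] == pytest.approx(1.0)

    def test_bounded_by_unity(self):
        q = np.geomspace(0.01, 6.0, 50)
        P = elliptical_cylinder_ff(q, R=1.7, eps=3.3)
        assert np.all(P >= 0) and np.all(P <= 1 + 1e-12)

    def test_circular_limit_matches_single_integral_oracle(self):
        """eps = 1 must agree with the closed-form circular-cylinder
        orientation average (adaptive single integral) to 1e-6 relative."""
        R, L, sigma = 2.0, 10.0, 0.5
        q_vals = np.linspace(0.2, 5.0, 12)  # q R <= 10

        def oracle(q):
            def integrand(alpha):
                u = q * np.sin(alpha) * R
                cross = 1.0 if u < 1e-12 else 2 * j1(u) / u
                x = q * L * np.cos(alpha) / 2
                axial = 1.0 if abs(x) < 1e-12 else np.sin(x) / x
                grading = np.exp(-((q * np.sin(alpha)) ** 2) * sigma**2 / 2)
                return (cross * axial * grading) ** 2 * np.sin(alpha)

            num, _ = integrate.quad(integrand, 0, np.pi / 2, epsabs=0, epsrel=1e-12, limit=400)
            return num  # /int sin = 1 over [0, pi/2]

        got = elliptical_cylinder_ff(q_vals, R=R, eps=1.0, L=L, sigma_surf=sigma)
        want = np.array([oracle(q) for q in q_vals])
        assert np.allclose(got, want, rtol=1e-6)

    def test_surface_grading_damps_scattering(self):
        q = np.geomspace(0.05, 5.0, 30)
        graded = elliptical_cylinder_ff(q, R=1.7, eps=3.3, sigma_surf=0.5)
        sharp = elliptical_cylinder_ff(q, R=1.7, eps=3.3, sigma_surf=0.0)
        assert np.all(graded <= sharp + 1e-15)


class TestModelIntensity:
    def test_zero_q_limit_is_sum_of_scales_plus_background(self):
        p = CylinderParams(R=1.7, eps=3.3, S_cyl=2.0, S_pol=0.5, b=0.25)
        assert model_intensity(np.array([0.0]), p)[0] == pytest.approx(2.75)

    def test_zero_scales_give_constant_background(self):
        p = CylinderParams(R=1.0, eps=1.0, S_cyl=0.0, S_pol=0.0, b=0.7)
        q = np.geomspace(0.1, 3, 10)
        assert np.allclose(model_intensity(q, p), 0.7)

    def test_matches_termwise_recomposition(self, rng):
        q = np.geomspace(0.05, 3, 25)
        for _ in range(5):
            p = CylinderParams(
                R=rng.uniform(1, 4), eps=rng.uniform(1, 4),
                S_cyl=rng.uniform(0.5, 2), S_pol=rng.uniform(0.1, 1),
                Rg=rng.uniform(1, 5), b=rng.uniform(0, 0.1),
            )
            want = (
                p.S_cyl * elliptical_cylinder_ff(q, p.R, p.eps, p.L, p.sigma_surf)
                + p.S_pol * debye_chain_ff(q, p.Rg)
                + p.b
            )
            assert np.allclose(model_intensity(q, p), want, rtol=1e-14)

    @pytest.mark.parametrize(
        "R,eps,axes",
        [
            (1.7, 3.3235, (3.4, 11.3)),  # UK4
            (3.5, 19.0 / 7.0, (7.0, 19.0)),  # F1
            (2.0, 1.0, (4.0, 4.0)),
        ],
    )
    def test_cross_section_reports_full_axes(self, R, eps, axes):
        got = cross_section_report(CylinderParams(R=R, eps=eps))
        assert got == pytest.approx(axes, rel=1e-3)


class TestCylinderFit:
    # reduced quadrature (64x32 nodes, converged to ~1e-3) keeps these fast
    QUAD = dict(n_alpha=64, n_phi=32)
    Q = np.geomspace(0.05, 3.0, 80)
    TRUE = CylinderParams(R=1.7, eps=3.3235, S_cyl=1.0, S_pol=0.3, Rg=3.0, b=1e-3)

    def test_noise_free_recovery_to_tenth_percent(self):
        I0 = model_intensity(self.Q, self.TRUE, **self.QUAD)
        curve = SAXSCurve(q=self.Q, I=I0, sigma=1e-6 * I0)
        init = replace(
            self.TRUE, R=self.TRUE.R * 1.3, eps=self.TRUE.eps * 1.3,
            S_cyl=1.3, S_pol=0.39, Rg=3.9, b=1.3e-3,
        )
        res = fit_cylinder_model(curve, init, **self.QUAD)
        assert res.chi2_red < 1e-6
        for name in ("R", "eps", "S_cyl", "S_pol", "Rg"):
            assert getattr(res.params, name) == pytest.approx(
                getattr(self.TRUE, name), rel=1e-3
            ), name

    def test_one_percent_noise_gives_unit_chi2(self):
        curve = synth_saxs_curve(self.TRUE, 0.01, self.Q, seed=11)
        init = replace(self.TRUE, R=2.1, eps=2.8, S_pol=0.2, Rg=4.0)
        res = fit_cylinder_model(curve, init, **self.QUAD)
        assert 0.5 <= res.chi2_red <= 2.0
        assert res.params.L == self.TRUE.L  # fixed by default mask

    def test_flat_background_data_drives_scales_to_zero(self):
        q = self.Q
        b = 0.5
        curve = SAXSCurve(q=q, I=np.full(len(q), b), sigma=np.full(len(q), 0.005))
        init = CylinderParams(R=1.5, eps=2.0, S_cyl=0.1, S_pol=0.05, Rg=2.0, b=0.4)
        res = fit_cylinder_model(curve, init, **self.QUAD)
        assert res.chi2_red == pytest.approx(0.0, abs=1e-4)
        assert res.params.S_cyl < 1e-4 * b and res.params.S_pol < 1e-4 * b
        assert res.params.b == pytest.approx(b, rel=1e-3)

    def test_underdetermined_fit_rejected(self):
        q = np.array([0.1, 0.2, 0.3])
        curve = SAXSCurve(q=q, I=np.ones(3), sigma=np.ones(3))
        with pytest.raises(ValueError, match="points"):
            fit_cylinder_model(curve, CylinderParams())


class TestScaleOffset:
    def test_exact_affine_relation_recovered(self):
        q = np.linspace(0.1, 2, 30)
        model = np.exp(-(q**2))
        data = SAXSCurve(q=q, I=2.5 * model + 0.1, sigma=np.full(30, 0.01))
        scale, const, chi2 = fit_scale_offset(model, data)
        assert scale == pytest.approx(2.5, rel=1e-10)
        assert const == pytest.approx(0.1, rel=1e-8)
        assert chi2 == pytest.approx(0.0, abs=1e-16)

    def test_matches_weighted_regression_oracle(self, rng):
        q = np.linspace(0.1, 2, 50)
        model = np.exp(-(q**2))
        sigma = np.full(50, 0.02)
        data = SAXSCurve(q=q, I=model + rng.normal(0, 0.02, 50), sigma=sigma)
        scale, const, _ = fit_scale_offset(model, data)
        # independent oracle: statsmodels WLS
        import statsmodels.api as sm

        X = sm.add_constant(model)
        fit = sm.WLS(data.I, X, weights=1 / sigma**2).fit()
        assert scale == pytest.approx(fit.params[1], rel=1e-8)
        assert const == pytest.approx(fit.params[0], rel=1e-8)
        se = fit.bse[1]
        assert abs(scale - 1.0) < 3 * se

    def test_constant_model_is_degenerate(self):
        q = np.linspace(0.1, 1, 10)
        data = SAXSCurve(q=q, I=np.ones(10), sigma=np.ones(10))
        with pytest.raises(ValueError, match="degenerate"):
            fit_scale_offset(np.ones(10), data)


class TestDebyeScattering:
    def test_single_scatterer_is_flat_f_squared(self):
        m = AtomicModel(coords=np.zeros((1, 3)), f=np.array([3.0]))
        curve = atomic_debye_intensity(m, np.geomspace(0.1, 5, 10))
        assert np.allclose(curve.I, 9.0)

    def test_two_unit_scatterers_closed_form(self):
        d_A = 10.0
        m = AtomicModel(coords=np.array([[0, 0, 0], [d_A, 0, 0.0]]), f=np.ones(2))
        q = np.linspace(0.1, 5, 40)  # nm^-1
        curve = atomic_debye_intensity(m, q)
        x = q * d_A / 10.0
        assert np.allclose(curve.I, 2 * (1 + np.sin(x) / x), rtol=1e-12)
        # at q d = pi the cross term vanishes exactly
        q_pi = np.array([np.pi / (d_A / 10.0)])
        assert atomic_debye_intensity(m, q_pi).I[0] == pytest.approx(2.0, rel=1e-12)

    def test_histogram_matches_exact_double_sum(self, rng):
        coords = rng.uniform(0, 30, size=(100, 3))
        f = rng.uniform(0.5, 2.0, 100)
        m = AtomicModel(coords=coords, f=f)
        q = np.linspace(0.1, 5.0, 25)
        exact = atomic_debye_intensity(m, q, method="exact")
        hist = atomic_debye_intensity(m, q, method="histogram", bin_width_A=0.05)
        assert np.allclose(hist.I, exact.I, rtol=5e-3)

    def test_element_table_excess_lengths(self):
        m = AtomicModel(coords=np.zeros((2, 3)), elements=["C", "O"])
        f = excess_scattering_lengths(m)
        assert f[0] == pytest.approx(6.0 - 0.334 * 16.44)
        assert f[1] == pytest.approx(8.0 - 0.334 * 9.13)

    def test_hydration_shell_surrounds_model(self):
        m = AtomicModel(coords=np.zeros((1, 3)), f=np.array([10.0]))
        shell = hydration_shell(m, HydrationConfig(spacing_A=1.0))
        d = np.linalg.norm(shell.coords, axis=1)
        assert np.all(d >= 1.8 - 1e-9) and np.all(d <= 4.8 + 1e-9)
        assert np.all(shell.f > 0)

    def test_long_fibril_scattering_is_length_insensitive(self):
        """Per-layer intensity of an assembled fibril converges once the
        fibril is much longer than 2 pi / q_min, the rationale for fixing L."""
        p = HelicalParams(4.8, -2.0)
        q = np.geomspace(0.3, 2.0, 15)
        m150, _ = synth_helical_trace(p, 150, atoms_per_layer=12, seed=5)
        m225, _ = synth_helical_trace(p, 225, atoms_per_layer=12, seed=5)
        I150 = atomic_debye_intensity(m150, q, method="histogram").I / 150
        I225 = atomic_debye_intensity(m225, q, method="histogram").I / 225
        assert np.allclose(I150, I225, rtol=0.05)


class TestIO:
    def test_three_column_reader_skips_headers(self, tmp_path):
        path = tmp_path / "curve.dat"
        path.write_text("# synthetic\nq I sigma\n0.1 5.0 0.05\n0.2 4.0 0.04\n0.3 3.0 0.03\n")
        curve = read_saxs(path)
        assert len(curve) == 3
        assert curve.q[1] == pytest.approx(0.2)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            SAXSCurve(q=np.array([0.1, 0.2]), I=np.ones(2), sigma=np.array([0.1, 0.0]))
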