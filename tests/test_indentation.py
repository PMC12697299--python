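"""Hertz conical-contact model and fitting tests."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mcfnano import (
    CurveSpec,
    FitConfig,
    ForceCurve,
    ProbeParams,
    batch_fit,
    fit_hertz_cone,
    force_indentation,
    hertz_force,
    simulate_force_curve,
)


class TestHertzForce:
    def test_printed_value(self, probe):
        """1 GPa at 100 nm depth, nu = 0.3, alpha = 10 deg:
        hand evaluation 0.63662 x 1.098901 x 0.176327 x 1e9 Pa x 1e-14 m^2
        = 1.23355e-6 N = 1233.55 nN."""
        assert hertz_force(1.0, 100.0, probe) == pytest.approx(
            1233.55, abs=0.05
        )

    def test_zero_depth_zero_force(self, probe):
        assert hertz_force(2.0, 0.0, probe) == 0.0

    def test_poisson_ratio_structure(self):
        f0 = hertz_force(1.0, 50.0, ProbeParams(poisson=0.0))
        f3 = hertz_force(1.0, 50.0, ProbeParams(poisson=0.3))
        assert f3 / f0 == pytest.approx(1.0 / (1.0 - 0.09), rel=1e-12)

    @given(
        st.floats(0.05, 5.0), st.floats(1.0, 300.0), st.floats(0.1, 10.0)
    )
    def test_homogeneity(self, e, delta, c):
        probe = ProbeParams()
        assert hertz_force(c * e, delta, probe) == pytest.approx(
            c * hertz_force(e, delta, probe), rel=1e-12
        )
        assert hertz_force(e, c * delta, probe) == pytest.approx(
            c**2 * hertz_force(e, delta, probe), rel=1e-12
        )

    def test_negative_depth_rejected(self, probe):
        with pytest.raises(ValueError):
            hertz_force(1.0, -1.0, probe)

    def test_probe_invariants(self):
        with pytest.raises(ValueError):
            ProbeParams(half_angle_deg=95.0)
        with pytest.raises(ValueError):
            ProbeParams(poisson=0.6)


class TestForceIndentation:
    def test_recovers_generative_depth(self, probe):
        spec = CurveSpec(
            n_samples=500, force_noise_sd=0.0, baseline_slope_range=(0, 0)
        )
        curve, truth = simulate_force_curve(0.5, spec, probe, seed=2)
        delta, force = force_indentation(curve, truth["z0_nm"])
        np.testing.assert_allclose(
            force, hertz_force(0.5, delta, probe), atol=1e-9
        )

    def test_lever_correction_arithmetic(self):
        z = np.linspace(0.0, 20.0, 201)
        curve = ForceCurve(z, np.full_like(z, 100.0))
        delta, force = force_indentation(
            curve, 0.0, stiffness_correction=50.0
        )
        # delta = (z - z0) - F/k; at z = 10 nm: 10 - 100/50 = 8 nm
        expected = z - 100.0 / 50.0
        np.testing.assert_allclose(delta, expected[expected >= 0])
        assert 8.0 in np.round(delta, 9)

    def test_infinite_stiffness_limit(self, probe):
        spec = CurveSpec(n_samples=300, force_noise_sd=0.0)
        curve, truth = simulate_force_curve(0.3, spec, probe, seed=8)
        d0, f0 = force_indentation(curve, truth["z0_nm"])
        d1, f1 = force_indentation(
            curve, truth["z0_nm"], stiffness_correction=1e15
        )
        np.testing.assert_allclose(d0, d1, atol=1e-9)

    def test_z0_outside_span_rejected(self, probe):
        spec = CurveSpec(n_samples=300, force_noise_sd=0.0)
        curve, _ = simulate_force_curve(0.3, spec, probe, seed=8)
        with pytest.raises(ValueError, match="span"):
            force_indentation(curve, 1e6)


class TestFitHertzCone:
    def test_noise_free_exact_recovery(self, probe):
        spec = CurveSpec(
            n_samples=4000, force_noise_sd=0.0,
            baseline_slope_range=(0.0, 0.0),
        )
        curve, truth = simulate_force_curve(0.5, spec, probe, seed=1)
        fit = fit_hertz_cone(curve, probe)
        assert fit.converged
        assert fit.E_gpa == pytest.approx(0.5, rel=1e-6)
        dz = spec.span_nm / (spec.n_samples - 1)
        assert abs(fit.z0_nm - truth["z0_nm"]) <= dz

    def test_noise_free_with_baseline_drift(self, probe):
        spec = CurveSpec(
            n_samples=4000, force_noise_sd=0.0,
            baseline_slope_range=(0.004, 0.004),
        )
        curve, truth = simulate_force_curve(0.8, spec, probe, seed=4)
        fit = fit_hertz_cone(curve, probe)
        assert fit.converged
        assert fit.E_gpa == pytest.approx(0.8, rel=1e-4)

    def test_monte_carlo_mean_within_two_percent(self, probe):
        """100 noisy curves at E = 0.30 GPa, 5% force noise: the mean
        fitted modulus recovers the truth within 2%."""
        spec = CurveSpec(n_samples=2000)
        fits = []
        for i in range(100):
            curve, _ = simulate_force_curve(0.30, spec, probe, seed=i)
            fit = fit_hertz_cone(curve, probe)
            assert fit.converged
            fits.append(fit.E_gpa)
        assert np.mean(fits) == pytest.approx(0.30, rel=0.02)

    def test_pure_baseline_not_converged(self, probe):
        z = np.linspace(0.0, 270.0, 1000)
        rng = np.random.default_rng(0)
        curve = ForceCurve(z, 0.002 * z + rng.normal(0, 0.05, z.size))
        fit = fit_hertz_cone(curve, probe)
        assert not fit.converged

    def test_threshold_detector_agrees(self, probe):
        spec = CurveSpec(n_samples=2000, force_noise_sd=2.0)
        curve, _ = simulate_force_curve(0.5, spec, probe, seed=17)
        scan = fit_hertz_cone(curve, probe)
        thresh = fit_hertz_cone(
            curve, probe, FitConfig(contact_detector="threshold")
        )
        assert thresh.converged
        assert thresh.E_gpa == pytest.approx(scan.E_gpa, rel=0.05)


class TestBatchFit:
    def test_identical_noise_free_curves_sd_zero(self, probe):
        spec = CurveSpec(
            n_samples=1000, force_noise_sd=0.0,
            baseline_slope_range=(0.0, 0.0),
        )
        curve, _ = simulate_force_curve(0.4, spec, probe, seed=3)
        fits, summary = batch_fit([curve] * 20, probe)
        assert len(fits) == 20
        assert summary.loc[0, "sd_E_GPa"] == pytest.approx(0.0, abs=1e-12)
        assert summary.loc[0, "n"] == 20

    def test_mixed_convergence_bookkeeping(self, probe):
        spec = CurveSpec(n_samples=1000)
        good, _ = simulate_force_curve(0.4, spec, probe, seed=3)
        z = np.linspace(0.0, 270.0, 1000)
        bad = ForceCurve(z, np.zeros_like(z))
        fits, summary = batch_fit([good, bad, good], probe)
        assert fits["converged"].sum() == 2
        assert summary.loc[0, "n"] == 2

    def test_all_non_converged_warns_empty_summary(self, probe):
        z = np.linspace(0.0, 270.0, 500)
        bad = ForceCurve(z, np.zeros_like(z))
        with pytest.warns(UserWarning, match="no curve converged"):
            fits, summary = batch_fit([bad, bad], probe)
        assert summary.empty

    def test_empty_input_rejected(self, probe):
        with pytest.raises(ValueError):
            batch_fit([], probe)


class TestForceCurveInvariants:
    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            ForceCurve(np.arange(200.0), np.arange(199.0))

    def test_short_curve_rejected(self):
        with pytest.raises(ValueError, match="100"):
            ForceCurve(np.arange(50.0), np.arange(50.0))

    def test_non_monotone_displacement_rejected(self):
        z = np.linspace(0, 100, 200)
        z[100] = 0.0
        with pytest.raises(ValueError, match="monotone"):
            ForceCurve(z, np.zeros_like(z))
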