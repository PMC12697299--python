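"""Generator tests: group defaults, rendering, force-curve simulation."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal

from mcfnano import (
    CurveSpec,
    FibrilSpec,
    GROUP_LABELS,
    ImageSpec,
    ProbeParams,
    default_group_params,
    render_fibril_image,
    simulate_dataset,
    simulate_force_curve,
)
from mcfnano.synthgen import truncated_normal


class TestGroupDefaults:
    @pytest.mark.parametrize(
        "label, d_mean, d_sd, e_mean",
        [
            ("adult-control-0N", 70.0, 9.0, 0.30),
            ("adult-control-4N", 70.0, 9.0, 0.39),
            ("adult-HLU-0N", 71.0, 13.0, 0.32),
            ("adult-HLU-4N", 76.0, 7.0, 0.33),
            ("aged-control-0N", 77.0, 11.0, 0.74),
            ("aged-control-4N", 76.0, 12.0, 0.67),
            ("aged-HLU-0N", 74.0, 11.0, 0.77),
            ("aged-HLU-4N", 77.0, 11.0, 0.75),
        ],
    )
    def test_published_group_values(self, label, d_mean, d_sd, e_mean):
        p = default_group_params(label)
        assert p.d_mean == d_mean
        assert p.d_sd == d_sd
        assert p.modulus_mean == e_mean

    def test_all_labels_satisfy_invariants(self):
        for label in GROUP_LABELS:
            p = default_group_params(label)
            assert p.d_mean > 0 and p.d_sd >= 0
            assert p.modulus_mean > 0 and p.angle_sd >= 0
            assert min(
                p.n_mice, p.sites_per_mouse, p.fibrils_dspacing_per_site,
                p.fibrils_orientation_per_site, p.indents_per_site,
            ) >= 1

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown group"):
            default_group_params("juvenile-control-0N")

    def test_overrides_apply(self):
        p = default_group_params("adult-control-0N", n_mice=2)
        assert p.n_mice == 2


class TestRenderFibrilImage:
    def test_known_period_recovered_by_cycle_counting(self):
        """Noise-free horizontal fibril: count modulation cycles along the
        axis; period = span / cycles must match the requested 67 nm."""
        gp = default_group_params("adult-control-0N")
        spec = ImageSpec(
            n_pixels=512, scan_size_nm=2500.0, noise_sd=0.0, bow_amplitude=0.0
        )
        fib = FibrilSpec(1250.0, 1250.0, 0.0, 2000.0, 200.0, 67.0)
        amp, _, truth = render_fibril_image(gp, spec, seed=0, fibrils=[fib])
        px = spec.pixel_size_nm
        row = int(round(1250.0 / px))
        c0 = int(round((1250.0 - 900.0) / px))
        c1 = int(round((1250.0 + 900.0) / px))
        profile = amp.values[row, c0:c1]
        peaks, _ = signal.find_peaks(profile - profile.mean())
        assert peaks.size >= 6
        span_nm = (peaks[-1] - peaks[0]) * px
        period = span_nm / (peaks.size - 1)
        assert period == pytest.approx(67.0, abs=px)
        assert truth.fibrils.loc[0, "d_nm"] == 67.0

    def test_same_seed_bit_identical(self):
        gp = default_group_params("aged-control-0N")
        spec = ImageSpec(n_pixels=128, scan_size_nm=1250.0)
        a1, h1, t1 = render_fibril_image(gp, spec, seed=7, n_fibrils=3)
        a2, h2, t2 = render_fibril_image(gp, spec, seed=7, n_fibrils=3)
        np.testing.assert_array_equal(a1.values, a2.values)
        np.testing.assert_array_equal(h1.values, h2.values)
        pd.testing.assert_frame_equal(t1.fibrils, t2.fibrils)

    def test_zero_fibrils_gives_pure_background(self):
        gp = default_group_params("adult-control-0N")
        spec = ImageSpec(
            n_pixels=128, scan_size_nm=1250.0, noise_sd=0.0, bow_amplitude=0.0
        )
        amp, _, truth = render_fibril_image(gp, spec, seed=0, n_fibrils=0)
        assert truth.fibrils.empty
        assert np.all(amp.values == 0.0)

    def test_unresolvable_period_rejected(self):
        gp = default_group_params("adult-control-0N", d_mean=45.0, d_sd=0.0)
        spec = ImageSpec(n_pixels=64, scan_size_nm=5000.0)  # 78 nm/px
        with pytest.raises(ValueError, match="resolve"):
            render_fibril_image(gp, spec, seed=0, n_fibrils=1)

    def test_pixel_size(self):
        assert ImageSpec().pixel_size_nm == pytest.approx(4.8828125)


class TestSimulateForceCurve:
    def test_printed_force_value(self, probe):
        """E = 1 GPa, nu = 0.3, alpha = 10 deg, delta = 100 nm ->
        F = (2/pi)(1e9/0.91) tan(10 deg) (1e-7 m)^2 = 1233.55 nN
        (hand-evaluated: 0.63662 * 1.098901 * 0.176327 * 1e9 * 1e-14)."""
        spec = CurveSpec(
            n_samples=2001, force_noise_sd=0.0,
            baseline_slope_range=(0.0, 0.0), max_indentation_nm=100.0,
            contact_offset_range_nm=(50.0, 50.0),
        )
        curve, truth = simulate_force_curve(1.0, spec, probe, seed=0)
        z0 = truth["z0_nm"]
        i = np.argmin(np.abs(curve.displacement_nm - (z0 + 100.0)))
        assert curve.displacement_nm[i] == pytest.approx(z0 + 100.0, abs=0.05)
        assert curve.force_nN[i] == pytest.approx(1233.55, rel=2e-3)

    def test_contact_onset_and_quadratic_law(self, probe, fast_curve_spec):
        spec = CurveSpec(
            n_samples=2000, force_noise_sd=0.0,
            baseline_slope_range=(0.0, 0.0),
        )
        curve, truth = simulate_force_curve(0.5, spec, probe, seed=3)
        z, f = curve.displacement_nm, curve.force_nN
        pre = z < truth["z0_nm"]
        assert np.all(f[pre] == 0.0)
        delta = z - truth["z0_nm"]
        i1 = np.argmin(np.abs(delta - 60.0))
        i2 = np.argmin(np.abs(delta - 120.0))
        assert f[i2] / f[i1] == pytest.approx(
            (delta[i2] / delta[i1]) ** 2, rel=1e-9
        )

    def test_noise_free_force_is_nondecreasing(self, probe):
        spec = CurveSpec(
            n_samples=500, force_noise_sd=0.0,
            baseline_slope_range=(0.0, 0.0),
        )
        curve, _ = simulate_force_curve(0.3, spec, probe, seed=11)
        assert np.all(np.diff(curve.force_nN) >= 0)

    def test_invalid_modulus_rejected(self, probe, fast_curve_spec):
        with pytest.raises(ValueError):
            simulate_force_curve(-1.0, fast_curve_spec, probe, seed=0)

    def test_curve_spec_invariants(self):
        with pytest.raises(ValueError):
            CurveSpec(n_samples=50)
        with pytest.raises(ValueError):
            CurveSpec(duration_s=0.001)  # travel cannot cover window


class TestSimulateDataset:
    def test_counts_and_determinism(self, tmp_path, probe, fast_curve_spec,
                                    small_image_spec):
        groups = [
            default_group_params(
                label, n_mice=1, sites_per_mouse=2, indents_per_site=3
            )
            for label in ("adult-control-0N", "adult-control-4N")
        ]
        ds1 = simulate_dataset(
            groups, small_image_spec, fast_curve_spec, probe, seed=5
        )
        assert len(ds1.images) == 2 * 1 * 2
        assert len(ds1.curves) == 2 * 1 * 2 * 3
        assert len(ds1.manifest) == 4
        assert len(ds1.truth.curves) == 12
        ds2 = simulate_dataset(
            groups, small_image_spec, fast_curve_spec, probe, seed=5
        )
        pd.testing.assert_frame_equal(ds1.manifest, ds2.manifest)
        pd.testing.assert_frame_equal(ds1.truth.curves, ds2.truth.curves)

    def test_truth_means_approach_group_params(self, rng):
        """Law of large numbers on the generative draws themselves."""
        vals = truncated_normal(rng, 70.0, 9.0, low=40.0, size=4000)
        assert vals.mean() == pytest.approx(70.0, abs=3 * 9.0 / np.sqrt(4000))
        mods = truncated_normal(rng, 0.74, 0.17, size=4000)
        assert mods.mean() == pytest.approx(
            0.74, abs=3 * 0.17 / np.sqrt(4000)
        )
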