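"""Segmentation, tracing, D-spacing and orientation measurement tests."""

import numpy as np
import pytest

from mcfnano import (
    FibrilSpec,
    FibrilTrace,
    ImageSpec,
    RasterImage,
    default_group_params,
    dspacing_from_profile,
    fibril_orientation,
    normalize_orientations,
    profile_along_trace,
    render_fibril_image,
    segment_fibrils,
    select_random_fibrils,
    trace_axis,
)
from mcfnano.morphometry import axial_mean_deg
from mcfnano.preprocess import flatten_lines, lowpass_amplitude


@pytest.fixture(scope="module")
def clean_field():
    """Low-noise rendered field with well-separated fibrils + truth."""
    gp = default_group_params("adult-control-0N", angle_sd=10.0)
    spec = ImageSpec(
        n_pixels=512, scan_size_nm=5000.0, noise_sd=0.02, bow_amplitude=0.1,
        fibrils_per_image=10,
    )
    amp, _, truth = render_fibril_image(gp, spec, seed=21, image_id="field")
    flat = flatten_lines(amp)
    return flat, truth, spec


def _straight_trace(r0, c0, r1, c1, n, px):
    rows = np.linspace(r0, r1, n)
    cols = np.linspace(c0, c1, n)
    steps = np.hypot(np.diff(rows), np.diff(cols))
    s = np.concatenate([[0.0], np.cumsum(steps)]) * px
    return FibrilTrace(0, np.column_stack([rows, cols]), s)


class TestSegmentation:
    def test_each_label_matches_one_truth_fibril(self, clean_field):
        flat, truth, spec = clean_field
        labels, ids = segment_fibrils(flat)
        assert len(ids) == len(truth.fibrils)
        px = spec.pixel_size_nm
        matched = set()
        for fid in ids:
            rows, cols = np.nonzero(labels == fid)
            cx, cy = cols.mean() * px, rows.mean() * px
            mid_x = (truth.fibrils.x0_nm + truth.fibrils.x1_nm) / 2
            mid_y = (truth.fibrils.y0_nm + truth.fibrils.y1_nm) / 2
            d = np.hypot(mid_x - cx, mid_y - cy)
            matched.add(int(d.idxmin()))
        assert len(matched) == len(ids)  # bijective match

    def test_pure_background_yields_no_labels(self):
        gp = default_group_params("adult-control-0N")
        spec = ImageSpec(n_pixels=256, scan_size_nm=2500.0)
        amp, _, _ = render_fibril_image(gp, spec, seed=3, n_fibrils=0)
        flat = flatten_lines(amp)
        with pytest.warns(UserWarning, match="no fibrils"):
            labels, ids = segment_fibrils(flat)
        assert ids == [] and labels.max() == 0

    def test_deterministic(self, clean_field):
        flat, _, _ = clean_field
        l1, i1 = segment_fibrils(flat)
        l2, i2 = segment_fibrils(flat)
        np.testing.assert_array_equal(l1, l2)
        assert i1 == i2

    def test_rejects_unflattened_and_lowpassed(self):
        raw = RasterImage(np.zeros((64, 64)), 5.0, "amplitude")
        with pytest.raises(ValueError, match="flatten"):
            segment_fibrils(raw)
        lp = lowpass_amplitude(flatten_lines(raw))
        with pytest.raises(ValueError, match="quantitative"):
            segment_fibrils(lp)


class TestTraceAxis:
    def test_horizontal_ribbon_arclength(self):
        labels = np.zeros((60, 240), int)
        labels[25:35, 20:220] = 1  # 200 px long
        trace = trace_axis(labels, 1, pixel_size_nm=10.0)
        assert trace.length_nm == pytest.approx(200 * 10.0, rel=0.02)

    def test_diagonal_line_arclength(self):
        labels = np.zeros((150, 150), int)
        idx = np.arange(100)
        labels[20 + idx, 20 + idx] = 1
        trace = trace_axis(labels, 1, pixel_size_nm=1.0)
        assert trace.length_nm == pytest.approx(99 * np.sqrt(2), rel=0.03)

    def test_endpoints_inside_region(self):
        labels = np.zeros((60, 240), int)
        labels[25:35, 20:220] = 1
        trace = trace_axis(labels, 1, pixel_size_nm=10.0)
        for pt in (trace.points[0], trace.points[-1]):
            r, c = int(round(pt[0])), int(round(pt[1]))
            assert labels[r, c] == 1

    def test_missing_label_rejected(self):
        with pytest.raises(ValueError, match="not present"):
            trace_axis(np.zeros((10, 10), int), 3, 1.0)


class TestProfileAndDSpacing:
    def test_constant_image_gives_constant_profile(self):
        img = RasterImage(
            np.full((50, 200), 5.0), 5.0, "amplitude", flattened=True
        )
        trace = _straight_trace(25, 10, 25, 190, 180, 5.0)
        s, v = profile_along_trace(img, trace, half_width_nm=10.0)
        np.testing.assert_allclose(v, 5.0, atol=1e-12)
        assert s.size == trace.points.shape[0]

    def test_rendered_fibril_autocorrelation_period(self):
        """Noise-free fibril at D = 67 nm: first autocorrelation peak of
        the along-axis profile sits at 67 nm +/- one pixel."""
        gp = default_group_params("adult-control-0N")
        spec = ImageSpec(
            n_pixels=512, scan_size_nm=2500.0, noise_sd=0.0, bow_amplitude=0.0
        )
        fib = FibrilSpec(1250.0, 1250.0, 0.0, 2000.0, 200.0, 67.0)
        amp, _, _ = render_fibril_image(gp, spec, seed=0, fibrils=[fib])
        flat = flatten_lines(amp)
        labels, ids = segment_fibrils(flat)
        trace = trace_axis(labels, ids[0], spec.pixel_size_nm)
        s, v = profile_along_trace(flat, trace, half_width_nm=10.0)
        x = v - v.mean()
        ac = np.correlate(x, x, mode="full")[x.size - 1:]
        step = np.median(np.diff(s))
        lo = int(40.0 / step)
        hi = int(100.0 / step)
        lag = lo + int(np.argmax(ac[lo:hi]))
        assert lag * step == pytest.approx(67.0, abs=step)

    @pytest.mark.parametrize("period", [67.0, 77.0])
    def test_pure_cosine_period(self, period):
        s = np.arange(0, 12 * period, 4.88)
        v = np.cos(2 * np.pi * s / period)
        m = dspacing_from_profile(s, v)
        assert m is not None
        assert m.d_spacing_nm == pytest.approx(period, abs=0.5)
        assert m.d_spacing_nm == pytest.approx(m.intervals_nm.mean())
        assert m.n_peaks >= 6

    def test_constant_profile_rejected(self):
        s = np.arange(0, 500, 5.0)
        assert dspacing_from_profile(s, np.full_like(s, 2.0)) is None

    def test_too_few_peaks_rejected(self):
        s = np.arange(0, 100, 5.0)
        v = np.cos(2 * np.pi * s / 70.0)  # < 2 full cycles
        assert dspacing_from_profile(s, v) is None


class TestOrientation:
    @pytest.mark.parametrize(
        "dr, dc, expected",
        [(0.0, 1.0, 0.0), (-1.0, 0.0, 90.0), (1.0, 0.0, 90.0)],
    )
    def test_axis_aligned(self, dr, dc, expected):
        n = 50
        rows = 100 + dr * np.arange(n)
        cols = 100 + dc * np.arange(n)
        tr = FibrilTrace(
            0, np.column_stack([rows, cols]), np.arange(n, dtype=float)
        )
        assert fibril_orientation(tr).angle_raw_deg == pytest.approx(
            expected, abs=1e-6
        )

    def test_rendered_fibril_at_30_degrees(self):
        gp = default_group_params("adult-control-0N")
        spec = ImageSpec(
            n_pixels=512, scan_size_nm=2500.0, noise_sd=0.02, bow_amplitude=0.1
        )
        fib = FibrilSpec(1250.0, 1250.0, 30.0, 1800.0, 200.0, 70.0)
        amp, _, _ = render_fibril_image(gp, spec, seed=5, fibrils=[fib])
        flat = flatten_lines(amp)
        labels, ids = segment_fibrils(flat)
        trace = trace_axis(labels, ids[0], spec.pixel_size_nm)
        assert fibril_orientation(trace).angle_raw_deg == pytest.approx(
            30.0, abs=1.0
        )

    def test_degenerate_trace_rejected(self):
        tr = FibrilTrace(
            0, np.full((5, 2), 3.0), np.arange(5, dtype=float) + 1
        )
        with pytest.raises(ValueError, match="degenerate"):
            fibril_orientation(tr)


class TestSelection:
    def test_sampling_contract(self):
        subset = select_random_fibrils(range(1, 51), n=20, seed=4)
        assert len(subset) == 20 == len(set(subset))
        assert set(subset) <= set(range(1, 51))

    def test_shortfall_returns_all_with_warning(self):
        with pytest.warns(UserWarning, match="only"):
            subset = select_random_fibrils(range(12), n=20, seed=0)
        assert subset == list(range(12))

    def test_same_seed_same_subset(self):
        a = select_random_fibrils(range(100), n=20, seed=9)
        b = select_random_fibrils(range(100), n=20, seed=9)
        assert a == b


class TestNormalizeOrientations:
    def test_arithmetic_case(self):
        np.testing.assert_allclose(
            normalize_orientations([10.0, 20.0, 30.0]), [-10.0, 0.0, 10.0]
        )

    def test_single_angle_maps_to_zero(self):
        np.testing.assert_allclose(normalize_orientations([37.0]), [0.0])

    def test_axial_wraparound_against_brute_force(self):
        """{85, -85}: axial mean must minimize summed squared axial
        distance; brute-force over a 0.01-degree grid gives 90 deg and
        deviations {-5, +5}."""
        angles = np.array([85.0, -85.0])

        def axial_dist(a, b):
            d = np.abs(a - b) % 180.0
            return np.minimum(d, 180.0 - d)

        grid = np.arange(-90.0, 90.0, 0.01)
        cost = [(axial_dist(angles, g) ** 2).sum() for g in grid]
        best = grid[int(np.argmin(cost))]
        assert axial_dist(best, 90.0) < 0.01
        dev = normalize_orientations(angles)
        assert sorted(dev) == pytest.approx([-5.0, 5.0], abs=1e-9)

    def test_axial_mean_of_deviations_is_zero(self, rng):
        for _ in range(20):
            angles = rng.uniform(-90.0, 90.0, size=rng.integers(2, 40))
            dev = normalize_orientations(angles)
            assert abs(axial_mean_deg(dev)) < 1e-6
            assert np.all(dev > -90.0 - 1e-12) and np.all(dev <= 90.0 + 1e-12)
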