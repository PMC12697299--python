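"""Synthetic AFM micrographs and indentation curves with known ground truth.

The generator emulates what the instrument records on a demineralized
murine tibia surface: tapping-mode amplitude/height rasters showing fields
of D-banded collagen fibrils, and contact-mode force-displacement ramps on
individual fibrils.  Every synthetic object carries a truth record (true
D-period, axis angle, modulus, contact point), so each analysis stage can
be validated by parameter recovery.

Conventions
-----------
Image rows are scan lines (y, increasing downward); columns are x.  Fibril
axis angles are measured counter-clockwise from the image horizontal in a
y-up frame and are axial (defined modulo 180 deg, reported in (-90, 90]).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .groups import GroupParams
from .indentation import ForceCurve, ProbeParams, hertz_force
from .raster import RasterImage, write_raster

__all__ = [
    "ImageSpec",
    "CurveSpec",
    "FibrilSpec",
    "TruthTable",
    "render_fibril_image",
    "simulate_force_curve",
    "simulate_dataset",
    "truncated_normal",
    "seed_for",
]


@dataclass(frozen=True)
class ImageSpec:
    """Geometry and noise model of one synthetic AFM scan.

    Defaults follow the acquisition settings of the study images
    (5 um x 5 um scans at 1,024 x 1,024 px); ``band_contrast`` is the
    D-band modulation depth A1 relative to the fibril body amplitude A0.
    """

    n_pixels: int = 1024
    scan_size_nm: float = 5000.0
    noise_sd: float = 0.05
    bow_amplitude: float = 0.4
    band_contrast: float = 0.3
    body_amplitude: float = 1.0
    fibrils_per_image: int = 12
    fibril_width_range_nm: tuple[float, float] = (80.0, 300.0)
    fibril_length_range_nm: tuple[float, float] = (1200.0, 3200.0)
    # applied to both the candidate and the occupancy map, so the
    # edge-to-edge clearance between ribbons is twice this value
    placement_gap_nm: float = 100.0

    def __post_init__(self) -> None:
        if self.n_pixels < 64:
            raise ValueError(f"n_pixels must be >= 64, got {self.n_pixels}")
        if self.scan_size_nm <= 0:
            raise ValueError("scan_size_nm must be > 0")
        if self.noise_sd < 0 or self.bow_amplitude < 0:
            raise ValueError("noise_sd and bow_amplitude must be >= 0")
        if not (0 <= self.band_contrast < 1):
            raise ValueError("band_contrast must lie in [0, 1)")

    @property
    def pixel_size_nm(self) -> float:
        return self.scan_size_nm / self.n_pixels


@dataclass(frozen=True)
class CurveSpec:
    """Sampling and disturbance model of one synthetic indentation ramp.

    The instrument ramps the piezo at ``speed_um_s`` for ``duration_s``
    (2.5 um/s x 4.8 s, 24,000 points by default); that travel includes the
    approach, so the recorded window simulated here spans the region around
    contact: from 0 to ``contact_offset_range[1] + max_indentation_nm``.
    ``force_noise_sd`` is absolute (nN); ``None`` means 5% of the peak
    elastic force of each curve.
    """

    n_samples: int = 24000
    duration_s: float = 4.8
    speed_um_s: float = 2.5
    max_indentation_nm: float = 150.0
    force_noise_sd: float | None = None
    contact_offset_range_nm: tuple[float, float] = (30.0, 120.0)
    baseline_slope_range: tuple[float, float] = (-0.005, 0.005)

    def __post_init__(self) -> None:
        if self.n_samples < 100:
            raise ValueError(f"n_samples must be >= 100, got {self.n_samples}")
        if self.max_indentation_nm <= 0:
            raise ValueError("max_indentation_nm must be > 0")
        if self.duration_s <= 0 or self.speed_um_s <= 0:
            raise ValueError("duration_s and speed_um_s must be > 0")
        # the piezo travel must cover the simulated displacement window
        travel_nm = self.speed_um_s * self.duration_s * 1e3
        if travel_nm < self.span_nm:
            raise ValueError(
                f"piezo travel {travel_nm:.0f} nm cannot cover the "
                f"simulated window {self.span_nm:.0f} nm"
            )

    @property
    def span_nm(self) -> float:
        return self.contact_offset_range_nm[1] + self.max_indentation_nm


@dataclass(frozen=True)
class FibrilSpec:
    """Explicit placement of a single fibril (for deterministic fixtures)."""

    center_x_nm: float
    center_y_nm: float
    angle_deg: float
    length_nm: float
    width_nm: float
    d_nm: float
    phase_rad: float = 0.0


@dataclass
class TruthTable:
    """Ground truth of a synthetic dataset.

    ``fibrils``: one row per rendered fibril (id, angle, D-period,
    centerline endpoints in nm).  ``curves``: one row per indentation
    (true modulus, contact point, baseline slope).  ``background`` maps
    image id to the per-line quadratic coefficient array (n_lines x 3).
    """

    fibrils: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=[
                "image_id", "fibril_id", "angle_deg", "d_nm", "width_nm",
                "length_nm", "x0_nm", "y0_nm", "x1_nm", "y1_nm",
            ]
        )
    )
    curves: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["curve_id", "E_gpa", "z0_nm", "baseline_slope"]
        )
    )
    background: dict = field(default_factory=dict)

    def merge(self, other: "TruthTable") -> "TruthTable":
        frames_f = [df for df in (self.fibrils, other.fibrils) if len(df)]
        frames_c = [df for df in (self.curves, other.curves) if len(df)]
        return TruthTable(
            fibrils=pd.concat(frames_f, ignore_index=True)
            if frames_f else self.fibrils,
            curves=pd.concat(frames_c, ignore_index=True)
            if frames_c else self.curves,
            background={**self.background, **other.background},
        )


def seed_for(master_seed: int, *indices: int) -> np.random.SeedSequence:
    """Deterministic seed-splitting rule: one child per index tuple.

    Every stage derives its generator from ``(master, group, mouse, site,
    stream, ...)`` so any unit of the hierarchy is independently
    reproducible.
    """
    return np.random.SeedSequence([int(master_seed), *map(int, indices)])


def truncated_normal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    low: float = 0.0,
    size: int | None = None,
):
    """Normal(mean, sd) conditioned on values > ``low`` (by rejection)."""
    if sd == 0:
        out = np.full(size or 1, float(mean))
        return out if size is not None else float(out[0])
    n = size or 1
    out = rng.normal(mean, sd, size=n)
    bad = out <= low
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out <= low
    return out if size is not None else float(out[0])


def _fold_axial(angle_deg: float) -> float:
    """Fold an axial angle into (-90, 90]."""
    a = float(angle_deg) % 180.0
    if a > 90.0:
        a -= 180.0
    return a


def _paint_fibril(
    amp: np.ndarray,
    height: np.ndarray,
    fib: FibrilSpec,
    spec: ImageSpec,
    occupancy: np.ndarray | None = None,
    gap_nm: float = 0.0,
    check_only: bool = False,
) -> np.ndarray | None:
    """Rasterize one fibril ribbon; return its (possibly widened) mask.

    With ``check_only`` nothing is painted: the footprint widened by
    ``gap_nm`` is returned for overlap testing against ``occupancy``.
    """
    px = spec.pixel_size_nm
    theta = math.radians(fib.angle_deg)
    # y-up angle -> y-down (row) frame
    ux, uy = math.cos(theta), -math.sin(theta)
    nx, ny = -uy, ux
    half_len = fib.length_nm / 2.0
    half_w = fib.width_nm / 2.0
    x0 = fib.center_x_nm - half_len * ux
    y0 = fib.center_y_nm - half_len * uy

    pad = half_w + gap_nm + 2 * px
    xs_nm = np.array([
        x0 + 0 * ux, x0 + fib.length_nm * ux,
    ])
    ys_nm = np.array([
        y0 + 0 * uy, y0 + fib.length_nm * uy,
    ])
    c_lo = max(int((xs_nm.min() - pad) / px), 0)
    c_hi = min(int((xs_nm.max() + pad) / px) + 2, spec.n_pixels)
    r_lo = max(int((ys_nm.min() - pad) / px), 0)
    r_hi = min(int((ys_nm.max() + pad) / px) + 2, spec.n_pixels)
    if c_hi <= c_lo or r_hi <= r_lo:
        return None

    cols = (np.arange(c_lo, c_hi) + 0.5) * px
    rows = (np.arange(r_lo, r_hi) + 0.5) * px
    gx, gy = np.meshgrid(cols, rows)
    s = (gx - x0) * ux + (gy - y0) * uy
    t = (gx - x0) * nx + (gy - y0) * ny

    wide = (
        (np.abs(t) <= half_w + gap_nm)
        & (s >= -gap_nm)
        & (s <= fib.length_nm + gap_nm)
    )
    if check_only:
        footprint = np.zeros_like(amp, dtype=bool)
        footprint[r_lo:r_hi, c_lo:c_hi] = wide
        return footprint

    body = (np.abs(t) <= half_w) & (s >= 0) & (s <= fib.length_nm)
    if not body.any():
        return None
    # smooth edge taper so segmentation sees clean ribbons
    edge = min(2 * px, fib.width_nm / 4.0)
    taper_t = np.clip((half_w - np.abs(t)) / max(edge, 1e-9), 0.0, 1.0)
    taper_s = np.minimum(
        np.clip(s / max(edge, 1e-9), 0.0, 1.0),
        np.clip((fib.length_nm - s) / max(edge, 1e-9), 0.0, 1.0),
    )
    taper = np.where(body, np.sin(0.5 * np.pi * taper_t)
                     * np.sin(0.5 * np.pi * taper_s), 0.0)

    band = 1.0 + spec.band_contrast * np.cos(
        2 * np.pi * s / fib.d_nm + fib.phase_rad
    )
    patch_amp = spec.body_amplitude * band * taper
    sub = amp[r_lo:r_hi, c_lo:c_hi]
    np.maximum(sub, patch_amp, out=sub)

    # height: parabolic ridge cross-section with faint banding
    h0 = fib.width_nm / 6.0
    cross = np.clip(1.0 - (t / max(half_w, 1e-9)) ** 2, 0.0, 1.0)
    patch_h = h0 * np.sqrt(cross) * (
        1.0 + 0.1 * spec.band_contrast * np.cos(
            2 * np.pi * s / fib.d_nm + fib.phase_rad
        )
    ) * (taper > 0)
    subh = height[r_lo:r_hi, c_lo:c_hi]
    np.maximum(subh, patch_h, out=subh)

    footprint = np.zeros_like(amp, dtype=bool)
    footprint[r_lo:r_hi, c_lo:c_hi] = wide
    return footprint


def render_fibril_image(
    params: GroupParams,
    spec: ImageSpec,
    seed,
    n_fibrils: int | None = None,
    fibrils: list[FibrilSpec] | None = None,
    image_id: str = "synthetic",
) -> tuple[RasterImage, RasterImage, TruthTable]:
    """Render an amplitude/height image pair of a D-banded fibril field.

    Fibrils are straight ribbons with along-axis amplitude modulation
    ``A(s) = A0 * (1 + contrast * cos(2*pi*s/D + phase))``; placement uses
    rejection sampling so ribbons do not overlap.  A per-scan-line
    quadratic background and white Gaussian noise are added afterwards.

    Parameters
    ----------
    params:
        Group parameters supplying the D-period and angle distributions.
    spec:
        Image geometry/noise model.
    seed:
        Integer or :class:`numpy.random.SeedSequence`.
    n_fibrils:
        Number of ribbons to place (default ``spec.fibrils_per_image``;
        0 yields a pure-background image with an empty truth table).
    fibrils:
        Explicit :class:`FibrilSpec` placements overriding random layout.

    Returns
    -------
    (amplitude, height, truth)
    """
    rng = np.random.default_rng(seed)
    px = spec.pixel_size_nm
    amp = np.zeros((spec.n_pixels, spec.n_pixels))
    hgt = np.zeros_like(amp)
    occupancy = np.zeros_like(amp, dtype=bool)

    placed: list[dict] = []
    if fibrils is None:
        count = spec.fibrils_per_image if n_fibrils is None else n_fibrils
        dominant = rng.uniform(-90.0, 90.0)
        specs: list[FibrilSpec] = []
        for _ in range(count):
            # physical lower bound ~40 nm also guarantees >= 4 px/period
            d_low = max(40.0, 4 * px)
            if params.d_mean <= d_low:
                raise ValueError(
                    f"pixel size {px:.2f} nm cannot resolve D-periods near "
                    f"{params.d_mean:.1f} nm (need >= 4 px per period)"
                )
            d_nm = truncated_normal(rng, params.d_mean, params.d_sd, low=d_low)
            angle = _fold_axial(rng.normal(dominant, params.angle_sd))
            width = rng.uniform(*spec.fibril_width_range_nm)
            length = rng.uniform(*spec.fibril_length_range_nm)
            phase = rng.uniform(0, 2 * np.pi)
            placed_ok = False
            for _attempt in range(60):
                cx = rng.uniform(0.1, 0.9) * spec.scan_size_nm
                cy = rng.uniform(0.1, 0.9) * spec.scan_size_nm
                cand = FibrilSpec(cx, cy, angle, length, width, d_nm, phase)
                foot = _paint_fibril(
                    amp, hgt, cand, spec, gap_nm=spec.placement_gap_nm,
                    check_only=True,
                )
                if foot is None:
                    continue
                if not (foot & occupancy).any():
                    specs.append(cand)
                    occupancy |= foot
                    placed_ok = True
                    break
            if not placed_ok:
                warnings.warn(
                    f"{image_id}: could not place fibril without overlap "
                    "after 60 attempts; rendering fewer fibrils",
                    stacklevel=2,
                )
    else:
        specs = list(fibrils)
        for fib in specs:
            if fib.d_nm < 4 * px:
                raise ValueError(
                    f"pixel size {px:.2f} nm cannot resolve D-period "
                    f"{fib.d_nm:.1f} nm (need >= 4 px per period)"
                )

    for k, fib in enumerate(specs):
        _paint_fibril(amp, hgt, fib, spec)
        theta = math.radians(fib.angle_deg)
        ux, uy = math.cos(theta), -math.sin(theta)
        placed.append(
            {
                "image_id": image_id,
                "fibril_id": k,
                "angle_deg": _fold_axial(fib.angle_deg),
                "d_nm": fib.d_nm,
                "width_nm": fib.width_nm,
                "length_nm": fib.length_nm,
                "x0_nm": fib.center_x_nm - fib.length_nm / 2 * ux,
                "y0_nm": fib.center_y_nm - fib.length_nm / 2 * uy,
                "x1_nm": fib.center_x_nm + fib.length_nm / 2 * ux,
                "y1_nm": fib.center_y_nm + fib.length_nm / 2 * uy,
            }
        )

    # per-scan-line quadratic background (tilt + bow) and white noise
    x = np.linspace(-1.0, 1.0, spec.n_pixels)
    coeffs = rng.uniform(
        -spec.bow_amplitude, spec.bow_amplitude, size=(spec.n_pixels, 3)
    )
    background = (
        coeffs[:, [0]] + coeffs[:, [1]] * x + coeffs[:, [2]] * x**2
    )
    amp = amp + background
    hgt = hgt + 25.0 * background
    if spec.noise_sd > 0:
        amp = amp + rng.normal(0.0, spec.noise_sd, amp.shape)
        hgt = hgt + rng.normal(0.0, 10.0 * spec.noise_sd, hgt.shape)

    truth = TruthTable(
        fibrils=pd.DataFrame(
            placed,
            columns=[
                "image_id", "fibril_id", "angle_deg", "d_nm", "width_nm",
                "length_nm", "x0_nm", "y0_nm", "x1_nm", "y1_nm",
            ],
        ),
        background={image_id: coeffs},
    )
    amp_img = RasterImage(amp, px, "amplitude", image_id=image_id)
    hgt_img = RasterImage(hgt, px, "height", image_id=image_id)
    return amp_img, hgt_img, truth


def simulate_force_curve(
    E_gpa: float,
    spec: CurveSpec,
    probe: ProbeParams,
    seed,
    curve_id: str = "synthetic",
) -> tuple[ForceCurve, dict]:
    """Simulate one Hertzian conical-contact indentation ramp.

    Below the contact point z0 the record is baseline drift plus noise;
    above it the elastic force ``(2/pi) * E/(1-nu^2) * tan(alpha) *
    (z - z0)^2`` is added.  Returns the curve and its truth record.
    """
    if E_gpa <= 0:
        raise ValueError(f"E_gpa must be > 0, got {E_gpa}")
    rng = np.random.default_rng(seed)
    z = np.linspace(0.0, spec.span_nm, spec.n_samples)
    z0 = rng.uniform(*spec.contact_offset_range_nm)
    slope = rng.uniform(*spec.baseline_slope_range)
    delta = np.clip(z - z0, 0.0, None)
    elastic = hertz_force(E_gpa, delta, probe)
    noise_sd = spec.force_noise_sd
    if noise_sd is None:
        noise_sd = 0.05 * float(elastic[-1])
    force = slope * z + elastic
    if noise_sd > 0:
        force = force + rng.normal(0.0, noise_sd, z.shape)
    curve = ForceCurve(
        displacement_nm=z,
        force_nN=force,
        metadata={
            "curve_id": curve_id,
            "speed_um_s": spec.speed_um_s,
            "n_samples": spec.n_samples,
        },
    )
    truth = {
        "curve_id": curve_id,
        "E_gpa": float(E_gpa),
        "z0_nm": float(z0),
        "baseline_slope": float(slope),
    }
    return curve, truth


@dataclass
class SyntheticDataset:
    """In-memory synthetic cohort: images, curves, truth and manifest."""

    images: list  # (amplitude RasterImage, height RasterImage)
    curves: list  # ForceCurve
    truth: TruthTable
    manifest: pd.DataFrame


def simulate_dataset(
    groups: list[GroupParams],
    image_spec: ImageSpec,
    curve_spec: CurveSpec,
    probe: ProbeParams,
    seed: int,
    outdir=None,
    keep_in_memory: bool = True,
) -> SyntheticDataset:
    """Simulate the full hierarchical design: groups -> mice -> sites.

    Per site one image pair and ``indents_per_site`` force curves are
    produced; the manifest records the seed-splitting indices so any unit
    can be regenerated in isolation.  With ``outdir`` set, images go to
    32-bit-compatible TIFF (one file per channel, named
    ``<group>_<mouse>_<site>_<channel>.tif``), curves to per-indent TSV,
    truth/manifest to CSV.
    """
    outpath = None
    if outdir is not None:
        outpath = Path(outdir)
        try:
            outpath.mkdir(parents=True, exist_ok=True)
        except OSError as exc:
            raise ValueError(f"cannot create output directory {outdir}: {exc}")

    images, curves, rows = [], [], []
    truth = TruthTable()
    for gi, params in enumerate(groups):
        for mouse in range(params.n_mice):
            for site in range(params.sites_per_mouse):
                image_id = f"{params.label}_m{mouse}_s{site}"
                amp, hgt, t_img = render_fibril_image(
                    params, image_spec, seed_for(seed, gi, mouse, site, 0),
                    image_id=image_id,
                )
                truth = truth.merge(t_img)
                if outpath is not None:
                    write_raster(
                        amp, outpath / f"{image_id}_amplitude.tif"
                    )
                    write_raster(hgt, outpath / f"{image_id}_height.tif")
                if keep_in_memory:
                    images.append((amp, hgt))
                curve_truths = []
                for k in range(params.indents_per_site):
                    curve_id = f"{image_id}_i{k}"
                    rng_e = np.random.default_rng(
                        seed_for(seed, gi, mouse, site, 1, k)
                    )
                    e_true = truncated_normal(
                        rng_e, params.modulus_mean, params.modulus_sd,
                        low=0.0,
                    )
                    curve, t_curve = simulate_force_curve(
                        e_true, curve_spec, probe,
                        seed_for(seed, gi, mouse, site, 2, k),
                        curve_id=curve_id,
                    )
                    t_curve.update(group=params.label)
                    curve_truths.append(t_curve)
                    if outpath is not None:
                        pd.DataFrame(
                            {
                                "displacement_nm": curve.displacement_nm,
                                "force_nN": curve.force_nN,
                            }
                        ).to_csv(
                            outpath / f"{curve_id}.tsv",
                            sep="\t", index=False, float_format="%.17g",
                        )
                    if keep_in_memory:
                        curves.append(curve)
                truth = truth.merge(
                    TruthTable(curves=pd.DataFrame(curve_truths))
                )
                rows.append(
                    {
                        "group": params.label,
                        "group_index": gi,
                        "mouse": mouse,
                        "site": site,
                        "image_id": image_id,
                        "n_indents": params.indents_per_site,
                        "master_seed": seed,
                    }
                )
    manifest = pd.DataFrame(rows)
    if outpath is not None:
        manifest.to_csv(outpath / "manifest.csv", index=False)
        truth.fibrils.to_csv(outpath / "truth_fibrils.csv", index=False)
        truth.curves.to_csv(outpath / "truth_curves.csv", index=False)
    return SyntheticDataset(images, curves, truth, manifest)
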