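"""Fibril segmentation, axis tracing, D-spacing and orientation analysis.

The D-periodic spacing of a fibril is measured from the amplitude
deviation sampled along its traced longitudinal axis: local maxima of the
profile are located, refined to sub-sample positions by parabolic
interpolation, and the spacing is the mean of consecutive peak-to-peak
intervals.  Orientation is the axial angle (mod 180 deg) of the
total-least-squares line through the trace, and per-image angles are
normalized to the circular-aware axial mean so that the reported values
are deviations from the dominant fibril direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal
from skimage import filters, measure, morphology

from .preprocess import (
    require_flattened,
    require_quantitative,
    robust_line_detrend,
)
from .raster import RasterImage

__all__ = [
    "SegmentConfig",
    "FibrilTrace",
    "DSpacingMeasurement",
    "OrientationMeasurement",
    "segment_fibrils",
    "trace_axis",
    "profile_along_trace",
    "dspacing_from_profile",
    "fibril_orientation",
    "select_random_fibrils",
    "normalize_orientations",
    "axial_mean_deg",
]


@dataclass(frozen=True)
class SegmentConfig:
    """Classical ridge-segmentation settings.

    The ridge image is the local band-texture energy: the sum of squared
    high-pass residuals taken along rows (immune to any per-line
    background bias the plain flatten leaves behind) and along columns of
    a robustly re-detrended copy (which covers fibrils running parallel
    to the scan lines), envelope-smoothed.  Otsu thresholding, a
    morphological closing that bridges sub-threshold D-band valleys,
    small-object removal and shape filtering follow: regions shorter than
    ``min_length_nm`` along their major axis or with aspect ratio below
    ``min_aspect`` are discarded.  Everything here feeds segmentation
    only, never quantitation.
    """

    highpass_sigma_px: float = 8.0
    envelope_sigma_px: float = 4.0
    threshold: float | None = None
    close_radius_nm: float = 30.0
    min_length_nm: float = 300.0
    min_aspect: float = 3.0


@dataclass
class FibrilTrace:
    """Ordered sub-pixel centerline of one fibril."""

    fibril_id: int
    points: np.ndarray  # (N, 2) float (row, col) pixel coordinates
    arclength_nm: np.ndarray  # (N,) strictly increasing
    image_id: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.arclength_nm = np.asarray(self.arclength_nm, dtype=float)
        if self.points.ndim != 2 or self.points.shape[0] < 2:
            raise ValueError("trace needs >= 2 points")
        if np.any(np.diff(self.arclength_nm) <= 0):
            raise ValueError("arclength must be strictly increasing")

    @property
    def length_nm(self) -> float:
        return float(self.arclength_nm[-1] - self.arclength_nm[0])


@dataclass
class DSpacingMeasurement:
    """Per-fibril D-period: mean of consecutive peak-to-peak intervals."""

    fibril_id: int
    d_spacing_nm: float
    n_peaks: int
    intervals_nm: np.ndarray

    def __post_init__(self) -> None:
        if self.n_peaks < 3 or self.d_spacing_nm <= 0:
            raise ValueError("need >= 3 peaks and a positive spacing")


@dataclass
class OrientationMeasurement:
    fibril_id: int
    angle_raw_deg: float
    angle_norm_deg: float = float("nan")


def _drop_small(mask: np.ndarray, min_px: int) -> np.ndarray:
    """Remove connected components smaller than ``min_px`` pixels."""
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return mask
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_px
    keep[0] = False
    return keep[labels]


def segment_fibrils(
    image: RasterImage, config: SegmentConfig = SegmentConfig()
) -> tuple[np.ndarray, list[int]]:
    """Label elongated ridge regions in a flattened amplitude image.

    Returns an integer label map (0 = background, labels 1..K consecutive
    and deterministic for a given input) and the list of kept labels.
    """
    require_flattened(image)
    require_quantitative(image)
    px = image.pixel_size_nm
    v = image.values.astype(float)
    hp_x = v - ndimage.gaussian_filter1d(v, config.highpass_sigma_px, axis=1)
    detrended = robust_line_detrend(v)
    hp_y = detrended - ndimage.gaussian_filter1d(
        detrended, config.highpass_sigma_px, axis=0
    )
    energy = np.sqrt(
        ndimage.gaussian_filter(hp_x**2, config.envelope_sigma_px)
        + ndimage.gaussian_filter(hp_y**2, config.envelope_sigma_px)
    )
    thr = config.threshold
    if thr is None:
        thr = float(filters.threshold_otsu(energy))
    mask = energy > thr
    # drop speckle, then bridge the sub-threshold D-band valleys
    mask = _drop_small(mask, 16)
    radius = max(1, int(round(config.close_radius_nm / px)))
    mask = morphology.closing(mask, morphology.disk(radius))
    min_px = max(int((config.min_length_nm / px) * 2), 16)
    mask = _drop_small(mask, min_px)
    labels = measure.label(mask, connectivity=2)
    keep = []
    for region in measure.regionprops(labels):
        major = region.axis_major_length * px
        minor = max(region.axis_minor_length * px, px)
        if major >= config.min_length_nm and major / minor >= config.min_aspect:
            keep.append(region.label)
    if not keep:
        warnings.warn("no fibrils found in image", stacklevel=2)
        return np.zeros_like(labels), []
    out = np.zeros_like(labels)
    ids = []
    for new, old in enumerate(keep, start=1):
        out[labels == old] = new
        ids.append(new)
    return out, ids


def _skeleton_path(skel: np.ndarray) -> np.ndarray | None:
    """Longest geodesic path through a skeleton (array of (r, c) pixels)."""
    coords = np.argwhere(skel)
    if coords.shape[0] < 3:
        return None
    index = {(int(r), int(c)): i for i, (r, c) in enumerate(coords)}
    nbrs: list[list[int]] = [[] for _ in range(len(coords))]
    for i, (r, c) in enumerate(coords):
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                j = index.get((int(r) + dr, int(c) + dc))
                if j is not None:
                    nbrs[i].append(j)

    def bfs(start: int) -> tuple[int, np.ndarray]:
        parent = np.full(len(coords), -1, dtype=int)
        parent[start] = start
        frontier = [start]
        last = start
        while frontier:
            nxt = []
            for u in frontier:
                for v in nbrs[u]:
                    if parent[v] == -1:
                        parent[v] = u
                        nxt.append(v)
            if nxt:
                last = nxt[-1]
            frontier = nxt
        return last, parent

    a, _ = bfs(0)
    b, parent = bfs(a)
    path = [b]
    while path[-1] != a:
        path.append(int(parent[path[-1]]))
    return coords[np.array(path[::-1])]


def trace_axis(
    labels: np.ndarray,
    fibril_id: int,
    pixel_size_nm: float,
    smooth_window: int = 7,
    min_path_coverage: float = 0.75,
    image_id: str = "",
) -> FibrilTrace | None:
    """Trace the longitudinal axis of one labeled fibril.

    The region is skeletonized, pruned to its longest path, smoothed to
    sub-pixel nodes and resampled at one-pixel arclength steps.  Returns
    ``None`` (with a warning) for degenerate regions and for branched
    skeletons with no dominant path (longest path covering less than
    ``min_path_coverage`` of the skeleton), which indicate crossing or
    merged fibrils rather than a single axis.
    """
    mask = labels == fibril_id
    if not mask.any():
        raise ValueError(f"label {fibril_id} not present in label map")
    skel = morphology.skeletonize(mask)
    path = _skeleton_path(skel)
    if path is None or path.shape[0] < 3:
        warnings.warn(
            f"fibril {fibril_id}: skeleton too short to trace", stacklevel=2
        )
        return None
    if path.shape[0] < min_path_coverage * int(skel.sum()):
        warnings.warn(
            f"fibril {fibril_id}: branched skeleton with no dominant path; "
            "skipped", stacklevel=2,
        )
        return None
    pts = path.astype(float)
    # skeleton spurs hook into the rounded region ends; trim roughly half
    # the ribbon width from each end (the tangent extension below restores
    # the lost arclength along the true axis direction)
    width_px = mask.sum() / max(path.shape[0], 1)
    trim = int(round(width_px))
    if pts.shape[0] > 4 * trim + 8:
        pts = pts[trim: pts.shape[0] - trim]
    if pts.shape[0] >= smooth_window:
        pts = np.column_stack(
            [
                ndimage.uniform_filter1d(pts[:, 0], smooth_window, mode="nearest"),
                ndimage.uniform_filter1d(pts[:, 1], smooth_window, mode="nearest"),
            ]
        )
    # skeletonization erodes the ribbon ends by about half the width;
    # extend both ends along their tangents while still inside the region
    def _extend(anchor, tangent):
        extra = []
        pos = anchor.copy()
        for _ in range(mask.shape[0] + mask.shape[1]):
            pos = pos + tangent
            r, c = int(round(pos[0])), int(round(pos[1]))
            if not (0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]):
                break
            if not mask[r, c]:
                break
            extra.append(pos.copy())
        return extra

    k = min(15, pts.shape[0] - 1)
    t_head = pts[0] - pts[k]
    t_tail = pts[-1] - pts[-1 - k]
    head, tail = [], []
    for tangent, anchor, store in (
        (t_head, pts[0], head), (t_tail, pts[-1], tail)
    ):
        norm = np.linalg.norm(tangent)
        if norm > 0:
            store.extend(_extend(anchor, tangent / norm))
    if head:
        pts = np.vstack([head[::-1], pts])
    if tail:
        pts = np.vstack([pts, tail])

    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s_px = np.concatenate([[0.0], np.cumsum(steps)])
    if s_px[-1] < 2.0:
        warnings.warn(
            f"fibril {fibril_id}: trace shorter than two pixels", stacklevel=2
        )
        return None
    # resample at uniform one-pixel arclength spacing
    s_new = np.arange(0.0, s_px[-1] + 1e-9, 1.0)
    rows = np.interp(s_new, s_px, pts[:, 0])
    cols = np.interp(s_new, s_px, pts[:, 1])
    return FibrilTrace(
        fibril_id=int(fibril_id),
        points=np.column_stack([rows, cols]),
        arclength_nm=s_new * pixel_size_nm,
        image_id=image_id,
    )


def profile_along_trace(
    image: RasterImage,
    trace: FibrilTrace,
    half_width_nm: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Amplitude deviation along a trace, averaged across the fibril.

    At each centerline node the image is sampled by bilinear interpolation
    at offsets perpendicular to the local tangent, out to
    ``+/- half_width_nm``, and averaged.  Returns (arclength nm, value).
    """
    require_quantitative(image)
    px = image.pixel_size_nm
    pts = trace.points
    n_rows, n_cols = image.values.shape
    if (
        pts[:, 0].min() < -0.5 or pts[:, 1].min() < -0.5
        or pts[:, 0].max() > n_rows - 0.5 or pts[:, 1].max() > n_cols - 0.5
    ):
        raise ValueError("trace lies outside the image bounds")
    tangents = np.gradient(pts, axis=0)
    norms = np.linalg.norm(tangents, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    tangents = tangents / norms
    normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])

    k = int(round(half_width_nm / px))
    offsets = np.arange(-k, k + 1, dtype=float)
    rows = pts[:, 0][None, :] + offsets[:, None] * normals[:, 0][None, :]
    cols = pts[:, 1][None, :] + offsets[:, None] * normals[:, 1][None, :]
    clipped = (
        (rows < -0.5) | (rows > n_rows - 0.5)
        | (cols < -0.5) | (cols > n_cols - 0.5)
    )
    if clipped.any():
        warnings.warn(
            "profile band exits the image; samples clipped to the border",
            stacklevel=2,
        )
    sampled = ndimage.map_coordinates(
        image.values.astype(float), [rows.ravel(), cols.ravel()],
        order=1, mode="nearest",
    ).reshape(rows.shape)
    return trace.arclength_nm.copy(), sampled.mean(axis=0)


def dspacing_from_profile(
    arclength_nm: np.ndarray,
    values: np.ndarray,
    fibril_id: int = 0,
    min_prominence: float | None = None,
    min_separation_nm: float = 40.0,
) -> DSpacingMeasurement | None:
    """Peak-to-peak D-spacing of an along-axis amplitude profile.

    The profile is detrended by subtracting its mean; local maxima with
    prominence >= ``min_prominence`` (default half the profile SD) and
    separation >= ``min_separation_nm`` are refined to sub-sample
    positions by parabolic interpolation through their three-point
    neighbourhood.  Fewer than three peaks rejects the fibril.
    """
    s = np.asarray(arclength_nm, dtype=float)
    v = np.asarray(values, dtype=float)
    if s.size != v.size or s.size < 5:
        raise ValueError("profile arrays must match and have >= 5 samples")
    step = float(np.median(np.diff(s)))
    detrended = v - v.mean()
    sd = float(detrended.std())
    if sd == 0:
        return None
    prom = 0.5 * sd if min_prominence is None else min_prominence
    distance = max(1, int(min_separation_nm / step))
    peaks, _ = signal.find_peaks(detrended, prominence=prom, distance=distance)
    peaks = peaks[(peaks > 0) & (peaks < v.size - 1)]
    if peaks.size < 3:
        return None
    y0, y1, y2 = detrended[peaks - 1], detrended[peaks], detrended[peaks + 1]
    denom = y0 - 2 * y1 + y2
    offset = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / denom, 0.0)
    offset = np.clip(offset, -0.5, 0.5)
    positions = s[peaks] + offset * step
    intervals = np.diff(positions)
    return DSpacingMeasurement(
        fibril_id=int(fibril_id),
        d_spacing_nm=float(intervals.mean()),
        n_peaks=int(peaks.size),
        intervals_nm=intervals,
    )


def fibril_orientation(trace: FibrilTrace) -> OrientationMeasurement:
    """Axial angle of the total-least-squares line through a trace.

    Measured against the image horizontal, positive counter-clockwise,
    reported in (-90, 90].  A fibril is an axial object: theta and
    theta + 180 deg are the same orientation.
    """
    pts = trace.points
    # (x, y-up) frame: x = col, y = -row
    xy = np.column_stack([pts[:, 1], -pts[:, 0]])
    centered = xy - xy.mean(axis=0)
    if np.allclose(centered, 0):
        raise ValueError("degenerate trace: all nodes coincide")
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    vx, vy = vt[0]
    angle = np.degrees(np.arctan2(vy, vx))
    angle = angle % 180.0
    if angle > 90.0:
        angle -= 180.0
    return OrientationMeasurement(trace.fibril_id, float(angle))


def select_random_fibrils(fibril_ids, n: int = 20, seed=None) -> list[int]:
    """Uniform sample of ``n`` fibrils without replacement.

    Mirrors the protocol of randomly selecting twenty fibrils per image;
    with fewer candidates all are returned with a warning.
    """
    ids = sorted(int(i) for i in fibril_ids)
    if not ids:
        raise ValueError("no fibril candidates to select from")
    if len(ids) <= n:
        if len(ids) < n:
            warnings.warn(
                f"only {len(ids)} fibrils available, requested {n}; "
                "returning all", stacklevel=2,
            )
        return ids
    rng = np.random.default_rng(seed)
    chosen = rng.choice(ids, size=n, replace=False)
    return sorted(int(i) for i in chosen)


def axial_mean_deg(angles_deg) -> float:
    """Circular-aware mean of axial angles (period 180 deg)."""
    a = np.radians(np.asarray(angles_deg, dtype=float)) * 2.0
    mean = 0.5 * np.arctan2(np.sin(a).sum(), np.cos(a).sum())
    out = np.degrees(mean) % 180.0
    if out > 90.0:
        out -= 180.0
    return float(out)


def normalize_orientations(angles_raw_deg) -> np.ndarray:
    """Signed deviations from the per-image axial mean, in (-90, 90].

    The axial mean respects the 180-degree wraparound, so e.g.
    {85, -85} deg normalizes to {-5, +5} about a mean of 90 deg.
    """
    a = np.asarray(angles_raw_deg, dtype=float)
    if a.size == 0:
        raise ValueError("need at least one angle")
    mean = axial_mean_deg(a)
    dev = (a - mean) % 180.0
    dev[dev > 90.0] -= 180.0
    return dev
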