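"""Standardized AFM post-processing: line flattening and display low-pass.

Every raw height and amplitude scan is flattened line by line with a
second-order polynomial to remove piezo tilt and bow.  A mild Gaussian
low-pass (sigma = 0.8 px) may be applied to amplitude images for display
only; downstream quantitative steps reject low-passed input.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .raster import RasterImage


def robust_line_detrend(
    values: np.ndarray, order: int = 2, n_iter: int = 2, clip: float = 2.0
) -> np.ndarray:
    """Per-line polynomial subtraction with iterative feature exclusion.

    After an ordinary fit, pixels deviating more than ``clip`` line-SDs are
    down-weighted to zero and the line is refitted, so bright fibrils do
    not drag the background estimate.
    """
    x = np.linspace(-1.0, 1.0, values.shape[1])
    design = np.vander(x, order + 1, increasing=True)
    coefs, *_ = np.linalg.lstsq(design, values.T, rcond=None)
    residual = values - (design @ coefs).T
    for _ in range(n_iter):
        sd = residual.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        w = (np.abs(residual) <= clip * sd).astype(float)
        # weighted normal equations, one 3x3-ish solve per line
        xtx = np.einsum("rc,ci,cj->rij", w, design, design)
        xty = np.einsum("rc,ci,rc->ri", w, design, values)
        coefs_r = np.linalg.solve(
            xtx + 1e-12 * np.eye(design.shape[1]), xty[..., None]
        )[..., 0]
        residual = values - coefs_r @ design.T
    return residual


def flatten_lines(
    image: RasterImage, order: int = 2, robust: bool = False
) -> RasterImage:
    """Subtract the least-squares polynomial of ``order`` from each scan line.

    Each image row is fitted independently; the returned image carries the
    residuals, so the best-fit polynomial of the same order on any output
    line is identically zero (the operation is a projection and therefore
    idempotent).

    Parameters
    ----------
    image:
        Input scan; rows are scan lines.
    order:
        Polynomial order; 2 (default) removes tilt and bow.
    robust:
        Iteratively exclude bright feature pixels from the per-line fit.
        Off by default: the plain fit is the standard instrument behaviour.
    """
    if order < 0:
        raise ValueError(f"order must be >= 0, got {order}")
    n_cols = image.values.shape[1]
    if n_cols < order + 1:
        raise ValueError(
            f"need at least order+1={order + 1} columns, image has {n_cols}"
        )
    if robust:
        residual = robust_line_detrend(np.asarray(image.values, float), order)
    else:
        # Vandermonde on [-1, 1] for conditioning; one pinv serves all rows
        x = np.linspace(-1.0, 1.0, n_cols)
        design = np.vander(x, order + 1, increasing=True)
        coefs, *_ = np.linalg.lstsq(design, image.values.T, rcond=None)
        residual = image.values - (design @ coefs).T
    return image.with_values(residual, flattened=True)


def lowpass_amplitude(image: RasterImage, sigma_px: float = 0.8) -> RasterImage:
    """Gaussian low-pass for amplitude display (reflective boundary).

    The output is flagged ``lowpass_applied`` and must not be fed to any
    quantitative measurement; height images are rejected outright.
    """
    if image.channel != "amplitude":
        raise ValueError(
            "low-pass filtering is restricted to amplitude images; "
            f"got channel {image.channel!r}"
        )
    if sigma_px <= 0:
        raise ValueError(f"sigma_px must be > 0, got {sigma_px}")
    smoothed = ndimage.gaussian_filter(
        image.values.astype(float), sigma=sigma_px, mode="reflect"
    )
    return image.with_values(smoothed, lowpass_applied=True)


def require_quantitative(image: RasterImage) -> None:
    """Raise if ``image`` is unfit for quantitative analysis."""
    if image.lowpass_applied:
        raise ValueError(
            "image has been low-pass filtered (display only); quantitative "
            "analysis requires unfiltered data"
        )


def require_flattened(image: RasterImage) -> None:
    if not image.flattened:
        raise ValueError("image must be line-flattened before this step")
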