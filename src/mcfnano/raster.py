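"""Raster AFM image container and lossless file I/O.

Images are stored as TIFF (any float dtype, written unmodified) or as a
whitespace-delimited text matrix, each with a YAML sidecar
(``<file>.meta.yaml``) carrying the physical pixel size, channel and
processing provenance.  Scan lines are image rows; the coordinate origin is
the top-left corner and x increases with column index.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
import yaml

CHANNELS = ("height", "amplitude")


@dataclass
class RasterImage:
    """A single-channel AFM scan grid with physical pixel size.

    ``flattened`` / ``lowpass_applied`` record the post-processing already
    applied; quantitative operations refuse low-passed input (the filter is
    display-only).
    """

    values: np.ndarray
    pixel_size_nm: float
    channel: str
    flattened: bool = False
    lowpass_applied: bool = False
    image_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError(
                f"values must be a 2-D grid, got shape {self.values.shape}"
            )
        if self.pixel_size_nm <= 0:
            raise ValueError(
                f"pixel_size_nm must be > 0, got {self.pixel_size_nm}"
            )
        if self.channel not in CHANNELS:
            raise ValueError(
                f"channel must be one of {CHANNELS}, got {self.channel!r}"
            )
        if self.lowpass_applied and self.channel != "amplitude":
            raise ValueError(
                "lowpass_applied may be true only for amplitude images"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def scan_size_nm(self) -> float:
        return self.values.shape[1] * self.pixel_size_nm

    def with_values(self, values: np.ndarray, **flags) -> "RasterImage":
        """Copy of this image with new values and updated provenance."""
        out = replace(self, values=values, **flags)
        return out


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".meta.yaml")


def write_raster(image: RasterImage, path) -> None:
    """Write an image as TIFF (``.tif``/``.tiff``) or text matrix.

    The numeric payload round-trips exactly; metadata go to a YAML sidecar.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image.values)
    else:
        np.savetxt(path, image.values, fmt="%.17g")
    meta = {
        "pixel_size_nm": float(image.pixel_size_nm),
        "channel": image.channel,
        "flattened": bool(image.flattened),
        "lowpass_applied": bool(image.lowpass_applied),
        "image_id": image.image_id,
    }
    _sidecar(path).write_text(yaml.safe_dump(meta))


def read_raster(path) -> RasterImage:
    """Read a TIFF or text-matrix image plus its YAML sidecar metadata."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    side = _sidecar(path)
    if not side.exists():
        raise ValueError(f"missing sidecar metadata file {side}")
    meta = yaml.safe_load(side.read_text())
    for key in ("pixel_size_nm", "channel"):
        if key not in meta:
            raise ValueError(f"sidecar {side} is missing field {key!r}")
    if path.suffix.lower() in (".tif", ".tiff"):
        values = tifffile.imread(path)
    else:
        try:
            values = np.loadtxt(path, ndmin=2)
        except ValueError as exc:
            raise ValueError(
                f"malformed text matrix in {path}: {exc}"
            ) from exc
    return RasterImage(
        values=values,
        pixel_size_nm=float(meta["pixel_size_nm"]),
        channel=meta["channel"],
        flattened=bool(meta.get("flattened", False)),
        lowpass_applied=bool(meta.get("lowpass_applied", False)),
        image_id=str(meta.get("image_id", "")),
    )
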