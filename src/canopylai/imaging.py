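"""Raster I/O, false-colour conversion, and view-zenith ROI clipping.

Nadir canopy photographs come from a fixed downward-looking camera (wide
field of view, a few metres above the canopy).  Only the near-nadir part of
the frame is usable for gap-fraction work: off-nadir pixels suffer geometric
distortion and FVC saturation, so the image is clipped to the largest
centred rectangle whose every pixel has view zenith below a configurable
limit (30 degrees by default, roughly a 2 m x 2 m ground footprint for a
camera at 3 m).
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np
from PIL import Image

__all__ = [
    "CameraGeometry",
    "CanopyImage",
    "RoiSpec",
    "FormatError",
    "EmptyRoiError",
    "read_image",
    "write_image",
    "write_mask",
    "convert_false_color",
    "pixel_view_zenith",
    "clip_roi",
    "doy",
]


class FormatError(ValueError):
    """Raster file is readable but not a 3-channel image we accept."""


class EmptyRoiError(ValueError):
    """No pixel satisfies the view-zenith constraint."""


@dataclass(frozen=True)
class CameraGeometry:
    """Geometry of the nadir camera.

    Parameters
    ----------
    fov_deg : float
        Full field of view across the image diagonal, degrees.  120 by
        default (wide-angle lens); values above 180 are rejected.
    mount_height_m : float
        Camera height above ground, metres.  Default 3.0.
    projection : {"equidistant", "rectilinear"}
        Lens projection model.  Equidistant (zenith proportional to radial
        pixel distance) is the default, typical for very wide lenses.
    principal_point : (row, col) or None
        Pixel coordinates of the optical axis; ``None`` means image centre.
    """

    fov_deg: float = 120.0
    mount_height_m: float = 3.0
    projection: str = "equidistant"
    principal_point: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.fov_deg <= 180.0:
            raise ValueError(f"fov_deg must be in (0, 180], got {self.fov_deg}")
        if self.mount_height_m <= 0:
            raise ValueError("mount_height_m must be positive")
        if self.projection not in ("equidistant", "rectilinear"):
            raise ValueError(f"unknown projection {self.projection!r}")


@dataclass(frozen=True)
class RoiSpec:
    """Region-of-interest clip specification.

    ``max_view_zenith_deg`` bounds the view zenith of every retained pixel;
    ``target_ground_side_m`` is the nominal ground side the clip aims for
    (informational — the zenith limit is what is enforced).
    """

    max_view_zenith_deg: float = 30.0
    target_ground_side_m: float = 2.0

    def __post_init__(self) -> None:
        if self.max_view_zenith_deg < 0:
            raise ValueError("max_view_zenith_deg must be non-negative")


@dataclass
class CanopyImage:
    """A 3-channel canopy raster with colour-mode and geometry metadata.

    ``pixels`` is a (height, width, 3) array, row-major, origin top-left.
    ``bit_depth`` is the significant bit depth of the data (8, 10 or 16);
    10-bit data is carried in a 16-bit container at its stored scale.
    """

    pixels: np.ndarray
    bit_depth: int = 8
    color_mode: str = "true_color"
    acquired_at: Optional[_dt.datetime] = None
    geometry: Optional[CameraGeometry] = None
    ground_side_m: Optional[float] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise FormatError(
                f"expected (H, W, 3) pixel array, got shape {self.pixels.shape}"
            )
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise FormatError("image must have positive width and height")
        if self.bit_depth not in (8, 10, 16):
            raise ValueError(f"bit_depth must be 8, 10 or 16, got {self.bit_depth}")
        if self.color_mode not in ("true_color", "false_color"):
            raise ValueError(f"unknown color_mode {self.color_mode!r}")
        if self.pixels.size and int(self.pixels.max()) > self.max_value:
            raise ValueError(
                f"channel sample exceeds 2^{self.bit_depth}-1 = {self.max_value}"
            )

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1

    def principal_point(self) -> tuple[float, float]:
        """Principal point (row, col); image centre when geometry omits it."""
        if self.geometry is not None and self.geometry.principal_point is not None:
            return self.geometry.principal_point
        return ((self.height - 1) / 2.0, (self.width - 1) / 2.0)


_ACCEPTED_SUFFIXES = {".png", ".tif", ".tiff", ".bmp"}


def read_image(
    path: str | Path,
    bit_depth_hint: Optional[int] = None,
    color_mode: str = "true_color",
    geometry: Optional[CameraGeometry] = None,
) -> CanopyImage:
    """Read a PNG/TIFF/BMP raster into a :class:`CanopyImage`.

    16-bit containers are kept at their stored scale; pass
    ``bit_depth_hint=10`` to record that only 10 bits are significant.
    """
    path = Path(path)
    if path.suffix.lower() not in _ACCEPTED_SUFFIXES:
        raise FormatError(f"unsupported raster format: {path.suffix!r}")
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        with Image.open(path) as im:
            arr = np.asarray(im)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha written by other tools
        raise FormatError("expected 3 channels, got RGBA")
    if arr.ndim != 3 or arr.shape[2] != 3:
        n = 1 if arr.ndim == 2 else arr.shape[2]
        raise FormatError(f"expected 3 channels, got {n}")
    native_depth = 16 if arr.dtype.itemsize > 1 else 8
    bit_depth = bit_depth_hint if bit_depth_hint is not None else native_depth
    return CanopyImage(arr, bit_depth=bit_depth, color_mode=color_mode, geometry=geometry)


def write_image(img: CanopyImage, path: str | Path) -> None:
    """Write the pixel grid losslessly (PNG or TIFF)."""
    path = Path(path)
    if path.suffix.lower() not in _ACCEPTED_SUFFIXES:
        raise FormatError(f"unsupported raster format: {path.suffix!r}")
    arr = img.pixels
    if img.bit_depth == 8:
        arr = arr.astype(np.uint8)
    else:
        arr = arr.astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, arr)
    elif arr.dtype != np.uint8:
        raise FormatError("16-bit containers can only be written as TIFF")
    else:
        Image.fromarray(arr).save(path)


def write_mask(grid: np.ndarray, path: str | Path) -> None:
    """Write a binary leaf mask as PNG: leaf = 255, background = 0."""
    arr = (np.asarray(grid).astype(bool).astype(np.uint8)) * 255
    Image.fromarray(arr, mode="L").save(path)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a mask PNG written by :func:`write_mask` back into a bool grid."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return arr >= 128


def convert_false_color(img: CanopyImage, matrix: Optional[np.ndarray] = None) -> CanopyImage:
    """Convert a false-colour (NIR-substituted) acquisition to true colour.

    Each pixel 3-vector is left-multiplied by a 3x3 band-mixing matrix and
    clamped to the valid range.  The default matrix swaps the second and
    third channels, the band reorder that puts the vegetation-bright band
    back on green.
    """
    if img.color_mode != "false_color":
        raise ValueError("convert_false_color requires a false_color image")
    if matrix is None:
        matrix = np.array([[1.0, 0, 0], [0, 0, 1.0], [0, 1.0, 0]])
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (3, 3):
        raise ValueError(f"conversion matrix must be 3x3, got {matrix.shape}")
    if not np.any(matrix):
        raise ValueError("conversion matrix is all zero")
    mixed = img.pixels.astype(float) @ matrix.T
    mixed = np.clip(np.rint(mixed), 0, img.max_value)
    out = mixed.astype(img.pixels.dtype)
    return replace(img, pixels=out, color_mode="true_color")


def _max_radius(pp: tuple[float, float], height: int, width: int) -> float:
    """Distance from the principal point to the farthest image corner."""
    pr, pc = pp
    dr = max(pr, (height - 1) - pr)
    dc = max(pc, (width - 1) - pc)
    return math.hypot(dr, dc)


def pixel_view_zenith(
    geom: CameraGeometry,
    pixel: tuple[float, float],
    image_dims: tuple[int, int],
) -> float:
    """View zenith angle (degrees) of a pixel (row, col).

    ``image_dims`` is (height, width).  The mapping is normalised so that
    the half-diagonal (principal point to farthest corner) sees
    ``fov_deg / 2``: proportional for the equidistant model,
    ``arctan(r / f)`` for the rectilinear model.
    """
    height, width = image_dims
    pp = geom.principal_point or ((height - 1) / 2.0, (width - 1) / 2.0)
    r = math.hypot(pixel[0] - pp[0], pixel[1] - pp[1])
    r_max = _max_radius(pp, height, width)
    if r_max == 0:
        return 0.0
    half_fov = geom.fov_deg / 2.0
    if geom.projection == "equidistant":
        return (r / r_max) * half_fov
    f = r_max / math.tan(math.radians(half_fov))
    return math.degrees(math.atan2(r, f))


def _zenith_to_radius(geom: CameraGeometry, zenith_deg: float, r_max: float) -> float:
    half_fov = geom.fov_deg / 2.0
    if geom.projection == "equidistant":
        return (zenith_deg / half_fov) * r_max
    f = r_max / math.tan(math.radians(half_fov))
    return f * math.tan(math.radians(zenith_deg))


def clip_roi(img: CanopyImage, roi: RoiSpec | None = None) -> CanopyImage:
    """Clip to the largest centred rectangle inside the zenith limit.

    The retained rectangle is centred on the principal point and its every
    pixel has view zenith <= ``roi.max_view_zenith_deg``; equivalently its
    half-diagonal stays within the radius that maps to the limit, so the
    optimum is the inscribed square of the zenith disc (half-side
    r_limit / sqrt(2)), intersected with the image bounds.
    """
    if roi is None:
        roi = RoiSpec()
    if img.geometry is None:
        raise ValueError("clip_roi requires image geometry")
    geom = img.geometry
    limit = roi.max_view_zenith_deg
    if limit > geom.fov_deg / 2.0:
        raise ValueError("max_view_zenith_deg exceeds the half field of view")
    pr, pc = img.principal_point()
    r_max = _max_radius((pr, pc), img.height, img.width)
    r_lim = _zenith_to_radius(geom, limit, r_max)
    # tiny slack so an exact-boundary pixel is not lost to rounding; the
    # corner check below still enforces the limit
    half = r_lim / math.sqrt(2.0) + 1e-9

    r0 = max(int(math.ceil(pr - half)), 0)
    r1 = min(int(math.floor(pr + half)), img.height - 1)
    c0 = max(int(math.ceil(pc - half)), 0)
    c1 = min(int(math.floor(pc + half)), img.width - 1)

    def corner_ok(r0: int, r1: int, c0: int, c1: int) -> bool:
        dr = max(abs(r0 - pr), abs(r1 - pr))
        dc = max(abs(c0 - pc), abs(c1 - pc))
        return math.hypot(dr, dc) <= r_lim + 1e-9

    # Guard against rounding: shrink the longer half-extent until the worst
    # corner is inside the zenith disc.
    while r0 <= r1 and c0 <= c1 and not corner_ok(r0, r1, c0, c1):
        dr = max(abs(r0 - pr), abs(r1 - pr))
        dc = max(abs(c0 - pc), abs(c1 - pc))
        if dr >= dc:
            if abs(r0 - pr) >= abs(r1 - pr):
                r0 += 1
            else:
                r1 -= 1
        else:
            if abs(c0 - pc) >= abs(c1 - pc):
                c0 += 1
            else:
                c1 -= 1
    if r0 > r1 or c0 > c1:
        raise EmptyRoiError(
            f"no pixel satisfies view zenith <= {limit} degrees"
        )
    sub = img.pixels[r0 : r1 + 1, c0 : c1 + 1]
    # Ground side implied by the zenith angle at the clip half-extent.
    half_px = max((r1 - r0 + 1) / 2.0, (c1 - c0 + 1) / 2.0)
    edge_zenith = pixel_view_zenith(
        geom, (pr, pc + half_px), (img.height, img.width)
    )
    ground_side = 2.0 * geom.mount_height_m * math.tan(math.radians(edge_zenith))
    new_pp = (pr - r0, pc - c0)
    new_geom = replace(geom, principal_point=new_pp)
    return CanopyImage(
        sub.copy(),
        bit_depth=img.bit_depth,
        color_mode=img.color_mode,
        acquired_at=img.acquired_at,
        geometry=new_geom,
        ground_side_m=ground_side,
    )


def doy(date: _dt.date | str) -> int:
    """1-based ordinal day of year (e.g. 2015-05-30 -> 150)."""
    if isinstance(date, str):
        date = _dt.date.fromisoformat(date)
    if not isinstance(date, _dt.date):
        raise TypeError("doy expects a date or ISO date string")
    return date.timetuple().tm_yday
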