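"""Leaf/background threshold classification of canopy photographs.

Two pixel rules are provided, both combining three branches with OR:

* method 1 (sparse canopy, evening true-colour image):
  ``(t1 < H < t2 and S*255 > t3) or (G > t4) or (R < t5 and B < t5)``
  — a green hue window with a saturation floor, a highlight branch for
  sun-glinted leaves, and a dark branch that only fires on dry soil
  (t5 = 40); with moist soil t5 = -1 disables it.
* method 2 (dense canopy, converted false-colour noon image):
  ``(G > R + t1 and G > B + t2) or (G > t4) or (R < t5 and B < t5)``
  — green excess over red and blue, plus the same two auxiliary branches.

Hue is in degrees [0, 360); saturation thresholds are on the 0-255 scale
(S*255 compared to t3).  Channel thresholds are 8-bit values and are
rescaled linearly for deeper images.  All inequalities are strict.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .imaging import CanopyImage

__all__ = [
    "ThresholdSet",
    "LeafMask",
    "SelectionError",
    "rgb_to_hls",
    "classify_pixel_method1",
    "classify_pixel_method2",
    "classify_image",
    "choose_classifier",
]


class SelectionError(ValueError):
    """No usable time slot for classifier selection."""


@dataclass(frozen=True)
class ThresholdSet:
    """Thresholds (t1..t5) for one classification rule.

    For method 1, t1/t2 are hue bounds in degrees and t3 a saturation floor
    on the 0-255 scale; for method 2, t1/t2 are green-excess margins.  t4 is
    the highlight floor and t5 the dark-branch ceiling, both 8-bit channel
    values.  A threshold of -1 disables the branch it guards (no
    non-negative sample can satisfy ``x < -1``).
    """

    method: str
    t1: float
    t2: float
    t3: float
    t4: float
    t5: float

    def __post_init__(self) -> None:
        if self.method not in ("method1", "method2"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.method == "method1" and not self.t1 < self.t2:
            raise ValueError("method1 requires t1 < t2 (hue window)")

    @classmethod
    def method1_defaults(cls, soil: str = "moist") -> "ThresholdSet":
        """Defaults (80, 160, 18, 240); t5 = -1 for moist soil, 40 for dry."""
        t5 = {"moist": -1.0, "dry": 40.0}[soil]
        return cls("method1", 80.0, 160.0, 18.0, 240.0, t5)

    @classmethod
    def method2_defaults(cls) -> "ThresholdSet":
        """Defaults (5, 5, -1, 80, -1)."""
        return cls("method2", 5.0, 5.0, -1.0, 80.0, -1.0)


@dataclass
class LeafMask:
    """Binary leaf/background raster aligned with its source image."""

    grid: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid).astype(bool)
        if self.grid.ndim != 2:
            raise ValueError("mask grid must be 2-D")

    @property
    def leaf_count(self) -> int:
        return int(self.grid.sum())

    @property
    def total_count(self) -> int:
        return int(self.grid.size)

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape


def rgb_to_hls(rgb: np.ndarray | Iterable[float], max_value: float = 255.0):
    """Hexcone RGB -> (H, L, S): H in degrees [0, 360), L and S in [0, 1].

    Accepts a single pixel or an (..., 3) array.  Achromatic pixels get
    H = 0, S = 0.  Matches the stdlib ``colorsys`` convention (hue scaled
    to degrees).
    """
    arr = np.asarray(rgb, dtype=float) / max_value
    scalar = arr.ndim == 1
    arr = np.atleast_2d(arr)
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    maxc = np.max(arr, axis=-1)
    minc = np.min(arr, axis=-1)
    L = (maxc + minc) / 2.0
    delta = maxc - minc
    chromatic = delta > 0

    S = np.zeros_like(L)
    lo = chromatic & (L <= 0.5)
    hi = chromatic & (L > 0.5)
    S[lo] = delta[lo] / (maxc + minc)[lo]
    S[hi] = delta[hi] / (2.0 - maxc - minc)[hi]

    H = np.zeros_like(L)
    with np.errstate(invalid="ignore", divide="ignore"):
        rc = np.where(chromatic, (maxc - r) / np.where(delta == 0, 1, delta), 0)
        gc = np.where(chromatic, (maxc - g) / np.where(delta == 0, 1, delta), 0)
        bc = np.where(chromatic, (maxc - b) / np.where(delta == 0, 1, delta), 0)
    is_r = chromatic & (maxc == r)
    is_g = chromatic & (maxc == g) & ~is_r
    is_b = chromatic & ~is_r & ~is_g
    H[is_r] = bc[is_r] - gc[is_r]
    H[is_g] = 2.0 + rc[is_g] - bc[is_g]
    H[is_b] = 4.0 + gc[is_b] - rc[is_b]
    H = (H / 6.0) % 1.0 * 360.0
    if scalar:
        return float(H[0]), float(L[0]), float(S[0])
    return H, L, S


def _rule_method1(r, g, b, thr: ThresholdSet, max_value: float):
    """Vectorised method-1 rule; channel thresholds rescaled to max_value."""
    scale = max_value / 255.0
    H, _, S = rgb_to_hls(np.stack([r, g, b], axis=-1), max_value=max_value)
    branch_hue = (thr.t1 < H) & (H < thr.t2) & (S * 255.0 > thr.t3)
    branch_glint = g > thr.t4 * scale
    branch_dark = (r < thr.t5 * scale) & (b < thr.t5 * scale)
    return branch_hue | branch_glint | branch_dark


def _rule_method2(r, g, b, thr: ThresholdSet, max_value: float):
    scale = max_value / 255.0
    branch_green = (g > r + thr.t1 * scale) & (g > b + thr.t2 * scale)
    branch_glint = g > thr.t4 * scale
    branch_dark = (r < thr.t5 * scale) & (b < thr.t5 * scale)
    return branch_green | branch_glint | branch_dark


def classify_pixel_method1(pixel, thr: ThresholdSet, max_value: float = 255.0) -> bool:
    """Method-1 rule on one pixel: True for leaf."""
    if thr.method != "method1":
        raise ValueError("threshold set is not for method1")
    r, g, b = (np.asarray([float(c)]) for c in pixel)
    return bool(_rule_method1(r, g, b, thr, max_value)[0])


def classify_pixel_method2(pixel, thr: ThresholdSet, max_value: float = 255.0) -> bool:
    """Method-2 rule on one pixel: True for leaf."""
    if thr.method != "method2":
        raise ValueError("threshold set is not for method2")
    r, g, b = (np.asarray([float(c)]) for c in pixel)
    return bool(_rule_method2(r, g, b, thr, max_value)[0])


def classify_image(img: CanopyImage, thr: ThresholdSet) -> LeafMask:
    """Apply the selected pixel rule to every pixel of a true-colour image.

    False-colour acquisitions must go through
    :func:`canopylai.imaging.convert_false_color` first.
    """
    if img.color_mode != "true_color":
        raise ValueError("classify_image requires a true_color image")
    px = img.pixels.astype(float)
    r, g, b = px[..., 0], px[..., 1], px[..., 2]
    rule = _rule_method1 if thr.method == "method1" else _rule_method2
    return LeafMask(rule(r, g, b, thr, float(img.max_value)))


_SLOT_PREFERENCE = {
    # Sparse canopy: evening diffuse light, true colour, hue rule.
    "sparse": ("method1", ("1830", "0530", "1330")),
    # Dense canopy: noon false-colour image, green-excess rule.
    "dense": ("method2", ("1330", "1830", "0530")),
}


def choose_classifier(stage_hint: str, available_slots) -> tuple[str, str]:
    """Pick (method, time slot) for a growth stage.

    Sparse canopies prefer the 18:30 true-colour image with method 1; dense
    canopies prefer the 13:30 false-colour image with method 2.  Falls back
    to any available slot when the preferred one is missing.
    """
    if stage_hint not in _SLOT_PREFERENCE:
        raise ValueError(f"stage_hint must be 'sparse' or 'dense', got {stage_hint!r}")
    slots = {str(s).zfill(4) for s in available_slots}
    if not slots:
        raise SelectionError("no accepted time slots available")
    method, order = _SLOT_PREFERENCE[stage_hint]
    for slot in order:
        if slot in slots:
            return method, slot
    raise SelectionError(f"no recognised time slot in {sorted(slots)}")
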