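"""Boolean-model canopy scene simulator with exactly known LAI.

Flat, horizontal, lens-shaped ("fusiform") leaves are dropped on a
torus-wrapped square plot, either completely at random (Poisson / Boolean
model) or clustered around plant centres.  Because the leaves are flat and
viewed at nadir, the true LAI is exactly (number of leaves x single-leaf
area) / plot area, and for Poisson placement the gap fraction follows the
Boolean-model closed form P_gap = exp(-LAI).  Scenes are rasterised to
binary leaf masks (the ground truth for classification tests) and rendered
to RGB images (the input for classification tests); both are deterministic
under fixed seeds.

The leaf outline is the intersection of two circular arcs through the leaf
tips — pointed ends, widest at midspan — with its area computed in closed
form, so every scene knows its LAI exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .classify import LeafMask
from .imaging import CanopyImage

__all__ = [
    "SceneSpec",
    "ClusterParams",
    "Scene",
    "Appearance",
    "lens_geometry",
    "simulate_scene",
    "rasterize",
    "render_rgb",
]


def lens_geometry(D: float, aspect: float) -> tuple[float, float, float, float]:
    """Dimensions of a circular-arc lens leaf with sqrt(area) = D.

    Returns ``(length, width, arc_radius, area)``.  The outline is the
    intersection of two circles through the tips, with maximal width at
    midspan; for fixed aspect = length/width the area scales with length^2,
    so the closed-form unit-length area gives the length directly.
    """
    if D <= 0:
        raise ValueError("D must be positive")
    if aspect < 1:
        raise ValueError("aspect (length/width) must be >= 1")
    unit_area = _lens_area(1.0, 1.0 / aspect)
    length = D / math.sqrt(unit_area)
    width = length / aspect
    radius = _arc_radius(length, width)
    return length, width, radius, D * D


def _arc_radius(length: float, width: float) -> float:
    h = width / 2.0  # sagitta of each arc
    return length**2 / (8.0 * h) + h / 2.0


def _lens_area(length: float, width: float) -> float:
    """Area of the symmetric two-arc lens (twice a circular segment)."""
    h = width / 2.0
    R = _arc_radius(length, width)
    seg = R * R * math.acos(1.0 - h / R) - (R - h) * math.sqrt(2.0 * R * h - h * h)
    return 2.0 * seg


@dataclass(frozen=True)
class ClusterParams:
    """Clustered-placement parameters: plant density and per-plant leaves.

    Leaves are scattered around their plant centre with an isotropic
    Gaussian of standard deviation ``spread_m`` (defaults to 1.5 D when
    unset, a compact corn-like rosette).
    """

    plants_per_m2: float = 4.0
    leaves_per_plant: int = 12
    spread_m: Optional[float] = None


@dataclass(frozen=True)
class SceneSpec:
    """Specification of a synthetic canopy scene.

    extent : plot side length in metres (torus-wrapped square).
    resolution : raster resolution in pixels per metre.
    target_lai : desired true LAI; whole leaves are added until it is
        first reached or exceeded, so true_lai is within one leaf of it.
    D : equivalent leaf length in metres, sqrt of the single-leaf area.
    aspect : leaf length/width ratio (6 by default, corn-like).
    placement : "poisson" (Boolean model) or "clustered".
    """

    target_lai: float
    extent: float = 6.0
    resolution: float = 300.0
    D: float = 0.09
    aspect: float = 6.0
    placement: str = "poisson"
    cluster_params: ClusterParams = field(default_factory=ClusterParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.extent <= 0 or self.resolution <= 0:
            raise ValueError("extent and resolution must be positive")
        if self.target_lai < 0:
            raise ValueError("target_lai must be non-negative")
        if self.D <= 0:
            raise ValueError("D must be positive")
        if self.aspect < 1:
            raise ValueError("aspect must be >= 1")
        if self.placement not in ("poisson", "clustered"):
            raise ValueError(f"unknown placement {self.placement!r}")
        if self.target_lai > 0 and self.D > self.extent:
            raise ValueError("leaf length D exceeds the scene extent")


@dataclass
class Scene:
    """Placed leaves with their exactly known LAI.

    ``centers`` is an (n, 2) array of (x, y) leaf centres in metres,
    ``angles`` the leaf long-axis orientations in radians.
    """

    centers: np.ndarray
    angles: np.ndarray
    length: float
    width: float
    arc_radius: float
    true_lai: float
    spec: SceneSpec

    @property
    def n_leaves(self) -> int:
        return int(len(self.centers))

    @property
    def leaf_area(self) -> float:
        return self.spec.D ** 2


def simulate_scene(spec: SceneSpec) -> Scene:
    """Place leaves according to the spec; deterministic for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    length, width, radius, leaf_area = lens_geometry(spec.D, spec.aspect)
    area = spec.extent**2
    n = int(math.ceil(spec.target_lai * area / leaf_area)) if spec.target_lai > 0 else 0
    if n == 0:
        centers = np.empty((0, 2))
        angles = np.empty(0)
    elif spec.placement == "poisson":
        centers = rng.uniform(0.0, spec.extent, size=(n, 2))
        angles = rng.uniform(0.0, 2.0 * math.pi, size=n)
    else:
        cp = spec.cluster_params
        n_plants = max(1, int(round(cp.plants_per_m2 * area)))
        plant_xy = rng.uniform(0.0, spec.extent, size=(n_plants, 2))
        owner = rng.integers(0, n_plants, size=n)
        spread = cp.spread_m if cp.spread_m is not None else 1.5 * spec.D
        offsets = rng.normal(0.0, spread, size=(n, 2))
        centers = (plant_xy[owner] + offsets) % spec.extent
        angles = rng.uniform(0.0, 2.0 * math.pi, size=n)
    true_lai = n * leaf_area / area
    return Scene(
        centers=centers,
        angles=angles,
        length=length,
        width=width,
        arc_radius=radius,
        true_lai=true_lai,
        spec=spec,
    )


def rasterize(scene: Scene, resolution: Optional[float] = None) -> LeafMask:
    """Rasterise leaf outlines to a binary mask (torus-wrapped).

    A pixel is leaf iff its centre falls inside at least one leaf outline
    (inside both defining circles).  Requires at least 4 pixels across a
    leaf so outlines are resolved.
    """
    res = resolution if resolution is not None else scene.spec.resolution
    if res * scene.spec.D < 4:
        raise ValueError(
            f"under-resolved leaves: resolution*D = {res * scene.spec.D:.2f} < 4 px"
        )
    extent = scene.spec.extent
    npx = int(round(extent * res))
    mask = np.zeros((npx, npx), dtype=bool)
    if scene.n_leaves == 0:
        return LeafMask(mask)

    R = scene.arc_radius
    off = R - scene.width / 2.0  # arc-centre offset from the leaf centre
    half_len = scene.length / 2.0
    half_wid = scene.width / 2.0
    cos_a = np.cos(scene.angles)
    sin_a = np.sin(scene.angles)
    # Arc centres lie on the width axis, symmetric about the leaf centre.
    c1 = scene.centers + off * np.stack([-sin_a, cos_a], axis=1)
    c2 = scene.centers - off * np.stack([-sin_a, cos_a], axis=1)
    # Axis-aligned bounding half-sizes of the rotated leaf.
    bx = np.abs(cos_a) * half_len + np.abs(sin_a) * half_wid
    by = np.abs(sin_a) * half_len + np.abs(cos_a) * half_wid

    R2 = R * R
    for i in range(scene.n_leaves):
        x, y = scene.centers[i]
        col0 = int(math.floor((x - bx[i]) * res - 0.5))
        col1 = int(math.ceil((x + bx[i]) * res - 0.5))
        row0 = int(math.floor((y - by[i]) * res - 0.5))
        row1 = int(math.ceil((y + by[i]) * res - 0.5))
        cols = np.arange(col0, col1 + 1)
        rows = np.arange(row0, row1 + 1)
        xs = (cols + 0.5) / res
        ys = (rows + 0.5) / res
        dx1 = xs[None, :] - c1[i, 0]
        dy1 = ys[:, None] - c1[i, 1]
        dx2 = xs[None, :] - c2[i, 0]
        dy2 = ys[:, None] - c2[i, 1]
        inside = (dx1 * dx1 + dy1 * dy1 <= R2) & (dx2 * dx2 + dy2 * dy2 <= R2)
        rr, cc = np.nonzero(inside)
        if rr.size:
            mask[rows[rr] % npx, cols[cc] % npx] = True
    return LeafMask(mask)


@dataclass(frozen=True)
class Appearance:
    """Rendering appearance: base colours, jitter, glint and sensor noise.

    ``glint_fraction`` of leaf pixels are pushed to white (sun glint);
    ``noise_sd`` is additive Gaussian channel noise on the 8-bit scale.
    """

    leaf_color: tuple[float, float, float] = (0.0, 200.0, 0.0)
    # Soil green kept below the method-2 highlight threshold (G > 80), as in
    # the darkened false-colour acquisitions that rule is designed for.
    soil_color: tuple[float, float, float] = (110.0, 70.0, 45.0)
    leaf_jitter: float = 0.0
    soil_jitter: float = 0.0
    glint_fraction: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.glint_fraction <= 1.0:
            raise ValueError("glint_fraction must lie in [0, 1]")
        if self.noise_sd < 0 or self.leaf_jitter < 0 or self.soil_jitter < 0:
            raise ValueError("noise and jitter must be non-negative")


def render_rgb(
    scene: Scene,
    app: Appearance | None = None,
    resolution: Optional[float] = None,
) -> tuple[CanopyImage, LeafMask]:
    """Render the scene to an 8-bit RGB image plus its ground-truth mask."""
    app = app or Appearance()
    truth = rasterize(scene, resolution)
    rng = np.random.default_rng(app.seed)
    h, w = truth.shape
    img = np.empty((h, w, 3), dtype=float)
    img[~truth.grid] = app.soil_color
    img[truth.grid] = app.leaf_color
    if app.soil_jitter > 0:
        img[~truth.grid] += rng.normal(0, app.soil_jitter, size=(int((~truth.grid).sum()), 3))
    if app.leaf_jitter > 0:
        img[truth.grid] += rng.normal(0, app.leaf_jitter, size=(truth.leaf_count, 3))
    if app.glint_fraction > 0 and truth.leaf_count:
        leaf_idx = np.flatnonzero(truth.grid.ravel())
        n_glint = int(round(app.glint_fraction * leaf_idx.size))
        if n_glint:
            chosen = rng.choice(leaf_idx, size=n_glint, replace=False)
            flat = img.reshape(-1, 3)
            flat[chosen] = (255.0, 255.0, 255.0)
    if app.noise_sd > 0:
        img += rng.normal(0, app.noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return CanopyImage(img, bit_depth=8, color_mode="true_color"), truth
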