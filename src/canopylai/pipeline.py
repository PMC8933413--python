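"""End-to-end pipeline: manifest of photographs -> per-image LAI table.

Each manifest row names an image with its site, date, time slot, colour
mode and a human-inspection accept flag.  Accepted images are read,
converted from false colour if needed, clipped to the near-nadir ROI,
classified, tiled into sample squares, and inverted to LAI with both the
classical and the improved estimator.  Failures are logged per image and
skipped; the run is deterministic for a fixed configuration.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import classify as _classify
from . import gaps as _gaps
from . import imaging as _imaging
from . import validation as _validation

__all__ = ["PipelineConfig", "run_pipeline", "run_validation", "RESULT_COLUMNS"]

log = logging.getLogger("canopylai")

RESULT_COLUMNS = [
    "image", "site", "doy", "time_slot", "method", "classifier",
    "L", "omega", "fvc", "m", "W_px", "D_px", "zero_gap_squares",
]


@dataclass
class PipelineConfig:
    """All tunables of the measurement pipeline with their defaults.

    Defaults mirror the deployed system: method-1 thresholds
    (80, 160, 18, 240) with the dry-soil branch off, method-2 thresholds
    (5, 5, -1, 80, -1), a 30-degree zenith ROI from a 120-degree lens at
    3 m, and sample squares of side W = 3 D.
    """

    classifier: str = "method1"        # method1 | method2 | auto
    soil: str = "moist"                # moist | dry (method1 t5 branch)
    t_overrides: dict = field(default_factory=dict)
    stage_hint: str = "sparse"         # used when classifier == "auto"
    fov_deg: float = 120.0
    mount_height_m: float = 3.0
    projection: str = "equidistant"
    max_view_zenith_deg: float = 30.0
    D_px: int = 30
    W_px: Optional[int] = None         # default 3 * D_px
    lad: str = "spherical"             # spherical | horizontal
    log_base: str = "natural"
    zero_gap: str = "substitute"       # substitute | error
    seed: int = 0
    out_dir: str = "."
    verbosity: int = 1

    def __post_init__(self) -> None:
        if self.W_px is None:
            self.W_px = 3 * self.D_px
        if self.classifier not in ("method1", "method2", "auto"):
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if self.soil not in ("moist", "dry"):
            raise ValueError(f"unknown soil mode {self.soil!r}")
        if self.lad not in ("spherical", "horizontal"):
            raise ValueError(f"unknown leaf angle model {self.lad!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__ if not f.startswith("_")}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {k: v for k, v in asdict(self).items() if not k.startswith("_")}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    def threshold_set(self, method: str) -> _classify.ThresholdSet:
        if method == "method1":
            thr = _classify.ThresholdSet.method1_defaults(self.soil)
        else:
            thr = _classify.ThresholdSet.method2_defaults()
        if self.t_overrides:
            thr = replace(thr, **{k: float(v) for k, v in self.t_overrides.items()})
        return thr

    def camera_geometry(self) -> _imaging.CameraGeometry:
        return _imaging.CameraGeometry(
            fov_deg=self.fov_deg,
            mount_height_m=self.mount_height_m,
            projection=self.projection,
        )


def _process_one(row: pd.Series, config: PipelineConfig) -> list[dict]:
    img = _imaging.read_image(
        row["path"],
        color_mode=row.get("color_mode", "true_color"),
        geometry=config.camera_geometry(),
    )
    slot = str(row.get("time_slot", "")).zfill(4)
    if img.color_mode == "false_color":
        img = _imaging.convert_false_color(img)
    roi = _imaging.clip_roi(
        img, _imaging.RoiSpec(max_view_zenith_deg=config.max_view_zenith_deg)
    )
    if config.classifier == "auto":
        method, _ = _classify.choose_classifier(config.stage_hint, {slot} if slot.strip("0") else {"1830"})
    else:
        method = config.classifier
    mask = _classify.classify_image(roi, config.threshold_set(method))
    grid = _gaps.gap_grid(mask, config.W_px)
    lad = _gaps.LeafAngleModel(config.lad)
    coeff = _gaps.ImprovedCoefficients(
        W=float(config.W_px), D=float(config.D_px), log_base=config.log_base
    )
    est_c = _gaps.lai_classical(grid, lad, zero_gap=config.zero_gap)
    est_i = _gaps.lai_improved(grid, coeff, lad)
    base = {
        "image": str(row["path"]),
        "site": row.get("site", ""),
        "doy": row.get("doy", ""),
        "time_slot": slot,
        "classifier": method,
        "m": grid.m,
        "W_px": config.W_px,
        "D_px": config.D_px,
    }
    out = []
    for est in (est_c, est_i):
        rec = dict(base)
        rec.update(
            method=est.method, L=est.L, omega=est.omega, fvc=est.fvc,
            zero_gap_squares=est.zero_gap_squares,
        )
        out.append(rec)
    return out


def run_pipeline(manifest: pd.DataFrame | str | Path, config: PipelineConfig | None = None):
    """Run the full measurement chain over an image manifest.

    Returns ``(results DataFrame, skipped list)``; each skipped entry is
    (path, reason).  Rows with ``accepted`` false are skipped up front (the
    human image-quality inspection is modelled as this flag).
    """
    config = config or PipelineConfig()
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest)
    if len(manifest) == 0:
        raise ValueError("empty manifest")
    results: list[dict] = []
    skipped: list[tuple[str, str]] = []
    for _, row in manifest.iterrows():
        path = str(row["path"])
        accepted = row.get("accepted", True)
        if isinstance(accepted, str):
            accepted = accepted.strip().lower() in ("1", "true", "yes")
        if not accepted:
            skipped.append((path, "rejected by image-quality inspection"))
            log.info("skip %s: rejected", path)
            continue
        try:
            results.extend(_process_one(row, config))
        except Exception as exc:  # per-image failure must not kill the run
            skipped.append((path, str(exc)))
            log.warning("skip %s: %s", path, exc)
    df = pd.DataFrame(results, columns=RESULT_COLUMNS)
    return df, skipped


def run_validation(results: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Join estimate and truth tables on (site, doy) and score each source.

    ``results`` needs columns (site, doy, lai_est, source); ``truth`` needs
    (site, doy, lai_true).  Returns one row of comparison statistics per
    source.
    """
    merged = results.merge(truth, on=["site", "doy"])
    if len(merged) == 0:
        raise ValueError("no (site, doy) keys in common between results and truth")
    rows = []
    for source, grp in merged.groupby("source"):
        st = _validation.comparison_stats(grp["lai_true"], grp["lai_est"])
        rows.append(
            {
                "source": source,
                "n": st.n,
                "slope": st.slope,
                "intercept": st.intercept,
                "r_value": st.r_value,
                "rmse_error": st.rmse_error,
                "rmse_residual": st.rmse_residual,
                "max_abs_error": st.max_abs_error,
                "bias": st.bias,
            }
        )
    return pd.DataFrame(rows)
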