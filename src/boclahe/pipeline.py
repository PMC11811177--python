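"""End-to-end BO-CLAHE orchestration.

Loads an image and its lung mask, optimizes the CLAHE clip limit and
tile grid against the combined SSIM/BRISQUE objective evaluated inside
the mask, and emits the enhanced image plus a JSON-serializable report
carrying the best parameters, the objective components, and the full
iteration trace.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from boclahe.bayes_opt import (
    AcquisitionSpec,
    Bounds,
    GpConfig,
    OptSettings,
    Trace,
    TraceRecord,
    optimize,
)
from boclahe.clahe_core import ClaheParams, apply_clahe_masked
from boclahe.errors import ConsistencyError, FormatError, InputError
from boclahe.quality_metrics import ObjectiveConfig, objective_components

__all__ = [
    "RunConfig",
    "EnhancementReport",
    "load_gray_image",
    "load_mask",
    "save_gray_image",
    "run_boclahe",
    "write_report",
    "read_report",
]


def load_gray_image(path) -> np.ndarray:
    """Load a PNG as an 8-bit grayscale array.

    RGB inputs are converted by integer BT.601 luma (rounded);
    16-bit inputs are linearly rescaled to 0-255.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            mode = im.mode
            arr = np.asarray(im)
    except Exception as exc:
        raise InputError(f"cannot read image file: {path}") from exc
    if mode == "L":
        return arr.astype(np.uint8)
    if mode in ("I", "I;16", "I;16B"):
        a = arr.astype(np.float64)
        return np.floor(a * 255.0 / 65535.0 + 0.5).clip(0, 255).astype(np.uint8)
    if mode in ("RGB", "RGBA"):
        rgb = arr[..., :3].astype(np.float64)
        luma = 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
        return np.floor(luma + 0.5).clip(0, 255).astype(np.uint8)
    raise InputError(f"unsupported image mode {mode!r}: {path}")


def load_mask(path) -> np.ndarray:
    """Load a PNG mask; nonzero pixels are foreground."""
    path = Path(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except Exception as exc:
        raise InputError(f"cannot read mask file: {path}") from exc
    if arr.ndim == 3:
        arr = arr[..., :3].max(axis=-1)
    return arr != 0


def save_gray_image(image: np.ndarray, path) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="L").save(path)


@dataclass(frozen=True)
class RunConfig:
    """Run-level parameter set; defaults follow the study's settings."""

    clip_limit_min: float = 1.0
    clip_limit_max: float = 255.0
    tile_grid_min: float = 8.0
    tile_grid_max: float = 32.0
    init_points: int = 25
    n_iter: int = 25
    kappa: float = 2.576
    xi: float = 0.01
    noise_alpha: float = 1e-6
    n_restarts: int = 5
    normalize_y: bool = True
    acquisition: str = "ucb"
    w_ssim: float = 1.0
    w_brisque: float = 1.0
    brisque_norm: float = 100.0
    seed: int = 0

    def bounds(self) -> Bounds:
        return Bounds(clip_limit=(self.clip_limit_min, self.clip_limit_max),
                      tile_grid=(self.tile_grid_min, self.tile_grid_max))

    def gp_config(self) -> GpConfig:
        return GpConfig(noise_alpha=self.noise_alpha, normalize_y=self.normalize_y,
                        n_restarts=self.n_restarts)

    def settings(self) -> OptSettings:
        return OptSettings(init_points=self.init_points, n_iter=self.n_iter,
                           seed=self.seed,
                           acquisition=AcquisitionSpec(kind=self.acquisition,
                                                       kappa=self.kappa, xi=self.xi))

    def objective_config(self) -> ObjectiveConfig:
        return ObjectiveConfig(w_ssim=self.w_ssim, w_brisque=self.w_brisque,
                               brisque_norm=self.brisque_norm)


@dataclass
class EnhancementReport:
    best_clip_limit: float
    best_tile_grid: float
    best_objective: float
    best_ssim: float
    best_brisque: float
    trace: list  # of TraceRecord
    warnings: list
    config: dict
    seed: int

    def to_dict(self) -> dict:
        return {
            "best_clip_limit": self.best_clip_limit,
            "best_tile_grid": self.best_tile_grid,
            "best_objective": self.best_objective,
            "best_ssim": self.best_ssim,
            "best_brisque": self.best_brisque,
            "trace": [
                {
                    "iteration": r.iteration,
                    "phase": r.phase,
                    "clip_limit": r.clip_limit,
                    "tile_grid": r.tile_grid,
                    "objective": r.objective,
                    **{k: r.extras[k] for k in ("ssim", "brisque") if k in r.extras},
                }
                for r in self.trace
            ],
            "warnings": list(self.warnings),
            "config": dict(self.config),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnhancementReport":
        try:
            trace = [
                TraceRecord(
                    iteration=row["iteration"],
                    phase=row["phase"],
                    clip_limit=row["clip_limit"],
                    tile_grid=row["tile_grid"],
                    objective=row["objective"],
                    extras={k: row[k] for k in ("ssim", "brisque") if k in row},
                )
                for row in d["trace"]
            ]
            return cls(
                best_clip_limit=d["best_clip_limit"],
                best_tile_grid=d["best_tile_grid"],
                best_objective=d["best_objective"],
                best_ssim=d["best_ssim"],
                best_brisque=d["best_brisque"],
                trace=trace,
                warnings=list(d["warnings"]),
                config=dict(d["config"]),
                seed=d["seed"],
            )
        except (KeyError, TypeError) as exc:
            raise FormatError(f"malformed report document: {exc}") from exc


def run_boclahe(image, mask, config: RunConfig | None = None):
    """Optimize CLAHE parameters for one image and apply the best pair.

    Returns ``(enhanced_image, report)``.  Pixels outside the mask are
    never modified.  An empty mask short-circuits: the input is returned
    unchanged and the report carries a warning.
    """
    if config is None:
        config = RunConfig()
    img = np.asarray(image, dtype=np.uint8)
    m = np.asarray(mask, dtype=bool)
    if m.shape != img.shape:
        raise ConsistencyError("mask shape must match image shape")

    if not m.any():
        report = EnhancementReport(
            best_clip_limit=float("nan"), best_tile_grid=float("nan"),
            best_objective=float("nan"), best_ssim=float("nan"),
            best_brisque=float("nan"), trace=[],
            warnings=["empty mask: image returned unchanged"],
            config=dataclasses.asdict(config), seed=config.seed)
        return img.copy(), report

    obj_cfg = config.objective_config()
    cache: dict[tuple, tuple] = {}

    def evaluate(clip_limit: float, tile_grid: float):
        key = (clip_limit, tile_grid)
        if key not in cache:
            enhanced = apply_clahe_masked(img, m, ClaheParams(clip_limit, tile_grid))
            comps = objective_components(img, enhanced, m, obj_cfg)
            cache[key] = (enhanced, comps)
        enhanced, comps = cache[key]
        return comps["objective"], {"ssim": comps["ssim"], "brisque": comps["brisque"]}

    trace = optimize(evaluate, config.bounds(), config.settings(), config.gp_config())

    best_clip, best_grid = trace.best_params
    enhanced, comps = cache[(best_clip, best_grid)]
    report = EnhancementReport(
        best_clip_limit=best_clip, best_tile_grid=best_grid,
        best_objective=comps["objective"], best_ssim=comps["ssim"],
        best_brisque=comps["brisque"], trace=trace.records, warnings=[],
        config=dataclasses.asdict(config), seed=config.seed)
    return enhanced.copy(), report


def run_boclahe_cohort(images, masks, config: RunConfig | None = None):
    """Optimize one shared CLAHE parameter pair for a cohort of images.

    The shared objective is the mean of the per-image combined objectives;
    a shared pair is a constrained special case of per-image optimization,
    so any image's own run with the same budget should match or beat the
    shared value for that image.  Returns ``(params, per_image_objectives,
    trace)`` with the enhanced images left to the caller.
    """
    if config is None:
        config = RunConfig()
    imgs = [np.asarray(im, dtype=np.uint8) for im in images]
    ms = [np.asarray(m, dtype=bool) for m in masks]
    if len(imgs) != len(ms) or not imgs:
        raise ConsistencyError("need equally many images and masks, at least one")
    for im, m in zip(imgs, ms):
        if im.shape != m.shape or not m.any():
            raise ConsistencyError("each mask must match its image and be nonempty")
    obj_cfg = config.objective_config()

    def evaluate(clip_limit: float, tile_grid: float):
        params = ClaheParams(clip_limit, tile_grid)
        vals = [
            objective_components(im, apply_clahe_masked(im, m, params), m, obj_cfg)["objective"]
            for im, m in zip(imgs, ms)
        ]
        return float(np.mean(vals))

    trace = optimize(evaluate, config.bounds(), config.settings(), config.gp_config())
    best = ClaheParams(*trace.best_params)
    per_image = [
        objective_components(im, apply_clahe_masked(im, m, best), m, obj_cfg)["objective"]
        for im, m in zip(imgs, ms)
    ]
    return best, per_image, trace


def write_report(report: EnhancementReport, path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)


def read_report(path) -> EnhancementReport:
    try:
        with open(path) as fh:
            d = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed report file: {path}") from exc
    return EnhancementReport.from_dict(d)
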