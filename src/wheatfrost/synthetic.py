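"""Seeded synthetic nadir canopy scenes with exact ground-truth masks.

The generator emulates what the segmentation pipeline actually sees in a
frost-damaged wheat plot photographed straight down: narrow green blades
clustered into planting rows over a textured brown soil background, with an
optional fraction of each blade's tip recolored to the straw/white palette of
freeze-killed tissue.  It does not attempt photorealism — no specular
highlights, no 3-D canopy, no cast shadows — only the color statistics that
drive index-based segmentation.

Ground truth is exact by construction: blades are rasterized with hard pixel
membership (no anti-aliasing on the truth masks), withered tip pixels are
excluded from the plant mask (frozen tissue does not count toward coverage),
and the generator keeps adding blades until the green coverage is within
+/- 0.5 percentage points of the requested target or errors out.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage.draw import polygon

from .experiment import ExperimentLayout, PlotID, count_images, enumerate_plots
from .phenotypes import grade

__all__ = [
    "GREEN_PALETTE",
    "SOIL_PALETTE",
    "WITHERED_PALETTE",
    "SceneParams",
    "SyntheticScene",
    "generate_scene",
    "generate_experiment",
    "DEFAULT_COVERAGE_BY_GRADE",
]

# Wheat-seedling greens, dark post-frost soil browns, and straw-to-bleached
# withered tones.  Soil hues sit near 30 deg, well below the straw-yellow
# window, and green ExV exceeds soil ExV by > 1 index unit.
GREEN_PALETTE: tuple[tuple[int, int, int], ...] = (
    (25, 140, 35),
    (45, 165, 55),
    (15, 120, 30),
    (60, 180, 70),
)
SOIL_PALETTE: tuple[tuple[int, int, int], ...] = (
    (120, 84, 48),
    (105, 74, 42),
    (90, 64, 38),
)
WITHERED_PALETTE: tuple[tuple[int, int, int], ...] = (
    (210, 200, 120),
    (228, 222, 170),
    (238, 236, 214),
    (200, 182, 95),
)

COVERAGE_TOL_PCT = 0.5  # generator stops within this many points of target


@dataclass(frozen=True)
class SceneParams:
    """Knobs of one synthetic plot scene.

    ``target_coverage_pct`` is the green (non-withered) pixel fraction the
    scene must hit to within 0.5 points.  ``withered_tip_fraction`` is the
    fraction of each blade's pixels (at the tip end) recolored from the
    withered palette; those pixels leave the plant truth mask.
    ``illumination_jitter`` applies one multiplicative brightness factor per
    scene, drawn uniformly from 1 +/- the given half-range, mimicking the
    narrow illumination band of controlled acquisition; ``noise_sd`` is
    additive Gaussian sensor noise in gray levels per channel.
    """

    width: int = 256
    height: int = 256
    target_coverage_pct: float = 12.0
    n_rows: int = 6
    blade_length_px: tuple[int, int] = (24, 60)
    blade_width_px: tuple[int, int] = (2, 5)
    withered_tip_fraction: float = 0.0
    green_palette: tuple[tuple[int, int, int], ...] = GREEN_PALETTE
    soil_palette: tuple[tuple[int, int, int], ...] = SOIL_PALETTE
    withered_palette: tuple[tuple[int, int, int], ...] = WITHERED_PALETTE
    illumination_jitter: float = 0.04
    noise_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 8 or self.height < 8:
            raise ValueError("scene must be at least 8 x 8 pixels")
        if not 0.0 <= self.target_coverage_pct <= 95.0:
            raise ValueError(
                f"target_coverage_pct must be in [0, 95], got {self.target_coverage_pct}"
            )
        if not 0.0 <= self.withered_tip_fraction <= 1.0:
            raise ValueError("withered_tip_fraction must be in [0, 1]")
        if self.n_rows < 1:
            raise ValueError("n_rows must be >= 1")
        for name in ("green_palette", "soil_palette", "withered_palette"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"{name} must be non-empty")
        lo, hi = self.blade_length_px
        wlo, whi = self.blade_width_px
        if not (1 <= lo <= hi and 1 <= wlo <= whi):
            raise ValueError("blade length/width ranges must be 1 <= lo <= hi")


@dataclass(frozen=True)
class SyntheticScene:
    image: np.ndarray          # H x W x 3 uint8
    plant_truth: np.ndarray    # H x W bool: green pixels only
    withered_truth: np.ndarray # H x W bool: recolored tip pixels
    true_coverage_pct: float
    params: SceneParams


def _soil_background(p: SceneParams, rng: np.random.Generator) -> np.ndarray:
    """Brightness-modulated soil: one base hue per scene, low-frequency texture.

    Modulating brightness only (not chroma) keeps the soil hue fixed, the way
    moist bare soil varies in a nadir photo.
    """
    base = np.array(p.soil_palette[rng.integers(len(p.soil_palette))], dtype=np.float64)
    coarse = rng.random((max(2, p.height // 32), max(2, p.width // 32)))
    zoom = (p.height / coarse.shape[0], p.width / coarse.shape[1])
    texture = ndimage.zoom(coarse, zoom, order=1)[: p.height, : p.width]
    gain = 0.88 + 0.22 * texture  # value-noise brightness field in [0.88, 1.10]
    return base[None, None, :] * gain[..., None]


def _blade_pixels(
    p: SceneParams, rng: np.random.Generator, length_cap: int | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rasterize one blade; returns (rows, cols, tip_flag) per pixel.

    Blades are oriented elongated strips; centers cluster into ``n_rows``
    horizontal bands (the planting rows).  ``tip_flag`` marks the pixels in
    the final ``withered_tip_fraction`` of the blade's long axis.
    """
    lo, hi = p.blade_length_px
    if length_cap is not None:
        # final filler blades may be shorter than the nominal range so the
        # coverage target can be approached without overshooting
        hi = min(hi, max(3, length_cap))
        lo = min(lo, hi)
    length = int(rng.integers(lo, hi + 1))
    width = int(rng.integers(p.blade_width_px[0], p.blade_width_px[1] + 1))

    band = int(rng.integers(p.n_rows))
    band_h = p.height / p.n_rows
    cy = band * band_h + band_h / 2 + rng.normal(0, band_h / 5)
    cx = rng.uniform(0, p.width)
    theta = rng.uniform(0, 2 * np.pi)

    ax = np.array([np.cos(theta), np.sin(theta)])       # along blade
    px_ = np.array([-np.sin(theta), np.cos(theta)])     # across blade
    base = np.array([cx, cy]) - ax * length / 2
    corners = np.array(
        [
            base + px_ * width / 2,
            base - px_ * width / 2,
            base + ax * length - px_ * width / 2,
            base + ax * length + px_ * width / 2,
        ]
    )
    rr, cc = polygon(corners[:, 1], corners[:, 0], shape=(p.height, p.width))
    if rr.size == 0:
        return rr, cc, np.zeros(0, dtype=bool)
    # position of each pixel along the blade axis, 0 at base, 1 at tip
    rel = ((cc - base[0]) * ax[0] + (rr - base[1]) * ax[1]) / max(length, 1)
    tip = rel >= 1.0 - p.withered_tip_fraction if p.withered_tip_fraction > 0 else np.zeros(rr.size, dtype=bool)
    return rr, cc, tip


def generate_scene(p: SceneParams) -> SyntheticScene:
    """Render one scene; deterministic for a fixed parameter set (seed included).

    Raises ``RuntimeError`` if the coverage target cannot be reached within a
    bounded number of blade placements (e.g. geometry too coarse for the
    requested tolerance).
    """
    rng = np.random.default_rng(p.seed)
    total_px = p.height * p.width
    img = _soil_background(p, rng)
    plant = np.zeros((p.height, p.width), dtype=bool)
    withered = np.zeros((p.height, p.width), dtype=bool)

    target_px = p.target_coverage_pct / 100.0 * total_px
    tol_px = COVERAGE_TOL_PCT / 100.0 * total_px
    max_iter = 200 + int(40 * target_px / max(p.blade_length_px[0], 1))

    if p.target_coverage_pct > 0:
        for _ in range(max_iter):
            green_px = int(plant.sum())
            deficit = target_px - green_px
            if deficit <= tol_px * 0.5:
                break
            # shrink blades as the target nears so a single blade cannot
            # overshoot the +/-0.5-point band
            mean_w = (p.blade_width_px[0] + p.blade_width_px[1]) / 2
            cap = max(3, int(deficit / mean_w) + 2)
            rr, cc, tip = _blade_pixels(p, rng, length_cap=cap)
            if rr.size == 0:
                continue
            color = np.array(
                p.green_palette[rng.integers(len(p.green_palette))], dtype=np.float64
            ) * rng.uniform(0.93, 1.07)
            img[rr[~tip], cc[~tip]] = np.clip(color, 0, 255)
            plant[rr[~tip], cc[~tip]] = True
            withered[rr[~tip], cc[~tip]] = False
            if tip.any():
                wcolor = np.array(
                    p.withered_palette[rng.integers(len(p.withered_palette))],
                    dtype=np.float64,
                )
                img[rr[tip], cc[tip]] = wcolor
                withered[rr[tip], cc[tip]] = True
                plant[rr[tip], cc[tip]] = False
        green_px = int(plant.sum())
        if abs(green_px - target_px) > tol_px:
            raise RuntimeError(
                f"could not reach target coverage {p.target_coverage_pct}% "
                f"within {max_iter} blade placements "
                f"(achieved {100.0 * green_px / total_px:.2f}%)"
            )

    illum = 1.0 + rng.uniform(-p.illumination_jitter, p.illumination_jitter)
    img = img * illum
    if p.noise_sd > 0:
        img = img + rng.normal(0.0, p.noise_sd, size=img.shape)
    img = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)

    return SyntheticScene(
        image=img,
        plant_truth=plant,
        withered_truth=withered,
        true_coverage_pct=100.0 * float(plant.sum()) / total_px,
        params=p,
    )


# Target-coverage band (percent) per true frost grade, spanning the grade's
# interval with margin so the scene's own +/-0.5-point tolerance cannot move
# it across a grade boundary.
DEFAULT_COVERAGE_BY_GRADE: dict[int, tuple[float, float]] = {
    1: (16.0, 21.0),
    2: (11.0, 14.0),
    3: (6.0, 9.0),
    4: (1.0, 4.0),
}


def generate_experiment(
    layout: ExperimentLayout,
    out_dir: str | Path,
    coverage_by_grade: dict[int, tuple[float, float]] | None = None,
    seed: int = 0,
    scene_params: SceneParams | None = None,
) -> Path:
    """Emit one scene per (plot, image index) plus a ground-truth CSV.

    Each plot is assigned a true grade uniformly at random, a per-plot target
    coverage drawn from that grade's band, and ``images_per_plot`` scenes
    whose per-image targets jitter slightly around the plot target.  Images
    are named ``{variety}_{treatment}_{replicate}_{k}.png``; the truth table
    ``truth.csv`` lists plot id, image path, true coverage and true grade.

    Returns the path of the truth CSV.
    """
    coverage_by_grade = coverage_by_grade or DEFAULT_COVERAGE_BY_GRADE
    base = scene_params or SceneParams()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    plots = enumerate_plots(layout)

    rows = []
    for plot in plots:
        g = int(rng.choice(sorted(coverage_by_grade)))
        lo, hi = coverage_by_grade[g]
        plot_target = float(rng.uniform(lo, hi))
        for k in range(1, layout.images_per_plot + 1):
            img_target = float(
                np.clip(plot_target + rng.uniform(-0.3, 0.3), 0.0, 95.0)
            )
            scene = generate_scene(
                replace(
                    base,
                    target_coverage_pct=img_target,
                    seed=int(rng.integers(2**31)),
                )
            )
            name = f"{plot.variety}_{plot.treatment_label}_{plot.replicate}_{k}.png"
            iio.imwrite(out_dir / name, scene.image)
            rows.append(
                {
                    "plot_id": str(plot),
                    "variety": plot.variety,
                    "treatment": plot.treatment_label,
                    "replicate": plot.replicate,
                    "image": name,
                    "true_coverage_pct": round(scene.true_coverage_pct, 4),
                    "true_grade": grade(scene.true_coverage_pct).grade,
                    "plot_true_grade": g,
                }
            )
    assert len(rows) == count_images(layout)

    truth_path = out_dir / "truth.csv"
    with open(truth_path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)
    return truth_path
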