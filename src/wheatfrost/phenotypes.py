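"""Per-image and per-plot frost-injury phenotypes.

Three quantities are extracted from each nadir plot photo:

* **vegetation coverage** — the fraction of pixels classified as green plant
  tissue, in percent.  Withered (frozen) tissue is excluded by construction,
  since it segments as background.
* **frost-damage grade** — an ordinal 1–4 severity class from coverage
  intervals: grade 1 (lightest, "no obvious") above 15 %, grade 2 ("slight")
  in [10, 15), grade 3 ("severe") in [5, 10), grade 4 ("most severe") below
  5 %.  Lower coverage after a freeze means more tissue was killed.
* **withered-leaf fraction** — the share of pixels that are desiccated
  yellow-white leaf tissue, found by thresholding in HSI color space: a hue
  window around yellow for the straw-colored tips plus a low-saturation /
  high-intensity branch for fully bleached (near-white) tissue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .indices import as_rgb_array

__all__ = [
    "CoverageResult",
    "FrostGrade",
    "GRADE_LABELS",
    "WitheredThresholds",
    "WitheredResult",
    "coverage",
    "grade",
    "rgb_to_hsi",
    "withered_extract",
    "aggregate_plot",
    "treatment_ranking_summary",
]

GRADE_LABELS = {1: "no obvious", 2: "slight", 3: "severe", 4: "most severe"}

# Coverage-percent lower bounds of grades 1..4 under the severity mapping
# (grade 1 = lightest injury = highest coverage).
_GRADE_BOUNDS = (15.0, 10.0, 5.0)


@dataclass(frozen=True)
class CoverageResult:
    """Green-pixel fraction of one image."""

    coverage_pct: float
    plant_px: int
    total_px: int


@dataclass(frozen=True)
class FrostGrade:
    grade: int
    label: str


def coverage(mask: np.ndarray) -> CoverageResult:
    """Vegetation coverage of a plant mask as an exact pixel ratio."""
    mask = np.asarray(mask, dtype=bool)
    total = mask.size
    if total == 0:
        raise ValueError("cannot compute coverage of an empty (zero-size) mask")
    plant = int(mask.sum())
    return CoverageResult(
        coverage_pct=100.0 * plant / total, plant_px=plant, total_px=total
    )


def grade(
    c: CoverageResult | float, mapping: str = "severity"
) -> FrostGrade:
    """Map a coverage percentage to a frost-damage grade.

    ``mapping="severity"`` (default): grade 1 = lightest injury = coverage
    >= 15 %, down to grade 4 = most severe = coverage < 5 %.  The literal
    interval-order variant (``"interval_order"``: < 5 % -> grade 1, ...,
    >= 15 % -> grade 4) is kept for compatibility with scoring sheets that
    number the intervals in listed order.

    Total and piecewise-constant: every coverage in [0, 100] maps to exactly
    one grade, and under the severity mapping the grade never increases as
    coverage rises.
    """
    pct = c.coverage_pct if isinstance(c, CoverageResult) else float(c)
    if not 0.0 <= pct <= 100.0:
        raise ValueError(f"coverage percent must be in [0, 100], got {pct}")
    g = 4
    for i, bound in enumerate(_GRADE_BOUNDS, start=1):
        if pct >= bound:
            g = i
            break
    if mapping == "severity":
        pass
    elif mapping == "interval_order":
        g = 5 - g
    else:
        raise ValueError(
            f"mapping must be 'severity' or 'interval_order', got {mapping!r}"
        )
    return FrostGrade(grade=g, label=GRADE_LABELS[g])


def rgb_to_hsi(img: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Classical (geometric, arccos-based) HSI transform.

    Returns (H, S, I) arrays: hue in degrees [0, 360) with the reflection
    H -> 360 - theta when B > G, saturation 1 - 3*min(r,g,b) on normalized
    channels, intensity (R+G+B)/(3*255).  Achromatic pixels (S = 0) take
    H = 0 by convention.
    """
    arr = as_rgb_array(img).astype(np.float64)
    R, G, B = arr[..., 0], arr[..., 1], arr[..., 2]
    total = R + G + B
    intensity = total / (3.0 * 255.0)
    safe_total = np.where(total > 0, total, 1.0)
    minimum = np.minimum(np.minimum(R, G), B)
    saturation = np.where(total > 0, 1.0 - 3.0 * minimum / safe_total, 0.0)

    num = 0.5 * ((R - G) + (R - B))
    den = np.sqrt((R - G) ** 2 + (R - B) * (G - B))
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.degrees(np.arccos(np.clip(num / np.where(den > 0, den, 1.0), -1, 1)))
    hue = np.where(B > G, 360.0 - theta, theta)
    hue = np.where((den > 0) & (saturation > 0), hue, 0.0)
    return hue, saturation, intensity


@dataclass(frozen=True)
class WitheredThresholds:
    """HSI decision rule for withered (yellow-white) tissue.

    A pixel is withered when its hue falls in [h_lo, h_hi] degrees with
    intensity >= i_min (straw-yellow branch), or when it is nearly achromatic
    and bright: S <= s_max_white and I >= i_min_white (bleached-white branch).
    Defaults bracket the straw-to-white palette of freeze-killed leaf tips;
    all four are exposed because field conditions (sunlight reflection,
    background color) shift them.
    """

    h_lo: float = 40.0
    h_hi: float = 75.0
    i_min: float = 0.35
    s_max_white: float = 0.15
    i_min_white: float = 0.70

    def __post_init__(self) -> None:
        if not 0.0 <= self.h_lo <= self.h_hi < 360.0:
            raise ValueError(
                f"need 0 <= h_lo <= h_hi < 360, got [{self.h_lo}, {self.h_hi}]"
            )
        for name in ("i_min", "s_max_white", "i_min_white"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class WitheredResult:
    withered_px: int
    total_px: int
    withered_fraction: float
    mask: np.ndarray


def withered_extract(
    img: np.ndarray,
    plant_region: np.ndarray | None = None,
    thresholds: WitheredThresholds | None = None,
) -> WitheredResult:
    """Extract withered-leaf pixels by HSI thresholding.

    When ``plant_region`` is given the withered mask is intersected with it;
    the fraction is always taken over the total pixel count of the image.
    """
    thresholds = thresholds or WitheredThresholds()
    hue, sat, intens = rgb_to_hsi(img)
    yellow = (
        (hue >= thresholds.h_lo)
        & (hue <= thresholds.h_hi)
        & (intens >= thresholds.i_min)
    )
    white = (sat <= thresholds.s_max_white) & (intens >= thresholds.i_min_white)
    mask = yellow | white
    if plant_region is not None:
        plant_region = np.asarray(plant_region, dtype=bool)
        if plant_region.shape != mask.shape:
            raise ValueError(
                f"plant_region shape {plant_region.shape} does not match "
                f"image {mask.shape}"
            )
        mask = mask & plant_region
    withered = int(mask.sum())
    return WitheredResult(
        withered_px=withered,
        total_px=mask.size,
        withered_fraction=withered / mask.size,
        mask=mask,
    )


def aggregate_plot(
    results: Sequence[CoverageResult | float], mapping: str = "severity"
) -> tuple[float, FrostGrade]:
    """Plot-level coverage (arithmetic mean over images) and its grade."""
    if len(results) == 0:
        raise ValueError("cannot aggregate an empty list of coverage results")
    values = [
        r.coverage_pct if isinstance(r, CoverageResult) else float(r)
        for r in results
    ]
    mean = float(np.mean(values))
    return mean, grade(mean, mapping=mapping)


def treatment_ranking_summary(table: pd.DataFrame) -> dict:
    """Per-treatment fractions of varieties where it ranks lowest / highest.

    ``table`` is a variety x treatment matrix of mean coverages (index =
    variety, columns = treatment labels).  For each variety the treatment(s)
    with the minimum and maximum mean coverage are counted; ties count for
    every tied treatment and are flagged.  With no ties the fractions sum to
    1 per rank.
    """
    if table.shape[0] == 0 or table.shape[1] == 0:
        raise ValueError("ranking table must have at least one variety and treatment")
    missing = [
        (str(v), str(t))
        for v in table.index
        for t in table.columns
        if pd.isna(table.loc[v, t])
    ]
    if missing:
        raise ValueError(f"missing coverage cells for (variety, treatment): {missing}")

    n = table.shape[0]
    lowest = {str(t): 0 for t in table.columns}
    highest = {str(t): 0 for t in table.columns}
    any_tie = False
    for _, row in table.iterrows():
        lo, hi = row.min(), row.max()
        lo_t = [str(t) for t in table.columns if row[t] == lo]
        hi_t = [str(t) for t in table.columns if row[t] == hi]
        any_tie = any_tie or len(lo_t) > 1 or len(hi_t) > 1
        for t in lo_t:
            lowest[t] += 1
        for t in hi_t:
            highest[t] += 1
    return {
        "lowest_fraction": {t: c / n for t, c in lowest.items()},
        "highest_fraction": {t: c / n for t, c in highest.items()},
        "n_varieties": n,
        "ties_present": any_tie,
    }
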