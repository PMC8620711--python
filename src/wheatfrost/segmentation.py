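"""Plant/background segmentation of nadir canopy images.

Pipeline: RGB -> sum-normalized channels -> ExV index -> fixed-range gray
rendering -> Otsu threshold on the 256-bin histogram -> binarize (plant where
gray > t, i.e. greener than threshold) -> morphological cleanup (drop specks,
fill holes).  Withered yellow-white tissue has near-zero ExV and deliberately
segments as background: frozen tissue does not count toward coverage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure, morphology

from .indices import INDEX_RANGES, as_rgb_array, compute_index, to_gray

__all__ = [
    "SegmentationParams",
    "SegmentationResult",
    "histogram256",
    "otsu_threshold",
    "binarize",
    "clean_mask",
    "extract_roi",
    "segment",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Tunables of the segmentation stage.

    ``min_object_px`` drops 8-connected plant components smaller than this
    many pixels (specks of sensor noise); ``fill_holes`` closes small
    enclosed background pockets (up to ``max_hole_px`` pixels) inside plant
    components — genuine soil visible between overlapping leaves is left
    alone.  ``neutral_floor`` clamps the
    applied threshold at the gray level of index value 0 (the achromatic
    point): green tissue has strictly positive ExG/ExV, so a plant class is
    only declared on the green side of neutral.  Without the floor, Otsu —
    which always splits a histogram — would halve a plant-free soil image
    into spurious foreground.
    """

    index_kind: str = "ExV"
    min_object_px: int = 16
    fill_holes: bool = True
    max_hole_px: int = 16
    neutral_floor: bool = True

    def __post_init__(self) -> None:
        if self.min_object_px < 0:
            raise ValueError(
                f"min_object_px must be >= 0, got {self.min_object_px}"
            )


@dataclass(frozen=True)
class SegmentationResult:
    mask: np.ndarray          # H x W bool, True = plant
    threshold: int            # threshold actually applied (after any floor)
    otsu_t: int               # raw Otsu choice before the neutral floor
    gray: np.ndarray          # the gray rendering that was thresholded
    params: SegmentationParams


def neutral_gray_level(index_kind: str) -> int:
    """Gray level that index value 0 maps to under the fixed-range rescale."""
    lo, hi = INDEX_RANGES[index_kind]
    return int(np.floor(255.0 * (0.0 - lo) / (hi - lo) + 0.5))


def histogram256(gray: np.ndarray) -> np.ndarray:
    """256-bin histogram of an 8-bit grayscale image."""
    gray = np.asarray(gray)
    if gray.dtype != np.uint8:
        raise ValueError(f"expected uint8 gray image, got dtype {gray.dtype}")
    return np.bincount(gray.ravel(), minlength=256)


def otsu_threshold(counts: np.ndarray) -> int:
    """Otsu's threshold on a 256-bin histogram.

    Picks t maximizing the between-class variance
    ``sigma_b^2(t) = w0 * w1 * (mu0 - mu1)^2`` with classes {level <= t} and
    {level > t}.  Ties break toward the smallest maximizing t among
    thresholds whose lower class is non-empty (so a single-level histogram
    returns that level).
    """
    counts = np.asarray(counts, dtype=np.float64)
    if counts.shape != (256,):
        raise ValueError(f"expected 256 histogram counts, got shape {counts.shape}")
    if counts.sum() <= 0:
        raise ValueError("histogram is empty: no pixels to threshold")

    p = counts / counts.sum()
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(p)                      # weight of class {<= t}
    mu = np.cumsum(p * levels)             # unnormalized class-0 mean
    mu_total = mu[-1]
    w1 = 1.0 - w0
    sigma_b = np.zeros(256)
    both = (w0 > 0) & (w1 > 0)
    sigma_b[both] = (mu_total * w0[both] - mu[both]) ** 2 / (w0[both] * w1[both])

    candidates = np.flatnonzero(w0 > 0)
    return int(candidates[np.argmax(sigma_b[candidates])])


def binarize(gray: np.ndarray, t: int) -> np.ndarray:
    """Plant where gray > t (higher ExV = greener), background where <= t."""
    if not 0 <= t <= 255:
        raise ValueError(f"threshold must be in [0, 255], got {t}")
    gray = np.asarray(gray)
    return gray > t


def clean_mask(
    mask: np.ndarray,
    min_object_px: int = 16,
    fill_holes: bool = True,
    max_hole_px: int = 16,
) -> np.ndarray:
    """Remove small plant components (8-connectivity) and small holes.

    Salt-and-pepper symmetric cleanup: plant specks smaller than
    ``min_object_px`` are erased, enclosed background pockets of up to
    ``max_hole_px`` pixels are filled when ``fill_holes`` is set.  Larger
    holes are genuine soil showing between leaves and are kept.  Idempotent:
    filling small holes only grows components and opens no new holes.
    """
    if min_object_px < 0:
        raise ValueError(f"min_object_px must be >= 0, got {min_object_px}")
    if max_hole_px < 0:
        raise ValueError(f"max_hole_px must be >= 0, got {max_hole_px}")
    out = np.asarray(mask, dtype=bool)
    if min_object_px > 0:
        # max_size removes components <= its value, i.e. strictly smaller
        # than min_object_px
        out = morphology.remove_small_objects(
            out, max_size=min_object_px - 1, connectivity=2
        )
    if fill_holes and max_hole_px > 0:
        # holes of 8-connected foreground are 4-connected background
        out = morphology.remove_small_holes(
            out, max_size=max_hole_px, connectivity=1
        )
    return out


def extract_roi(
    mask: np.ndarray, img: np.ndarray
) -> tuple[list[np.ndarray], np.ndarray]:
    """Outer contours of plant components plus the background-removed image.

    Returns one ordered (row, col) contour per 8-connected plant component
    and a copy of the source image with background pixels zeroed.
    """
    mask = np.asarray(mask, dtype=bool)
    img = as_rgb_array(img)
    if mask.shape != img.shape[:2]:
        raise ValueError(
            f"mask shape {mask.shape} does not match image {img.shape[:2]}"
        )
    labels = measure.label(mask, connectivity=2)
    contours: list[np.ndarray] = []
    for region in measure.regionprops(labels):
        # Pad so components touching the border still yield closed contours;
        # filled_image ignores interior holes, keeping only outer boundaries.
        filled = np.pad(region.image_filled, 1)
        found = measure.find_contours(filled.astype(float), 0.5)
        outer = max(found, key=len)
        r0, c0, _, _ = region.bbox
        contours.append(outer + np.array([r0 - 1, c0 - 1]))
    masked = img.copy()
    masked[~mask] = 0
    return contours, masked


def segment(
    img: np.ndarray, params: SegmentationParams | None = None
) -> SegmentationResult:
    """End-to-end segmentation of one RGB canopy image.

    Deterministic for a fixed image and parameter set; the chosen Otsu
    threshold is reported alongside the mask for logging and debugging.
    """
    params = params or SegmentationParams()
    index_map = compute_index(img, params.index_kind)
    gray = to_gray(index_map)
    otsu_t = otsu_threshold(histogram256(gray))
    t = otsu_t
    if params.neutral_floor:
        t = max(t, neutral_gray_level(params.index_kind))
    mask = clean_mask(
        binarize(gray, t),
        min_object_px=params.min_object_px,
        fill_holes=params.fill_holes,
        max_hole_px=params.max_hole_px,
    )
    return SegmentationResult(
        mask=mask, threshold=t, otsu_t=otsu_t, gray=gray, params=params
    )
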