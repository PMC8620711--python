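"""Chromatic vegetation indices: ExG, ExR and their difference ExV.

On sum-normalized channels r = R/(R+G+B) etc., excess green ExG = 2g - r - b
is high on green tissue, excess red ExR = 1.4r - g is high on reddish soil
tones, and ExV = ExG - ExR = 3g - 2.4r - b combines green enhancement with
red suppression.  ExV is the default segmentation feature: it separates green
wheat blades from soil, shadow and withered (yellow-white) tissue in nadir
canopy photos.

All index math runs in float64; quantization happens only in :func:`to_gray`,
which maps each index's fixed theoretical range onto 0..255 so Otsu
thresholds stay comparable across images.
"""

from __future__ import annotations

from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np

__all__ = [
    "INDEX_RANGES",
    "NormalizedRGB",
    "IndexMap",
    "as_rgb_array",
    "read_rgb",
    "normalize",
    "excess_green",
    "excess_red",
    "excess_veg",
    "compute_index",
    "to_gray",
]

# Theoretical per-pixel bounds given r, g, b in [0, 1] with r + g + b <= 1.
INDEX_RANGES: dict[str, tuple[float, float]] = {
    "ExG": (-1.0, 2.0),
    "ExR": (-1.0, 1.4),
    "ExV": (-2.4, 3.0),
}


def as_rgb_array(img: np.ndarray) -> np.ndarray:
    """Validate an 8-bit H x W x 3 RGB raster and return it as uint8."""
    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(
            f"expected an HxWx3 RGB array, got shape {arr.shape}"
        )
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError("image must have at least one pixel")
    if arr.dtype != np.uint8:
        info = np.iinfo(arr.dtype) if np.issubdtype(arr.dtype, np.integer) else None
        if info is None or arr.min() < 0 or arr.max() > 255:
            raise ValueError(
                f"expected 8-bit integer values in [0, 255], got dtype {arr.dtype}"
            )
        arr = arr.astype(np.uint8)
    return arr


def read_rgb(path) -> np.ndarray:
    """Decode a PNG/JPEG file into an 8-bit RGB array (alpha dropped)."""
    arr = iio.imread(path)
    if arr.ndim == 2:  # grayscale file: replicate channels
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    return as_rgb_array(arr)


@dataclass(frozen=True)
class NormalizedRGB:
    """Per-pixel chromatic coordinates r, g, b with r+g+b = 1 (or all 0)."""

    r: np.ndarray
    g: np.ndarray
    b: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.r.shape


@dataclass(frozen=True)
class IndexMap:
    """A per-pixel float index map together with which index it holds."""

    values: np.ndarray
    index_kind: str

    def __post_init__(self) -> None:
        if self.index_kind not in INDEX_RANGES:
            raise ValueError(
                f"index_kind must be one of {sorted(INDEX_RANGES)}, "
                f"got {self.index_kind!r}"
            )

    @property
    def theoretical_range(self) -> tuple[float, float]:
        return INDEX_RANGES[self.index_kind]


def normalize(img: np.ndarray) -> NormalizedRGB:
    """Sum-normalize RGB channels: r = R/(R+G+B), g = G/(R+G+B), b = B/(R+G+B).

    Zero-sum (black) pixels map to (0, 0, 0) rather than NaN; they then get
    index value 0 and are classed with the background by thresholding.
    """
    arr = as_rgb_array(img).astype(np.float64)
    total = arr.sum(axis=2)
    safe = np.where(total > 0, total, 1.0)
    r = np.where(total > 0, arr[..., 0] / safe, 0.0)
    g = np.where(total > 0, arr[..., 1] / safe, 0.0)
    b = np.where(total > 0, arr[..., 2] / safe, 0.0)
    return NormalizedRGB(r=r, g=g, b=b)


def excess_green(n: NormalizedRGB) -> IndexMap:
    """ExG = 2g - r - b."""
    return IndexMap(values=2.0 * n.g - n.r - n.b, index_kind="ExG")


def excess_red(n: NormalizedRGB) -> IndexMap:
    """ExR = 1.4r - g."""
    return IndexMap(values=1.4 * n.r - n.g, index_kind="ExR")


def excess_veg(n: NormalizedRGB) -> IndexMap:
    """ExV = ExG - ExR = 3g - 2.4r - b."""
    return IndexMap(values=3.0 * n.g - 2.4 * n.r - n.b, index_kind="ExV")


_INDEX_FUNCS = {"ExG": excess_green, "ExR": excess_red, "ExV": excess_veg}


def compute_index(img: np.ndarray, index_kind: str = "ExV") -> IndexMap:
    """Normalize an RGB image and compute the requested index map."""
    try:
        fn = _INDEX_FUNCS[index_kind]
    except KeyError:
        raise ValueError(
            f"index_kind must be one of {sorted(_INDEX_FUNCS)}, got {index_kind!r}"
        ) from None
    return fn(normalize(img))


def to_gray(index_map: IndexMap) -> np.ndarray:
    """Rescale an index map onto 0..255 using its fixed theoretical range.

    The affine map sends range minimum to 0 and maximum to 255, rounding
    half-up; using the fixed range (not the per-image min/max) keeps gray
    levels, and hence Otsu thresholds, comparable across images.
    """
    lo, hi = index_map.theoretical_range
    scaled = 255.0 * (index_map.values - lo) / (hi - lo)
    # 1e-9 guard: values that are exactly half-integers in real arithmetic
    # can land a few ulp below in float64 and would otherwise round down
    return np.clip(np.floor(scaled + 0.5 + 1e-9), 0, 255).astype(np.uint8)
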