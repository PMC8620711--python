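import numpy as np
import pytest
from hypothesis import settings

from wheatfrost import ExperimentLayout, NitrogenTreatment, SceneParams, generate_scene

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def small_layout() -> ExperimentLayout:
    return ExperimentLayout(
        varieties=("VarA", "VarB", "VarC"),
        treatments=(
            NitrogenTreatment("N1", 0.0),
            NitrogenTreatment("N2", 180.0),
        ),
        replicates=2,
        images_per_plot=2,
    )


@pytest.fixture
def scene_12pct():
    """A default 256x256 scene at 12% green coverage with withered tips."""
    return generate_scene(
        SceneParams(seed=42, target_coverage_pct=12.0, withered_tip_fraction=0.1)
    )


def brute_force_otsu(counts) -> int:
    """Exhaustive-search reference for Otsu's threshold.

    Loops over every candidate t, computing between-class variance
    w0*w1*(mu0-mu1)^2 for classes {level <= t} / {level > t}; keeps the
    smallest t among maximizers whose lower class is non-empty.
    """
    counts = np.asarray(counts, dtype=np.float64)
    n = counts.sum()
    assert n > 0
    levels = np.arange(256)
    best_t, best_s = None, -1.0
    for t in range(256):
        n0 = counts[: t + 1].sum()
        n1 = n - n0
        if n0 == 0:
            continue
        if n1 == 0:
            s = 0.0
        else:
            mu0 = (levels[: t + 1] * counts[: t + 1]).sum() / n0
            mu1 = (levels[t + 1 :] * counts[t + 1 :]).sum() / n1
            s = (n0 / n) * (n1 / n) * (mu0 - mu1) ** 2
        if s > best_s:
            best_s, best_t = s, t
    return best_t


def hsi_to_rgb(h: float, s: float, i: float) -> tuple[float, float, float]:
    """Naive sector-formula inverse of the geometric HSI transform.

    Returns unrounded channel values on the 0-255 scale.
    """
    h = h % 360.0
    if h < 120.0:
        b = i * (1 - s)
        r = i * (1 + s * np.cos(np.radians(h)) / np.cos(np.radians(60 - h)))
        g = 3 * i - (r + b)
    elif h < 240.0:
        h -= 120.0
        r = i * (1 - s)
        g = i * (1 + s * np.cos(np.radians(h)) / np.cos(np.radians(60 - h)))
        b = 3 * i - (r + g)
    else:
        h -= 240.0
        g = i * (1 - s)
        b = i * (1 + s * np.cos(np.radians(h)) / np.cos(np.radians(60 - h)))
        r = 3 * i - (g + b)
    return r * 255.0, g * 255.0, b * 255.0
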