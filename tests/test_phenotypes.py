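import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from wheatfrost import (
    CoverageResult,
    SceneParams,
    aggregate_plot,
    coverage,
    generate_scene,
    grade,
    rgb_to_hsi,
    segment,
    treatment_ranking_summary,
    withered_extract,
)
from wheatfrost.phenotypes import WitheredThresholds

from conftest import hsi_to_rgb


def px(r, g, b, shape=(1, 1)):
    img = np.empty(shape + (3,), dtype=np.uint8)
    img[:] = (r, g, b)
    return img


class TestCoverage:
    def test_exact_pixel_ratio(self):
        m = np.zeros((10, 10), dtype=bool)
        m.flat[:25] = True
        c = coverage(m)
        assert c.coverage_pct == 25.0
        assert (c.plant_px, c.total_px) == (25, 100)

    def test_all_plant(self):
        assert coverage(np.ones((5, 5), dtype=bool)).coverage_pct == 100.0

    def test_zero_size_rejected(self):
        with pytest.raises(ValueError, match="zero-size"):
            coverage(np.zeros((0, 5), dtype=bool))


class TestGrade:
    @pytest.mark.parametrize(
        "pct,expected",
        [
            (2.0, 4), (21.0, 1),            # field extremes: 2% and 21% coverage
            (12.0, 2), (7.0, 3),
            (5.0, 3), (10.0, 2), (15.0, 1),  # boundaries go to the lighter grade
            (0.0, 4), (100.0, 1),
        ],
    )
    def test_severity_mapping(self, pct, expected):
        g = grade(pct)
        assert g.grade == expected

    def test_labels_track_severity(self):
        assert grade(21.0).label == "no obvious"
        assert grade(2.0).label == "most severe"

    def test_interval_order_variant_reverses(self):
        assert grade(2.0, mapping="interval_order").grade == 1
        assert grade(21.0, mapping="interval_order").grade == 4

    def test_exhaustive_sweep_total_and_monotone(self):
        """Every coverage in [0,100] maps to exactly one of 4 grades, and the
        grade never increases as coverage rises."""
        pcts = np.round(np.arange(0, 100.01, 0.1), 10)
        grades = [grade(p).grade for p in pcts]
        assert set(grades) == {1, 2, 3, 4}
        assert all(b <= a for a, b in zip(grades, grades[1:]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="\\[0, 100\\]"):
            grade(101.0)


class TestHSI:
    @pytest.mark.parametrize(
        "rgb,h,s,i",
        [
            ((255, 0, 0), 0.0, 1.0, 1 / 3),
            ((255, 255, 0), 60.0, 1.0, 2 / 3),
            ((100, 100, 100), 0.0, 0.0, 100 / 255),
        ],
    )
    def test_reference_pixels(self, rgb, h, s, i):
        H, S, I = rgb_to_hsi(px(*rgb))
        assert H[0, 0] == pytest.approx(h, abs=1e-9)
        assert S[0, 0] == pytest.approx(s, abs=1e-9)
        assert I[0, 0] == pytest.approx(i, abs=1e-9)

    def test_blue_side_hue_reflected(self):
        H, _, _ = rgb_to_hsi(px(0, 0, 255))
        assert H[0, 0] == pytest.approx(240.0, abs=1e-9)

    def test_roundtrip_via_sector_inverse(self):
        """rgb -> HSI -> naive sector inverse lands within 1 gray level."""
        rng = np.random.default_rng(123)
        pixels = rng.integers(0, 256, size=(10_000, 3))
        pixels = pixels[~np.all(pixels == pixels[:, :1], axis=1)]  # drop achromatic
        img = pixels.astype(np.uint8)[None, :, :]
        H, S, I = rgb_to_hsi(img)
        for j in range(pixels.shape[0]):
            r, g, b = hsi_to_rgb(H[0, j], S[0, j], I[0, j])
            assert abs(r - pixels[j, 0]) <= 1.0
            assert abs(g - pixels[j, 1]) <= 1.0
            assert abs(b - pixels[j, 2]) <= 1.0


class TestWithered:
    def test_pure_green_has_no_withered(self):
        res = withered_extract(px(0, 180, 40, shape=(8, 8)))
        assert res.withered_fraction == 0.0

    def test_all_yellow_is_fully_withered(self):
        res = withered_extract(px(255, 255, 0, shape=(8, 8)))
        assert res.withered_fraction == 1.0

    def test_white_branch_catches_bleached_tissue(self):
        res = withered_extract(px(240, 240, 228, shape=(4, 4)))
        assert res.withered_fraction == 1.0

    def test_plant_region_intersection(self):
        img = px(255, 255, 0, shape=(2, 2))
        region = np.array([[True, False], [False, False]])
        res = withered_extract(img, plant_region=region)
        assert res.withered_px == 1
        assert res.withered_fraction == 0.25

    def test_recovers_generator_truth(self):
        scene = generate_scene(
            SceneParams(seed=21, target_coverage_pct=12.0, withered_tip_fraction=0.1)
        )
        truth = scene.withered_truth.mean()
        res = withered_extract(scene.image)
        assert res.withered_fraction == pytest.approx(truth, abs=0.03)

    def test_withered_and_coverage_pixels_disjoint(self):
        scene = generate_scene(
            SceneParams(seed=22, target_coverage_pct=12.0, withered_tip_fraction=0.15)
        )
        plant = segment(scene.image).mask
        withered = withered_extract(scene.image).mask
        overlap = (plant & withered).sum()
        assert overlap <= 0.001 * plant.size

    def test_malformed_thresholds_rejected(self):
        with pytest.raises(ValueError, match="h_lo"):
            WitheredThresholds(h_lo=80, h_hi=40)
        with pytest.raises(ValueError, match="i_min"):
            WitheredThresholds(i_min=1.5)


class TestAggregation:
    def test_mean_and_regrade(self):
        mean, g = aggregate_plot([10.0, 12.0, 14.0])
        assert mean == 12.0 and g.grade == 2

    def test_single_image_identity(self):
        mean, g = aggregate_plot([8.0])
        assert mean == 8.0 and g.grade == 3

    @settings(max_examples=30, deadline=None)
    @given(v=st.floats(0, 100), k=st.integers(1, 6))
    def test_mean_of_equal_values(self, v, k):
        mean, _ = aggregate_plot([v] * k)
        assert mean == pytest.approx(v)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            aggregate_plot([])

    def test_accepts_coverage_results(self):
        results = [CoverageResult(10.0, 10, 100), CoverageResult(20.0, 20, 100)]
        mean, g = aggregate_plot(results)
        assert mean == 15.0 and g.grade == 1


class TestTreatmentRanking:
    def test_counting(self):
        table = pd.DataFrame(
            {"N1": [10, 11, 12], "N3": [5, 6, 13]},
            index=["a", "b", "c"],
        )
        out = treatment_ranking_summary(table)
        assert out["lowest_fraction"]["N3"] == pytest.approx(2 / 3)
        assert out["highest_fraction"]["N1"] == pytest.approx(2 / 3)
        assert not out["ties_present"]

    def test_all_tied_flagged(self):
        table = pd.DataFrame({"N1": [7, 7], "N2": [7, 7]}, index=["a", "b"])
        out = treatment_ranking_summary(table)
        assert out["ties_present"]
        assert out["lowest_fraction"] == {"N1": 1.0, "N2": 1.0}

    def test_missing_cells_listed(self):
        table = pd.DataFrame({"N1": [1.0, np.nan]}, index=["a", "b"])
        with pytest.raises(ValueError, match="missing.*b.*N1"):
            treatment_ranking_summary(table)

    def test_matches_brute_force_argmin_loop(self):
        rng = np.random.default_rng(9)
        table = pd.DataFrame(
            rng.uniform(2, 21, size=(12, 3)),
            index=[f"v{i}" for i in range(12)],
            columns=["N1", "N2", "N3"],
        )
        out = treatment_ranking_summary(table)
        lo_counts = {c: 0 for c in table.columns}
        hi_counts = {c: 0 for c in table.columns}
        for v in table.index:  # independent per-variety loop
            lo_counts[table.loc[v].idxmin()] += 1
            hi_counts[table.loc[v].idxmax()] += 1
        for c in table.columns:
            assert out["lowest_fraction"][c] == pytest.approx(lo_counts[c] / 12)
            assert out["highest_fraction"][c] == pytest.approx(hi_counts[c] / 12)
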