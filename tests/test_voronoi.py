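"""Voronoi model: partition exactness, rank correlation, recovery, stats."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scmbench import voronoi


class TestCenters:
    @pytest.mark.parametrize("c", [16, 64])
    def test_count_and_min_separation(self, c):
        pts = voronoi.sample_centers(c, seed=2)
        assert pts.shape == (c, 2)
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= voronoi.MIN_CENTER_SEPARATION

    def test_single_center_covers_whole_image(self):
        real = voronoi.generate_voronoi(1, seed=3)
        assert len(real.regions) == 1
        assert not real.edge_mask.any()
        assert real.regions["area"].iloc[0] == 256 * 256


class TestPartition:
    def test_symmetric_two_centers_edge_on_midline(self):
        centers = np.array([[128.0, 64.0], [128.0, 192.0]])
        label_map, edge = voronoi.rasterize_partition(centers)
        ys, xs = np.where(edge)
        assert set(xs.tolist()) == {127}
        assert ys.size == 256

    def test_labels_agree_with_brute_force_scan(self):
        # exhaustive nearest-center oracle on a 64x64 toy
        rng = np.random.default_rng(5)
        centers = rng.uniform(0, 64, size=(7, 2))
        label_map, _ = voronoi.rasterize_partition(centers, image_size=64)
        for r in range(64):
            for c in range(64):
                if label_map[r, c] > 0:
                    d2 = ((np.array([r + 0.5, c + 0.5]) - centers) ** 2).sum(axis=1)
                    assert label_map[r, c] - 1 == int(d2.argmin())

    def test_conservation_edges_plus_areas(self):
        real = voronoi.generate_voronoi(48, seed=6)
        assert int(real.edge_mask.sum()) + int(real.regions["area"].sum()) == 256 * 256


class TestIntensities:
    def test_spearman_exactly_one(self):
        real = voronoi.generate_voronoi(64, seed=7)
        assert voronoi.area_gray_spearman(real.regions) == pytest.approx(1.0)

    def test_two_regions_smaller_is_darker(self):
        real = voronoi.generate_voronoi(2, seed=8)
        df = real.regions.sort_values("area")
        assert df["gray"].iloc[0] < df["gray"].iloc[1]

    def test_permuted_intensities_destroy_correlation(self):
        real = voronoi.generate_voronoi(64, seed=9)
        rng = np.random.default_rng(0)
        rhos = []
        for _ in range(30):
            shuffled = real.regions.copy()
            shuffled["gray"] = rng.permutation(shuffled["gray"].to_numpy())
            rhos.append(voronoi.area_gray_spearman(shuffled))
        assert abs(float(np.mean(rhos))) < 0.2

    def test_area_ties_raise(self):
        label_map = np.zeros((8, 8), dtype=int)
        label_map[:4] = 1
        label_map[4:] = 2  # two regions of equal area
        with pytest.raises(voronoi.AreaTieError):
            voronoi.assign_region_intensities(label_map, seed=0)


class TestRecovery:
    def test_clean_recovery_region_counts(self, voronoi_mini_ensemble):
        errors = []
        for real in voronoi_mini_ensemble:
            _, regions = voronoi.recover_regions(real.image)
            errors.append(abs(len(regions) - len(real.regions)))
        within = np.mean([e <= 2 for e in errors])
        assert within >= 0.95

    def test_clean_recovery_preserves_rank_correlation(self, voronoi_mini_ensemble):
        for real in voronoi_mini_ensemble[:12]:
            _, regions = voronoi.recover_regions(real.image)
            assert voronoi.area_gray_spearman(regions) > 0.95

    def test_uniform_image_single_region(self):
        img = np.full((256, 256), 100, dtype=np.uint8)
        _, regions = voronoi.recover_regions(img)
        assert len(regions) == 1

    def test_all_zero_image_zero_regions(self):
        _, regions = voronoi.recover_regions(np.zeros((256, 256), dtype=np.uint8))
        assert len(regions) == 0


class TestImplicitContext:
    def test_two_region_symmetric_case(self):
        centers = np.array([[128.0, 64.0], [128.0, 192.0]])
        label_map, edge = voronoi.rasterize_partition(centers)
        stats = voronoi.implicit_context_stats(label_map, edge)
        assert stats["n_regions"] == 2
        assert stats["n_junctions"] == 0
        assert stats["mean_edge_length"] == pytest.approx(256, rel=0.05)

    def test_region_area_conservation(self):
        real = voronoi.generate_voronoi(32, seed=10)
        stats = voronoi.implicit_context_stats(real.label_map, real.edge_mask)
        non_edge = 256 * 256 - int(real.edge_mask.sum())
        assert stats["mean_region_area"] * stats["n_regions"] == pytest.approx(non_edge)

    def test_class64_smaller_regions_than_class16(self):
        areas_16 = [
            voronoi.implicit_context_stats(r.label_map, r.edge_mask)["mean_region_area"]
            for r in (voronoi.generate_voronoi(16, 100 + s) for s in range(5))
        ]
        areas_64 = [
            voronoi.implicit_context_stats(r.label_map, r.edge_mask)["mean_region_area"]
            for r in (voronoi.generate_voronoi(64, 200 + s) for s in range(5))
        ]
        assert np.median(areas_64) < np.median(areas_16)


class TestClassification:
    @pytest.mark.parametrize(
        "n,expected",
        [
            (64, (64, "in-class")),
            (16, (16, "in-class")),
            (40, (32, "interpolated")),  # equidistant tie -> lower class
            (80, (64, "extrapolated")),
            (8, (16, "extrapolated")),
        ],
    )
    def test_examples(self, n, expected):
        assert voronoi.classify_by_region_count(n) == expected

    @settings(deadline=None, derandomize=True)
    @given(st.integers(min_value=1, max_value=500))
    def test_every_count_maps_to_exactly_one_status(self, n):
        nearest, status = voronoi.classify_by_region_count(n)
        assert nearest in voronoi.CLASSES
        in_class = n in voronoi.CLASSES
        interpolated = voronoi.CLASSES[0] < n < voronoi.CLASSES[-1] and not in_class
        extrapolated = n < voronoi.CLASSES[0] or n > voronoi.CLASSES[-1]
        assert [in_class, interpolated, extrapolated].count(True) == 1
        assert status == {0: "in-class", 1: "interpolated", 2: "extrapolated"}[
            [in_class, interpolated, extrapolated].index(True)
        ]
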