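"""Flag model: templates, Beta tiles, recovery, RMAE, Moran's I, chi2."""

import numpy as np
import pytest

from scmbench import flags


class TestTemplates:
    def test_column_constraints(self, templates):
        assert (templates.A.sum(axis=0) == 80).all()
        assert ((1 - templates.A).sum(axis=0) == 176).all()

    def test_exactly_24_forbidden_indices(self, templates):
        assert templates.forbidden.size == 24
        assert (templates.A[templates.forbidden] == 0).all()

    def test_columns_pairwise_distinct(self, templates):
        cols = {templates.A[:, c].tobytes() for c in range(8)}
        assert len(cols) == 8

    def test_deterministic_and_text_roundtrip(self, tmp_path, templates):
        again = flags.build_class_templates(templates.seed)
        assert (again.A == templates.A).all()
        path = tmp_path / "templates.txt"
        flags.save_templates(templates, path)
        assert (flags.load_templates(path).A == templates.A).all()


class TestTiles:
    def test_supports(self, rng):
        fg = flags.sample_tile(True, rng)
        bg = flags.sample_tile(False, rng)
        assert fg.min() >= 96 and fg.max() <= 248
        assert bg.min() >= 8 and bg.max() <= 200

    def test_foreground_mean_matches_beta_moment(self, rng):
        means = [flags.sample_tile(True, rng).mean() for _ in range(2000)]
        # E = 152*(4/6) + 96 = 197.33; SE of the grand mean ~ 0.03
        assert np.mean(means) == pytest.approx(flags.FG_MEAN, abs=0.5)


class TestRenderRecover:
    def test_same_seed_identical_renders(self, templates):
        a = flags.render_flag(2, templates, 99)
        b = flags.render_flag(2, templates, 99)
        assert (a == b).all()

    def test_invalid_class_rejected(self, templates):
        with pytest.raises(ValueError):
            flags.render_flag(9, templates, 0)

    @pytest.mark.parametrize("class_id", range(1, 9))
    def test_roundtrip_across_all_classes(self, class_id, templates):
        for seed in range(4):
            img = flags.render_flag(class_id, templates, 1000 * class_id + seed)
            pattern = flags.recover_foreground_pattern(img)
            assert (pattern == templates.column(class_id)).all()

    def test_zero_order_invariance_foreground_pixel_count(self, templates):
        # identical foreground pixel budget in every class
        for class_id in (1, 5, 8):
            img = flags.render_flag(class_id, templates, 7)
            pattern = flags.recover_foreground_pattern(img)
            assert int(pattern.sum()) * 256 == 80 * 256

    def test_all_background_image_recovers_empty_pattern(self, rng):
        img = np.concatenate(
            [flags.sample_tile(False, rng).ravel() for _ in range(256)]
        ).reshape(16, 16, 16, 16).transpose(0, 2, 1, 3).reshape(256, 256).astype(np.uint8)
        assert flags.recover_foreground_pattern(img).sum() == 0


class TestRmae:
    def test_exact_column_zero_error(self, templates):
        cls, rmae, forbidden, errors = flags.classify_by_rmae(templates.column(4), templates)
        assert cls == 4 and rmae[3] == 0.0
        assert not forbidden and errors.size == 0

    def test_forbidden_move_flags_two_error_tiles(self, templates):
        pattern = templates.column(1).copy()
        fg = np.flatnonzero(pattern)
        pattern[fg[0]] = 0
        pattern[templates.forbidden[0]] = 1
        cls, _, forbidden, errors = flags.classify_by_rmae(pattern, templates)
        assert cls == 1 and forbidden and errors.size == 2

    def test_mae_tie_resolves_to_lower_class(self, templates):
        # an all-zero pattern is equidistant from every column
        cls, rmae, _, _ = flags.classify_by_rmae(np.zeros(256, dtype=np.uint8), templates)
        assert (rmae == rmae[0]).all()
        assert cls == 1


class TestMorans:
    def test_checkerboard_maximally_negative(self):
        tile = (np.indices((16, 16)).sum(axis=0) % 2 * 100).astype(float)
        assert flags.morans_i(tile) == pytest.approx(-1.0)

    def test_sorted_gradient_strongly_positive(self):
        tile = np.sort(np.random.default_rng(0).normal(size=256)).reshape(16, 16)
        assert flags.morans_i(tile) > 0.5

    def test_constant_tile_undefined(self):
        assert flags.morans_i(np.full((16, 16), 9.0)) is None

    def test_null_mean_and_band_coverage(self, rng):
        vals = np.array([flags.morans_i(flags.sample_tile(True, rng)) for _ in range(4000)])
        se = vals.std() / np.sqrt(vals.size)
        assert abs(vals.mean() - flags.MORANS_NULL_MEAN) < 4 * se
        lo, hi = flags.morans_null_band(n_tiles=2000, seed=3)
        inside = ((vals >= lo) & (vals <= hi)).mean()
        assert inside >= 0.97


class TestIntensityGof:
    def test_chi2_zero_when_counts_equal_expectations(self):
        # manufactured sample whose histogram equals the expected counts
        probs = flags._FG_PROBS
        n = 100_000
        counts = np.rint(probs * n).astype(int)
        mids = (flags._FG_EDGES[:-1] + flags._FG_EDGES[1:]) / 2
        sample = np.repeat(mids, counts)
        chi2 = flags._chi2_against_beta(sample, flags._FG_EDGES, probs / probs.sum())
        # rounding of expected counts leaves a negligible residual
        assert chi2 < 0.5

    def test_clean_images_mostly_acceptable(self, templates, intensity_null):
        ok = 0
        for i in range(40):
            c = 1 + i % 8
            img = flags.render_flag(c, templates, 40_000 + i)
            pattern = flags.recover_foreground_pattern(img)
            _, _, acceptable = flags.intensity_gof(img, pattern, intensity_null)
            ok += acceptable
        assert ok >= 37  # 99% construction, small-sample slack

    def test_uniform_foreground_rejected(self, templates, intensity_null, rng):
        img = flags.render_flag(3, templates, 123).copy()
        pattern = flags.recover_foreground_pattern(img)
        fg_mask = np.repeat(np.repeat(pattern.reshape(16, 16), 16, 0), 16, 1).astype(bool)
        img[fg_mask] = rng.integers(96, 249, size=int(fg_mask.sum()))
        _, _, acceptable = flags.intensity_gof(img, pattern, intensity_null)
        assert not acceptable

    def test_empty_foreground_rejected(self, templates, intensity_null):
        img = np.full((256, 256), 72, dtype=np.uint8)
        with pytest.raises(ValueError):
            flags.intensity_gof(img, np.zeros(256, dtype=np.uint8), intensity_null)
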