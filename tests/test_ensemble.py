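"""Evaluation framework: features, PCA, cosine pairs, KS, coverage/density."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from scmbench import ensemble


class TestFeatures:
    def test_constant_image_glcm(self):
        f = ensemble.texture_features(np.full((64, 64), 9, dtype=np.uint8))
        assert f["glcm_energy"] == pytest.approx(1.0)
        assert f["glcm_contrast"] == pytest.approx(0.0)

    def test_straight_line_skeleton(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[32, 10:50] = True
        f = ensemble.skeleton_features(mask)
        assert f["skel_n_branches"] == 1
        assert f["skel_n_junctions"] == 0

    def test_empty_skeleton_flagged_nan(self):
        f = ensemble.skeleton_features(np.zeros((16, 16), dtype=bool))
        assert np.isnan(f["skel_total_len"])

    def test_glcm_contrast_matches_naive_oracle(self):
        # brute-force per-pixel co-occurrence on a toy image, offset (0, 1)
        rng = np.random.default_rng(0)
        img = rng.integers(0, 8, size=(16, 16)).astype(np.uint8)
        from skimage.feature import graycomatrix, graycoprops

        glcm = graycomatrix(img, distances=[1], angles=[0], levels=8, symmetric=True, normed=True)
        contrast = float(graycoprops(glcm, "contrast")[0, 0])
        pairs = [
            (int(img[r, c]), int(img[r, c + 1]))
            for r in range(16)
            for c in range(15)
        ]
        naive = np.mean([(i - j) ** 2 for i, j in pairs])
        assert contrast == pytest.approx(naive)

    def test_morphology_single_square(self):
        mask = np.zeros((32, 32), dtype=bool)
        mask[8:24, 8:24] = True
        f = ensemble.morphology_features(mask)
        assert f["morph_area"] == 256
        assert f["morph_solidity"] == pytest.approx(1.0)


class TestPca:
    def test_identical_sets_identical_embeddings(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(30, 6)), columns=list("abcdef"))
        t, g = ensemble.pca_embed(df, df, n_components=3)
        assert np.allclose(t, g)

    def test_small_hand_computed_pca(self):
        # 3 points in 2-D: top axis via explicit eigen-decomposition
        df = pd.DataFrame({"x": [0.0, 1.0, 2.0], "y": [0.0, 1.0, 2.0]})
        t, _ = ensemble.pca_embed(df, df, n_components=1)
        z = (df - df.mean()) / df.std(ddof=0)
        cov = np.cov(z.to_numpy().T, ddof=0)
        w, v = np.linalg.eigh(cov)
        proj = z.to_numpy() @ v[:, np.argmax(w)]
        assert np.allclose(np.abs(t.ravel()), np.abs(proj))

    def test_explained_variance_non_increasing(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(50, 8)))
        from sklearn.decomposition import PCA

        z = (df - df.mean()) / df.std(ddof=0)
        ev = PCA(n_components=5).fit(z.to_numpy()).explained_variance_
        assert (np.diff(ev) <= 1e-12).all()

    def test_fewer_features_than_components_uses_all(self):
        df = pd.DataFrame(np.random.default_rng(3).normal(size=(20, 3)))
        t, _ = ensemble.pca_embed(df, df, n_components=10)
        assert t.shape[1] == 3


class TestCosine:
    def test_hand_computed_similarities(self):
        a = np.array([[1.0, 0.0], [0.0, 2.0], [1.0, 1.0]])
        sims = ensemble._cosine(a[[0, 0, 1]], a[[0, 1, 2]])
        assert sims == pytest.approx([1.0, 0.0, np.sqrt(2) / 2])

    def test_samples_bounded_and_self_pairs_excluded(self):
        rng = np.random.default_rng(4)
        emb = rng.normal(size=(12, 10))
        tt, tg = ensemble.cosine_similarity_samples(emb, emb, n_pairs=500, seed=0)
        assert tt.shape == tg.shape == (500,)
        assert (np.abs(tt) <= 1 + 1e-12).all() and (np.abs(tg) <= 1 + 1e-12).all()

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            ensemble.cosine_similarity_samples(np.ones((1, 10)), np.ones((5, 10)))


class TestKs:
    def test_identical_samples_zero(self):
        assert ensemble.ks_statistic([1, 2, 3], [1, 2, 3]) == 0.0

    def test_disjoint_supports_one(self):
        assert ensemble.ks_statistic([0, 1], [5, 6]) == 1.0

    def test_ecdf_enumeration_oracle(self):
        # D on {1,2,3} vs {2,3,4}: max ECDF gap is 1/3
        assert ensemble.ks_statistic([1, 2, 3], [2, 3, 4]) == pytest.approx(1 / 3)

    @settings(deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-10, 10), min_size=1, max_size=10),
        st.lists(st.floats(-10, 10), min_size=1, max_size=10),
    )
    def test_symmetric_and_bounded(self, a, b):
        d1 = ensemble.ks_statistic(a, b)
        d2 = ensemble.ks_statistic(b, a)
        assert d1 == pytest.approx(d2)
        assert 0.0 <= d1 <= 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ensemble.ks_statistic([], [1.0])


class TestCoverageDensity:
    def test_identical_sets_full_coverage(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(20, 2))
        cov, _ = ensemble.coverage_density(pts, pts, k=3)
        assert cov == 1.0

    def test_distant_generated_zero(self):
        rng = np.random.default_rng(6)
        real = rng.normal(size=(10, 2))
        gen = real + 1000.0
        cov, den = ensemble.coverage_density(real, gen, k=2)
        assert cov == 0.0 and den == 0.0

    def test_brute_force_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        real = rng.normal(size=(5, 2))
        gen = rng.normal(size=(3, 2))
        k = 2
        cov, den = ensemble.coverage_density(real, gen, k=k)
        radii = []
        for i in range(5):
            ds = sorted(np.linalg.norm(real[i] - real[j]) for j in range(5) if j != i)
            radii.append(ds[k - 1])
        inside = [
            [np.linalg.norm(gen[j] - real[i]) <= radii[i] for i in range(5)] for j in range(3)
        ]
        assert den == pytest.approx(sum(map(sum, inside)) / (k * 3))
        assert cov == pytest.approx(
            sum(any(row[i] for row in inside) for i in range(5)) / 5
        )

    def test_too_few_real_samples_rejected(self):
        with pytest.raises(ValueError):
            ensemble.coverage_density(np.ones((3, 2)), np.ones((3, 2)), k=5)


class TestPrevalence:
    def test_1441_allocation(self):
        labels = ["a"] * 10 + ["b"] * 40 + ["c"] * 40 + ["d"] * 10
        out = ensemble.class_prevalence_summary(labels)
        assert out == {"a": 10.0, "b": 40.0, "c": 40.0, "d": 10.0}

    def test_single_class_hundred(self):
        assert ensemble.class_prevalence_summary(["x"] * 7) == {"x": 100.0}

    def test_random_labels_near_uniform(self):
        rng = np.random.default_rng(8)
        labels = rng.integers(0, 4, size=10_000)
        out = ensemble.class_prevalence_summary(labels)
        assert sum(out.values()) == pytest.approx(100.0)
        for v in out.values():
            assert v == pytest.approx(25.0, abs=2.0)  # ~4.6 binomial sigma

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ensemble.class_prevalence_summary([])
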