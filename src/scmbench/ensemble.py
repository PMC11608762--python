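"""Ensemble-level contextual-fidelity evaluation.

Generic framework for comparing a generated image ensemble to a training
(reference) ensemble:

1. extract per-image feature vectors grouped into named families —
   gray-level co-occurrence texture, region morphology, skeleton
   statistics and the fat-to-glandular (F/G) tissue ratio;
2. z-score by training statistics and project onto the top principal
   components fit on the training rows only (10 components for the
   similarity analysis, 2 for coverage/density);
3. estimate the distribution of cosine similarity over randomly selected
   training-training pairs and training-generated pairs, and summarize
   the difference by the two-sample Kolmogorov-Smirnov statistic;
4. compute class coverage and density (k-NN-ball manifold metrics) in the
   top-2 principal-component space, and class prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skimage.feature import graycomatrix, graycoprops
from skimage.measure import label as sk_label, regionprops
from skimage.morphology import skeletonize
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from ._skeleton import skeleton_stats

#: Feature family names.
FAMILIES = ("texture", "morphology", "skeleton", "fg_ratio")

_GLCM_DISTANCES = (1, 2, 4)
_GLCM_ANGLES = (0.0, np.pi / 2)
_GLCM_PROPS = ("contrast", "homogeneity", "energy", "correlation")


@dataclass
class FeatureTable:
    """Per-image features with a family tag for every column."""

    data: pd.DataFrame
    families: dict[str, list[str]] = field(default_factory=dict)

    def family_columns(self, family: str) -> list[str]:
        return self.families[family]

    def family_matrix(self, family: str) -> pd.DataFrame:
        """Rows with complete values for one family (incomputable rows are
        excluded per family)."""
        cols = self.families[family]
        return self.data[cols].dropna()

    def complete(self, families: tuple[str, ...] = FAMILIES) -> pd.DataFrame:
        cols = [c for f in families for c in self.families.get(f, [])]
        return self.data[cols].dropna()


def texture_features(image: np.ndarray) -> dict[str, float]:
    """GLCM summary statistics averaged over offsets {1,2,4} x {0, 90} deg."""
    glcm = graycomatrix(
        np.asarray(image, dtype=np.uint8),
        distances=_GLCM_DISTANCES,
        angles=_GLCM_ANGLES,
        levels=256,
        symmetric=True,
        normed=True,
    )
    return {f"glcm_{p}": float(graycoprops(glcm, p).mean()) for p in _GLCM_PROPS}


def morphology_features(mask: np.ndarray) -> dict[str, float]:
    """Mean area, perimeter, eccentricity and solidity over labeled regions."""
    labeled = sk_label(np.asarray(mask, dtype=bool))
    props = regionprops(labeled)
    if not props:
        return {f"morph_{k}": np.nan for k in ("area", "perimeter", "eccentricity", "solidity")}
    return {
        "morph_area": float(np.mean([p.area for p in props])),
        "morph_perimeter": float(np.mean([p.perimeter for p in props])),
        "morph_eccentricity": float(np.mean([p.eccentricity for p in props])),
        "morph_solidity": float(np.mean([p.solidity for p in props])),
    }


def skeleton_features(mask: np.ndarray) -> dict[str, float]:
    """Branch/junction statistics of the thinned mask."""
    sk = skeletonize(np.asarray(mask, dtype=bool))
    st = skeleton_stats(sk)
    if st.total_length == 0:
        return {
            f"skel_{k}": np.nan
            for k in ("n_branches", "n_junctions", "mean_branch_len", "std_branch_len", "total_len")
        }
    return {
        "skel_n_branches": float(st.n_branches),
        "skel_n_junctions": float(st.n_junctions),
        "skel_mean_branch_len": st.mean_branch_length,
        "skel_std_branch_len": st.std_branch_length,
        "skel_total_len": float(st.total_length),
    }


def fg_ratio_feature(fatty: np.ndarray, glandular: np.ndarray) -> dict[str, float]:
    n_gland = int(np.asarray(glandular).sum())
    if n_gland == 0:
        return {"fg_ratio": np.nan}
    return {"fg_ratio": float(np.asarray(fatty).sum()) / n_gland}


def extract_feature_families(
    images: list[np.ndarray],
    masks: list[dict[str, np.ndarray]],
) -> FeatureTable:
    """Per-image feature table over all four families.

    ``masks[i]`` supplies the per-image masks the families operate on:
    ``morphology`` (region mask), ``skeleton`` (mask to thin), ``fatty``
    and ``glandular``.  A family whose mask is missing or degenerate
    yields NaN for that row and is excluded per family downstream.
    """
    rows = []
    for image, m in zip(images, masks):
        row: dict[str, float] = {}
        row.update(texture_features(image))
        row.update(
            morphology_features(m["morphology"])
            if "morphology" in m
            else {k: np.nan for k in ("morph_area", "morph_perimeter", "morph_eccentricity", "morph_solidity")}
        )
        row.update(
            skeleton_features(m["skeleton"])
            if "skeleton" in m
            else {
                k: np.nan
                for k in (
                    "skel_n_branches",
                    "skel_n_junctions",
                    "skel_mean_branch_len",
                    "skel_std_branch_len",
                    "skel_total_len",
                )
            }
        )
        if "fatty" in m and "glandular" in m:
            row.update(fg_ratio_feature(m["fatty"], m["glandular"]))
        else:
            row["fg_ratio"] = np.nan
        rows.append(row)
    data = pd.DataFrame(rows)
    families = {
        "texture": [c for c in data.columns if c.startswith("glcm_")],
        "morphology": [c for c in data.columns if c.startswith("morph_")],
        "skeleton": [c for c in data.columns if c.startswith("skel_")],
        "fg_ratio": ["fg_ratio"],
    }
    return FeatureTable(data=data, families=families)


def phantom_masks(image: np.ndarray, bands=None) -> dict[str, np.ndarray]:
    """Standard mask set for a phantom image via global-threshold segmentation."""
    from .phantom import DEFAULT_BANDS, segment_tissues

    m = segment_tissues(image, bands or DEFAULT_BANDS)
    return {
        "morphology": ~m["background"],
        "skeleton": m["ligament"],
        "fatty": m["fatty"],
        "glandular": m["glandular"],
    }


# ---------------------------------------------------------------------------
# Embedding and similarity
# ---------------------------------------------------------------------------


def pca_embed(
    train_features: pd.DataFrame,
    gen_features: pd.DataFrame,
    n_components: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Z-score by training statistics and project on training-fit PCA axes.

    Components are fit on the training rows only so that pathologies of the
    generated set cannot distort the reference axes.  When fewer features
    (or rows) than components are available, all usable components are kept.
    """
    if list(train_features.columns) != list(gen_features.columns):
        raise ValueError("train and generated feature tables must share columns")
    x_train = train_features.to_numpy(dtype=float)
    x_gen = gen_features.to_numpy(dtype=float)
    mu = x_train.mean(axis=0)
    sd = x_train.std(axis=0)
    sd[sd == 0] = 1.0
    z_train = (x_train - mu) / sd
    z_gen = (x_gen - mu) / sd
    k = min(n_components, z_train.shape[1], z_train.shape[0])
    pca = PCA(n_components=k)
    emb_train = pca.fit_transform(z_train)
    emb_gen = pca.transform(z_gen)
    return emb_train, emb_gen


def cosine_similarity_samples(
    train_emb: np.ndarray,
    gen_emb: np.ndarray,
    n_pairs: int = 10_000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Cosine similarities of random train-train and train-generated pairs.

    Pairs are drawn with replacement across pairs; train-train self-pairs
    are excluded.
    """
    train_emb = np.asarray(train_emb, dtype=float)
    gen_emb = np.asarray(gen_emb, dtype=float)
    n, m = len(train_emb), len(gen_emb)
    if n < 2 or m < 1:
        raise ValueError("need at least two training rows and one generated row")
    rng = np.random.default_rng(seed)
    i = rng.integers(n, size=n_pairs)
    j = rng.integers(n, size=n_pairs)
    clash = i == j
    while clash.any():
        j[clash] = rng.integers(n, size=int(clash.sum()))
        clash = i == j
    sims_tt = _cosine(train_emb[i], train_emb[j])
    a = rng.integers(n, size=n_pairs)
    b = rng.integers(m, size=n_pairs)
    sims_tg = _cosine(train_emb[a], gen_emb[b])
    return sims_tt, sims_tg


def _cosine(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    num = (a * b).sum(axis=1)
    denom = np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
    out = np.zeros_like(num)
    nz = denom > 0
    out[nz] = num[nz] / denom[nz]
    return out


def ks_statistic(sample_a: np.ndarray, sample_b: np.ndarray) -> float:
    """Two-sample Kolmogorov-Smirnov statistic sup |ECDF_a - ECDF_b|."""
    sample_a = np.asarray(sample_a)
    sample_b = np.asarray(sample_b)
    if sample_a.size == 0 or sample_b.size == 0:
        raise ValueError("both samples must be non-empty")
    return float(stats.ks_2samp(sample_a, sample_b).statistic)


def similarity_summary(
    train_table: FeatureTable,
    gen_table: FeatureTable,
    n_pairs: int = 10_000,
    n_components: int = 10,
    seed: int = 0,
) -> dict:
    """KS statistic per feature family and over all features together."""
    out: dict[str, float] = {}
    for family in FAMILIES:
        tr = train_table.family_matrix(family)
        ge = gen_table.family_matrix(family)
        if tr.empty or ge.empty:
            out[f"ks_{family}"] = float("nan")
            continue
        emb_t, emb_g = pca_embed(tr, ge, n_components=n_components)
        tt, tg = cosine_similarity_samples(emb_t, emb_g, n_pairs=n_pairs, seed=seed)
        out[f"ks_{family}"] = ks_statistic(tt, tg)
    tr = train_table.complete()
    ge = gen_table.complete()
    emb_t, emb_g = pca_embed(tr, ge, n_components=n_components)
    tt, tg = cosine_similarity_samples(emb_t, emb_g, n_pairs=n_pairs, seed=seed)
    out["ks_overall"] = ks_statistic(tt, tg)
    return out


# ---------------------------------------------------------------------------
# Coverage / density / prevalence
# ---------------------------------------------------------------------------


def coverage_density(
    real_emb: np.ndarray, gen_emb: np.ndarray, k: int = 5
) -> tuple[float, float]:
    """k-NN-ball manifold coverage and density.

    Each real sample owns a ball of radius equal to the distance to its
    k-th nearest other real sample.  Density is the mean number of real
    balls containing a generated sample, divided by k; coverage is the
    fraction of real balls containing at least one generated sample.
    """
    real_emb = np.asarray(real_emb, dtype=float)
    gen_emb = np.asarray(gen_emb, dtype=float)
    if len(real_emb) < k + 1:
        raise ValueError("need more than k real samples")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(real_emb)
    dists, _ = nn.kneighbors(real_emb)
    radii = dists[:, -1]  # k-th neighbor excluding the point itself
    d = np.linalg.norm(gen_emb[:, None, :] - real_emb[None, :, :], axis=-1)
    inside = d <= radii[None, :]
    density = float(inside.sum() / (k * len(gen_emb)))
    coverage = float(inside.any(axis=0).mean())
    return coverage, density


def class_prevalence_summary(labels) -> dict[str, float]:
    """Per-class percentage of labels (summing to 100)."""
    labels = list(labels)
    if not labels:
        raise ValueError("empty label set")
    counts = pd.Series(labels).value_counts()
    return {str(k): float(100.0 * v / len(labels)) for k, v in counts.items()}
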