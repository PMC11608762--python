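"""Flag stochastic context model (eight classes).

A realization is a 256x256 grayscale image divided into a 16x16 grid of
16x16-pixel tiles.  A binary class-template matrix ``A`` (256 tile indices
x 8 classes) prescribes which tiles are foreground: every class has
exactly 80 foreground and 176 background tiles, and 24 tile indices are
never foreground in any class.  Tile intensities follow scaled Beta laws,

* foreground: ``152 X + 96`` with ``X ~ Beta(4, 2)`` (support [96, 248]),
* background: ``192 X + 8`` with ``X ~ Beta(2, 4)`` (support [8, 200]),

with the variates placed at uniformly random pixel positions within each
tile, so tile texture is spatially random.  Because every class has the
same foreground tile count, the total number of foreground pixels per
image is constant across classes (80 x 256), removing zero-order variance.

Analyzers: tile-mean thresholding recovers the foreground pattern;
relative mean absolute error (RMAE) against the templates recovers class
identity and localizes misplaced or forbidden tiles; Moran's I per tile
tests the random-placement texture; a chi-squared test against the Beta
bin probabilities checks the intensity laws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

IMAGE_SIZE = 256
GRID = 16
TILE = 16
N_TILES = GRID * GRID  # 256
N_CLASSES = 8
N_FOREGROUND = 80
N_BACKGROUND = N_TILES - N_FOREGROUND  # 176
N_FORBIDDEN = 24

FG_SCALE, FG_OFFSET, FG_A, FG_B = 152.0, 96.0, 4.0, 2.0
BG_SCALE, BG_OFFSET, BG_A, BG_B = 192.0, 8.0, 2.0, 4.0

#: Theoretical tile means: fg 152*(4/6)+96, bg 192*(2/6)+8.
FG_MEAN = FG_SCALE * (FG_A / (FG_A + FG_B)) + FG_OFFSET  # 197.33...
BG_MEAN = BG_SCALE * (BG_A / (BG_A + BG_B)) + BG_OFFSET  # 72.0
#: Foreground decision threshold: midpoint of the theoretical tile means.
TILE_MEAN_THRESHOLD = (FG_MEAN + BG_MEAN) / 2.0  # 134.67

DEFAULT_TEMPLATE_SEED = 20240831


@dataclass
class ClassTemplateSet:
    """Binary foreground matrix A: (256 tile indices, 8 classes)."""

    A: np.ndarray
    seed: int

    @property
    def forbidden(self) -> np.ndarray:
        """Tile indices that are foreground in no class."""
        return np.flatnonzero(self.A.sum(axis=1) == 0)

    def column(self, class_id: int) -> np.ndarray:
        """Foreground pattern of a 1-based class id, as a 256-bit vector."""
        return self.A[:, class_id - 1]


def build_class_templates(seed: int = DEFAULT_TEMPLATE_SEED) -> ClassTemplateSet:
    """Constrained-random class templates, deterministic given the seed.

    Construction: 24 forbidden indices are drawn first; each class then
    draws 80 foreground indices from the 232 allowed ones; finally, allowed
    indices that no class selected are swapped in (for a redundantly
    covered index) so that *exactly* the 24 forbidden indices are
    never-foreground.  Columns are checked pairwise distinct.
    """
    rng = np.random.default_rng(seed)
    for _ in range(100):
        forbidden = rng.choice(N_TILES, size=N_FORBIDDEN, replace=False)
        allowed = np.setdiff1d(np.arange(N_TILES), forbidden)
        A = np.zeros((N_TILES, N_CLASSES), dtype=np.uint8)
        for c in range(N_CLASSES):
            fg = rng.choice(allowed, size=N_FOREGROUND, replace=False)
            A[fg, c] = 1
        cover = A.sum(axis=1)
        uncovered = [i for i in allowed if cover[i] == 0]
        rng.shuffle(uncovered)
        for idx in uncovered:
            for c in rng.permutation(N_CLASSES):
                col_fg = np.flatnonzero(A[:, c])
                swappable = col_fg[cover[col_fg] >= 2]
                if swappable.size:
                    j = int(rng.choice(swappable))
                    A[j, c] = 0
                    A[idx, c] = 1
                    cover[j] -= 1
                    cover[idx] += 1
                    break
        if (A.sum(axis=0) != N_FOREGROUND).any():
            continue
        if np.flatnonzero(A.sum(axis=1) == 0).size != N_FORBIDDEN:
            continue
        distinct = all(
            (A[:, i] != A[:, j]).any() for i in range(N_CLASSES) for j in range(i + 1, N_CLASSES)
        )
        if distinct:
            return ClassTemplateSet(A=A, seed=seed)
    raise RuntimeError("template construction failed")


def save_templates(templates: ClassTemplateSet, path) -> None:
    """Plain-text 256x8 0/1 matrix, one tile index per row."""
    np.savetxt(path, templates.A, fmt="%d")


def load_templates(path) -> ClassTemplateSet:
    A = np.loadtxt(path, dtype=np.uint8)
    if A.shape != (N_TILES, N_CLASSES):
        raise ValueError(f"expected {(N_TILES, N_CLASSES)} matrix, got {A.shape}")
    return ClassTemplateSet(A=A, seed=-1)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def sample_tile(is_foreground: bool, rng: np.random.Generator) -> np.ndarray:
    """One 16x16 tile: 256 iid scaled-Beta variates at random pixel positions."""
    if is_foreground:
        values = FG_SCALE * rng.beta(FG_A, FG_B, size=TILE * TILE) + FG_OFFSET
    else:
        values = BG_SCALE * rng.beta(BG_A, BG_B, size=TILE * TILE) + BG_OFFSET
    values = np.rint(values)
    rng.shuffle(values)
    return values.reshape(TILE, TILE).astype(np.uint8)


def render_from_pattern(pattern: np.ndarray, seed: int) -> np.ndarray:
    """Render an image from an arbitrary 256-bit foreground pattern."""
    rng = np.random.default_rng(seed)
    image = np.zeros((IMAGE_SIZE, IMAGE_SIZE), dtype=np.uint8)
    for k in range(N_TILES):
        r, c = divmod(k, GRID)
        image[r * TILE : (r + 1) * TILE, c * TILE : (c + 1) * TILE] = sample_tile(
            bool(pattern[k]), rng
        )
    return image


def render_flag(class_id: int, templates: ClassTemplateSet, seed: int) -> np.ndarray:
    """Render one realization of a 1-based class id."""
    if not 1 <= class_id <= N_CLASSES:
        raise ValueError(f"class id must be in 1..{N_CLASSES}, got {class_id}")
    return render_from_pattern(templates.column(class_id), seed)


def generate_flag_ensemble(
    classes: tuple[int, ...],
    per_class: int,
    seed: int,
    templates: ClassTemplateSet | None = None,
):
    """Balanced ensemble; per-image seeds ``seed + i``."""
    import pandas as pd

    if templates is None:
        templates = build_class_templates()
    images, rows = [], []
    i = 0
    for c in classes:
        for _ in range(per_class):
            images.append(render_flag(c, templates, seed + i))
            rows.append({"index": i, "class": c, "seed": seed + i})
            i += 1
    return images, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Recovery and classification
# ---------------------------------------------------------------------------


def tile_means(image: np.ndarray) -> np.ndarray:
    """Per-tile pixel means in tile-index order, shape (256,)."""
    image = np.asarray(image, dtype=float)
    return image.reshape(GRID, TILE, GRID, TILE).mean(axis=(1, 3)).ravel()


def recover_foreground_pattern(
    image: np.ndarray, threshold: float = TILE_MEAN_THRESHOLD
) -> np.ndarray:
    """Classify each tile foreground iff its mean exceeds ``threshold``."""
    if np.asarray(image).shape != (IMAGE_SIZE, IMAGE_SIZE):
        raise ValueError("expected 256x256 image")
    return (tile_means(image) > threshold).astype(np.uint8)


def classify_by_rmae(
    pattern: np.ndarray, templates: ClassTemplateSet
) -> tuple[int, np.ndarray, bool, np.ndarray]:
    """RMAE classification of a recovered 256-bit foreground pattern.

    Returns (1-based class of minimal error, RMAE per class, whether any
    never-foreground index appears as foreground, mismatched tile indices
    against the best class).  RMAE is the mean absolute error relative to
    the per-class foreground count.  MAE ties resolve to the lower class.
    """
    pattern = np.asarray(pattern).astype(np.uint8)
    errors = np.abs(templates.A - pattern[:, None]).sum(axis=0)
    rmae = errors / N_FOREGROUND
    best = int(np.argmin(errors)) + 1  # argmin takes lower class on ties
    forbidden_violation = bool(pattern[templates.forbidden].any())
    error_tiles = np.flatnonzero(pattern != templates.column(best))
    return best, rmae, forbidden_violation, error_tiles


# ---------------------------------------------------------------------------
# Texture: Moran's I
# ---------------------------------------------------------------------------


def morans_i(tile: np.ndarray) -> float | None:
    """Moran's I with binary rook-adjacency weights on a square tile.

    Returns ``None`` for constant tiles (statistic undefined).  Under iid
    random placement the expected value is -1/(n-1).
    """
    x = np.asarray(tile, dtype=float)
    z = x - x.mean()
    denom = (z**2).sum()
    if denom == 0:
        return None
    num_h = (z[:, :-1] * z[:, 1:]).sum()
    num_v = (z[:-1, :] * z[1:, :]).sum()
    n = x.size
    w_sum = 2 * (x.shape[0] * (x.shape[1] - 1) + (x.shape[0] - 1) * x.shape[1])
    return float(n / w_sum * 2 * (num_h + num_v) / denom)


MORANS_NULL_MEAN = -1.0 / (TILE * TILE - 1)


def morans_null_band(
    n_tiles: int = 10_000,
    seed: int = 0,
    lower_pct: float = 0.5,
    upper_pct: float = 99.5,
) -> tuple[float, float]:
    """Simulation null band for Moran's I on iid foreground tiles.

    The band is the central (upper - lower) percent of I over ``n_tiles``
    independently generated tiles; tiles whose I lies inside are deemed
    random-texture.
    """
    rng = np.random.default_rng(seed)
    vals = np.empty(n_tiles)
    for i in range(n_tiles):
        vals[i] = morans_i(sample_tile(True, rng))
    return float(np.percentile(vals, lower_pct)), float(np.percentile(vals, upper_pct))


def image_morans(image: np.ndarray) -> np.ndarray:
    """Moran's I for each of the 256 tiles (NaN where undefined)."""
    image = np.asarray(image)
    out = np.empty(N_TILES)
    for k in range(N_TILES):
        r, c = divmod(k, GRID)
        v = morans_i(image[r * TILE : (r + 1) * TILE, c * TILE : (c + 1) * TILE])
        out[k] = np.nan if v is None else v
    return out


# ---------------------------------------------------------------------------
# Intensity goodness of fit
# ---------------------------------------------------------------------------

N_GOF_BINS = 16
_FG_EDGES = np.linspace(FG_OFFSET, FG_OFFSET + FG_SCALE, N_GOF_BINS + 1)
_BG_EDGES = np.linspace(BG_OFFSET, BG_OFFSET + BG_SCALE, N_GOF_BINS + 1)
_FG_PROBS = np.diff(stats.beta.cdf((_FG_EDGES - FG_OFFSET) / FG_SCALE, FG_A, FG_B))
_BG_PROBS = np.diff(stats.beta.cdf((_BG_EDGES - BG_OFFSET) / BG_SCALE, BG_A, BG_B))


def _chi2_against_beta(values: np.ndarray, edges: np.ndarray, probs: np.ndarray) -> float:
    observed, _ = np.histogram(values, bins=edges)
    expected = probs * values.size
    return float(((observed - expected) ** 2 / expected).sum())


def intensity_chi2(image: np.ndarray, pattern: np.ndarray) -> tuple[float, float]:
    """Chi-squared of pooled foreground/background pixels against the
    theoretical Beta bin probabilities (16 equal-width bins per support)."""
    image = np.asarray(image)
    pattern = np.asarray(pattern).astype(bool)
    tiles = image.reshape(GRID, TILE, GRID, TILE).transpose(0, 2, 1, 3).reshape(N_TILES, -1)
    fg = tiles[pattern].ravel()
    bg = tiles[~pattern].ravel()
    if fg.size == 0 or bg.size == 0:
        raise ValueError("empty foreground or background pixel set")
    return (
        _chi2_against_beta(fg, _FG_EDGES, _FG_PROBS),
        _chi2_against_beta(bg, _BG_EDGES, _BG_PROBS),
    )


def build_intensity_null(
    n_images: int = 200,
    seed: int = 0,
    percentile: float = 99.5,
    templates: ClassTemplateSet | None = None,
) -> tuple[float, float]:
    """Null chi-squared percentiles from a reference generated ensemble.

    Statistics are computed per image, separately for the pooled foreground
    and background pixels; the returned pair is the requested percentile of
    each, used as the acceptability cutoff.
    """
    if templates is None:
        templates = build_class_templates()
    rng = np.random.default_rng(seed)
    fg_stats, bg_stats = np.empty(n_images), np.empty(n_images)
    for i in range(n_images):
        c = 1 + int(rng.integers(N_CLASSES))
        img = render_flag(c, templates, int(rng.integers(2**31)))
        f, b = intensity_chi2(img, templates.column(c))
        fg_stats[i], bg_stats[i] = f, b
    return float(np.percentile(fg_stats, percentile)), float(np.percentile(bg_stats, percentile))


def intensity_gof(
    image: np.ndarray,
    pattern: np.ndarray,
    null_percentiles: tuple[float, float],
) -> tuple[float, float, bool]:
    """Acceptability of per-image intensity distributions.

    Acceptable iff both the foreground and background chi-squared statistics
    stay within their training-null percentiles.
    """
    chi2_fg, chi2_bg = intensity_chi2(image, pattern)
    acceptable = chi2_fg <= null_percentiles[0] and chi2_bg <= null_percentiles[1]
    return chi2_fg, chi2_bg, acceptable
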