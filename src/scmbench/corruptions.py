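"""Controlled injection of contextual error modes into clean ensembles.

Each corruption emulates an error mode observed in generated-image
ensembles — broken letter pairings, extra pairs, rank-correlation loss,
merged Voronoi regions, off-class region counts, misplaced or forbidden
foreground tiles, wrong intensity laws, broken ligaments — at a controlled
rate, with ground truth recorded per image.  This provides the reference
against which every detector's estimated error rate can be calibrated:
exactly for deterministic detectors, within binomial error for
statistical ones.

Exactly ``round(rate * n)`` images are affected and each affected image
receives exactly one violation of the named kind; a rate of zero is the
identity transform.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import alphabet, flags, phantom, voronoi

ALPHABET_MODES = ("swap_pair_order", "duplicate_pair", "orphan_letter", "replace_letter")
VORONOI_MODES = ("permute_intensities", "erase_edge_segment", "off_class_count")
FLAG_MODES = ("misplace_tile", "forbidden_fg_tile", "wrong_intensity_law")

_OFF_CLASS_COUNTS = (8, 24, 40, 56, 80)


def select_affected(n: int, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Boolean mask with exactly round(rate * n) affected images."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    k = int(round(rate * n))
    mask = np.zeros(n, dtype=bool)
    if k:
        mask[rng.choice(n, size=k, replace=False)] = True
    return mask


# ---------------------------------------------------------------------------
# Alphabet
# ---------------------------------------------------------------------------


def _corrupt_alphabet_layout(
    layout: alphabet.LetterLayout, mode: str, rng: np.random.Generator
) -> alphabet.LetterLayout:
    grid = layout.grid.copy()
    if mode == "swap_pair_order":
        xs = np.argwhere(grid == "X")
        r, c = xs[rng.integers(len(xs))]
        grid[r, c], grid[r, c + 1] = "Y", "X"
    elif mode == "duplicate_pair":
        sites = [
            (r, c)
            for r in range(alphabet.GRID - 1)
            for c in range(alphabet.GRID)
            if grid[r, c] in alphabet.FILLER and grid[r + 1, c] in alphabet.FILLER
        ]
        if not sites:
            raise LookupError("no vertical filler pair available")
        r, c = sites[rng.integers(len(sites))]
        grid[r, c], grid[r + 1, c] = "Z", "K"
    elif mode == "orphan_letter":
        sites = np.argwhere(np.isin(grid, alphabet.FILLER))
        r, c = sites[rng.integers(len(sites))]
        # any paired letter dropped on a filler cell is necessarily an
        # orphan: all existing pair partners are already adjacent to their
        # own pair, never to filler cells
        grid[r, c] = alphabet.PAIRED[rng.integers(len(alphabet.PAIRED))]
    elif mode == "replace_letter":
        sites = np.argwhere(grid == "H")
        r, c = sites[rng.integers(len(sites))]
        grid[r, c] = "L"
    else:
        raise ValueError(f"unknown alphabet corruption mode {mode!r}")
    return alphabet.LetterLayout(grid=grid, seed=layout.seed)


def corrupt_alphabet(
    layouts: list[alphabet.LetterLayout], mode: str, rate: float, seed: int
) -> tuple[list[alphabet.LetterLayout], pd.DataFrame]:
    """Corrupt a layout ensemble; returns new layouts and a truth manifest."""
    rng = np.random.default_rng(seed)
    affected = select_affected(len(layouts), rate, rng)
    out = []
    for i, layout in enumerate(layouts):
        out.append(_corrupt_alphabet_layout(layout, mode, rng) if affected[i] else layout)
    manifest = pd.DataFrame({"index": range(len(layouts)), "mode": mode, "affected": affected})
    return out, manifest


def detect_alphabet_violation(grid: np.ndarray, mode: str) -> bool:
    """Matched detector for each alphabet corruption mode.

    Pair-structure modes are flagged by the pair-prevalence scan (wrong
    counts or orphaned letters); ``replace_letter`` preserves pairs and is
    flagged by exact letter prevalence.
    """
    counts, orphans = alphabet.pair_prevalence(grid)
    if mode in ("swap_pair_order", "duplicate_pair", "orphan_letter"):
        return counts != alphabet.PAIR_COUNTS or bool(orphans)
    if mode == "replace_letter":
        letters, n = np.unique(grid, return_counts=True)
        observed = dict(zip(letters.tolist(), n.tolist()))
        return any(
            observed.get(letter, 0) != alphabet.LETTER_MULTISET[letter]
            for letter in alphabet.LETTERS
        )
    raise ValueError(f"unknown alphabet corruption mode {mode!r}")


# ---------------------------------------------------------------------------
# Voronoi
# ---------------------------------------------------------------------------


def _permute_intensities(real: voronoi.VoronoiRealization, rng) -> voronoi.VoronoiRealization:
    regions = real.regions.copy()
    regions["gray"] = rng.permutation(regions["gray"].to_numpy())
    image = voronoi.compose_image(real.label_map, regions)
    return voronoi.VoronoiRealization(
        image, real.centers, real.label_map, real.edge_mask, regions, real.seed
    )


def _erase_edge_segment(
    real: voronoi.VoronoiRealization, rng, radius: int = 5
) -> voronoi.VoronoiRealization:
    """Erase edge pixels in a disk, bridging two adjacent regions."""
    image = real.image.copy()
    ys, xs = np.where(real.edge_mask)
    # choose an interior edge pixel so the gap merges two regions
    interior = (ys > 8) & (ys < image.shape[0] - 8) & (xs > 8) & (xs < image.shape[1] - 8)
    ys, xs = ys[interior], xs[interior]
    i = int(rng.integers(ys.size))
    cy, cx = int(ys[i]), int(xs[i])
    yy, xx = np.mgrid[0 : image.shape[0], 0 : image.shape[1]]
    disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    erase = disk & real.edge_mask
    # fill with the gray of the nearest region pixel
    lut = np.zeros(int(real.label_map.max()) + 1, dtype=np.uint8)
    lut[real.regions["region"].to_numpy()] = real.regions["gray"].to_numpy()
    from scipy import ndimage

    _, (iy, ix) = ndimage.distance_transform_edt(real.label_map == 0, return_indices=True)
    image[erase] = lut[real.label_map[iy[erase], ix[erase]]]
    return voronoi.VoronoiRealization(
        image, real.centers, real.label_map, real.edge_mask, real.regions, real.seed
    )


def corrupt_voronoi(
    realizations: list[voronoi.VoronoiRealization], mode: str, rate: float, seed: int
) -> tuple[list[voronoi.VoronoiRealization], pd.DataFrame]:
    rng = np.random.default_rng(seed)
    affected = select_affected(len(realizations), rate, rng)
    out = []
    for i, real in enumerate(realizations):
        if not affected[i]:
            out.append(real)
        elif mode == "permute_intensities":
            out.append(_permute_intensities(real, rng))
        elif mode == "erase_edge_segment":
            out.append(_erase_edge_segment(real, rng))
        elif mode == "off_class_count":
            c = int(rng.choice(_OFF_CLASS_COUNTS))
            out.append(voronoi.generate_voronoi(c, real.seed + 500_009))
        else:
            raise ValueError(f"unknown voronoi corruption mode {mode!r}")
    manifest = pd.DataFrame(
        {"index": range(len(realizations)), "mode": mode, "affected": affected}
    )
    return out, manifest


def detect_voronoi_violation(image: np.ndarray, mode: str, rho_flag: float = 0.9) -> bool:
    """Matched image-based detector for each Voronoi corruption mode.

    ``permute_intensities``: recovered Spearman rho(area, gray) below the
    flag threshold.  ``erase_edge_segment``: a recovered region containing
    two substantial gray populations (a merge signature).
    ``off_class_count``: recovered region count classifies off-class.
    """
    labeled, regions = voronoi.recover_regions(image)
    if mode == "permute_intensities":
        return voronoi.area_gray_spearman(regions) < rho_flag
    if mode == "off_class_count":
        if len(regions) == 0:
            return True
        # tolerate the +/-2 recovery error on region counts; injected
        # off-class counts sit at least 8 away from any class
        return min(abs(len(regions) - c) for c in voronoi.CLASSES) > 3
    if mode == "erase_edge_segment":
        return _has_merged_region(image, labeled, regions)
    raise ValueError(f"unknown voronoi corruption mode {mode!r}")


def _has_merged_region(
    image: np.ndarray,
    labeled: np.ndarray,
    regions: pd.DataFrame,
    min_share: float = 0.2,
    min_pixels: int = 40,
) -> bool:
    """A region whose nonzero grays split into two substantial populations
    indicates two true regions bridged through an edge gap."""
    for rid in regions["region"]:
        vals = image[labeled == rid]
        nz = vals[vals > 0]
        if nz.size < 2 * min_pixels:
            continue
        counts = np.sort(np.bincount(nz))[::-1]
        if counts.size >= 2 and counts[1] >= max(min_pixels, min_share * nz.size):
            return True
    return False


# ---------------------------------------------------------------------------
# Flags
# ---------------------------------------------------------------------------


def corrupt_flags(
    classes: list[int],
    seeds: list[int],
    mode: str,
    rate: float,
    seed: int,
    templates: flags.ClassTemplateSet | None = None,
) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Render a flag ensemble with the named corruption at the given rate.

    The clean ensemble is defined by per-image (class, render seed) pairs;
    unaffected images render exactly as the clean ensemble would.
    """
    if templates is None:
        templates = flags.build_class_templates()
    rng = np.random.default_rng(seed)
    affected = select_affected(len(classes), rate, rng)
    images = []
    for i, (c, s) in enumerate(zip(classes, seeds)):
        pattern = templates.column(c).copy()
        if not affected[i]:
            images.append(flags.render_flag(c, templates, s))
            continue
        if mode == "misplace_tile":
            fg = np.flatnonzero(pattern == 1)
            allowed_bg = np.setdiff1d(np.flatnonzero(pattern == 0), templates.forbidden)
            pattern[rng.choice(fg)] = 0
            pattern[rng.choice(allowed_bg)] = 1
            images.append(flags.render_from_pattern(pattern, s))
        elif mode == "forbidden_fg_tile":
            fg = np.flatnonzero(pattern == 1)
            pattern[rng.choice(fg)] = 0
            pattern[rng.choice(templates.forbidden)] = 1
            images.append(flags.render_from_pattern(pattern, s))
        elif mode == "wrong_intensity_law":
            images.append(_render_wrong_fg_law(pattern, s))
        else:
            raise ValueError(f"unknown flag corruption mode {mode!r}")
    manifest = pd.DataFrame(
        {"index": range(len(classes)), "mode": mode, "affected": affected, "class": classes}
    )
    return images, manifest


def _render_wrong_fg_law(pattern: np.ndarray, seed: int) -> np.ndarray:
    """Foreground tiles drawn with the background Beta law rescaled to the
    foreground support, so position recovery succeeds but the intensity
    distribution is wrong."""
    rng = np.random.default_rng(seed)
    image = np.zeros((flags.IMAGE_SIZE, flags.IMAGE_SIZE), dtype=np.uint8)
    for k in range(flags.N_TILES):
        r, c = divmod(k, flags.GRID)
        if pattern[k]:
            values = flags.FG_SCALE * rng.beta(flags.BG_A, flags.BG_B, size=flags.TILE**2) + flags.FG_OFFSET
            values = np.rint(values)
            rng.shuffle(values)
            tile = values.reshape(flags.TILE, flags.TILE).astype(np.uint8)
        else:
            tile = flags.sample_tile(False, rng)
        image[r * flags.TILE : (r + 1) * flags.TILE, c * flags.TILE : (c + 1) * flags.TILE] = tile
    return image


def detect_flag_violation(
    image: np.ndarray,
    mode: str,
    templates: flags.ClassTemplateSet,
    null_percentiles: tuple[float, float] | None = None,
    chi2_margin: float = 2.0,
) -> bool:
    """Matched detector per flag corruption mode.

    ``misplace_tile``: mismatched tiles against the best class without a
    forbidden-index violation.  ``forbidden_fg_tile``: forbidden-index
    violation.  ``wrong_intensity_law``: foreground chi-squared beyond
    ``chi2_margin`` times the training-null percentile (the margin keeps
    the false-positive rate on clean images negligible).
    """
    pattern = flags.recover_foreground_pattern(image)
    _, _, forbidden, error_tiles = flags.classify_by_rmae(pattern, templates)
    if mode == "misplace_tile":
        return error_tiles.size > 0
    if mode == "forbidden_fg_tile":
        return forbidden
    if mode == "wrong_intensity_law":
        if null_percentiles is None:
            raise ValueError("wrong_intensity_law detection needs null percentiles")
        # guard the degenerate all-one-kind patterns
        if pattern.sum() in (0, pattern.size):
            return True
        chi2_fg, _ = flags.intensity_chi2(image, pattern)
        return chi2_fg > chi2_margin * null_percentiles[0]
    raise ValueError(f"unknown flag corruption mode {mode!r}")


# ---------------------------------------------------------------------------
# Phantom
# ---------------------------------------------------------------------------


def shift_tissue_intensities(
    image: np.ndarray, strength: float, rng: np.random.Generator, bands=None
) -> np.ndarray:
    """Promote each glandular pixel into the fatty band with probability
    ``strength``.

    Emulates progressive tissue-intensity misallocation: the measured F/G
    ratio of the corrupted image grows monotonically with ``strength``,
    which makes this the graded corruption used to probe the monotone
    sensitivity of the ensemble evaluation framework.
    """
    if strength == 0.0:
        return image
    b = bands or phantom.DEFAULT_BANDS
    image = np.asarray(image).copy()
    g_lo, g_hi = b["glandular"]
    f_lo, f_hi = b["fatty"]
    gland = (image >= g_lo) & (image <= g_hi)
    flip = gland & (rng.random(image.shape) < strength)
    image[flip] = rng.integers(f_lo, f_hi + 1, size=int(flip.sum()))
    return image


def corrupt_phantom(
    images: list[np.ndarray], rate: float, seed: int
) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Break one ligament per affected image (delegates to the phantom
    module's ligament eraser)."""
    rng = np.random.default_rng(seed)
    affected = select_affected(len(images), rate, rng)
    out = []
    for i, img in enumerate(images):
        if affected[i]:
            out.append(phantom.apply_ligament_break(img, rng))
        else:
            out.append(img)
    manifest = pd.DataFrame({"index": range(len(images)), "mode": "break_ligaments", "affected": affected})
    return out, manifest


def detect_ligament_break(clean: np.ndarray, corrupted: np.ndarray, bands=None) -> bool:
    """Paired skeleton-statistics break detector.

    A break opens a gap in the ligament web: skeleton endpoints increase
    and/or total skeleton length drops.
    """
    from skimage.morphology import skeletonize

    from ._skeleton import skeleton_stats

    b = bands or phantom.DEFAULT_BANDS
    lo, hi = b["ligament"]

    def _stats(im):
        return skeleton_stats(skeletonize((im >= lo) & (im <= hi)))

    s_clean, s_corr = _stats(clean), _stats(corrupted)
    return (
        s_corr.n_endpoints > s_clean.n_endpoints
        or s_corr.total_length <= s_clean.total_length - 8
    )
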