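"""Alphabet stochastic context model (single class).

A realization is a 256x256 grayscale image tiled into an 8x8 grid of
32x32-pixel letter glyphs.  Two kinds of spatial context are prescribed
exactly in every realization:

* per-image letter prevalence: the tile letters form the exact multiset
  ``{24 H, 2 K, 16 L, 1 V, 1 W, 8 X, 8 Y, 4 Z}``;
* ordered letter pairs: every X has a Y immediately to its right, and every
  K, V and W has a Z immediately above it, giving per-image pair counts
  X-Y = 8, Z-K = 2, Z-V = 1, Z-W = 1.  The letters X, Y, Z, K, V, W occur
  only inside these pairings; H and L are unconstrained filler.

Letter placement is otherwise unconstrained, so distinct seeds produce
diverse layouts that all satisfy the same contextual rules.  Recovery of
the layout from an image is by per-tile template matching with normalized
cross-correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

GRID = 8
TILE = 32
IMAGE_SIZE = GRID * TILE  # 256

LETTERS = ("H", "K", "L", "V", "W", "X", "Y", "Z")

#: Exact per-image letter multiset.
LETTER_MULTISET = {"H": 24, "K": 2, "L": 16, "V": 1, "W": 1, "X": 8, "Y": 8, "Z": 4}

#: Ordered pair counts prescribed per image: X-Y horizontal, Z above K/V/W.
PAIR_COUNTS = {"XY": 8, "ZK": 2, "ZV": 1, "ZW": 1}

FILLER = ("H", "L")
PAIRED = ("K", "V", "W", "X", "Y", "Z")


# ---------------------------------------------------------------------------
# Glyphs
# ---------------------------------------------------------------------------

# Block-letter stroke endpoints in (row, col) tile coordinates.  These are a
# versioned fixture: changing them changes rendered ensembles.
_STROKES = {
    "H": [((4, 7), (27, 7)), ((4, 24), (27, 24)), ((15.5, 7), (15.5, 24))],
    "K": [((4, 7), (27, 7)), ((15.5, 8), (4, 24)), ((15.5, 8), (27, 24))],
    "L": [((4, 8), (27, 8)), ((27, 8), (27, 25))],
    "V": [((4, 6), (27, 15.5)), ((4, 25), (27, 15.5))],
    "W": [((4, 5), (27, 10)), ((27, 10), (11, 15.5)), ((11, 15.5), (27, 21)), ((27, 21), (4, 26))],
    "X": [((4, 6), (27, 25)), ((4, 25), (27, 6))],
    "Y": [((4, 6), (15.5, 15.5)), ((4, 25), (15.5, 15.5)), ((15.5, 15.5), (27, 15.5))],
    "Z": [((4, 6), (4, 25)), ((4, 25), (27, 6)), ((27, 6), (27, 25))],
}
_STROKE_WIDTH = 4.0


def _render_strokes(segments, size=TILE, width=_STROKE_WIDTH) -> np.ndarray:
    rr, cc = np.mgrid[0:size, 0:size].astype(float)
    pts = np.stack([rr, cc], axis=-1)
    mask = np.zeros((size, size), dtype=bool)
    for (r0, c0), (r1, c1) in segments:
        p0 = np.array([r0, c0], dtype=float)
        d = np.array([r1 - r0, c1 - c0], dtype=float)
        denom = float(d @ d)
        if denom == 0:
            dist = np.linalg.norm(pts - p0, axis=-1)
        else:
            t = np.clip(((pts - p0) @ d) / denom, 0.0, 1.0)
            proj = p0 + t[..., None] * d
            dist = np.linalg.norm(pts - proj, axis=-1)
        mask |= dist <= width / 2.0
    return np.where(mask, 255, 0).astype(np.uint8)


def build_glyph_set() -> dict[str, np.ndarray]:
    """Deterministic 32x32 block-letter bitmaps for all eight letters.

    Foreground is 255, background 0.  The glyphs are pairwise
    distinguishable: the normalized cross-correlation between any two
    distinct bitmaps is below 0.8.
    """
    return {letter: _render_strokes(_STROKES[letter]) for letter in LETTERS}


def normalized_cross_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Zero-lag, zero-mean normalized cross-correlation of two equal-size tiles."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(a @ b / denom)


# ---------------------------------------------------------------------------
# Layout sampling
# ---------------------------------------------------------------------------


@dataclass
class LetterLayout:
    """8x8 grid of letter labels plus the seed that produced it."""

    grid: np.ndarray  # dtype <U1, shape (8, 8)
    seed: int

    def counts(self) -> dict[str, int]:
        letters, n = np.unique(self.grid, return_counts=True)
        out = {letter: 0 for letter in LETTERS}
        out.update(dict(zip(letters.tolist(), n.tolist())))
        return out


# Dominoes to place: (letter_at_anchor, letter_at_second, d_row, d_col).
# X-Y is horizontal with Y to the right of X; Z sits above K, V and W.
_DOMINOES = (
    [("X", "Y", 0, 1)] * PAIR_COUNTS["XY"]
    + [("Z", "K", 1, 0)] * PAIR_COUNTS["ZK"]
    + [("Z", "V", 1, 0)] * PAIR_COUNTS["ZV"]
    + [("Z", "W", 1, 0)] * PAIR_COUNTS["ZW"]
)


def sample_letter_layout(seed: int, max_attempts: int = 10_000) -> LetterLayout:
    """Sample a layout satisfying the multiset and pair constraints.

    The 12 letter-pair dominoes are placed in random order at uniformly
    random admissible grid positions; if a placement pass dead-ends the
    whole pass restarts (constraints are then guaranteed by construction).
    The remaining 40 cells are filled with a random permutation of
    24 H and 16 L.
    """
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        grid = np.full((GRID, GRID), "", dtype="<U1")
        order = rng.permutation(len(_DOMINOES))
        ok = True
        for idx in order:
            first, second, dr, dc = _DOMINOES[idx]
            free = [
                (r, c)
                for r in range(GRID - dr)
                for c in range(GRID - dc)
                if grid[r, c] == "" and grid[r + dr, c + dc] == ""
            ]
            if not free:
                ok = False
                break
            r, c = free[rng.integers(len(free))]
            grid[r, c] = first
            grid[r + dr, c + dc] = second
        if not ok:
            continue
        filler = np.array(["H"] * LETTER_MULTISET["H"] + ["L"] * LETTER_MULTISET["L"])
        rng.shuffle(filler)
        grid[grid == ""] = filler
        return LetterLayout(grid=grid, seed=seed)
    raise RuntimeError(f"layout sampling exhausted {max_attempts} attempts (seed={seed})")


def validate_layout(grid: np.ndarray) -> list[str]:
    """Brute-force constraint check; returns a list of violation messages.

    Independent of the sampler: scans all 64 cells and all adjacencies.
    """
    violations = []
    letters, n = np.unique(grid, return_counts=True)
    counts = dict(zip(letters.tolist(), n.tolist()))
    for letter in LETTERS:
        if counts.get(letter, 0) != LETTER_MULTISET[letter]:
            violations.append(
                f"count[{letter}]={counts.get(letter, 0)} != {LETTER_MULTISET[letter]}"
            )
    for r in range(GRID):
        for c in range(GRID):
            g = grid[r, c]
            if g == "X" and (c + 1 >= GRID or grid[r, c + 1] != "Y"):
                violations.append(f"X at {(r, c)} lacks Y to its right")
            if g == "Y" and (c == 0 or grid[r, c - 1] != "X"):
                violations.append(f"Y at {(r, c)} lacks X to its left")
            if g in ("K", "V", "W") and (r == 0 or grid[r - 1, c] != "Z"):
                violations.append(f"{g} at {(r, c)} lacks Z above")
            if g == "Z" and (r + 1 >= GRID or grid[r + 1, c] not in ("K", "V", "W")):
                violations.append(f"Z at {(r, c)} lacks K/V/W below")
    return violations


# ---------------------------------------------------------------------------
# Rendering and recovery
# ---------------------------------------------------------------------------


def render_realization(layout: LetterLayout, glyphs: dict[str, np.ndarray] | None = None) -> np.ndarray:
    """Stamp glyph bitmaps onto the 8x8 tile grid."""
    if glyphs is None:
        glyphs = build_glyph_set()
    image = np.zeros((IMAGE_SIZE, IMAGE_SIZE), dtype=np.uint8)
    for r in range(GRID):
        for c in range(GRID):
            image[r * TILE : (r + 1) * TILE, c * TILE : (c + 1) * TILE] = glyphs[layout.grid[r, c]]
    return image


def recover_layout(
    image: np.ndarray,
    glyphs: dict[str, np.ndarray] | None = None,
    threshold: float = 0.9,
) -> tuple[LetterLayout, np.ndarray, bool]:
    """Per-tile template matching by normalized cross-correlation.

    Each tile is assigned the glyph with the highest correlation score.
    Returns the recovered layout, the 8x8 array of best scores (for audit),
    and whether all 64 best scores reach ``threshold`` (letters deemed
    unambiguously recognizable).
    """
    image = np.asarray(image)
    if image.shape != (IMAGE_SIZE, IMAGE_SIZE):
        raise ValueError(f"expected {IMAGE_SIZE}x{IMAGE_SIZE} image, got {image.shape}")
    if glyphs is None:
        glyphs = build_glyph_set()
    letters = list(glyphs)
    # (n_glyphs, TILE*TILE) centered unit templates
    templates = np.stack([glyphs[g].astype(float).ravel() for g in letters])
    templates -= templates.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(templates, axis=1)
    grid = np.full((GRID, GRID), "", dtype="<U1")
    scores = np.zeros((GRID, GRID))
    for r in range(GRID):
        for c in range(GRID):
            tile = image[r * TILE : (r + 1) * TILE, c * TILE : (c + 1) * TILE].astype(float).ravel()
            tile = tile - tile.mean()
            tnorm = np.linalg.norm(tile)
            if tnorm == 0:
                corr = np.zeros(len(letters))
            else:
                corr = templates @ tile / (norms * tnorm)
            best = int(np.argmax(corr))
            grid[r, c] = letters[best]
            scores[r, c] = corr[best]
    recognizable = bool(np.all(scores >= threshold))
    return LetterLayout(grid=grid, seed=-1), scores, recognizable


# ---------------------------------------------------------------------------
# Prevalence statistics
# ---------------------------------------------------------------------------


def letter_prevalence_gof(counts: dict[str, int], critical: float = 0.95) -> tuple[float, bool]:
    """Chi-squared goodness of fit of per-image letter counts against the
    prescribed multiset (8 categories, 7 degrees of freedom).

    Passes iff the statistic does not exceed the ``critical`` quantile of
    the chi-squared distribution.
    """
    observed = np.array([counts.get(letter, 0) for letter in LETTERS], dtype=float)
    if observed.sum() != GRID * GRID:
        raise ValueError(f"counts sum to {observed.sum()}, expected {GRID * GRID}")
    expected = np.array([LETTER_MULTISET[letter] for letter in LETTERS], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    crit = stats.chi2.ppf(critical, df=len(LETTERS) - 1)
    return chi2, chi2 <= crit


def pair_prevalence(grid: np.ndarray) -> tuple[dict[str, int], list[tuple[int, int, str]]]:
    """Scan all adjacencies for the four prescribed ordered pairs.

    Works on arbitrary 8x8 label grids (not necessarily constraint
    satisfying).  Returns pair counts and orphan flags: any X, Y, K, V, W
    or Z not participating in its prescribed pairing, as (row, col, letter).
    """
    counts = {"XY": 0, "ZK": 0, "ZV": 0, "ZW": 0}
    orphans = []
    for r in range(GRID):
        for c in range(GRID):
            g = grid[r, c]
            if g == "X" and c + 1 < GRID and grid[r, c + 1] == "Y":
                counts["XY"] += 1
            if g == "Z" and r + 1 < GRID and grid[r + 1, c] in ("K", "V", "W"):
                counts["Z" + grid[r + 1, c]] += 1
    for r in range(GRID):
        for c in range(GRID):
            g = grid[r, c]
            if g == "X" and not (c + 1 < GRID and grid[r, c + 1] == "Y"):
                orphans.append((r, c, g))
            elif g == "Y" and not (c > 0 and grid[r, c - 1] == "X"):
                orphans.append((r, c, g))
            elif g in ("K", "V", "W") and not (r > 0 and grid[r - 1, c] == "Z"):
                orphans.append((r, c, g))
            elif g == "Z" and not (r + 1 < GRID and grid[r + 1, c] in ("K", "V", "W")):
                orphans.append((r, c, g))
    return counts, orphans


def generate_alphabet_ensemble(n: int, seed: int) -> tuple[list[np.ndarray], list[LetterLayout]]:
    """Render ``n`` realizations with per-image seeds ``seed + i``."""
    glyphs = build_glyph_set()
    layouts = [sample_letter_layout(seed + i) for i in range(n)]
    images = [render_realization(layout, glyphs) for layout in layouts]
    return images, layouts
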