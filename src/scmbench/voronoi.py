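"""Voronoi stochastic context model (four classes).

A realization is a 256x256 grayscale Voronoi partition with c regions,
where the class label c is one of {16, 32, 48, 64}.  Region centers are
placed uniformly at random (with a minimum separation so every region is
resolvable); edges between regions are rendered at intensity 0; every
pixel of a region shares one gray level drawn from a 128-value palette in
[1, 254]; and gray levels are assigned so that the Spearman rank
correlation between region area and region gray level is exactly 1 —
larger regions are always brighter.

Post-hoc recovery isolates the dark edge network with Sauvola local
thresholding, thins it to a skeleton, and takes 4-connected components of
the complement as regions (modal gray, pixel-count area).  Implicit
context statistics (junction counts, edge lengths, region areas) are
derived from the skeletonized edge graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import cKDTree
from skimage.filters import threshold_sauvola
from skimage.morphology import skeletonize

from ._skeleton import skeleton_stats

IMAGE_SIZE = 256
CLASSES = (16, 32, 48, 64)
MIN_CENTER_SEPARATION = 8.0
EDGE_INTENSITY = 0

#: 128 evenly spaced gray levels in [1, 254].
PALETTE = np.unique(np.round(np.linspace(1, 254, 128)).astype(np.uint8))
assert PALETTE.size == 128


class AreaTieError(RuntimeError):
    """Raised when region areas tie, making an exact rank correlation of 1
    unattainable under tie-aware Spearman."""


@dataclass
class VoronoiRealization:
    image: np.ndarray
    centers: np.ndarray  # (c, 2) float (row, col)
    label_map: np.ndarray  # region ids 1..c, edge pixels 0
    edge_mask: np.ndarray
    regions: pd.DataFrame  # columns: region, area, gray
    seed: int


def sample_centers(
    c: int,
    seed: int,
    image_size: int = IMAGE_SIZE,
    d_min: float = MIN_CENTER_SEPARATION,
    max_attempts: int = 200,
) -> np.ndarray:
    """c spatially random points with pairwise separation >= d_min.

    Dart-throwing: points are placed one at a time, rejecting candidates
    closer than ``d_min`` to an accepted point; a full restart occurs if a
    point cannot be placed within ``max_attempts`` candidates.
    """
    if c < 1:
        raise ValueError("need at least one center")
    rng = np.random.default_rng(seed)
    for _ in range(20):
        pts: list[np.ndarray] = []
        ok = True
        for _ in range(c):
            for _ in range(max_attempts):
                p = rng.uniform(0, image_size, size=2)
                if not pts or np.linalg.norm(np.array(pts) - p, axis=1).min() >= d_min:
                    pts.append(p)
                    break
            else:
                ok = False
                break
        if ok:
            return np.array(pts)
    raise RuntimeError(f"center sampling failed (c={c}, d_min={d_min})")


def rasterize_partition(centers: np.ndarray, image_size: int = IMAGE_SIZE) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-center (Euclidean) labeling plus a thin edge mask.

    Labels are 1-based region ids; ``label_map`` is 0 on edge pixels.  A
    pixel is an edge pixel when its label differs from the pixel to its
    right or the pixel below (forward differences), which yields an
    approximately one-pixel boundary between regions.
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    rr, cc = np.mgrid[0:image_size, 0:image_size]
    pix = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float) + 0.5
    _, nearest = cKDTree(centers).query(pix)
    labels = (nearest + 1).reshape(image_size, image_size)
    edge = np.zeros((image_size, image_size), dtype=bool)
    edge[:, :-1] |= labels[:, :-1] != labels[:, 1:]
    edge[:-1, :] |= labels[:-1, :] != labels[1:, :]
    label_map = np.where(edge, 0, labels)
    return label_map, edge


def region_areas(label_map: np.ndarray) -> np.ndarray:
    """Pixel counts per region id (edge pixels excluded), 1-based order."""
    n = label_map.max()
    return np.bincount(label_map.ravel(), minlength=n + 1)[1:]


def assign_region_intensities(
    label_map: np.ndarray,
    seed: int,
    palette: np.ndarray = PALETTE,
) -> pd.DataFrame:
    """Draw a random subset of the palette and assign grays by area rank.

    Regions sorted by ascending area receive palette values in ascending
    order, so Spearman rho(area, gray) = 1 exactly.  Raises
    :class:`AreaTieError` when two regions have identical pixel areas.
    """
    areas = region_areas(label_map)
    if np.unique(areas).size != areas.size:
        raise AreaTieError("tied region areas; resample centers")
    rng = np.random.default_rng(seed)
    grays = np.sort(rng.choice(palette, size=areas.size, replace=False))
    order = np.argsort(areas)
    gray_by_region = np.empty(areas.size, dtype=np.uint8)
    gray_by_region[order] = grays
    return pd.DataFrame(
        {"region": np.arange(1, areas.size + 1), "area": areas, "gray": gray_by_region}
    )


def compose_image(label_map: np.ndarray, regions: pd.DataFrame) -> np.ndarray:
    lut = np.zeros(int(label_map.max()) + 1, dtype=np.uint8)
    lut[regions["region"].to_numpy()] = regions["gray"].to_numpy()
    return lut[label_map]


def generate_voronoi(c: int, seed: int, max_resamples: int = 100) -> VoronoiRealization:
    """Generate one realization of class ``c`` (any positive region count is
    accepted, enabling off-class fixtures)."""
    for attempt in range(max_resamples):
        centers = sample_centers(c, seed + 1_000_003 * attempt)
        label_map, edge = rasterize_partition(centers)
        # every center must own at least one non-edge pixel
        if (region_areas(label_map) == 0).any():
            continue
        try:
            regions = assign_region_intensities(label_map, seed)
        except AreaTieError:
            continue
        image = compose_image(label_map, regions)
        return VoronoiRealization(image, centers, label_map, edge, regions, seed)
    raise AreaTieError(f"could not resolve area ties in {max_resamples} resamples")


def area_gray_spearman(regions: pd.DataFrame) -> float:
    if len(regions) < 2:
        return 1.0
    return float(stats.spearmanr(regions["area"], regions["gray"]).statistic)


# ---------------------------------------------------------------------------
# Recovery
# ---------------------------------------------------------------------------


_EDGE_PAD = 4


def detect_edges(
    image: np.ndarray,
    window_size: int = 15,
    k: float = 0.2,
    dark_cap: int | None = EDGE_INTENSITY,
) -> np.ndarray:
    """Skeletonized edge network of a realization.

    Candidate edge pixels fall below the Sauvola local threshold and, when
    ``dark_cap`` is given, at or below that absolute intensity.  The cap is
    needed because the palette spans [1, 254]: inter-region contrast can
    exceed region-to-edge contrast, so a local threshold alone absorbs dark
    regions bordering bright ones.  The mask is padded with a true margin
    before thinning so that edge branches terminating at the image border
    are not retracted as topological spurs; the margin's own skeleton lies
    outside the image and is cropped away.
    """
    image = np.asarray(image)
    t = threshold_sauvola(image.astype(float), window_size=window_size, k=k)
    edge = image < t
    if dark_cap is not None:
        edge &= image <= dark_cap
    padded = np.pad(edge, _EDGE_PAD, constant_values=True)
    return skeletonize(padded)[_EDGE_PAD:-_EDGE_PAD, _EDGE_PAD:-_EDGE_PAD]


def recover_regions(
    image: np.ndarray,
    window_size: int = 15,
    k: float = 0.2,
    dark_cap: int | None = EDGE_INTENSITY,
    min_area: int = 10,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Recover the region partition from an image alone.

    Sauvola local thresholding (with a darkness cap, see
    :func:`detect_edges`) isolates the dark edge network, morphological
    thinning reduces it to a 1-pixel skeleton, and 4-connected components of
    the skeleton complement are taken as regions.  Per-region gray is the
    modal non-zero intensity; area is the component pixel count.  Components
    below ``min_area`` pixels (isolated holes left by thinning, far smaller
    than any resolvable region) are dropped.
    """
    image = np.asarray(image)
    if image.max() == 0:
        return np.zeros_like(image, dtype=np.int32), pd.DataFrame(
            columns=["region", "area", "gray"]
        )
    skel = detect_edges(image, window_size=window_size, k=k, dark_cap=dark_cap)
    labeled, n = ndimage.label(~skel, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    sizes = np.bincount(labeled.ravel(), minlength=n + 1)
    rows = []
    for rid in range(1, n + 1):
        if sizes[rid] < min_area:
            labeled[labeled == rid] = 0
            continue
        mask = labeled == rid
        vals = image[mask]
        nz = vals[vals > 0]
        gray = int(np.bincount(nz).argmax()) if nz.size else 0
        rows.append((rid, int(mask.sum()), gray))
    return labeled, pd.DataFrame(rows, columns=["region", "area", "gray"])


def implicit_context_stats(label_map: np.ndarray, edge_mask: np.ndarray) -> dict[str, float]:
    """Seven implicit-context statistics of the Voronoi edge graph.

    Junctions and edge segments are read off the skeletonized edge network;
    region statistics come from the label map.  Junction density is
    junctions per pixel of image area.
    """
    skel = skeletonize(edge_mask)
    sk = skeleton_stats(skel)
    areas = region_areas(label_map)
    areas = areas[areas > 0]
    n_pix = label_map.size
    return {
        "n_regions": float(areas.size),
        "n_junctions": float(sk.n_junctions),
        "junction_density": sk.n_junctions / n_pix,
        "mean_edge_length": sk.mean_branch_length,
        "std_edge_length": sk.std_branch_length,
        "mean_region_area": float(areas.mean()) if areas.size else 0.0,
        "std_region_area": float(areas.std()) if areas.size else 0.0,
    }


def classify_by_region_count(n_regions: int) -> tuple[int, str]:
    """Map a region count to (nearest class, status).

    Status is ``in-class`` for counts in {16, 32, 48, 64}, ``interpolated``
    strictly between the extreme classes, and ``extrapolated`` outside
    them.  Equidistant counts resolve to the lower class.
    """
    if n_regions < 1:
        raise ValueError("need at least one region")
    classes = np.array(CLASSES)
    dist = np.abs(classes - n_regions)
    nearest = int(classes[int(np.argmin(dist))])  # argmin takes the lower class on ties
    if n_regions in CLASSES:
        status = "in-class"
    elif CLASSES[0] < n_regions < CLASSES[-1]:
        status = "interpolated"
    else:
        status = "extrapolated"
    return nearest, status


def generate_voronoi_ensemble(
    classes: tuple[int, ...],
    per_class: int,
    seed: int,
) -> tuple[list[VoronoiRealization], pd.DataFrame]:
    """Balanced ensemble across ``classes``, per-image seeds ``seed + i``."""
    reals, rows = [], []
    i = 0
    for c in classes:
        for _ in range(per_class):
            r = generate_voronoi(c, seed + i)
            reals.append(r)
            rows.append({"index": i, "class": c, "seed": seed + i})
            i += 1
    return reals, pd.DataFrame(rows)
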