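"""Synthetic breast-slice phantom fixture (four density classes).

A lightweight, fully synthetic stand-in for an anatomy-derived stochastic
object model of coronal breast slices, reproducing only the properties the
ensemble evaluation pipeline needs to recover:

* zero-valued background surrounding a compact, ellipse-like breast region;
* two tissue intensity bands — fatty and glandular — disjoint from each
  other, from the background and from a bright ligament band, so global
  thresholding segments tissues exactly;
* a thin ligament web (Voronoi ridges of random points clipped to the
  breast region) that yields a recoverable skeleton;
* a fat-to-glandular (F/G) pixel ratio that determines the density class
  (fatty, scattered, heterogeneous, dense), with class prevalence 1:4:4:1.

No anatomical realism is claimed: attenuation physics, 3D anatomy and
clinical BI-RADS fidelity are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

IMAGE_SIZE = 512

#: Disjoint 8-bit intensity bands (inclusive) per tissue type.
DEFAULT_BANDS = {
    "background": (0, 0),
    "glandular": (60, 120),
    "fatty": (150, 200),
    "ligament": (230, 255),
}

CLASS_NAMES = ("fatty", "scattered", "heterogeneous", "dense")

#: Disjoint F/G-ratio intervals per class, ordered fatty > ... > dense.
CLASS_FG_RANGES = {
    "fatty": (3.0, 5.0),
    "scattered": (1.5, 3.0),
    "heterogeneous": (0.5, 1.5),
    "dense": (0.1, 0.5),
}

#: Population class prevalence fatty:scattered:heterogeneous:dense.
CLASS_WEIGHTS = (1, 4, 4, 1)


@dataclass
class Phantom:
    image: np.ndarray
    class_name: str
    target_fg_ratio: float
    seed: int


def allocate_classes(n: int, weights: tuple[int, ...] = CLASS_WEIGHTS) -> list[str]:
    """Deterministic largest-remainder allocation of n images to classes."""
    if n < len(CLASS_NAMES):
        raise ValueError(f"need at least {len(CLASS_NAMES)} images")
    total = sum(weights)
    quotas = [n * w / total for w in weights]
    counts = [int(np.floor(q)) for q in quotas]
    remainder = n - sum(counts)
    frac_order = sorted(range(len(weights)), key=lambda i: quotas[i] - counts[i], reverse=True)
    for i in frac_order[:remainder]:
        counts[i] += 1
    labels = []
    for name, k in zip(CLASS_NAMES, counts):
        labels.extend([name] * k)
    return labels


def _breast_mask(rng: np.random.Generator, size: int) -> np.ndarray:
    """Random rotated ellipse occupying the central portion of the image."""
    cy = size / 2 + rng.uniform(-0.03, 0.03) * size
    cx = size / 2 + rng.uniform(-0.03, 0.03) * size
    a = rng.uniform(0.28, 0.40) * size
    b = rng.uniform(0.24, 0.36) * size
    theta = rng.uniform(0, np.pi)
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    dy, dx = yy - cy, xx - cx
    u = dy * np.cos(theta) + dx * np.sin(theta)
    v = -dy * np.sin(theta) + dx * np.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _ligament_mask(rng: np.random.Generator, region: np.ndarray) -> np.ndarray:
    """Voronoi ridges of random points, clipped to the breast region."""
    size = region.shape[0]
    n_pts = int(rng.integers(20, 35))
    ys, xs = np.where(region)
    pick = rng.choice(ys.size, size=n_pts, replace=False)
    pts = np.stack([ys[pick], xs[pick]], axis=1).astype(float)
    pix = np.stack([ys, xs], axis=1).astype(float)
    _, nearest = cKDTree(pts).query(pix)
    labels = np.zeros((size, size), dtype=np.int32)
    labels[ys, xs] = nearest + 1
    ridge = np.zeros_like(region)
    ridge[:, :-1] |= (labels[:, :-1] != labels[:, 1:]) & (labels[:, :-1] > 0) & (labels[:, 1:] > 0)
    ridge[:-1, :] |= (labels[:-1, :] != labels[1:, :]) & (labels[:-1, :] > 0) & (labels[1:, :] > 0)
    return ridge & region


def generate_phantom(
    class_name: str,
    seed: int,
    size: int = IMAGE_SIZE,
    bands: dict = DEFAULT_BANDS,
) -> Phantom:
    """One phantom of the given density class.

    The target F/G ratio is drawn from the class interval (slightly inset
    from the boundaries); tissue pixels are split into fatty and glandular
    by thresholding a smoothed random field at the exact pixel quantile,
    so the realized ratio matches the target almost exactly.
    """
    if class_name not in CLASS_NAMES:
        raise ValueError(f"unknown class {class_name!r}")
    rng = np.random.default_rng(seed)
    lo, hi = CLASS_FG_RANGES[class_name]
    inset = 0.05 * (hi - lo)
    target = float(rng.uniform(lo + inset, hi - inset))

    region = _breast_mask(rng, size)
    ligament = _ligament_mask(rng, region)
    tissue = region & ~ligament
    n_tissue = int(tissue.sum())
    n_fat = int(round(n_tissue * target / (1.0 + target)))

    field = ndimage.gaussian_filter(rng.standard_normal((size, size)), sigma=8)
    tvals = field[tissue]
    order = np.argsort(tvals)
    fat_flat = np.zeros(n_tissue, dtype=bool)
    fat_flat[order[n_tissue - n_fat :]] = True
    fatty = np.zeros_like(tissue)
    fatty[tissue] = fat_flat
    glandular = tissue & ~fatty

    image = np.zeros((size, size), dtype=np.uint8)
    image[fatty] = rng.integers(bands["fatty"][0], bands["fatty"][1] + 1, size=int(fatty.sum()))
    image[glandular] = rng.integers(
        bands["glandular"][0], bands["glandular"][1] + 1, size=int(glandular.sum())
    )
    image[ligament] = rng.integers(
        bands["ligament"][0], bands["ligament"][1] + 1, size=int(ligament.sum())
    )
    return Phantom(image=image, class_name=class_name, target_fg_ratio=target, seed=seed)


def generate_phantom_ensemble(
    n: int, seed: int, size: int = IMAGE_SIZE
) -> tuple[list[np.ndarray], pd.DataFrame]:
    """n phantoms with 1:4:4:1 class allocation; per-image seeds seed + i."""
    labels = allocate_classes(n)
    images, rows = [], []
    for i, name in enumerate(labels):
        p = generate_phantom(name, seed + i, size=size)
        images.append(p.image)
        rows.append(
            {
                "index": i,
                "class": name,
                "target_fg_ratio": p.target_fg_ratio,
                "seed": seed + i,
                "broken": False,
            }
        )
    return images, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Segmentation and statistics
# ---------------------------------------------------------------------------


def _validate_bands(bands: dict) -> None:
    intervals = sorted(bands.values())
    for (lo1, hi1), (lo2, hi2) in zip(intervals, intervals[1:]):
        if lo2 <= hi1:
            raise ValueError(f"overlapping intensity bands: {(lo1, hi1)} and {(lo2, hi2)}")


def segment_tissues(image: np.ndarray, bands: dict = DEFAULT_BANDS) -> dict[str, np.ndarray]:
    """Global-threshold segmentation into per-tissue masks.

    Pixels outside every band (possible only on non-clean images) are
    assigned to the nearest band edge so the masks always partition the
    image.
    """
    _validate_bands(bands)
    image = np.asarray(image)
    names = list(bands)
    centers_lo = np.array([bands[n][0] for n in names], dtype=float)
    centers_hi = np.array([bands[n][1] for n in names], dtype=float)
    dist = np.maximum(centers_lo[:, None] - image.ravel()[None, :], 0) + np.maximum(
        image.ravel()[None, :] - centers_hi[:, None], 0
    )
    assignment = dist.argmin(axis=0).reshape(image.shape)
    return {name: assignment == i for i, name in enumerate(names)}


def fg_ratio(masks: dict[str, np.ndarray]) -> float:
    """Fatty-to-glandular pixel ratio; raises if no glandular tissue."""
    n_gland = int(masks["glandular"].sum())
    if n_gland == 0:
        raise ValueError("empty glandular mask; F/G ratio undefined")
    return float(masks["fatty"].sum()) / n_gland


def classify_by_fg_ratio(ratio: float) -> str:
    """Nearest density class for a measured F/G ratio."""
    for name, (lo, hi) in CLASS_FG_RANGES.items():
        if lo <= ratio < hi:
            return name
    return "fatty" if ratio >= CLASS_FG_RANGES["fatty"][1] else "dense"


# ---------------------------------------------------------------------------
# Ligament corruption
# ---------------------------------------------------------------------------

_BREAK_RADIUS = 8


def break_ligaments(
    image: np.ndarray,
    break_rate: float,
    seed: int,
    bands: dict = DEFAULT_BANDS,
    radius: int = _BREAK_RADIUS,
) -> tuple[np.ndarray, bool]:
    """With probability ``break_rate``, erase one ligament segment.

    A disk of ligament pixels around a random ligament point is replaced by
    the value of the nearest non-ligament pixel (local tissue intensity).
    Returns the (possibly copied) image and whether a break was applied.
    """
    if not 0.0 <= break_rate <= 1.0:
        raise ValueError("break_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if break_rate == 0.0 or rng.random() >= break_rate:
        return image, False
    return apply_ligament_break(image, rng, bands=bands, radius=radius), True


def apply_ligament_break(
    image: np.ndarray,
    rng: np.random.Generator,
    bands: dict = DEFAULT_BANDS,
    radius: int = _BREAK_RADIUS,
) -> np.ndarray:
    """Erase a disk of ligament pixels, filling with nearby tissue values."""
    image = np.asarray(image).copy()
    lig_lo, lig_hi = bands["ligament"]
    ligament = (image >= lig_lo) & (image <= lig_hi)
    ys, xs = np.where(ligament)
    if ys.size == 0:
        return image
    i = int(rng.integers(ys.size))
    cy, cx = int(ys[i]), int(xs[i])
    yy, xx = np.mgrid[0 : image.shape[0], 0 : image.shape[1]]
    disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    erase = disk & ligament
    # fill each erased pixel with its nearest tissue value (not ligament,
    # not background)
    non_tissue = ligament | (image == 0)
    _, (iy, ix) = ndimage.distance_transform_edt(non_tissue, return_indices=True)
    image[erase] = image[iy[erase], ix[erase]]
    return image
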