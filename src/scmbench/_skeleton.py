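"""Branch/junction statistics of a binary skeleton.

A skeleton is treated as an 8-connected pixel graph.  Junctions are skeleton
pixels with three or more skeleton neighbors; endpoints have exactly one.
Branches are the 8-connected components that remain after junction pixels are
removed; an isolated loop with no junctions counts as a single branch.
Branch length is measured in pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

# 3x3 kernel counting 8-neighbors (center excluded)
_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.uint8)
_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class SkeletonStats:
    n_branches: int
    n_junctions: int
    n_endpoints: int
    branch_lengths: np.ndarray = field(repr=False)
    total_length: int = 0

    @property
    def mean_branch_length(self) -> float:
        return float(np.mean(self.branch_lengths)) if self.n_branches else 0.0

    @property
    def std_branch_length(self) -> float:
        return float(np.std(self.branch_lengths)) if self.n_branches else 0.0


def neighbor_counts(skeleton: np.ndarray) -> np.ndarray:
    """Number of 8-connected skeleton neighbors for every skeleton pixel."""
    sk = skeleton.astype(np.uint8)
    counts = ndimage.convolve(sk, _NEIGHBOR_KERNEL, mode="constant", cval=0)
    return np.where(skeleton, counts, 0)


def junction_mask(skeleton: np.ndarray) -> np.ndarray:
    return neighbor_counts(skeleton) >= 3


def endpoint_mask(skeleton: np.ndarray) -> np.ndarray:
    return neighbor_counts(skeleton) == 1


def skeleton_stats(skeleton: np.ndarray) -> SkeletonStats:
    """Summarize a binary skeleton into branch/junction statistics."""
    skeleton = np.asarray(skeleton, dtype=bool)
    if not skeleton.any():
        return SkeletonStats(0, 0, 0, np.empty(0), 0)
    junctions = junction_mask(skeleton)
    endpoints = endpoint_mask(skeleton)
    # clusters of adjacent junction pixels count once
    _, n_junctions = ndimage.label(junctions, structure=_EIGHT)
    branches = skeleton & ~junctions
    labeled, n_branches = ndimage.label(branches, structure=_EIGHT)
    if n_branches:
        lengths = np.bincount(labeled.ravel())[1:].astype(float)
    else:
        lengths = np.empty(0)
    return SkeletonStats(
        n_branches=int(n_branches),
        n_junctions=int(n_junctions),
        n_endpoints=int(endpoints.sum()),
        branch_lengths=lengths,
        total_length=int(skeleton.sum()),
    )


def prune_spurs(skeleton: np.ndarray, min_length: int = 5, passes: int = 2) -> np.ndarray:
    """Remove short terminal branches (skeletonization spurs).

    A spur is a branch shorter than ``min_length`` that touches an endpoint.
    """
    sk = np.asarray(skeleton, dtype=bool).copy()
    for _ in range(passes):
        junctions = junction_mask(sk)
        endpoints = endpoint_mask(sk)
        branches = sk & ~junctions
        labeled, n = ndimage.label(branches, structure=_EIGHT)
        if n == 0:
            break
        lengths = np.bincount(labeled.ravel())[1:]
        end_labels = np.unique(labeled[endpoints & (labeled > 0)])
        removed = False
        for lab in end_labels:
            if lengths[lab - 1] < min_length:
                sk[labeled == lab] = False
                removed = True
        if not removed:
            break
    return sk
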