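"""K-means region-of-interest pretreatment.

Abdominal slices contain many irrelevant structures; clustering the gray
values, keeping the largest non-background connected region, filling its
holes and cropping to its padded bounding box shrinks the domain the
cellular automaton has to evolve over, without changing its result.

The clustering is a deterministic scalar Lloyd iteration: centres start at
the (2i+1)/(2K) intensity quantiles, each pixel is assigned to its nearest
centre (ties to the lower index), empty clusters are repaired by moving
their centre to the intensity farthest from its nearest centre, and the
sum-of-squares objective J = sum_j sum_{n in S_j} |x_n - mu_j|^2 is logged
per iteration (it is non-increasing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

__all__ = [
    "ClusterResult",
    "RoiResult",
    "kmeans_cluster",
    "extract_candidate",
    "fill_holes",
    "bounding_box",
    "crop_and_mask",
    "extract_roi",
]


@dataclass(frozen=True)
class ClusterResult:
    labels: np.ndarray          # per-pixel cluster index 0..K-1
    centers: np.ndarray         # K mean intensities
    inertia: float              # final sum-of-squares objective
    iterations: int
    inertia_trace: tuple[float, ...]


@dataclass(frozen=True)
class RoiResult:
    candidate_mask: np.ndarray  # largest non-background region
    filled_mask: np.ndarray     # candidate with holes filled
    bbox: tuple[int, int, int, int]  # half-open (r0, c0, r1, c1)
    cropped: np.ndarray         # image restricted to bbox, masked
    offset: tuple[int, int]     # (r0, c0) for re-embedding


def kmeans_cluster(
    image: np.ndarray,
    k: int = 4,
    max_iter: int = 100,
    tol: float = 1e-4,
    seed: "int | None" = None,
) -> ClusterResult:
    """Lloyd K-means on scalar intensities.

    Deterministic quantile initialisation by default; pass ``seed`` to draw
    the initial centres uniformly from the observed intensities instead.
    """
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    if k < 2:
        raise ValueError("k must be >= 2")
    x = arr.ravel()
    if seed is None:
        qs = (2.0 * np.arange(k) + 1.0) / (2.0 * k)
        centers = np.quantile(x, qs)
    else:
        rng = np.random.default_rng(seed)
        centers = rng.choice(x, size=k, replace=True).astype(np.float64)
    trace: list[float] = []
    assign = np.zeros(x.shape, dtype=np.intp)
    iterations = 0
    for iterations in range(1, max_iter + 1):
        dist = np.abs(x[:, None] - centers[None, :])
        assign = np.argmin(dist, axis=1)  # ties -> lower index
        # empty-cluster repair: move the empty centre to the intensity
        # farthest from its nearest centre, then re-assign
        for j in range(k):
            if not np.any(assign == j):
                nearest = dist.min(axis=1)
                centers[j] = x[np.argmax(nearest)]
                dist = np.abs(x[:, None] - centers[None, :])
                assign = np.argmin(dist, axis=1)
        trace.append(float(np.sum((x - centers[assign]) ** 2)))
        new_centers = centers.copy()
        for j in range(k):
            sel = assign == j
            if sel.any():
                new_centers[j] = x[sel].mean()
        move = float(np.max(np.abs(new_centers - centers)))
        centers = new_centers
        if move < tol:
            break
    inertia = float(np.sum((x - centers[assign]) ** 2))
    trace.append(inertia)
    return ClusterResult(
        labels=assign.reshape(arr.shape),
        centers=centers,
        inertia=inertia,
        iterations=iterations,
        inertia_trace=tuple(trace),
    )


def _background_cluster(labels: np.ndarray) -> int:
    """The cluster owning the majority of the image border."""
    border = np.concatenate(
        [labels[0, :], labels[-1, :], labels[1:-1, 0], labels[1:-1, -1]]
    )
    return int(np.bincount(border).argmax())


def extract_candidate(cluster: ClusterResult, image: np.ndarray) -> np.ndarray:
    """Largest 8-connected component over all non-background clusters.

    The liver generally takes up the largest area among the foreground
    structures, so the maximal region is taken as the candidate.  The
    border-dominant cluster is treated as background and excluded (the
    liver never owns the whole border).  Ties in component size break to
    the component whose first row-major pixel is smallest.
    """
    labels = cluster.labels
    bg = _background_cluster(labels)
    best_size = 0
    best_anchor: tuple[int, int] | None = None
    best_mask: np.ndarray | None = None
    for j in range(len(cluster.centers)):
        if j == bg:
            continue
        sel = labels == j
        if not sel.any():
            continue
        comp = measure.label(sel, connectivity=2)
        for region_id in range(1, comp.max() + 1):
            region = comp == region_id
            size = int(region.sum())
            rr, cc = np.nonzero(region)
            anchor = (int(rr[0]), int(cc[0]))  # first pixel in row-major order
            if size > best_size or (size == best_size and (best_anchor is None or anchor < best_anchor)):
                best_size, best_anchor, best_mask = size, anchor, region
    if best_mask is None:
        raise ValueError("all pixels belong to the background cluster")
    return best_mask.astype(np.uint8)


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill background regions not 4-connected to the image border."""
    arr = np.asarray(mask).astype(bool)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("mask must be a non-empty 2-D array")
    return ndimage.binary_fill_holes(arr).astype(np.uint8)


def bounding_box(mask: np.ndarray, pad: int = 5) -> tuple[int, int, int, int]:
    """Tight half-open box of the 1-pixels, padded and clipped to the image."""
    arr = np.asarray(mask).astype(bool)
    if pad < 0:
        raise ValueError("pad must be >= 0")
    rr, cc = np.nonzero(arr)
    if len(rr) == 0:
        raise ValueError("mask is empty")
    h, w = arr.shape
    r0 = max(int(rr.min()) - pad, 0)
    c0 = max(int(cc.min()) - pad, 0)
    r1 = min(int(rr.max()) + 1 + pad, h)
    c1 = min(int(cc.max()) + 1 + pad, w)
    return (r0, c0, r1, c1)


def crop_and_mask(
    image: np.ndarray, filled_mask: np.ndarray, bbox: tuple[int, int, int, int]
) -> RoiResult:
    """Restrict ``image`` to ``bbox`` with pixels outside the mask set to 0."""
    arr = np.asarray(image, dtype=np.float64)
    msk = np.asarray(filled_mask).astype(bool)
    if arr.shape != msk.shape:
        raise ValueError("image and mask shapes differ")
    r0, c0, r1, c1 = bbox
    h, w = arr.shape
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValueError(f"bbox {bbox} does not fit a {h}x{w} image")
    cropped = arr[r0:r1, c0:c1] * msk[r0:r1, c0:c1]
    candidate = msk.astype(np.uint8)
    return RoiResult(
        candidate_mask=candidate,
        filled_mask=candidate,
        bbox=bbox,
        cropped=cropped,
        offset=(r0, c0),
    )


def extract_roi(
    image: np.ndarray,
    k: int = 4,
    pad: int = 5,
    max_iter: int = 100,
    tol: float = 1e-4,
) -> RoiResult:
    """Full pretreatment: cluster, largest region, fill, box, masked crop."""
    cluster = kmeans_cluster(image, k=k, max_iter=max_iter, tol=tol)
    candidate = extract_candidate(cluster, image)
    filled = fill_holes(candidate)
    bbox = bounding_box(filled, pad=pad)
    result = crop_and_mask(image, filled, bbox)
    return RoiResult(
        candidate_mask=candidate,
        filled_mask=filled,
        bbox=bbox,
        cropped=result.cropped,
        offset=result.offset,
    )
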