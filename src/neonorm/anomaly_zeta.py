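"""Patch-based zeta anomaly scoring of deviation maps.

For every masked voxel, the 3×3×3 (27-voxel) patch of a subject's Z-map is
compared with the same patch drawn from a reference set of other subjects:
the references' patches are clustered per voxel with k-means (k = 8 by
default, reference size 80) and the zeta score is the Euclidean distance
from the subject's patch to the nearest cluster centroid — an outlier
magnitude index that uses neighbourhood context without smoothing the
underlying data.

A kNN variant (mean distance to the k nearest reference patches minus the
mean pairwise distance among them) is available as ``variant="knn"``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "PatchReference",
    "extract_patch",
    "extract_all_patches",
    "build_reference",
    "zeta_score",
    "zeta_map",
]

log = logging.getLogger(__name__)

PATCH_SIZE = 27
CENTER_INDEX = 13  # centre voxel of the x-fastest flattened 3x3x3 patch


@dataclass
class PatchReference:
    """Per-voxel reference structure for zeta scoring."""

    centroids: np.ndarray | None  # (V, k, 27) — centroid variant
    patches: np.ndarray | None  # (n_ref, V, 27) — kept for the kNN variant
    voxels: np.ndarray  # (V, 3) mask voxel coordinates
    n_ref: int
    k: int
    metric: str = "euclidean"
    variant: str = "centroid"


def extract_all_patches(volume, mask=None, voxels=None, edge_policy: str = "replicate"):
    """(V, 27) patches at ``voxels`` (default: all mask voxels), x-fastest order.

    Out-of-grid neighbours replicate the nearest edge voxel; out-of-mask
    neighbours are replaced per ``edge_policy``: "replicate" substitutes the
    patch's centre value, "zero" leaves them at zero.
    """
    vol = np.asarray(volume, dtype=float)
    if vol.ndim != 3:
        raise ValueError("volume must be 3-D")
    if mask is None:
        mask = np.ones(vol.shape, dtype=bool)
    if voxels is None:
        voxels = np.argwhere(mask)
    voxels = np.asarray(voxels, dtype=int)

    masked = np.where(mask, vol, 0.0)
    win = sliding_window_view(np.pad(masked, 1, mode="edge"), (3, 3, 3))
    mwin = sliding_window_view(np.pad(mask, 1, mode="edge"), (3, 3, 3))
    ix = tuple(voxels.T)
    # window axes come out (z-fastest on ravel); transpose so x varies fastest
    patches = win[ix].transpose(0, 3, 2, 1).reshape(-1, PATCH_SIZE)
    inmask = mwin[ix].transpose(0, 3, 2, 1).reshape(-1, PATCH_SIZE)
    if edge_policy == "replicate":
        centers = patches[:, CENTER_INDEX]
        patches = np.where(inmask, patches, centers[:, None])
    elif edge_policy == "zero":
        patches = np.where(inmask, patches, 0.0)
    else:
        raise ValueError(f"unknown edge_policy {edge_policy!r}")
    return patches


def extract_patch(volume, voxel, radius: int = 1, mask=None, edge_policy: str = "replicate"):
    """27-vector around one voxel (radius fixed at 1 ⇒ 3×3×3)."""
    if radius != 1:
        raise NotImplementedError("only radius-1 (27-voxel) patches are supported")
    voxel = np.asarray(voxel, dtype=int)
    if mask is not None and not mask[tuple(voxel)]:
        raise ValueError(f"voxel {tuple(voxel)} is outside the mask")
    return extract_all_patches(volume, mask=mask, voxels=voxel[None, :], edge_policy=edge_policy)[0]


def _batched_kmeans(points, k, seed, n_iter: int = 25):
    """Lloyd's algorithm run simultaneously for every voxel.

    points: (V, n, d) → centroids (V, k, d).  Seeded initialization picks k
    distinct reference patches per voxel; empty clusters are re-seeded with
    the point farthest from its assigned centroid.
    """
    V, n, d = points.shape
    rng = np.random.default_rng(seed)
    init = np.array([rng.choice(n, size=k, replace=False) for _ in range(V)])
    centroids = np.take_along_axis(points, init[:, :, None], axis=1).copy()

    assign_prev = None
    for _ in range(n_iter):
        # (V, n, k) squared distances
        d2 = ((points[:, :, None, :] - centroids[:, None, :, :]) ** 2).sum(axis=-1)
        assign = d2.argmin(axis=2)  # (V, n)
        if assign_prev is not None and np.array_equal(assign, assign_prev):
            break
        assign_prev = assign
        onehot = assign[:, :, None] == np.arange(k)[None, None, :]  # (V, n, k)
        counts = onehot.sum(axis=1)  # (V, k)
        sums = np.einsum("vnk,vnd->vkd", onehot.astype(float), points)
        nonempty = counts > 0
        centroids = np.where(
            nonempty[:, :, None], sums / np.maximum(counts, 1)[:, :, None], centroids
        )
        if not nonempty.all():
            # re-seed each empty cluster with the globally farthest point
            far = d2.min(axis=2).argmax(axis=1)  # (V,)
            for vi, ki in zip(*np.where(~nonempty)):
                centroids[vi, ki] = points[vi, far[vi]]
    return centroids


def build_reference(
    deviation_maps,
    mask,
    n_ref: int = 80,
    k: int = 8,
    seed: int = 0,
    variant: str = "centroid",
    edge_policy: str = "replicate",
) -> PatchReference:
    """Sample ``n_ref`` reference maps and cluster their patches per voxel.

    ``deviation_maps`` is a sequence of single-channel Z volumes from other
    subjects (the subject being scored must not be among them).  ``n_ref``
    and ``k`` are clamped, with a warning, when fewer maps are available.
    """
    maps = [np.asarray(m, dtype=float) for m in deviation_maps]
    if not maps:
        raise ValueError("no reference maps supplied")
    mask = np.asarray(mask, dtype=bool)
    rng = np.random.default_rng(seed)
    if n_ref > len(maps):
        warnings.warn(f"n_ref={n_ref} clamped to {len(maps)} available reference maps")
        n_ref = len(maps)
    chosen = rng.choice(len(maps), size=n_ref, replace=False)
    if k > n_ref:
        warnings.warn(f"k={k} clamped to n_ref={n_ref}")
        k = n_ref

    voxels = np.argwhere(mask)
    patches = np.stack(
        [extract_all_patches(maps[i], mask=mask, voxels=voxels, edge_policy=edge_policy)
         for i in chosen]
    )  # (n_ref, V, 27)

    centroids = None
    if variant == "centroid":
        centroids = _batched_kmeans(patches.transpose(1, 0, 2), k, seed=rng.integers(2**31))
    elif variant != "knn":
        raise ValueError(f"unknown zeta variant {variant!r}")
    return PatchReference(
        centroids=centroids,
        patches=patches if variant == "knn" else None,
        voxels=voxels,
        n_ref=n_ref,
        k=k,
        variant=variant,
    )


def zeta_score(patch, reference: PatchReference, voxel_pos: int) -> float:
    """Distance from one patch to the reference at mask-voxel ordinal ``voxel_pos``."""
    patch = np.asarray(patch, dtype=float)
    if reference.variant == "centroid":
        d = np.linalg.norm(reference.centroids[voxel_pos] - patch[None, :], axis=1)
        return float(d.min())
    return float(_knn_zeta(patch[None, :], reference.patches[:, voxel_pos, :], reference.k)[0])


def _knn_zeta(patches, ref_patches, k):
    """kNN zeta: mean distance to the k nearest reference patches minus the
    mean pairwise distance among those k neighbours."""
    d = np.linalg.norm(ref_patches[None, :, :] - patches[:, None, :], axis=2)  # (q, n_ref)
    nn = np.argsort(d, axis=1)[:, :k]
    dist_to = np.take_along_axis(d, nn, axis=1).mean(axis=1)
    out = np.empty(len(patches))
    for i in range(len(patches)):
        sel = ref_patches[nn[i]]
        pd = np.linalg.norm(sel[:, None, :] - sel[None, :, :], axis=2)
        within = pd.sum() / (k * (k - 1)) if k > 1 else 0.0
        out[i] = dist_to[i] - within
    return out


def zeta_map(
    deviation_map,
    reference_maps,
    mask,
    k: int = 8,
    n_ref: int = 80,
    seed: int = 0,
    variant: str = "centroid",
    edge_policy: str = "replicate",
    reference: PatchReference | None = None,
) -> np.ndarray:
    """Zeta score at every mask voxel of a single-channel Z volume.

    Builds (or reuses) the per-voxel patch reference from ``reference_maps``
    and scores the subject's patches against it.  Output is 0 outside the
    mask and non-negative inside (the kNN variant is clipped at 0).
    """
    mask = np.asarray(mask, dtype=bool)
    if reference is None:
        reference = build_reference(
            reference_maps, mask, n_ref=n_ref, k=k, seed=seed,
            variant=variant, edge_policy=edge_policy,
        )
    patches = extract_all_patches(
        deviation_map, mask=mask, voxels=reference.voxels, edge_policy=edge_policy
    )  # (V, 27)
    if reference.variant == "centroid":
        d2 = ((reference.centroids - patches[:, None, :]) ** 2).sum(axis=-1)  # (V, k)
        scores = np.sqrt(d2.min(axis=1))
    else:
        V = len(patches)
        scores = np.empty(V)
        for v in range(V):
            scores[v] = _knn_zeta(patches[v : v + 1], reference.patches[:, v, :], reference.k)[0]
        np.maximum(scores, 0.0, out=scores)
    out = np.zeros(mask.shape)
    out[tuple(reference.voxels.T)] = scores
    return out
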