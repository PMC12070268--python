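"""Source-peak identification: atlas masking, top-percentile
thresholding and DBSCAN clustering of contrast maps.

The stage runs in a fixed order — mask reserved atlas regions first,
then threshold to the top q% of contrast values, then density-cluster
the retained voxel coordinates — because thresholding a masked map and
masking a thresholded map generally retain different voxels.
"""
from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import DBSCAN

from .synthgen import RESERVED_LABELS, SourceModel


@dataclass
class VoxelCluster:
    voxels: np.ndarray                       # global voxel indices
    centroid_mm: np.ndarray
    label_counts: dict[str, int] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.voxels)

    @property
    def dominant_label(self) -> str | None:
        if not self.label_counts:
            return None
        return max(self.label_counts.items(), key=lambda kv: (kv[1], kv[0]))[0]


@dataclass
class VoxelClusterSet:
    clusters: list[VoxelCluster]
    eps_mm: float
    min_voxels: int

    def __len__(self) -> int:
        return len(self.clusters)

    def to_records(self) -> list[dict]:
        return [
            dict(size=c.size, centroid_mm=c.centroid_mm.tolist(),
                 dominant_label=c.dominant_label, label_counts=dict(c.label_counts))
            for c in self.clusters
        ]


def mask_by_atlas(
    values: np.ndarray,
    labels: np.ndarray,
    reserved: tuple[str, ...] = RESERVED_LABELS,
) -> np.ndarray:
    """Indices of voxels whose atlas label is not reserved
    (non-labelled / cerebellar voxels are excluded)."""
    values = np.asarray(values)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels must align")
    keep = ~np.isin(labels, list(reserved))
    if not keep.any():
        warnings.warn("atlas mask removed every voxel", stacklevel=2)
    return np.flatnonzero(keep)


def top_percent_threshold(
    values: np.ndarray,
    q: float = 1.0,
    direction: str = "positive",
) -> np.ndarray:
    """Indices of the ceil(q*N/100) most extreme voxels.

    ``direction`` selects the ranking key: "positive"/"negative" rank
    signed values toward the corresponding tail (matching the sign of
    the cluster under study), "absolute" ranks |value|.  Ties are
    broken by voxel index for determinism.  NaN voxels are never
    retained.
    """
    values = np.asarray(values, float)
    if values.size == 0:
        raise ValueError("empty contrast map")
    if not 0 < q <= 100:
        raise ValueError("percentage q must be in (0, 100]")
    if direction == "positive":
        key = -values
    elif direction == "negative":
        key = values
    elif direction == "absolute":
        key = -np.abs(values)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    key = np.where(np.isnan(key), np.inf, key)
    k = math.ceil(q * values.size / 100.0)
    order = np.lexsort((np.arange(values.size), key))
    return np.sort(order[:k])


def dbscan_voxels(
    positions_mm: np.ndarray,
    eps_mm: float,
    min_pts: int = 5,
    voxel_indices: np.ndarray | None = None,
) -> VoxelClusterSet:
    """Euclidean DBSCAN on voxel coordinates (standard core/border/noise
    semantics; ``min_pts`` counts the voxel itself).  Noise voxels are
    discarded; every returned cluster has at least ``min_pts`` members."""
    if eps_mm <= 0 or min_pts < 1:
        raise ValueError("eps must be positive and min_pts >= 1")
    positions_mm = np.asarray(positions_mm, float)
    if voxel_indices is None:
        voxel_indices = np.arange(len(positions_mm))
    clusters: list[VoxelCluster] = []
    if len(positions_mm):
        assignment = DBSCAN(eps=eps_mm, min_samples=min_pts).fit_predict(positions_mm)
        for cid in sorted(set(assignment) - {-1}):
            local = np.flatnonzero(assignment == cid)
            clusters.append(
                VoxelCluster(
                    voxels=np.asarray(voxel_indices)[local],
                    centroid_mm=positions_mm[local].mean(axis=0),
                )
            )
    clusters.sort(key=lambda c: -c.size)
    return VoxelClusterSet(clusters=clusters, eps_mm=eps_mm, min_voxels=min_pts)


def label_clusters(cluster_set: VoxelClusterSet, labels: np.ndarray) -> VoxelClusterSet:
    """Attach per-cluster atlas label histograms (labels indexed by
    global voxel index)."""
    labels = np.asarray(labels)
    for c in cluster_set.clusters:
        c.label_counts = dict(Counter(labels[c.voxels]))
    return cluster_set


def localize_peaks(
    model: SourceModel,
    contrast_values: np.ndarray,
    q: float = 1.0,
    eps_mult: float = 1.5,
    min_voxels: int = 5,
    direction: str = "positive",
) -> VoxelClusterSet:
    """Full localisation chain on an (unmasked) source contrast map:
    atlas masking, top-q% thresholding, DBSCAN with a search radius of
    ``eps_mult`` grid steps, and atlas labelling."""
    kept = mask_by_atlas(contrast_values, model.labels)
    if kept.size == 0:
        return VoxelClusterSet(clusters=[], eps_mm=eps_mult * model.spacing_mm,
                               min_voxels=min_voxels)
    top_local = top_percent_threshold(np.asarray(contrast_values, float)[kept],
                                      q=q, direction=direction)
    top = kept[top_local]
    out = dbscan_voxels(model.positions[top], eps_mm=eps_mult * model.spacing_mm,
                        min_pts=min_voxels, voxel_indices=top)
    return label_clusters(out, model.labels)
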