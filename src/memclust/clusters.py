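"""Cluster identification and descriptors for membrane point patterns.

Clusters are called with a deterministic density-based rule (DBSCAN-style
connectivity under the toroidal metric): molecules with at least
``min_neighbors`` others within ``linking_radius`` are *core* points;
core points within ``linking_radius`` of each other belong to the same
cluster; non-core molecules within ``linking_radius`` of a core join the
cluster of their nearest core.  Components smaller than ``min_size``
are relabelled noise.  Defaults (linking_radius = 50 nm,
min_neighbors = 5, min_size = 5) are tuned to SMLM-scale nanoclusters
on the reference 2000-molecule patch, where the CSR background yields
fewer than two neighbours within 50 nm on average.

Four descriptors summarise a labelled pattern: number of clusters,
percentage of molecules in clusters, mean molecules per cluster, and
mean cluster radius.  The default radius statistic is the per-axis
standard deviation of the members about the cluster centroid (the
sigma of the isotropic Gaussian with the same spread, the scale SMLM
cluster engines report); the equivalent-uniform-disc radius
(sqrt(2) x RMS distance to centroid, exactly twice sigma) is available
as an alternative.  Centroids use wrap-aware circular averaging so
seam-straddling clusters are handled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .geometry import Box, PointPattern

__all__ = [
    "ClusterReport",
    "call_clusters",
    "cluster_radius",
    "toroidal_centroid",
    "descriptor_report",
    "analyze_pattern",
    "NOISE",
]

#: Label assigned to unclustered molecules.
NOISE = -1


def _periodic_tree(pattern: PointPattern) -> cKDTree:
    return cKDTree(pattern.positions, boxsize=[pattern.box.width, pattern.box.height])


def call_clusters(
    pattern: PointPattern,
    linking_radius: float = 50.0,
    min_neighbors: int = 5,
    min_size: int = 5,
) -> np.ndarray:
    """Density-based cluster labels (NOISE = -1) under the toroidal metric.

    ``min_neighbors`` counts other molecules (self excluded), matching
    the neighbour-count convention used for density measurements.
    """
    if linking_radius >= pattern.box.min_dimension / 2:
        raise ValueError(
            f"linking radius {linking_radius} must be below half the smallest "
            f"box dimension ({pattern.box.min_dimension / 2})"
        )
    n = pattern.n
    labels = np.full(n, NOISE, dtype=np.int64)
    if n < max(min_size, 1):
        return labels
    tree = _periodic_tree(pattern)
    pairs = tree.query_pairs(r=linking_radius, output_type="ndarray")
    counts = np.zeros(n, dtype=np.int64)
    if pairs.size:
        np.add.at(counts, pairs[:, 0], 1)
        np.add.at(counts, pairs[:, 1], 1)
    core = counts >= min_neighbors
    if not core.any():
        return labels
    core_idx = np.flatnonzero(core)
    # Connected components of the core-core linkage graph.
    if pairs.size:
        cc_mask = core[pairs[:, 0]] & core[pairs[:, 1]]
        cp = pairs[cc_mask]
    else:
        cp = np.empty((0, 2), dtype=np.int64)
    remap = np.full(n, -1, dtype=np.int64)
    remap[core_idx] = np.arange(core_idx.size)
    graph = coo_matrix(
        (np.ones(cp.shape[0]), (remap[cp[:, 0]], remap[cp[:, 1]])),
        shape=(core_idx.size, core_idx.size),
    )
    _, comp = connected_components(graph, directed=False)
    labels[core_idx] = comp
    # Border molecules join the cluster of their nearest core within reach.
    border_idx = np.flatnonzero(~core)
    if border_idx.size:
        core_tree = cKDTree(
            pattern.positions[core_idx], boxsize=[pattern.box.width, pattern.box.height]
        )
        dist, nearest = core_tree.query(
            pattern.positions[border_idx], k=1, distance_upper_bound=linking_radius * (1 + 1e-12)
        )
        reach = np.isfinite(dist)
        labels[border_idx[reach]] = comp[nearest[reach]]
    # Drop undersized components and compact the label range.
    ids, sizes = np.unique(labels[labels >= 0], return_counts=True)
    keep = ids[sizes >= min_size]
    lut = np.full(comp.max() + 1, NOISE, dtype=np.int64)
    lut[keep] = np.arange(keep.size)
    clustered = labels >= 0
    labels[clustered] = lut[labels[clustered]]
    return labels


def toroidal_centroid(positions: np.ndarray, box: Box) -> np.ndarray:
    """Wrap-aware centroid via the circular mean of each axis."""
    pos = np.asarray(positions, dtype=np.float64)
    out = np.empty(2)
    for ax, dim in enumerate((box.width, box.height)):
        theta = pos[:, ax] * (2.0 * math.pi / dim)
        ang = math.atan2(np.mean(np.sin(theta)), np.mean(np.cos(theta)))
        out[ax] = (ang * dim / (2.0 * math.pi)) % dim
    return out


def cluster_radius(positions: np.ndarray, box: Box, kind: str = "sigma") -> float:
    """Radius statistic of a cluster from its members (toroidal metric).

    ``kind="sigma"`` (default) is the per-axis standard deviation about
    the wrap-aware centroid, i.e. RMS distance / sqrt(2): the sigma of
    an isotropic Gaussian blob, and half the radius of a uniform disc.
    ``kind="disc"`` is the equivalent-uniform-disc radius,
    sqrt(2) x RMS distance (2 sigma for a Gaussian blob, the disc
    radius for uniform members).
    """
    pos = np.asarray(positions, dtype=np.float64)
    if pos.shape[0] < 2:
        raise ValueError("cluster radius needs at least two members")
    c = toroidal_centroid(pos, box)
    d = pos - c
    dims = np.array([box.width, box.height])
    d -= dims * np.round(d / dims)
    rms = math.sqrt(float(np.mean(d[:, 0] ** 2 + d[:, 1] ** 2)))
    if kind == "sigma":
        return rms / math.sqrt(2.0)
    if kind == "disc":
        return math.sqrt(2.0) * rms
    raise ValueError(f"unknown radius kind {kind!r}")


@dataclass(frozen=True)
class ClusterReport:
    """Descriptors of one labelled pattern (the per-ROI summary)."""

    labels: np.ndarray
    n_clusters: int
    pct_clustered: float
    mean_molecules_per_cluster: Optional[float]
    mean_cluster_radius: Optional[float]
    per_cluster: pd.DataFrame


def descriptor_report(
    pattern: PointPattern, labels: np.ndarray, radius_kind: str = "sigma"
) -> ClusterReport:
    """Per-ROI descriptors: cluster count, % clustered, size and radius means."""
    labels = np.asarray(labels)
    if labels.shape[0] != pattern.n:
        raise ValueError("labels must have one entry per molecule")
    ids = np.unique(labels[labels != NOISE])
    rows = []
    for cid in ids:
        members = pattern.positions[labels == cid]
        centroid = toroidal_centroid(members, pattern.box)
        rows.append(
            {
                "cluster_id": int(cid),
                "size": int(members.shape[0]),
                "centroid_x_nm": centroid[0],
                "centroid_y_nm": centroid[1],
                "radius_nm": cluster_radius(members, pattern.box, kind=radius_kind)
                if members.shape[0] >= 2
                else np.nan,
            }
        )
    per_cluster = pd.DataFrame(
        rows, columns=["cluster_id", "size", "centroid_x_nm", "centroid_y_nm", "radius_nm"]
    )
    n_clusters = len(ids)
    pct = 100.0 * float((labels != NOISE).sum()) / pattern.n if pattern.n else 0.0
    return ClusterReport(
        labels=labels,
        n_clusters=n_clusters,
        pct_clustered=pct,
        mean_molecules_per_cluster=float(per_cluster["size"].mean()) if n_clusters else None,
        mean_cluster_radius=float(per_cluster["radius_nm"].mean()) if n_clusters else None,
        per_cluster=per_cluster,
    )


def analyze_pattern(
    pattern: PointPattern,
    linking_radius: float = 50.0,
    min_neighbors: int = 5,
    min_size: int = 5,
    radius_kind: str = "sigma",
) -> ClusterReport:
    """Call clusters and summarise descriptors in one step."""
    labels = call_clusters(pattern, linking_radius, min_neighbors, min_size)
    return descriptor_report(pattern, labels, radius_kind=radius_kind)
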