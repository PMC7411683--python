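"""Extraction of a clean single-pig cloud from raw two-view captures.

The chain mirrors a standard depth-camera foreground pipeline: background
difference on the depth image, pass-through filtering, voxel-grid
downsampling, dynamic outlier removal, Euclidean clustering (largest
cluster = the animal) and finally an automated density-based trim of the
ragged occlusion boundaries left by railings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .types import (DepthFrame, DegenerateGeometryError, InvalidInputError,
                    PipelineConfig, PointCloud)

log = logging.getLogger("girthkit")

__all__ = [
    "ClusterSet",
    "background_difference",
    "passthrough_filter",
    "voxel_downsample",
    "remove_outliers_dynamic",
    "euclidean_cluster",
    "boundary_trim",
    "extract_pig",
]

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass
class ClusterSet:
    """Disjoint index groups over a parent cloud, largest first."""

    clusters: list

    def __post_init__(self) -> None:
        sizes = [len(c) for c in self.clusters]
        if sizes != sorted(sizes, reverse=True):
            order = np.argsort([-s for s in sizes], kind="stable")
            self.clusters = [self.clusters[i] for i in order]

    def __len__(self) -> int:
        return len(self.clusters)

    def largest(self) -> np.ndarray:
        if not self.clusters:
            raise DegenerateGeometryError("no clusters")
        return self.clusters[0]


def background_difference(frame: DepthFrame, background: DepthFrame,
                          diff_threshold: float = 80.0) -> DepthFrame:
    """Keep pixels whose depth differs from the empty-scene frame.

    ``diff_threshold`` is in millimeters. Output depth equals the frame
    depth where ``|frame - background| > threshold`` and the frame pixel
    is valid; elsewhere 0.
    """
    if frame.depth.shape != background.depth.shape:
        raise InvalidInputError("frame/background shape mismatch")
    if frame.view_label != background.view_label:
        raise InvalidInputError("frame/background view mismatch")
    keep = (np.abs(frame.depth - background.depth) > diff_threshold) & (frame.depth > 0)
    out = np.where(keep, frame.depth, 0.0)
    log.debug("background_difference[%s]: %d -> %d valid pixels",
              frame.view_label, int((frame.depth > 0).sum()), int(keep.sum()))
    return DepthFrame(out, fx=frame.fx, fy=frame.fy, cx=frame.cx, cy=frame.cy,
                      view_label=frame.view_label, timestamp=frame.timestamp)


def passthrough_filter(cloud: PointCloud, axis: str, lo: float, hi: float) -> PointCloud:
    """Retain points whose ``axis`` coordinate lies in [lo, hi] (order kept)."""
    if lo > hi:
        raise InvalidInputError("passthrough: lo > hi")
    coords = cloud.points[:, _AXES[axis]]
    return cloud.select((coords >= lo) & (coords <= hi))


def voxel_downsample(cloud: PointCloud, voxel_size: float) -> PointCloud:
    """Replace the points of each occupied voxel by their centroid."""
    if voxel_size <= 0:
        raise InvalidInputError("voxel_size must be positive")
    if len(cloud) == 0:
        return cloud
    keys = np.floor(cloud.points / voxel_size).astype(np.int64)
    _, inv, counts = np.unique(keys, axis=0, return_inverse=True, return_counts=True)
    sums = np.zeros((counts.shape[0], 3))
    np.add.at(sums, inv, cloud.points)
    out = PointCloud(sums / counts[:, None], frame_label=cloud.frame_label)
    log.debug("voxel_downsample(%.4f): %d -> %d points", voxel_size, len(cloud), len(out))
    return out


def remove_outliers_dynamic(cloud: PointCloud, k: int = 8,
                            alpha: float = 2.0) -> PointCloud:
    """Drop points whose mean k-NN distance exceeds ``mu + alpha*sigma``.

    The threshold is recomputed from the cloud itself each call, so it
    adapts to the sampling density ("dynamic" neighbourhood average
    distance thresholding).
    """
    if k < 1:
        raise InvalidInputError("k must be >= 1")
    if len(cloud) <= k:
        log.warning("remove_outliers_dynamic: cloud smaller than k+1, returned unchanged")
        return cloud
    tree = cKDTree(cloud.points)
    dists, _ = tree.query(cloud.points, k=k + 1)
    mean_d = dists[:, 1:].mean(axis=1)
    thresh = mean_d.mean() + alpha * mean_d.std()
    keep = mean_d <= thresh
    log.debug("remove_outliers_dynamic(k=%d, alpha=%.2f): removed %d/%d",
              k, alpha, int((~keep).sum()), len(cloud))
    return cloud.select(keep)


def euclidean_cluster(cloud: PointCloud, tolerance: float,
                      min_size: int = 1) -> ClusterSet:
    """Connected components of the ``distance <= tolerance`` graph."""
    if tolerance <= 0:
        raise InvalidInputError("tolerance must be positive")
    n = len(cloud)
    if n == 0:
        return ClusterSet([])
    tree = cKDTree(cloud.points)
    pairs = tree.query_pairs(tolerance, output_type="ndarray")
    graph = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
                       shape=(n, n))
    n_comp, labels = connected_components(graph, directed=False)
    groups = [np.flatnonzero(labels == c) for c in range(n_comp)]
    groups = [g for g in groups if len(g) >= min_size]
    cs = ClusterSet(groups)
    log.debug("euclidean_cluster(tol=%.3f): %d clusters (largest %d)",
              tolerance, len(cs), len(cs.largest()) if len(cs) else 0)
    return cs


def boundary_trim(cloud: PointCloud, voxel_size: float,
                  fraction: float = 0.3) -> PointCloud:
    """Automated replacement for manual occlusion-boundary cleanup.

    Points whose neighbour count within radius ``2 * voxel_size`` falls
    below ``fraction`` of the cloud median are dropped; this trims the
    ragged low-density fringes that railings leave on the flank. Set
    ``fraction = 0`` to disable.
    """
    if fraction <= 0 or len(cloud) == 0:
        return cloud
    tree = cKDTree(cloud.points)
    counts = np.array(tree.query_ball_point(cloud.points, 2 * voxel_size,
                                            return_length=True))
    keep = counts >= fraction * np.median(counts)
    log.debug("boundary_trim: removed %d/%d fringe points",
              int((~keep).sum()), len(cloud))
    return cloud.select(keep)


def _clean_view(cloud: PointCloud, cfg: PipelineConfig,
                passthrough: dict | None) -> PointCloud:
    if passthrough:
        for axis, (lo, hi) in passthrough.items():
            cloud = passthrough_filter(cloud, axis, lo, hi)
    cloud = voxel_downsample(cloud, cfg.voxel_size)
    cloud = remove_outliers_dynamic(cloud, cfg.outlier_k, cfg.outlier_alpha)
    if len(cloud) == 0:
        raise DegenerateGeometryError("no points survive filtering")
    clusters = euclidean_cluster(cloud, cfg.cluster_tolerance, cfg.cluster_min_size)
    if len(clusters) == 0:
        raise DegenerateGeometryError("no pig-sized cluster found")
    pig = cloud.select(clusters.largest())
    return boundary_trim(pig, cfg.voxel_size, cfg.boundary_trim_fraction)


def extract_pig(raw_top: PointCloud, raw_side: PointCloud, cfg: PipelineConfig,
                passthrough_top: dict | None = None,
                passthrough_side: dict | None = None) -> tuple[PointCloud, PointCloud]:
    """Run the per-view cleaning chain and return (top pig, side pig).

    ``passthrough_*`` map axis name to (lo, hi) in meters; they are
    rig-specific and default to no cropping.
    """
    if len(raw_top) == 0 or len(raw_side) == 0:
        raise InvalidInputError("empty input cloud")
    top = _clean_view(raw_top, cfg, passthrough_top)
    side = _clean_view(raw_side, cfg, passthrough_side)
    log.info("extract_pig: top %d -> %d, side %d -> %d points",
             len(raw_top), len(top), len(raw_side), len(side))
    return top, side
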