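"""Registration-region extraction from the two sensor views.

The side view contributes the region to be registered, P: the dorsal
quarter of the cloud (the pig's back band, which is the only part of the
side silhouette guaranteed to reappear in the top view) plus the M
highest-curvature points (ears and tail, whose curvature is far above
the back's). The top view contributes the target region Q: the half of
the back facing the side sensor, split per body third (hip/trunk/head)
so a bent animal still splits along its local axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import measure

from .types import (DegenerateGeometryError, InvalidInputError,
                    PipelineConfig, PointCloud)

log = logging.getLogger("girthkit")

__all__ = [
    "Contour2D",
    "RegistrationRegions",
    "extract_contour",
    "back_profile",
    "curvature_pca",
    "ear_tail_region",
    "split_top_view",
    "build_regions",
]

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass
class Contour2D:
    """Ordered boundary polyline in a named projection plane.

    ``vertices`` is (N, 2) in the coordinates of ``plane`` (an axis pair
    such as ``"zx"``: first letter = first column).
    """

    vertices: np.ndarray
    plane: str
    closed: bool = True

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if self.closed and v.shape[0] < 3:
            raise DegenerateGeometryError("closed contour needs >= 3 vertices")
        keep = np.ones(len(v), dtype=bool)
        keep[1:] = np.any(np.diff(v, axis=0) != 0, axis=1)
        self.vertices = v[keep]

    def __len__(self) -> int:
        return len(self.vertices)


@dataclass
class RegistrationRegions:
    """Source region P (side view) and target region Q (top view)."""

    source_P: PointCloud
    target_Q: PointCloud
    source_mask: np.ndarray   # provenance: P indices into the side cloud
    target_mask: np.ndarray   # provenance: Q indices into the top cloud


def extract_contour(cloud: PointCloud, plane: str = "zx",
                    cell: float = 0.01) -> Contour2D:
    """Outer silhouette of the cloud projected onto an axis pair.

    The projection is rasterized to an occupancy grid at ``cell``
    resolution, morphologically closed by one cell, and the largest
    outer boundary is traced; vertices are returned at cell centers.
    """
    if len(cloud) == 0:
        raise DegenerateGeometryError("empty cloud")
    cols = [_AXES[c] for c in plane]
    pts2 = cloud.points[:, cols]
    origin = pts2.min(axis=0)
    ij = np.floor((pts2 - origin) / cell).astype(int)
    shape = ij.max(axis=0) + 1
    if np.prod(shape) < 3 or (ij[:, 0] == ij[0, 0]).all() or (ij[:, 1] == ij[0, 1]).all():
        raise DegenerateGeometryError("projection collapses to fewer than 3 cells")
    grid = np.zeros(shape, dtype=bool)
    grid[ij[:, 0], ij[:, 1]] = True
    grid = ndimage.binary_closing(grid, structure=np.ones((3, 3)))
    padded = np.pad(grid, 1)
    contours = measure.find_contours(padded.astype(float), 0.5)
    if not contours:
        raise DegenerateGeometryError("no boundary found")
    boundary = max(contours, key=len)
    verts = (boundary - 1.0) * cell + origin + 0.5 * cell
    return Contour2D(verts, plane=plane, closed=True)


def back_profile(side_cloud: PointCloud) -> PointCloud:
    """Dorsal quarter of the side view.

    In the side sensor's image frame y grows downward, so the back band
    is the low-y quarter: y in [y_min, y_min + (y_max - y_min) / 4].
    """
    mask = back_profile_mask(side_cloud)
    return side_cloud.select(mask)


def back_profile_mask(side_cloud: PointCloud) -> np.ndarray:
    if len(side_cloud) == 0:
        raise DegenerateGeometryError("empty side cloud")
    y = side_cloud.points[:, 1]
    y_min, y_max = y.min(), y.max()
    if y_max == y_min:
        raise DegenerateGeometryError("side cloud has zero y extent")
    return y <= y_min + 0.25 * (y_max - y_min)


def curvature_pca(cloud: PointCloud, k: int = 16) -> PointCloud:
    """Surface-variation curvature from local PCA.

    For each point, the covariance of its k-neighborhood is
    eigen-decomposed; curvature is ``lambda_min / (l1 + l2 + l3)``
    (in [0, 1/3]; 0 on a perfect plane, largest on thin protrusions).
    """
    if k < 4:
        raise InvalidInputError("curvature k must be >= 4")
    n = len(cloud)
    if n <= k:
        raise InvalidInputError("cloud must have more than k points")
    tree = cKDTree(cloud.points)
    _, idx = tree.query(cloud.points, k=k + 1)
    nbrs = cloud.points[idx]                     # (n, k+1, 3)
    centered = nbrs - nbrs.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered) / (k + 1)
    eig = np.linalg.eigvalsh(cov)                # ascending
    total = eig.sum(axis=1)
    curv = np.where(total > 0, eig[:, 0] / np.maximum(total, 1e-300), 0.0)
    return PointCloud(cloud.points, curvature=curv, frame_label=cloud.frame_label)


def ear_tail_region(side_cloud: PointCloud, M: int = 500) -> PointCloud:
    """The M highest-curvature points (ears/tail), stable input order on ties."""
    return side_cloud.select(ear_tail_mask(side_cloud, M))


def ear_tail_mask(side_cloud: PointCloud, M: int = 500) -> np.ndarray:
    if side_cloud.curvature is None:
        raise InvalidInputError("curvature not computed; run curvature_pca first")
    n = len(side_cloud)
    if M > n:
        log.warning("ear_tail_region: M=%d > N=%d, clipped", M, n)
        M = n
    # stable ordering: sort by (-curvature, original index)
    order = np.lexsort((np.arange(n), -side_cloud.curvature))
    mask = np.zeros(n, dtype=bool)
    mask[order[:M]] = True
    return mask


def _principal_axis_2d(pts2: np.ndarray) -> np.ndarray:
    c = pts2 - pts2.mean(axis=0)
    _, vecs = np.linalg.eigh(c.T @ c)
    u = vecs[:, -1]
    # deterministic sign: largest-magnitude component positive
    if u[np.argmax(np.abs(u))] < 0:
        u = -u
    return u


def split_top_view(top_cloud: PointCloud, side_label: str = "right",
                   n_segments: int = 3) -> PointCloud:
    """Half of the top view on the side sensor's side of the body axis.

    The cloud is cut into ``n_segments`` equal-length segments along its
    first principal axis (hip / trunk / head); each segment's own central
    axis is fit in the ground-plane projection, and points on the
    requested side of that local axis are kept. The per-segment axes make
    the split follow a slightly bent spine.
    """
    return top_cloud.select(split_top_view_mask(top_cloud, side_label, n_segments))


def split_top_view_mask(top_cloud: PointCloud, side_label: str = "right",
                        n_segments: int = 3) -> np.ndarray:
    if side_label not in ("left", "right"):
        raise InvalidInputError("side_label must be 'left' or 'right'")
    if len(top_cloud) == 0:
        raise DegenerateGeometryError("empty top cloud")
    # ground-plane projection in the top sensor frame = image plane (x, y)
    pts2 = top_cloud.points[:, :2]
    u = _principal_axis_2d(pts2)
    t = (pts2 - pts2.mean(axis=0)) @ u
    edges = np.linspace(t.min(), t.max() + 1e-12, n_segments + 1)
    mask = np.zeros(len(top_cloud), dtype=bool)
    for i in range(n_segments):
        seg = (t >= edges[i]) & (t < edges[i + 1])
        if seg.sum() < 10:
            log.warning("split_top_view: segment %d too sparse, using global axis", i)
            u_seg, c_seg = u, pts2.mean(axis=0)
        else:
            u_seg = _principal_axis_2d(pts2[seg])
            if u_seg @ u < 0:
                u_seg = -u_seg
            c_seg = pts2[seg].mean(axis=0)
        v = np.array([-u_seg[1], u_seg[0]])
        side = (pts2 - c_seg) @ v
        mask |= seg & (side > 0 if side_label == "right" else side < 0)
    return mask


def build_regions(side_cloud: PointCloud, top_cloud: PointCloud,
                  cfg: PipelineConfig | None = None) -> RegistrationRegions:
    """Assemble P (back profile + ear/tail) and Q (matched top half)."""
    cfg = cfg or PipelineConfig()
    side_c = (side_cloud if side_cloud.curvature is not None
              else curvature_pca(side_cloud, cfg.curvature_k))
    p_mask = back_profile_mask(side_c) | ear_tail_mask(side_c, cfg.M)
    q_mask = split_top_view_mask(top_cloud, cfg.side_label)
    if not p_mask.any() or not q_mask.any():
        raise DegenerateGeometryError("registration region extraction failed")
    log.info("build_regions: |P| = %d / %d side, |Q| = %d / %d top",
             int(p_mask.sum()), len(side_c), int(q_mask.sum()), len(top_cloud))
    return RegistrationRegions(source_P=side_c.select(p_mask),
                               target_Q=top_cloud.select(q_mask),
                               source_mask=np.flatnonzero(p_mask),
                               target_mask=np.flatnonzero(q_mask))
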