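"""Core data containers shared across the measurement pipeline.

All internal geometry is expressed in meters. Depth sensors report
millimeters and the reported heart girth is in centimeters; unit
conversion happens only at I/O boundaries (see :mod:`girthkit.io`) and
when formatting results.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Optional

import numpy as np

__all__ = [
    "GirthKitError",
    "InvalidInputError",
    "DegenerateGeometryError",
    "RegistrationError",
    "MeasurementError",
    "DepthFrame",
    "PointCloud",
    "RigidTransform",
    "PipelineConfig",
]


class GirthKitError(Exception):
    """Base class for pipeline failures."""


class InvalidInputError(GirthKitError):
    """Malformed input: shape mismatch, non-finite intrinsics, bad ranges."""


class DegenerateGeometryError(GirthKitError):
    """Geometry too degenerate to proceed (collinear cloud, empty contour...)."""


class RegistrationError(GirthKitError):
    """Coarse or fine registration failed."""


class MeasurementError(GirthKitError):
    """Girth measurement failed (sparse slice, unreachable anchor...)."""


@dataclass
class DepthFrame:
    """Single-channel range image from one sensor.

    ``depth`` is a (height, width) float array in millimeters; 0 marks an
    invalid pixel.  ``fx, fy, cx, cy`` are pinhole intrinsics in pixels.
    ``timestamp`` is an arbitrary monotone tag used for cross-view frame
    pairing.
    """

    depth: np.ndarray
    fx: float
    fy: float
    cx: float
    cy: float
    view_label: str = "top"
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.ndim != 2:
            raise InvalidInputError("depth must be a 2-D array")
        if not np.all(np.isfinite([self.fx, self.fy, self.cx, self.cy])):
            raise InvalidInputError("non-finite intrinsics")
        if self.fx <= 0 or self.fy <= 0:
            raise InvalidInputError("focal lengths must be positive")
        h, w = self.depth.shape
        if not (0 <= self.cx < w and 0 <= self.cy < h):
            raise InvalidInputError("principal point outside image")
        if np.any(self.depth < 0):
            raise InvalidInputError("negative depth values")

    @property
    def width(self) -> int:
        return self.depth.shape[1]

    @property
    def height(self) -> int:
        return self.depth.shape[0]


@dataclass
class PointCloud:
    """Unordered 3-D point set in meters, with optional per-point curvature.

    ``frame_label`` records the coordinate frame the points live in
    (``sensor_top``, ``sensor_side``, ``registered``, ``normalized``).
    """

    points: np.ndarray
    curvature: Optional[np.ndarray] = None
    frame_label: str = "sensor_top"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.size == 0:
            pts = pts.reshape(0, 3)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise InvalidInputError("points must be an (N, 3) array")
        if not np.all(np.isfinite(pts)):
            raise InvalidInputError("non-finite coordinates")
        self.points = pts
        if self.curvature is not None:
            cur = np.asarray(self.curvature, dtype=float).ravel()
            if cur.shape[0] != pts.shape[0]:
                raise InvalidInputError("curvature length != point count")
            self.curvature = cur

    def __len__(self) -> int:
        return self.points.shape[0]

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        if len(self) == 0:
            raise DegenerateGeometryError("empty cloud has no bounding box")
        return self.points.min(axis=0), self.points.max(axis=0)

    def select(self, mask_or_indices) -> "PointCloud":
        """Subset cloud by boolean mask or index array, keeping curvature."""
        idx = np.asarray(mask_or_indices)
        cur = self.curvature[idx] if self.curvature is not None else None
        return PointCloud(self.points[idx], curvature=cur,
                          frame_label=self.frame_label)

    def with_label(self, frame_label: str) -> "PointCloud":
        return PointCloud(self.points, curvature=self.curvature,
                          frame_label=frame_label)


@dataclass
class RigidTransform:
    """Proper rigid motion: ``x -> R @ x + t`` (source to target frame)."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).ravel()
        if t.shape[0] != 3:
            raise InvalidInputError("translation must be a 3-vector")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
            raise InvalidInputError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise InvalidInputError("rotation has det < 0 (reflection)")
        self.rotation = R
        self.translation = t

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.rotation.T + self.translation
        return out if np.asarray(points).ndim == 2 else out[0]

    def apply_cloud(self, cloud: PointCloud, frame_label: str | None = None) -> PointCloud:
        return PointCloud(self.apply(cloud.points), curvature=cloud.curvature,
                          frame_label=frame_label or cloud.frame_label)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply ``other`` first)."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform()

    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix."""
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    @staticmethod
    def from_matrix(M: np.ndarray) -> "RigidTransform":
        M = np.asarray(M, dtype=float).reshape(4, 4)
        return RigidTransform(M[:3, :3], M[:3, 3])

    def rotation_angle_deg(self) -> float:
        """Rotation magnitude in degrees (geodesic distance from identity)."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


@dataclass
class PipelineConfig:
    """Tunable parameters of the full measurement chain.

    Lengths are meters unless suffixed otherwise. Defaults are sized for a
    market-weight pig (~1.2 m long, girth ~1 m) scanned at centimeter-scale
    point spacing.
    """

    # preprocessing
    voxel_size: float = 0.008
    outlier_k: int = 8
    outlier_alpha: float = 2.0
    cluster_tolerance: float = 0.04
    cluster_min_size: int = 50
    diff_threshold_mm: float = 80.0
    boundary_trim_fraction: float = 0.3  # 0 disables the automated step-6 trim
    # registration-region extraction
    curvature_k: int = 16
    M: int = 500               # ear/tail high-curvature point count
    side_label: str = "right"  # which top-view half faces the side sensor
    # coarse registration (4PCS)
    overlap_estimate: float = 0.5
    coplanarity_tol: float = 0.01
    congruence_tol: float = 0.01
    lcp_delta: float = 0.01
    n_bases: int = 16
    # fine registration (ICP)
    icp_max_iter: int = 50
    icp_tol: float = 1e-6
    icp_trim_fraction: float = 0.2
    # girth measurement
    slab_thickness: float = 0.02
    anchor_offset: float = 0.10   # B2/B3 horizontal distance from the z-axis
    knn_k: int = 8
    smooth_voxel: float = 0.008   # in-plane averaging of the slice ring
    front_window: tuple = (0.0, 0.45)   # fraction of body length ahead of centroid
    contour_cell: float = 0.01
    # frame pairing
    pairing_tolerance_s: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.M < 4:
            raise InvalidInputError("M must be >= 4")
        if not (0.0 < self.overlap_estimate <= 1.0):
            raise InvalidInputError("overlap_estimate must be in (0, 1]")
        for name in ("voxel_size", "cluster_tolerance", "coplanarity_tol",
                     "congruence_tol", "lcp_delta", "slab_thickness",
                     "anchor_offset", "contour_cell"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be positive")

    def replace(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}
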