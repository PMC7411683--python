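"""Synthetic pig bodies and two-view depth scans with known ground truth.

The generator emulates the geometry the measurement pipeline faces in a
pig weigh channel: a smooth elongated torso with elliptical, z-varying
cross-sections, an axillary concavity just behind the forelimbs, four
tapered legs, two high-curvature ear bumps, a thin tail, a slight
left/right asymmetry of the flanks, and two partial-overlap sensor views
(top and side) related by a known rigid transform, with additive depth
noise and railing-style occlusion stripes on the side view.

World frame: ground plane at x = 0, +x vertically up, +z along the spine
toward the head, +y across the body (right-hand rule). Ground-truth heart
girth is the perimeter of the analytic cross-section at ``axilla_z``,
integrated densely (relative accuracy well below 1e-4).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import ConvexHull

from .types import (DepthFrame, InvalidInputError, PointCloud, RigidTransform)

__all__ = [
    "PigSpec",
    "LabeledCloud",
    "TwoViewScan",
    "make_pig",
    "render_two_views",
    "make_depth_scene",
    "hidden_point_removal",
    "default_top_pose",
    "default_side_pose",
    "RIG_UP_IN_TOP_FRAME",
    "RIG_UP_IN_SIDE_FRAME",
]

LABEL_NAMES = ("torso", "leg", "ear", "tail", "dorsal_quarter", "left", "right")


@dataclass
class PigSpec:
    """Dimensions of a market-weight pig (~1.2 m long, girth ~1 m).

    ``axilla_z`` is the spine coordinate of the heart-girth plane (the
    axillary concavity); the forelegs stand ``leg_gap`` ahead of it.
    ``bend_angle`` yaws the front half of the body about the vertical
    axis at mid-length (degrees). ``asymmetry`` widens the right flank
    by the given fraction — real pigs are not perfectly bilateral, which
    is what limits mirror-symmetry completion.
    """

    body_length: float = 1.20
    section_width: float = 0.30    # full width (y) of the mid-body ellipse
    section_height: float = 0.34   # full height (x) of the mid-body ellipse
    leg_length: float = 0.25
    leg_radius: float = 0.05       # at the shoulder; tapers to 0.015 at the hoof
    ear_size: float = 0.07
    tail_length: float = 0.22
    tail_radius: float = 0.016
    axilla_z: float = 0.27
    bend_angle: float = 0.0
    seed: int = 0
    asymmetry: float = 0.03
    notch_depth: float = 0.18      # relative radial depth of the axillary concavity
    notch_sigma_z: float = 0.04
    notch_sigma_theta: float = 0.5
    leg_gap: float = 0.06
    leg_y: float = 0.09
    stoutness: float = 1.0   # amplitude of the shoulder/rump/waist profile
    n_points: int = 16000

    def __post_init__(self) -> None:
        for name in ("body_length", "section_width", "section_height",
                     "leg_length", "n_points"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be positive")
        if not (-self.body_length / 2 < self.axilla_z < self.body_length / 2):
            raise InvalidInputError("axilla_z outside body extent")

    @property
    def axis_height(self) -> float:
        """Height of the spine axis above the ground plane."""
        return self.leg_length + self.section_height / 2.0

    def replace(self, **kw) -> "PigSpec":
        return replace(self, **kw)


@dataclass
class LabeledCloud:
    """Sampled pig surface with per-point part labels and ground truth.

    ``labels`` maps label name to boolean mask; ``ground_truth`` carries
    ``girth_cm``, the 3-D ``girth_plane_point`` (section center at the
    axilla), ``front_hoof`` (near-side front hoof bottom) and the world
    ``up`` direction.
    """

    cloud: PointCloud
    labels: dict
    ground_truth: dict
    spec: PigSpec = None

    def mask(self, *names: str) -> np.ndarray:
        m = np.zeros(len(self.cloud), dtype=bool)
        for n in names:
            m |= self.labels[n]
        return m


@dataclass
class TwoViewScan:
    """Paired partial scans in their sensor frames, with the true motion."""

    top: PointCloud
    side: PointCloud
    true_transform: RigidTransform       # maps side-frame -> top-frame
    top_indices: np.ndarray              # into the parent pig cloud
    side_indices: np.ndarray
    top_pose: RigidTransform             # world -> top sensor frame
    side_pose: RigidTransform            # world -> side sensor frame


# ---------------------------------------------------------------------------
# analytic body

def _taper(spec: PigSpec, z: np.ndarray) -> np.ndarray:
    u = np.clip(2.0 * np.asarray(z, dtype=float) / spec.body_length, -1.0, 1.0)
    return np.sqrt(np.maximum(0.0, 1.0 - u ** 4))


def _girth_profile(spec: PigSpec, z: np.ndarray) -> np.ndarray:
    """Longitudinal stoutness profile: shoulder and rump bulges, a slight
    waist between them, and a narrowing neck. Without this modulation the
    torso would be nearly slide-symmetric along the spine, which no real
    pig is."""
    z = np.asarray(z, dtype=float)
    L = spec.body_length
    mod = (0.05 * np.exp(-0.5 * ((z - 0.24 * L) / (0.10 * L)) ** 2)      # shoulders
           + 0.05 * np.exp(-0.5 * ((z + 0.28 * L) / (0.10 * L)) ** 2)   # rump
           - 0.04 * np.exp(-0.5 * (z / (0.12 * L)) ** 2)                # waist
           - 0.08 * np.exp(-0.5 * ((z - 0.46 * L) / (0.06 * L)) ** 2))  # neck
    return 1.0 + spec.stoutness * mod


def _radial_modifier(spec: PigSpec, theta: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Axillary concavity and left/right asymmetry, as a radial scale."""
    theta = np.asarray(theta, dtype=float)
    z = np.asarray(z, dtype=float)
    # concavity: Gaussian depression in z around the axilla, ventral in theta
    dth = np.arctan2(np.sin(theta + np.pi / 2), np.cos(theta + np.pi / 2))
    w_theta = np.exp(-0.5 * (dth / spec.notch_sigma_theta) ** 2)
    g_z = np.exp(-0.5 * ((z - spec.axilla_z) / spec.notch_sigma_z) ** 2)
    m = 1.0 - spec.notch_depth * g_z * w_theta
    # asymmetry: right flank (y > 0, theta near 0) slightly wider
    cos_t = np.cos(theta)
    m = m * (1.0 + spec.asymmetry * np.where(cos_t > 0, cos_t ** 2, 0.0))
    return m


def _section_points(spec: PigSpec, theta: np.ndarray, z: np.ndarray) -> np.ndarray:
    """World coordinates of torso surface points (straight spine)."""
    shape = _taper(spec, z) * _girth_profile(spec, z)
    a = 0.5 * spec.section_width * shape
    b = 0.5 * spec.section_height * shape
    m = _radial_modifier(spec, theta, z)
    x = spec.axis_height + m * b * np.sin(theta)
    y = m * a * np.cos(theta)
    return np.column_stack([x, y, np.asarray(z, dtype=float) * np.ones_like(x)])


def _section_perimeter(spec: PigSpec, z: float, n: int = 200_000) -> float:
    theta = np.linspace(-np.pi, np.pi, n + 1)
    pts = _section_points(spec, theta, np.full(n + 1, float(z)))
    return float(np.sum(np.linalg.norm(np.diff(pts[:, :2], axis=0), axis=1)))


def _bend_warp(spec: PigSpec, pts: np.ndarray) -> np.ndarray:
    """Yaw the front half (z > 0) about the vertical axis at mid-length."""
    if spec.bend_angle == 0.0:
        return pts
    psi = np.radians(spec.bend_angle)
    c, s = np.cos(psi), np.sin(psi)
    out = pts.copy()
    front = pts[:, 2] > 0
    y, z = pts[front, 1], pts[front, 2]
    out[front, 1] = c * y + s * z
    out[front, 2] = -s * y + c * z
    return out


def make_pig(spec: PigSpec | None = None) -> LabeledCloud:
    """Sample the analytic pig surface with part labels and ground truth."""
    spec = spec or PigSpec()
    rng = np.random.default_rng(spec.seed)
    L = spec.body_length
    half = L / 2.0

    parts: list[np.ndarray] = []
    names: list[str] = []

    # ---- torso (surface area ~ mean perimeter x length)
    peri_mid = _section_perimeter(spec, 0.0, n=2048)
    area_torso = 0.85 * peri_mid * L
    density = spec.n_points / (area_torso + 1e-9)  # refined below by part areas

    def _n_for(area: float) -> int:
        return max(8, int(round(density * area)))

    n_torso = _n_for(area_torso)
    z_t = rng.uniform(-half, half, n_torso)
    th_t = rng.uniform(-np.pi, np.pi, n_torso)
    parts.append(_section_points(spec, th_t, z_t))
    names.append("torso")

    # ---- legs: stout, gently tapered vertical frustums, hooves on the
    # ground; near-cylindrical so their curvature stays well below the
    # ears' (market pigs have thick legs)
    z_front = spec.axilla_z + spec.leg_gap
    r_hoof = 0.8 * spec.leg_radius
    if spec.leg_radius > 0 and spec.leg_length > 0:
        for zc in (z_front, -z_front):
            for yc in (spec.leg_y, -spec.leg_y):
                top_x = spec.axis_height - 0.35 * spec.section_height
                area = np.pi * (r_hoof + spec.leg_radius) * top_x
                n = _n_for(area)
                x = rng.uniform(0.0, top_x, n)
                r = r_hoof + (spec.leg_radius - r_hoof) * x / top_x
                ang = rng.uniform(0, 2 * np.pi, n)
                leg = np.column_stack([x, yc + r * np.sin(ang),
                                       zc + r * np.cos(ang)])
                # stop just short of the belly surface: a sharp
                # leg-into-torso crease would rival the ears' curvature,
                # which real (skin-folded) axillae do not
                a_z = 0.5 * spec.section_width * _taper(spec, leg[:, 2])
                b_z = 0.5 * spec.section_height * _taper(spec, leg[:, 2])
                ell = ((leg[:, 1] / np.maximum(a_z, 1e-9)) ** 2
                       + ((leg[:, 0] - spec.axis_height) / np.maximum(b_z, 1e-9)) ** 2)
                parts.append(leg[ell > 1.5])
                names.append("leg")

    # ---- ears: two elongated, sharply curved flaps on top of the head
    # (half-ellipsoids pointing along the spine; their tips and ridges
    # carry the high curvature the registration features rely on)
    if spec.ear_size > 0:
        z_ear = 0.80 * half
        b_ear = 0.5 * spec.section_height * _taper(spec, np.array([z_ear]))[0]
        semi = spec.ear_size * np.array([0.5, 0.4, 1.3])
        for yc in (0.06, -0.06):
            n = _n_for(3.5 * semi[1] * semi[2] * 4)
            v = rng.normal(size=(n, 3))
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            v[:, 0] = np.abs(v[:, 0])  # outward (upward) half
            center = np.array([spec.axis_height + 1.0 * b_ear, yc, z_ear])
            parts.append(center + semi * v)
            names.append("ear")

    # ---- tail: thin cylinder off the rear, near the top of the rump
    if spec.tail_length > 0:
        n = _n_for(2 * np.pi * spec.tail_radius * spec.tail_length)
        z = rng.uniform(-half - spec.tail_length, -half - 0.01, n)
        ang = rng.uniform(0, 2 * np.pi, n)
        x0 = spec.axis_height + 0.30 * spec.section_height * 0.5
        parts.append(np.column_stack([x0 + spec.tail_radius * np.sin(ang),
                                      spec.tail_radius * np.cos(ang), z]))
        names.append("tail")

    pts = np.vstack(parts)
    label_of = np.concatenate([[n] * len(p) for n, p in zip(names, parts)])
    left = pts[:, 1] > 0  # anatomical side, fixed before the bend warp
    pts = _bend_warp(spec, pts)

    labels = {name: label_of == name for name in ("torso", "leg", "ear", "tail")}
    # the ear/tail *regions* include the skin at their bases: dilate those
    # labels by a small radius so base-crease points count as the feature
    from scipy.spatial import cKDTree as _KD
    for name in ("ear", "tail"):
        if labels[name].any():
            d, _ = _KD(pts[labels[name]]).query(pts)
            labels[name] |= d < 0.025
    labels["torso"] &= ~(labels["ear"] | labels["tail"])
    labels["left"] = left
    labels["right"] = ~left
    x = pts[:, 0]
    labels["dorsal_quarter"] = x >= x.max() - 0.25 * (x.max() - x.min())

    landmarks = np.array([[0.0, -spec.leg_y, z_front],
                          [0.0, spec.leg_y, z_front],
                          [spec.axis_height, 0.0, spec.axilla_z]])
    landmarks = _bend_warp(spec, landmarks)
    ground_truth = {
        "girth_cm": 100.0 * _section_perimeter(spec, spec.axilla_z),
        "girth_plane_point": landmarks[2],
        "front_hoof": landmarks[0],
        "front_hooves": landmarks[:2],
        "axilla_z": spec.axilla_z,
        "up": np.array([1.0, 0.0, 0.0]),
    }
    return LabeledCloud(PointCloud(pts, frame_label="world"), labels,
                        ground_truth, spec)


# ---------------------------------------------------------------------------
# rendering

def hidden_point_removal(points: np.ndarray, viewpoint: np.ndarray,
                         radius_factor: float = 300.0) -> np.ndarray:
    """Indices of points visible from ``viewpoint`` (spherical-flip method).

    Each point is reflected through a sphere centred on the viewpoint;
    visible points are exactly the convex-hull vertices of the flipped
    set augmented with the viewpoint itself.
    """
    p = np.asarray(points, dtype=float) - np.asarray(viewpoint, dtype=float)
    norms = np.linalg.norm(p, axis=1)
    R = radius_factor * norms.max()
    flipped = p + 2.0 * (R - norms)[:, None] * (p / norms[:, None])
    hull = ConvexHull(np.vstack([flipped, np.zeros(3)]))
    idx = hull.vertices
    return np.sort(idx[idx < len(p)])


def default_top_pose(height: float = 1.55) -> RigidTransform:
    """World -> top-sensor frame: camera above the channel looking down."""
    R = np.array([[0.0, 1.0, 0.0],    # image x: across the channel (+y world)
                  [0.0, 0.0, -1.0],   # image y: toward the tail (-z world)
                  [-1.0, 0.0, 0.0]])  # view axis: downward (-x world)
    c = np.array([height, 0.0, 0.0])
    return RigidTransform(R, -R @ c)


def default_side_pose(height: float = 0.50, distance: float = 1.05) -> RigidTransform:
    """World -> side-sensor frame: camera beside the channel looking across.

    In this frame image y grows downward, so the animal's back (high in
    the world) maps to *small* y — the convention the back-profile
    extraction relies on.
    """
    R = np.array([[0.0, 0.0, -1.0],   # image x: along the channel (-z world)
                  [-1.0, 0.0, 0.0],   # image y: downward (-x world)
                  [0.0, 1.0, 0.0]])   # view axis: across (+y world)
    c = np.array([height, -distance, 0.0])
    return RigidTransform(R, -R @ c)


# up direction expressed in each sensor frame (fixed rig geometry)
RIG_UP_IN_TOP_FRAME = np.array([0.0, 0.0, -1.0])
RIG_UP_IN_SIDE_FRAME = np.array([0.0, -1.0, 0.0])

_DEFAULT_STRIPE_Z = (-0.40, 0.05, 0.50)


def render_two_views(pig: LabeledCloud,
                     top_pose: RigidTransform | None = None,
                     side_pose: RigidTransform | None = None,
                     noise_sigma: float = 0.002,
                     occlusion_stripes: int = 2,
                     stripe_width: float = 0.025,
                     seed: int | None = None) -> TwoViewScan:
    """Render partial top/side scans with known side->top rigid motion.

    Visibility is decided per sensor by hidden-point removal, Gaussian
    noise is added in the sensor frame, and vertical railing stripes are
    deleted from the side view at fixed rig positions (small seeded
    jitter).
    """
    top_pose = top_pose or default_top_pose()
    side_pose = side_pose or default_side_pose()
    pts = pig.cloud.points
    rng = np.random.default_rng(pig.spec.seed + 1 if seed is None else seed)

    vis = {}
    for name, pose in (("top", top_pose), ("side", side_pose)):
        cam_center = -pose.rotation.T @ pose.translation
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        if np.all(cam_center > lo) and np.all(cam_center < hi):
            raise InvalidInputError(f"{name} sensor placed inside the body")
        vis[name] = hidden_point_removal(pts, cam_center)

    side_idx = vis["side"]
    if occlusion_stripes > 0:
        centers = np.array(_DEFAULT_STRIPE_Z[:occlusion_stripes])
        centers = centers + rng.uniform(-0.01, 0.01, size=centers.shape)
        z = pts[side_idx, 2]
        occluded = np.zeros(len(side_idx), dtype=bool)
        for c in centers:
            occluded |= np.abs(z - c) < stripe_width / 2
        side_idx = side_idx[~occluded]

    top_cloud = top_pose.apply_cloud(
        PointCloud(pts[vis["top"]]), frame_label="sensor_top")
    side_cloud = side_pose.apply_cloud(
        PointCloud(pts[side_idx]), frame_label="sensor_side")
    if noise_sigma > 0:
        top_cloud.points += rng.normal(0, noise_sigma, top_cloud.points.shape)
        side_cloud.points += rng.normal(0, noise_sigma, side_cloud.points.shape)

    true_transform = top_pose.compose(side_pose.inverse())
    return TwoViewScan(top=top_cloud, side=side_cloud,
                       true_transform=true_transform,
                       top_indices=vis["top"], side_indices=side_idx,
                       top_pose=top_pose, side_pose=side_pose)


# ---------------------------------------------------------------------------
# depth-image scenes

@dataclass
class _Intrinsics:
    width: int = 256
    height: int = 212
    fx: float = 183.0
    fy: float = 183.0
    cx: float = 128.0
    cy: float = 106.0


def _rasterize(points: np.ndarray, pose: RigidTransform, K: _Intrinsics) -> np.ndarray:
    cam = pose.apply(points)
    z = cam[:, 2]
    ok = z > 0.05
    u = np.round(K.fx * cam[ok, 0] / z[ok] + K.cx).astype(int)
    v = np.round(K.fy * cam[ok, 1] / z[ok] + K.cy).astype(int)
    inside = (u >= 0) & (u < K.width) & (v >= 0) & (v < K.height)
    u, v, d = u[inside], v[inside], z[ok][inside] * 1000.0
    depth = np.full((K.height, K.width), np.inf)
    np.minimum.at(depth, (v, u), d)
    depth[np.isinf(depth)] = 0.0
    return depth


def _background_geometry(rng: np.random.Generator) -> np.ndarray:
    """Floor plane plus railing bars, as a dense point set."""
    yy, zz = np.meshgrid(np.arange(-1.4, 1.4, 0.012), np.arange(-1.4, 1.4, 0.012))
    floor = np.column_stack([np.zeros(yy.size), yy.ravel(), zz.ravel()])
    bars = []
    for zc in np.arange(-1.2, 1.21, 0.35):   # fence between side sensor and pig
        x = rng.uniform(0.0, 0.80, 800)
        ang = rng.uniform(0, 2 * np.pi, 800)
        bars.append(np.column_stack([x, -0.35 + 0.02 * np.sin(ang),
                                     zc + 0.02 * np.cos(ang)]))
    return np.vstack([floor] + bars)


def make_depth_scene(pig: LabeledCloud, view: str = "top",
                     intrinsics: _Intrinsics | None = None,
                     timestamp: float = 0.0) -> tuple[DepthFrame, DepthFrame]:
    """Return (scene-with-pig, background-only) depth frames for one view."""
    K = intrinsics or _Intrinsics()
    pose = default_top_pose() if view == "top" else default_side_pose()
    rng = np.random.default_rng(pig.spec.seed + 17)
    bg_pts = _background_geometry(rng)
    depth_bg = _rasterize(bg_pts, pose, K)
    if len(pig.cloud) > 0:
        scene_pts = np.vstack([pig.cloud.points, bg_pts])
    else:
        scene_pts = bg_pts
    depth_scene = _rasterize(scene_pts, pose, K)
    mk = lambda d: DepthFrame(d, fx=K.fx, fy=K.fy, cx=K.cx, cy=K.cy,
                              view_label=view, timestamp=timestamp)
    return mk(depth_scene), mk(depth_bg)
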