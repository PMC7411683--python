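"""Heart-girth measurement on the fused, pose-normalized pig cloud.

The chain mirrors how a stockman uses a tape: find the axillary point
just behind the forelimb (the envelope-line construction on the side
contour), cut a thin vertical slab there, complete the ~3/4 ring by
mirror symmetry across the sagittal plane, and measure the circumference
as geodesic shortest paths over a k-NN graph between three anchor points
around the ring.

Body frame convention: origin at the cloud centroid, +x vertically up,
+z along the spine toward the head, +y by the right-hand rule.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import features
from .types import (DegenerateGeometryError, InvalidInputError,
                    MeasurementError, PipelineConfig, PointCloud)

log = logging.getLogger("girthkit")

__all__ = [
    "BodyFrame",
    "GirthSlice",
    "NeighborGraph",
    "GirthResult",
    "pose_normalize",
    "front_leg_region",
    "find_front_hoof",
    "envelope_tangent",
    "find_measurement_point",
    "locate_measurement_point",
    "extract_girth_slice",
    "mirror_complete",
    "select_anchor_points",
    "build_knn_graph",
    "shortest_path_length",
    "measure_girth",
    "measure_at_plane",
    "measure_heart_girth",
]


@dataclass
class BodyFrame:
    """Canonical body coordinate frame (orthonormal, right-handed)."""

    origin: np.ndarray
    x_axis: np.ndarray   # vertical up
    y_axis: np.ndarray   # across the body
    z_axis: np.ndarray   # spine, toward the head

    def rotation(self) -> np.ndarray:
        return np.vstack([self.x_axis, self.y_axis, self.z_axis])

    def apply(self, points: np.ndarray) -> np.ndarray:
        """World/sensor coordinates -> body-frame coordinates."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = (pts - self.origin) @ self.rotation().T
        return out if np.asarray(points).ndim == 2 else out[0]


@dataclass
class GirthSlice:
    """Thin vertical slab at the measurement plane, before/after mirroring."""

    raw: PointCloud
    completed: PointCloud = None
    z_center: float = 0.0
    B1: np.ndarray = None
    B2: np.ndarray = None
    B3: np.ndarray = None


@dataclass
class NeighborGraph:
    """Symmetrized k-NN graph with Euclidean edge weights (meters)."""

    points: np.ndarray
    neighbors: list = field(default_factory=list)   # per-vertex index arrays
    weights: list = field(default_factory=list)     # matching distances
    connected: bool = True

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class GirthResult:
    girth_cm: float
    segment_lengths_cm: tuple
    measurement_z: float
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# pose normalization

def pose_normalize(fused: PointCloud, up_hint: np.ndarray | None = None,
                   curvature_k: int = 12) -> tuple[PointCloud, BodyFrame]:
    """Express the fused cloud in the canonical body frame.

    The vertical is taken from ``up_hint`` (the top sensor's viewing
    axis — known rig geometry) when given; otherwise the shortest
    principal axis of the cloud is used. The spine is the dominant
    principal direction orthogonal to the vertical; its sign is chosen
    so the half containing the high-curvature ear cluster (the head)
    gets positive z.
    """
    pts = fused.points
    if len(pts) < 10:
        raise DegenerateGeometryError("too few points to normalize")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    cov = centered.T @ centered / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    if evals[2] < 1.5 * evals[1]:
        raise DegenerateGeometryError(
            "ambiguous principal axes; cannot identify the spine direction")
    if up_hint is None:
        up = evecs[:, 0]
        if up[np.argmax(np.abs(up))] < 0:
            up = -up
    else:
        up = np.asarray(up_hint, dtype=float)
        up = up / np.linalg.norm(up)
    # spine: dominant direction in the plane orthogonal to the vertical
    proj = centered - np.outer(centered @ up, up)
    covp = proj.T @ proj / len(pts)
    pvals, pvecs = np.linalg.eigh(covp)
    spine = pvecs[:, -1]
    spine = spine - (spine @ up) * up
    spine /= np.linalg.norm(spine)

    # head-end disambiguation via the ear cluster: the two ears sit
    # either side of the midline, while the tail is a single on-axis
    # protrusion — so among the high-curvature points of each end, the
    # head end has the larger lateral spread
    sub = fused
    if len(fused) > 4000:
        idx = np.random.default_rng(0).choice(len(fused), 4000, replace=False)
        sub = fused.select(idx)
    curv = (sub.curvature if sub.curvature is not None
            else features.curvature_pca(sub, curvature_k).curvature)
    top = np.argsort(-curv)[:600]
    lateral = np.cross(spine, up)
    rel = sub.points[top] - centroid
    # ears and tail sit high on the body; discard low points (legs)
    high = rel @ up > 0
    rel = rel[high]
    s = rel @ spine
    y = rel @ lateral
    half_len = 0.25 * (s.max() - s.min())
    # spread about each end's own lateral center, so a bent spine (which
    # offsets an entire end sideways) does not masquerade as ears
    pos, neg = y[s > half_len], y[s < -half_len]
    spread_pos = float(np.std(pos)) if len(pos) >= 10 else 0.0
    spread_neg = float(np.std(neg)) if len(neg) >= 10 else 0.0
    if spread_pos < spread_neg:
        spine = -spine
    y_axis = np.cross(spine, up)
    y_axis /= np.linalg.norm(y_axis)
    frame = BodyFrame(origin=centroid, x_axis=up, y_axis=y_axis, z_axis=spine)
    out = PointCloud(frame.apply(pts), curvature=fused.curvature,
                     frame_label="normalized")
    return out, frame


# ---------------------------------------------------------------------------
# measurement-point extraction

def front_leg_region(normalized: PointCloud,
                     window: tuple = (0.10, 0.45)) -> PointCloud:
    """Forelimb-and-chest slab: z in the given fractions of body length
    ahead of the centroid, full height."""
    z = normalized.points[:, 2]
    L = z.max() - z.min()
    lo, hi = window[0] * L, window[1] * L
    if hi <= lo:
        raise DegenerateGeometryError("empty front-body window")
    mask = (z >= lo) & (z <= hi)
    if mask.sum() < 30:
        raise MeasurementError("front-body window contains too few points")
    return normalized.select(mask)


def find_front_hoof(C: PointCloud) -> np.ndarray:
    """Lowest point of the forelimb region (ties: min z, then min y)."""
    if len(C) == 0:
        raise InvalidInputError("empty region")
    p = C.points
    order = np.lexsort((p[:, 1], p[:, 2], p[:, 0]))
    return p[order[0]].copy()


def _lower_boundary(contour_vertices: np.ndarray, cell: float) -> np.ndarray:
    """Per-z-bin lowest contour vertex — the ventral contour line."""
    z, x = contour_vertices[:, 0], contour_vertices[:, 1]
    bins = np.floor(z / cell).astype(int)
    out = []
    for b in np.unique(bins):
        m = bins == b
        out.append(contour_vertices[np.flatnonzero(m)[np.argmin(x[m])]])
    return np.asarray(out)


def envelope_tangent(contour: features.Contour2D, T_A: np.ndarray,
                     exclude: float = 0.0,
                     min_height_frac: float = 0.2) -> tuple[float, np.ndarray]:
    """Rotate the envelope line about the hoof to tangency with the body.

    The line ``x = k (z - z_TA)`` pivots at the hoof; rotating down from
    horizontal (k decreasing from 0), the first contact with the contour
    is the vertex maximizing ``(x_p - x_TA) / (z_p - z_TA)`` over
    qualifying vertices behind the hoof. Qualifying vertices must sit at
    least ``min_height_frac`` of the contour height above the hoof and
    more than ``exclude`` behind it: the tangency target is the trunk
    underline, and the leg's own rasterized silhouette near the ground
    would otherwise produce spurious shallow slopes. Returns the slope
    k (< 0) and the tangency vertex T_B.
    """
    v = contour.vertices
    z_ta, x_ta = T_A[2], T_A[0]
    eps = max(exclude, 1e-9)
    h_min = min_height_frac * max(v[:, 1].max() - x_ta, 0.0)
    cand = (v[:, 0] < z_ta - eps) & (v[:, 1] > x_ta + max(h_min, 1e-9))
    if not cand.any():
        raise MeasurementError("no contour behind the hoof; tangent undefined")
    ratios = (v[cand, 1] - x_ta) / (v[cand, 0] - z_ta)
    i = int(np.argmax(ratios))
    k = float(ratios[i])
    T_B = v[np.flatnonzero(cand)[i]]
    if k >= 0:
        raise MeasurementError("tangent slope is not negative; geometry invalid")
    return k, T_B


def find_measurement_point(C_prime: np.ndarray, k: float,
                           T_A: np.ndarray, cell: float = 0.01) -> np.ndarray:
    """Translate the tangent line backwards; the last contour contact is
    the axillary concavity — the heart-girth measurement point B1.

    ``C_prime`` is the ventral contour between the tangency point and
    the hoof, as (z, x) vertices; the last contact is the vertex
    maximizing the line offset ``x - k (z - z_TA)``.
    """
    if len(C_prime) < 3:
        raise MeasurementError("local contour too short for the line sweep")
    z_ta, x_ta = T_A[2], T_A[0]
    offsets = C_prime[:, 1] - k * (C_prime[:, 0] - z_ta)
    if offsets.max() - offsets.min() < 2 * cell:
        raise MeasurementError("degenerate local contour: no unique last contact")
    return C_prime[int(np.argmax(offsets))]


def locate_measurement_point(normalized: PointCloud,
                             cfg: PipelineConfig | None = None) -> tuple[float, dict]:
    """Full axillary-point extraction; returns (z_B1, diagnostics)."""
    cfg = cfg or PipelineConfig()
    C = front_leg_region(normalized, cfg.front_window)
    hoof = find_front_hoof(C)
    contour = features.extract_contour(C, plane="zx", cell=cfg.contour_cell)
    k, T_B = envelope_tangent(contour, hoof, exclude=3 * cfg.contour_cell)
    low = _lower_boundary(contour.vertices, cfg.contour_cell)
    in_span = (low[:, 0] >= min(T_B[0], hoof[2])) & (low[:, 0] <= max(T_B[0], hoof[2]))
    B1 = find_measurement_point(low[in_span], k, hoof, cfg.contour_cell)
    diag = {"hoof": hoof, "tangent_slope": k, "T_B": T_B, "B1_contour": B1}
    log.info("locate_measurement_point: z_B1 = %.3f m (slope %.2f)", B1[0], k)
    return float(B1[0]), diag


# ---------------------------------------------------------------------------
# slice, mirroring, anchors

def extract_girth_slice(normalized: PointCloud, z_B1: float,
                        slab_thickness: float = 0.02) -> GirthSlice:
    """Slab of points within half a slab thickness of the measurement
    plane, projected onto that plane (the measured curve is planar)."""
    if slab_thickness <= 0:
        raise InvalidInputError("slab_thickness must be positive")
    z = normalized.points[:, 2]
    mask = np.abs(z - z_B1) <= slab_thickness / 2
    if mask.sum() < 20:
        raise MeasurementError("girth slab too sparse")
    pts = normalized.points[mask].copy()
    pts[:, 2] = z_B1
    return GirthSlice(raw=PointCloud(pts, frame_label="normalized"),
                      z_center=float(z_B1))


def mirror_complete(slice_: GirthSlice, dedup: float = 0.008,
                    plane: str = "sagittal") -> GirthSlice:
    """Complete the ring by mirror symmetry.

    ``plane='sagittal'`` reflects across y = 0 (the vertical plane
    through the spine — the standard bilateral completion);
    ``plane='horizontal'`` reflects across the slice's mid-height,
    which is the fallback used when only dorsal data exist (top view
    alone). Reflected duplicates within ``dedup`` of an existing point
    are dropped.
    """
    pts = slice_.raw.points if slice_.completed is None else slice_.completed.points
    mirrored = pts.copy()
    if plane == "sagittal":
        mirrored[:, 1] *= -1
    elif plane == "horizontal":
        mid = 0.5 * (pts[:, 0].min() + pts[:, 0].max())
        mirrored[:, 0] = 2 * mid - mirrored[:, 0]
    else:
        raise InvalidInputError(f"unknown mirror plane {plane!r}")
    d, _ = cKDTree(pts).query(mirrored)
    new = mirrored[d > dedup]
    completed = PointCloud(np.vstack([pts, new]), frame_label="normalized")
    log.debug("mirror_complete(%s): %d -> %d points", plane, len(pts),
              len(completed))
    return GirthSlice(raw=slice_.raw, completed=completed,
                      z_center=slice_.z_center, B1=slice_.B1)


def select_anchor_points(slice_: GirthSlice,
                         anchor_offset: float = 0.10) -> tuple[np.ndarray, np.ndarray]:
    """Anchors B2, B3 on the back surface, ~``anchor_offset`` laterally
    from the sagittal plane on either side (fault tolerance for the
    closed-contour shortest-path construction)."""
    pts = slice_.completed.points
    if not ((pts[:, 1] > 0).any() and (pts[:, 1] < 0).any()):
        raise MeasurementError("one-sided slice: cannot place both anchors")
    yc = float(pts[:, 1].mean())   # lateral center (the spine axis after
    y = pts[:, 1] - yc             # pose normalization; exactly 0 when mirrored)
    upper = pts[:, 0] > np.median(pts[:, 0])
    out = []
    for side in (1.0, -1.0):
        m = upper & (np.sign(y) == side)
        if not m.any():
            raise MeasurementError("no upper-surface points on one side")
        cand = pts[m]
        out.append(cand[np.argmin(np.abs(np.abs(cand[:, 1] - yc) - anchor_offset))])
    return out[0], out[1]


# ---------------------------------------------------------------------------
# graph and geodesics

def build_knn_graph(points: np.ndarray, k: int = 8) -> NeighborGraph:
    """Symmetrized k-nearest-neighbor graph with Euclidean weights."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if k < 2 or n <= k:
        raise InvalidInputError("need k >= 2 and more than k points")
    tree = cKDTree(pts)
    dists, idx = tree.query(pts, k=k + 1)
    adj: list[dict] = [dict() for _ in range(n)]
    for i in range(n):
        for dd, j in zip(dists[i, 1:], idx[i, 1:]):
            adj[i][int(j)] = float(dd)
            adj[int(j)][i] = float(dd)   # keep edge if either endpoint lists it
    neighbors = [np.array(sorted(a)) for a in adj]
    weights = [np.array([adj[i][j] for j in neighbors[i]]) for i in range(n)]
    graph = NeighborGraph(points=pts, neighbors=neighbors, weights=weights)
    # connectivity probe from vertex 0
    seen = np.zeros(n, dtype=bool)
    stack = [0]
    seen[0] = True
    while stack:
        u = stack.pop()
        for v in neighbors[u]:
            if not seen[v]:
                seen[v] = True
                stack.append(int(v))
    graph.connected = bool(seen.all())
    if not graph.connected:
        log.warning("build_knn_graph: graph disconnected (%d/%d reachable)",
                    int(seen.sum()), n)
    return graph


def _dijkstra(graph: NeighborGraph, source: int, target: int,
              allowed: np.ndarray | None = None):
    """Textbook Dijkstra with a binary heap; returns (distance, path).

    C(source) = 0 and C(x) = inf for the rest; repeatedly extract the
    unvisited vertex with minimum C and relax its neighbors via
    C(x1) + W(x1, x2) < C(x2), until the target is settled.
    """
    n = len(graph)
    C = np.full(n, np.inf)
    C[source] = 0.0
    prev = np.full(n, -1)
    visited = np.zeros(n, dtype=bool)
    heap = [(0.0, source)]
    while heap:
        d, u = heapq.heappop(heap)
        if visited[u]:
            continue
        visited[u] = True
        if u == target:
            break
        for v, w in zip(graph.neighbors[u], graph.weights[u]):
            v = int(v)
            if allowed is not None and not allowed[v]:
                continue
            nd = d + w
            if nd < C[v]:
                C[v] = nd
                prev[v] = u
                heapq.heappush(heap, (nd, v))
    if not np.isfinite(C[target]):
        return np.inf, []
    path = [target]
    while path[-1] != source:
        path.append(int(prev[path[-1]]))
    return float(C[target]), path[::-1]


def shortest_path_length(graph: NeighborGraph, u: int, v: int) -> float:
    """Geodesic distance between two graph vertices in meters."""
    if not (0 <= u < len(graph) and 0 <= v < len(graph)):
        raise InvalidInputError("vertex index out of range")
    d, _ = _dijkstra(graph, u, v)
    if not np.isfinite(d):
        raise MeasurementError(f"vertex {v} unreachable from {u}")
    return d


def _sector_mask(theta: np.ndarray, th_a: float, th_b: float, th_excl: float,
                 margin: float = np.radians(8)) -> np.ndarray:
    """Vertices on the arc from th_a to th_b that avoids th_excl."""
    def fwd(a, b):  # arc going counterclockwise from a to b
        return (b - a) % (2 * np.pi)

    if fwd(th_a, th_excl) < fwd(th_a, th_b):
        # excluded angle lies on the ccw arc: use the clockwise arc
        th_a, th_b = th_b, th_a
    width = fwd(th_a, th_b)
    rel = (theta - th_a) % (2 * np.pi)
    return (rel <= width + margin) | (rel >= 2 * np.pi - margin)


def measure_girth(slice_: GirthSlice, cfg: PipelineConfig | None = None) -> GirthResult:
    """Sum of the three geodesics B1->B2, B2->B3, B3->B1 around the ring.

    Each segment's search is restricted to the angular sector between
    its two anchors (so the three paths traverse complementary arcs);
    the paths are validated to be pairwise edge-disjoint, and on
    failure the graph is rebuilt with a larger k.
    """
    cfg = cfg or PipelineConfig()
    if slice_.completed is None or slice_.B1 is None:
        raise InvalidInputError("slice must be completed with anchors set")
    pts2 = slice_.completed.points[:, :2]   # (x, y) in the slice plane
    if cfg.smooth_voxel > 0:
        # in-plane averaging: suppresses sensor noise that would
        # otherwise inflate the zig-zag path length
        keys = np.floor(pts2 / cfg.smooth_voxel).astype(np.int64)
        _, inv, counts = np.unique(keys, axis=0, return_inverse=True,
                                   return_counts=True)
        sums = np.zeros((len(counts), 2))
        np.add.at(sums, inv, pts2)
        pts2 = sums / counts[:, None]
    # B1 sits on the ventral midline, which often falls inside the
    # sensors' blind underside sector; inserting it as an explicit graph
    # node (rather than snapping to a gap edge) keeps the three sectors
    # well ordered around the ring
    b1_xy = np.asarray(slice_.B1[:2], dtype=float)
    if np.min(np.sum((pts2 - b1_xy) ** 2, axis=1)) > 0.005 ** 2:
        pts2 = np.vstack([pts2, b1_xy])
    anchors = []
    for p in (slice_.B1, slice_.B2, slice_.B3):
        anchors.append(int(np.argmin(np.sum((pts2 - p[:2]) ** 2, axis=1))))
    center = pts2.mean(axis=0)
    theta = np.arctan2(pts2[:, 1] - center[1], pts2[:, 0] - center[0])
    th = [theta[a] for a in anchors]

    k = cfg.knn_k
    while True:
        graph = build_knn_graph(pts2, k)
        # ring-closure edges: the section's underside is invisible to both
        # sensors, so the ring may have one angular gap wider than any
        # k-NN reach; connecting angular neighbors bridges it with a
        # single chord (the geodesic's chord approximation over the gap)
        order = np.argsort(theta)
        for a, b in zip(order, np.roll(order, -1)):
            a, b = int(a), int(b)
            if b not in graph.neighbors[a]:
                w = float(np.linalg.norm(pts2[a] - pts2[b]))
                graph.neighbors[a] = np.append(graph.neighbors[a], b)
                graph.weights[a] = np.append(graph.weights[a], w)
                graph.neighbors[b] = np.append(graph.neighbors[b], a)
                graph.weights[b] = np.append(graph.weights[b], w)
        segs, paths = [], []
        ok = True
        for (ia, ib, ie) in ((0, 1, 2), (1, 2, 0), (2, 0, 1)):
            allowed = _sector_mask(theta, th[ia], th[ib], th[ie])
            allowed[anchors[ia]] = allowed[anchors[ib]] = True
            d, path = _dijkstra(graph, anchors[ia], anchors[ib], allowed)
            if not np.isfinite(d):
                ok = False
                break
            segs.append(d)
            paths.append(path)
        if ok:
            edge_sets = [set(frozenset(e) for e in zip(p[:-1], p[1:]))
                         for p in paths]
            disjoint = (not (edge_sets[0] & edge_sets[1])
                        and not (edge_sets[1] & edge_sets[2])
                        and not (edge_sets[0] & edge_sets[2]))
            if disjoint:
                break
        if k >= 32:
            raise MeasurementError(
                "girth paths unreachable or overlapping even at k = 32")
        k *= 2
        log.warning("measure_girth: retrying with k = %d", k)

    girth_cm = 100.0 * float(sum(segs))
    return GirthResult(
        girth_cm=girth_cm,
        segment_lengths_cm=tuple(100.0 * s for s in segs),
        measurement_z=slice_.z_center,
        diagnostics={"n_raw": len(slice_.raw), "n_completed": len(slice_.completed),
                     "n_graph": len(pts2), "k_used": k},
    )


# ---------------------------------------------------------------------------
# orchestration

def measure_at_plane(normalized: PointCloud, z_plane: float,
                     cfg: PipelineConfig | None = None,
                     completion: tuple = ("sagittal",),
                     b1: np.ndarray | None = None) -> GirthResult:
    """Measure the circumference at a given plane.

    ``completion`` lists the mirror planes applied in order; the default
    sagittal mirror is the standard bilateral completion, and adding
    ``'horizontal'`` closes a dorsal-only ring (single top view). If
    ``b1`` is not given, the lowest point of the completed ring is used
    as the ventral anchor.
    """
    cfg = cfg or PipelineConfig()
    sl = extract_girth_slice(normalized, z_plane, cfg.slab_thickness)
    # Forelimb points can fall inside the slab and hang below the chest
    # section; they must not be stitched into the measured ring. Cut
    # everything clearly below the ventral surface — at the B1 height
    # when known, otherwise predicted by a circle fit to the dorsal
    # crown (which is always clean) — then keep the largest connected
    # component.
    pts = sl.raw.points
    if b1 is not None:
        x_floor = float(b1[0]) - 0.03
    else:
        crown = pts[pts[:, 0] > pts[:, 0].max()
                    - 0.3 * (pts[:, 0].max() - pts[:, 0].min())]
        A = np.column_stack([crown[:, 0], crown[:, 1], np.ones(len(crown))])
        rhs = crown[:, 0] ** 2 + crown[:, 1] ** 2
        try:
            sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
            cx, cy = sol[0] / 2, sol[1] / 2
            r = np.sqrt(max(sol[2] + cx ** 2 + cy ** 2, 0.0))
            x_floor = cx - r - 0.05
        except np.linalg.LinAlgError:
            x_floor = pts[:, 0].min()
    keep = pts[:, 0] >= x_floor
    if keep.sum() >= 20:
        sl.raw = sl.raw.select(keep)
    # residual limb points sit just above the floor; drop connected
    # components confined to that band, but never sparse ring arcs
    # (which reach well above it)
    from .preprocess import euclidean_cluster
    clusters = euclidean_cluster(sl.raw, tolerance=0.03, min_size=3)
    if len(clusters) > 1:
        ring = [c for c in clusters.clusters
                if sl.raw.points[c, 0].max() >= x_floor + 0.06]
        if ring:
            sl.raw = sl.raw.select(np.sort(np.concatenate(ring)))
    elif len(clusters) == 1:
        sl.raw = sl.raw.select(clusters.largest())
    # The sagittal plane must bisect the body, but the centroid of a
    # *partial* fused cloud (one flank missing) sits a few cm off it.
    # The dorsal crown of the slice is fully covered by the top view and
    # bilaterally symmetric, so its lateral midrange locates the true
    # mid-plane; the slice is re-centered on it before mirroring.
    pts_raw = sl.raw.points
    x = pts_raw[:, 0]
    crown = x > x.max() - 0.25 * (x.max() - x.min())
    if crown.sum() >= 5:
        y_mid = 0.5 * (pts_raw[crown, 1].min() + pts_raw[crown, 1].max())
        sl.raw.points = pts_raw - np.array([0.0, y_mid, 0.0])
    for plane in completion:
        sl = mirror_complete(sl, dedup=cfg.voxel_size, plane=plane)
    if sl.completed is None:
        sl.completed = sl.raw
    pts = sl.completed.points
    if b1 is not None:
        sl.B1 = np.asarray(b1, float)
    else:
        # default ventral anchor: lowest ring height, on the midline (the
        # slice was just re-centered on the sagittal plane)
        sl.B1 = np.array([pts[:, 0].min(), 0.0, sl.z_center])
    sl.B2, sl.B3 = select_anchor_points(sl, cfg.anchor_offset)
    return measure_girth(sl, cfg)


def measure_heart_girth(normalized: PointCloud,
                        cfg: PipelineConfig | None = None) -> GirthResult:
    """Locate the axillary point and measure the heart girth there."""
    cfg = cfg or PipelineConfig()
    z_b1, diag = locate_measurement_point(normalized, cfg)
    result = measure_at_plane(normalized, z_b1, cfg,
                              b1=np.array([diag["B1_contour"][1], 0.0, z_b1]))
    result.diagnostics.update({"tangent_slope": diag["tangent_slope"],
                               "hoof_z": float(diag["hoof"][2])})
    return result
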