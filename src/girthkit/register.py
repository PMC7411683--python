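"""Coarse-to-fine registration of the two-view clouds.

Coarse registration is a feature-guided 4-Point Congruent Sets search:
coplanar four-point bases are sampled from the side-view region P, their
affine-invariant cross-ratios (r1, r2) are used to enumerate congruent
quadruples in the top-view region Q, and the candidate rigid transform
with the largest common pointset (LCP) wins. Fine registration is
trimmed point-to-point ICP on the full clouds, which tolerates the low
overlap between the two views. The registration error metric is the mean
Euclidean distance between matched point pairs (reported in cm), i.e.
the "RMSE" convention used in livestock-scanning work.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .types import (DegenerateGeometryError, InvalidInputError,
                    PipelineConfig, PointCloud, RegistrationError,
                    RigidTransform)

log = logging.getLogger("girthkit")

__all__ = [
    "FourPointBasis",
    "RegistrationResult",
    "max_pair_length",
    "scale_factors",
    "find_coplanar_bases",
    "find_congruent_sets",
    "best_rigid_fit",
    "coarse_register",
    "icp_refine",
    "register_views",
    "registration_rmse",
]


@dataclass
class FourPointBasis:
    """Coplanar quadruple {a, b, c, d} with segment-intersection ratios.

    ``e`` is the crossing point of segments ab and cd; ``r1 = |a-e|/|a-b|``
    and ``r2 = |c-e|/|c-d|`` are invariant under rigid (indeed affine)
    motion, which is what lets congruent quadruples be found in the
    target cloud by distance search alone.
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray
    e: np.ndarray
    r1: float
    r2: float

    @property
    def points(self) -> np.ndarray:
        return np.vstack([self.a, self.b, self.c, self.d])


@dataclass
class RegistrationResult:
    transform: RigidTransform
    lcp_count: int = 0
    rmse_cm: float = float("nan")
    iterations: int = 0


def max_pair_length(P: PointCloud, overlap_estimate: float) -> float:
    """Basis span m = overlap fraction x bounding-box diagonal of P."""
    if not (0.0 < overlap_estimate <= 1.0):
        raise InvalidInputError("overlap_estimate must be in (0, 1]")
    lo, hi = P.bounding_box()
    return float(overlap_estimate * np.linalg.norm(hi - lo))


def scale_factors(a, b, c, d, coplanarity_tol: float = 0.01):
    """Cross-ratios (r1, r2) and intersection e of segments ab and cd.

    Noisy 3-D segments never intersect exactly, so e is the midpoint of
    the closest-approach segment between the two lines; the gap must be
    within ``coplanarity_tol`` and the crossing interior to both
    segments.
    """
    a, b, c, d = (np.asarray(p, dtype=float) for p in (a, b, c, d))
    u = b - a
    v = d - c
    w = a - c
    uu, vv, uv = u @ u, v @ v, u @ v
    denom = uu * vv - uv * uv
    if uu == 0 or vv == 0 or denom <= 1e-12 * uu * vv:
        raise DegenerateGeometryError("segments parallel or degenerate")
    s = (uv * (w @ v) - vv * (w @ u)) / denom
    t = (uu * (w @ v) - uv * (w @ u)) / denom
    p1 = a + s * u
    p2 = c + t * v
    gap = np.linalg.norm(p1 - p2)
    if gap > coplanarity_tol or not (0.0 <= s <= 1.0 and 0.0 <= t <= 1.0):
        raise DegenerateGeometryError("segments do not cross within tolerance")
    e = 0.5 * (p1 + p2)
    r1 = np.linalg.norm(e - a) / np.sqrt(uu)
    r2 = np.linalg.norm(e - c) / np.sqrt(vv)
    return float(r1), float(r2), e


def find_coplanar_bases(P: PointCloud, m: float, n_bases: int = 16,
                        seed: int = 0, coplanarity_tol: float = 0.01,
                        length_tol: float = 0.15,
                        max_attempts: int = 4000) -> list[FourPointBasis]:
    """Sample wide-spread coplanar four-point bases from P.

    Randomized with a budget rather than exhaustive: pick a, then b with
    ``|a-b|`` within ``length_tol`` (relative) of m, then c, d near the
    ab plane whose segment crosses ab. Narrow bases (area below 1% of
    the bbox diagonal squared) are rejected for conditioning.
    """
    pts = P.points
    n = len(pts)
    if n < 4:
        raise DegenerateGeometryError("need at least 4 points for a basis")
    if m <= 0:
        raise DegenerateGeometryError("non-positive basis span")
    rng = np.random.default_rng(seed)
    tree = cKDTree(pts)
    lo, hi = P.bounding_box()
    diag2 = float(np.sum((hi - lo) ** 2))
    bases: list[FourPointBasis] = []
    for _ in range(max_attempts):
        if len(bases) >= n_bases:
            break
        ia = rng.integers(n)
        a = pts[ia]
        cand = tree.query_ball_point(a, m * (1 + length_tol))
        d_a = np.linalg.norm(pts[cand] - a, axis=1)
        ok = [j for j, dd in zip(cand, d_a) if dd >= m * (1 - length_tol) and j != ia]
        if not ok:
            continue
        ib = ok[rng.integers(len(ok))]
        b = pts[ib]
        # points near the plane... any plane through ab: choose c randomly,
        # then d near the plane through (a, b, c) on the far side of ab
        ic = rng.integers(n)
        if ic in (ia, ib):
            continue
        c = pts[ic]
        normal = np.cross(b - a, c - a)
        nn = np.linalg.norm(normal)
        if nn < 1e-9:
            continue
        normal /= nn
        dist_plane = np.abs((pts - a) @ normal)
        near = np.flatnonzero(dist_plane < coplanarity_tol)
        rng.shuffle(near)
        for idx in near[:40]:
            if idx in (ia, ib, ic):
                continue
            d = pts[idx]
            try:
                r1, r2, e = scale_factors(a, b, c, d, coplanarity_tol)
            except DegenerateGeometryError:
                continue
            area = 0.5 * np.linalg.norm(np.cross(b - a, d - c))
            if area < 0.01 * diag2 * 0.01:
                continue
            bases.append(FourPointBasis(a, b, c, d, e, r1, r2))
            break
    if not bases:
        raise RegistrationError("basis search failed: no coplanar crossing quadruple")
    return bases


def find_congruent_sets(Q: PointCloud, basis: FourPointBasis,
                        congruence_tol: float = 0.01,
                        max_candidates: int | None = None,
                        max_pairs: int | None = None,
                        rng: np.random.Generator | None = None) -> list[np.ndarray]:
    """4-point sets in Q congruent to the basis, via the (r1, r2) test.

    All point pairs at distance ~|a-b| propose crossing points
    ``e1 = q1 + r1 (q2 - q1)``; pairs at ~|c-d| propose
    ``e2 = q1 + r2 (q2 - q1)``. Where an e1 and an e2 coincide within
    ``congruence_tol``, the two pairs form a candidate congruent
    quadruple (ordered to match a, b, c, d). By default the enumeration
    is exhaustive; ``max_pairs`` / ``max_candidates`` bound the work for
    large clouds (seeded subsampling of the pair sets).
    """
    pts = Q.points
    n = len(pts)
    if n < 4:
        return []
    d1 = np.linalg.norm(basis.b - basis.a)
    d2 = np.linalg.norm(basis.d - basis.c)
    D = cdist(pts, pts)
    iu = np.triu_indices(n, k=1)

    def _pairs(target):
        sel = np.abs(D[iu] - target) <= congruence_tol
        i, j = iu[0][sel], iu[1][sel]
        if max_pairs is not None and len(i) > max_pairs:
            pick = (rng or np.random.default_rng()).choice(len(i), max_pairs,
                                                           replace=False)
            i, j = i[pick], j[pick]
        # both orientations: the basis points are ordered
        return np.concatenate([i, j]), np.concatenate([j, i])

    i1, j1 = _pairs(d1)
    i2, j2 = _pairs(d2)
    if len(i1) == 0 or len(i2) == 0:
        return []
    e1 = pts[i1] + basis.r1 * (pts[j1] - pts[i1])
    e2 = pts[i2] + basis.r2 * (pts[j2] - pts[i2])
    if max_candidates is None:
        # exhaustive: every (e1, e2) coincidence
        matches = cKDTree(e1).query_ball_point(e2, congruence_tol)
        hits = [(k1, k2) for k2, lst in enumerate(matches) for k1 in lst]
    else:
        # bounded: at most one e1 per e2 proposal
        dist, k1s = cKDTree(e1).query(e2, distance_upper_bound=congruence_tol)
        hits = [(k1, k2) for k2, (dd, k1) in enumerate(zip(dist, k1s))
                if np.isfinite(dd)]
        if len(hits) > max_candidates:
            pick = (rng or np.random.default_rng()).choice(len(hits),
                                                           max_candidates,
                                                           replace=False)
            hits = [hits[p] for p in pick]
    out = []
    for k1, k2 in hits:
        quad = (i1[k1], j1[k1], i2[k2], j2[k2])
        if len(set(quad)) < 4:
            continue
        out.append(pts[list(quad)])
    return out


def best_rigid_fit(src4: np.ndarray, dst4: np.ndarray,
                   weights: np.ndarray | None = None) -> RigidTransform:
    """Least-squares rigid transform src -> dst (Kabsch, det corrected).

    Optional per-correspondence weights (used by the feature-weighted
    ICP refinement).
    """
    src = np.asarray(src4, dtype=float)
    dst = np.asarray(dst4, dtype=float)
    if weights is None:
        w = np.full(len(src), 1.0 / len(src))
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
    cs, cd = w @ src, w @ dst
    H = ((src - cs) * w[:, None]).T @ (dst - cd)
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-12 * max(S[0], 1e-300):
        raise DegenerateGeometryError("collinear correspondence set")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return RigidTransform(R, cd - R @ cs)


def _lcp_score(tree_Q: cKDTree, P_sub: np.ndarray, T: RigidTransform,
               delta: float) -> int:
    d, _ = tree_Q.query(T.apply(P_sub), distance_upper_bound=delta)
    return int(np.sum(np.isfinite(d)))


def _up_angle_deg(T: RigidTransform, up_src: np.ndarray,
                  up_dst: np.ndarray) -> float:
    c = float(np.dot(T.rotation @ np.asarray(up_src, float),
                     np.asarray(up_dst, float)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def coarse_register(P: PointCloud, Q: PointCloud,
                    cfg: PipelineConfig | None = None,
                    up_prior: tuple | None = None) -> RegistrationResult:
    """Improved-4PCS coarse alignment of region P onto region Q.

    Over all (basis, congruent-candidate) pairs a rigid fit is scored by
    the LCP rule — the number of P points landing within ``lcp_delta``
    of Q — and the argmax transform is returned. Deterministic for a
    fixed ``cfg.seed``.

    ``up_prior`` is an optional rig-calibration constraint
    ``(up_in_P_frame, up_in_Q_frame, max_angle_deg)``: both sensors are
    rigidly mounted, so the vertical direction is known in each frame to
    within mounting tolerance, and candidate transforms that tilt it
    further than ``max_angle_deg`` are rejected. This suppresses the
    shell-on-shell failure mode where one quarter-shell view is rolled
    about the spine onto the other.
    """
    cfg = cfg or PipelineConfig()
    if len(P) < 4 or len(Q) < 4:
        raise RegistrationError("regions too small to register")
    rng = np.random.default_rng(cfg.seed)
    m = max_pair_length(P, cfg.overlap_estimate)
    bases = find_coplanar_bases(P, m, n_bases=cfg.n_bases, seed=cfg.seed,
                                coplanarity_tol=cfg.coplanarity_tol)
    # uniform subsample of Q for the congruent-pair search; full Q for scoring.
    # The match tolerance is widened by the subsample spacing h, otherwise a
    # congruent quadruple may have no representative at the coarser density.
    from .preprocess import voxel_downsample

    Q_sub = voxel_downsample(Q, 0.015)
    if len(Q_sub) > 1500:
        Q_sub = Q_sub.select(rng.choice(len(Q_sub), 1500, replace=False))
    d_nn, _ = cKDTree(Q_sub.points).query(Q_sub.points, k=2)
    h = float(np.median(d_nn[:, 1]))
    tol = cfg.congruence_tol + h
    # two scoring subsets: a uniform one for polishing, and one
    # stratified by curvature for the final LCP comparison — the smooth
    # back band is nearly invariant to sliding along the spine, so the
    # ear/tail features must carry enough scoring weight to reject
    # shifted alignments (the rationale of feature-guided 4PCS)
    if len(P) > 400:
        p_unif = rng.choice(len(P), 400, replace=False)
    else:
        p_unif = np.arange(len(P))
    P_unif = P.points[p_unif]
    if P.curvature is not None and len(P) > 400:
        order = np.argsort(-P.curvature)
        P_strat = P.points[np.concatenate(
            [order[:200], rng.choice(order[200:], 200, replace=False)])]
    else:
        P_strat = P_unif
    P_quick = P_unif[:: max(1, len(P_unif) // 80)]
    tree_Q = cKDTree(Q.points)

    best: tuple[int, RigidTransform] | None = None
    shortlist: list[tuple[int, RigidTransform]] = []
    for basis in bases:
        for quad in find_congruent_sets(Q_sub, basis, tol, max_candidates=300,
                                        max_pairs=6000, rng=rng):
            try:
                T = best_rigid_fit(basis.points, quad)
            except DegenerateGeometryError:
                continue
            shortlist.append((_lcp_score(tree_Q, P_quick, T, 2 * cfg.lcp_delta), T))
    if not shortlist:
        raise RegistrationError("coarse registration failed: no congruent sets")
    shortlist.sort(key=lambda st: -st[0])
    for _, T in shortlist[:40]:
        # local polish: the 4-point fit is only as good as the congruence
        # tolerance, so each finalist is tightened by gated rigid refits
        # (first wide, then tight) before the LCP comparison
        T = _polish(P_unif, tree_Q, Q.points, T, gate=3 * cfg.lcp_delta)
        T = _polish(P_unif, tree_Q, Q.points, T, gate=1.5 * cfg.lcp_delta)
        if up_prior is not None and _up_angle_deg(T, up_prior[0],
                                                 up_prior[1]) > up_prior[2]:
            continue
        score = _lcp_score(tree_Q, P_strat, T, cfg.lcp_delta)
        if best is None or score > best[0]:
            best = (score, T)
    if best is None:
        raise RegistrationError(
            "coarse registration failed: no candidate satisfies the up prior")
    score, T = best
    if score == 0:
        raise RegistrationError("coarse registration failed: zero LCP")
    log.info("coarse_register: LCP %d/%d over %d bases", score, len(P_strat),
             len(bases))
    rmse = registration_rmse(P, Q, T, gate=5 * cfg.lcp_delta)
    return RegistrationResult(transform=T, lcp_count=score, rmse_cm=rmse)


def _polish(P_sub: np.ndarray, tree_Q: cKDTree, Q_pts: np.ndarray,
            T: RigidTransform, gate: float, iters: int = 8) -> RigidTransform:
    for _ in range(iters):
        moved = T.apply(P_sub)
        d, j = tree_Q.query(moved, distance_upper_bound=gate)
        keep = np.isfinite(d)
        if keep.sum() < 4:
            return T
        try:
            T = best_rigid_fit(P_sub[keep], Q_pts[j[keep]])
        except DegenerateGeometryError:
            return T
    return T


def icp_refine(source_full: PointCloud, target_full: PointCloud,
               init: RigidTransform,
               cfg: PipelineConfig | None = None,
               feature_weight: float = 8.0) -> RegistrationResult:
    """Trimmed, gated, feature-weighted point-to-point ICP.

    Each iteration pairs every source point with its nearest target
    neighbor, keeps pairs inside an absolute distance gate (annealed
    from 4 cm down to 1.5 cm on a fixed schedule, so the non-overlap
    regions — far flank, belly, legs — drop out as alignment tightens),
    trims the worst ``icp_trim_fraction`` of the gated pairs, and refits
    the rigid transform. If the source cloud carries curvature, its M
    highest-curvature points (ears/tail) get ``feature_weight`` in the
    fit: the smooth back band constrains sliding along the spine only
    weakly, and the features pin that near-degenerate direction — the
    same rationale as the feature-guided coarse stage.
    """
    cfg = cfg or PipelineConfig()
    src = source_full.points
    weights = np.ones(len(src))
    if source_full.curvature is not None and feature_weight != 1.0:
        order = np.argsort(-source_full.curvature)
        weights[order[: min(cfg.M, len(src))]] = feature_weight
    if len(src) > 4000:
        pick = np.random.default_rng(cfg.seed).choice(len(src), 4000,
                                                      replace=False)
        src, weights = src[pick], weights[pick]
    tree = cKDTree(target_full.points)
    T = init
    prev_obj = np.inf
    iterations = 0
    # fixed annealing schedule: converging *at* a wide gate must be
    # avoided (the wide-gate fixed point is biased by rim attraction),
    # so wide gates get one iteration each on the way down
    schedule = [0.04 * 0.82 ** i for i in range(6)]
    tight = 1.5 * cfg.lcp_delta
    for iterations in range(1, cfg.icp_max_iter + 1):
        gate = schedule[iterations - 1] if iterations <= len(schedule) else tight
        moved = T.apply(src)
        d, j = tree.query(moved)
        inside = np.flatnonzero(d <= max(gate, tight))
        if inside.size < 4:
            raise RegistrationError("ICP: no correspondences within gate")
        order = inside[np.argsort(d[inside])]
        keep = order[: max(4, int(np.ceil(inside.size * (1 - cfg.icp_trim_fraction))))]
        obj = float(d[keep].mean())
        T = best_rigid_fit(src[keep], target_full.points[j[keep]], weights[keep])
        if iterations > len(schedule) and prev_obj - obj < cfg.icp_tol:
            prev_obj = min(prev_obj, obj)
            break
        prev_obj = obj
    rmse = registration_rmse(source_full, target_full, T, gate=0.1)
    log.info("icp_refine: %d iterations, objective %.4g m, rmse %.3f cm",
             iterations, prev_obj, rmse)
    return RegistrationResult(transform=T, rmse_cm=rmse, iterations=iterations)


def _level_to_up(T: RigidTransform, up_src, up_dst,
                 pivot: np.ndarray) -> RigidTransform:
    """Smallest rotation (about ``pivot``) making T map the rig vertical
    exactly onto the target frame's vertical."""
    v = T.rotation @ np.asarray(up_src, float)
    u = np.asarray(up_dst, float)
    axis = np.cross(v, u)
    s = np.linalg.norm(axis)
    c = float(v @ u)
    if s < 1e-12:
        return T
    axis /= s
    ang = np.arctan2(s, c)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    Rf = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)
    return RigidTransform(Rf, pivot - Rf @ pivot).compose(T)


def _translation_refine(src: np.ndarray, weights: np.ndarray,
                        tree_tgt: cKDTree, tgt: np.ndarray,
                        T: RigidTransform, gate: float = 0.015,
                        trim: float = 0.1, iters: int = 20,
                        tol: float = 1e-7) -> RigidTransform:
    """Gated ICP with the rotation frozen: a pure translation update per
    iteration, so leveled rotations cannot drift back."""
    prev = np.inf
    for _ in range(iters):
        moved = T.apply(src)
        d, j = tree_tgt.query(moved)
        inside = np.flatnonzero(d <= gate)
        if inside.size < 4:
            break
        order = inside[np.argsort(d[inside])]
        keep = order[: max(4, int(np.ceil(inside.size * (1 - trim))))]
        w = weights[keep] / weights[keep].sum()
        T = RigidTransform(T.rotation,
                           T.translation + w @ (tgt[j[keep]] - moved[keep]))
        obj = float(d[keep].mean())
        if prev - obj < tol:
            break
        prev = obj
    return T


def _mean_transform(Ts: list[RigidTransform], ws) -> RigidTransform:
    """Weighted chordal mean of rigid transforms (SVD-projected rotation)."""
    ws = np.asarray(ws, dtype=float)
    ws = ws / ws.sum()
    M = sum(w * T.rotation for w, T in zip(ws, Ts))
    U, _, Vt = np.linalg.svd(M)
    d = np.sign(np.linalg.det(U @ Vt))
    R = U @ np.diag([1.0, 1.0, d]) @ Vt
    t = sum(w * T.translation for w, T in zip(ws, Ts))
    return RigidTransform(R, t)


def register_views(side_cloud: PointCloud, top_cloud: PointCloud,
                   regions, cfg: PipelineConfig | None = None,
                   restarts: int = 6,
                   up_prior: tuple | None = None) -> RegistrationResult:
    """Full coarse + fine registration of the side view onto the top view.

    The 4PCS basis sampling is randomized, so the chain is run from up
    to ``restarts`` independent sampling seeds (stopping early once a
    draw is clearly good). With an ``up_prior`` (see
    :func:`coarse_register`) the rig-vertical consistency angle of each
    refined transform measures its residual error directly — the
    dominant failure mode tilts the vertical — so the final transform is
    the up-consistency argmin over the individual draws and their
    consensus (weighted chordal mean of the near-best draws), which
    averages out the independent per-draw scatter. Without a prior the
    draw with the highest feature-aware LCP wins. Deterministic for
    fixed ``cfg.seed``.
    """
    cfg = cfg or PipelineConfig()
    rng = np.random.default_rng(cfg.seed + 104729)
    pts = side_cloud.points
    if side_cloud.curvature is not None:
        order = np.argsort(-side_cloud.curvature)
        feat = pts[order[: min(cfg.M, len(pts))]]
    else:
        feat = pts[: min(cfg.M, len(pts))]
    unif = pts[rng.choice(len(pts), min(500, len(pts)), replace=False)]
    tree_top = cKDTree(top_cloud.points)

    draws: list[tuple[float, RegistrationResult]] = []
    failures = []
    for k in range(restarts):
        sub_cfg = cfg.replace(seed=cfg.seed + 1013 * k,
                              n_bases=cfg.n_bases if k % 2 == 0 else cfg.n_bases + 8)
        try:
            coarse = coarse_register(regions.source_P, regions.target_Q,
                                     sub_cfg, up_prior=up_prior)
            fine = icp_refine(side_cloud, top_cloud, coarse.transform, sub_cfg)
        except (RegistrationError, DegenerateGeometryError) as exc:
            failures.append(exc)
            continue
        fine.lcp_count = max(fine.lcp_count, coarse.lcp_count)
        if up_prior is None:
            quality = -(_lcp_score(tree_top, unif, fine.transform, cfg.lcp_delta)
                        + 2 * _lcp_score(tree_top, feat, fine.transform,
                                         cfg.lcp_delta))
        else:
            quality = _up_angle_deg(fine.transform, up_prior[0], up_prior[1])
            if quality > up_prior[2]:
                failures.append(RegistrationError("transform tilts the rig vertical"))
                continue
        draws.append((quality, fine))
        if up_prior is not None and quality <= 0.28:
            break
    if not draws:
        raise RegistrationError(f"all registration attempts failed: {failures}")
    draws.sort(key=lambda d: d[0])
    best = draws[0][1]
    if up_prior is not None and len(draws) > 1:
        near = [d for d in draws if d[0] <= max(1.0, 1.5 * draws[0][0])][:3]
        T_avg = _mean_transform([d[1].transform for d in near],
                                [1.0 / (0.2 + d[0]) for d in near])
        if _up_angle_deg(T_avg, up_prior[0], up_prior[1]) < draws[0][0]:
            rmse = registration_rmse(side_cloud, top_cloud, T_avg, gate=0.1)
            best = RegistrationResult(transform=T_avg, rmse_cm=rmse,
                                      lcp_count=best.lcp_count,
                                      iterations=best.iterations)
    if up_prior is not None:
        # rig-vertical leveling: the residual error mode is a roll about
        # the spine, which the calibrated vertical removes exactly; a
        # rotation-frozen gated refit then settles the translation
        T = best.transform
        pivot = T.apply(pts).mean(axis=0)
        T = _level_to_up(T, up_prior[0], up_prior[1], pivot)
        weights = np.ones(len(pts))
        if side_cloud.curvature is not None:
            order = np.argsort(-side_cloud.curvature)
            weights[order[: min(cfg.M, len(pts))]] = 8.0
        src, w = pts, weights
        if len(src) > 4000:
            pick = np.random.default_rng(cfg.seed).choice(len(src), 4000,
                                                          replace=False)
            src, w = src[pick], w[pick]
        T = _translation_refine(src, w, tree_top, top_cloud.points, T,
                                gate=1.5 * cfg.lcp_delta,
                                trim=cfg.icp_trim_fraction)
        best = RegistrationResult(
            transform=T,
            rmse_cm=registration_rmse(side_cloud, top_cloud, T, gate=0.1),
            lcp_count=best.lcp_count, iterations=best.iterations)
    log.info("register_views: %d draws, selected quality %.3f",
             len(draws), draws[0][0])
    return best


def registration_rmse(P: PointCloud, Q: PointCloud, T: RigidTransform,
                      gate: float = 0.1) -> float:
    """Mean nearest-neighbor distance (cm) of T(P) against Q within ``gate``.

    Defined as the average Euclidean distance between matched pairs —
    the registration-error convention of depth-sensor livestock studies
    (despite the customary "RMSE" name).
    """
    if len(P) == 0 or len(Q) == 0:
        raise InvalidInputError("empty cloud")
    d, _ = cKDTree(Q.points).query(T.apply(P.points), distance_upper_bound=gate)
    d = d[np.isfinite(d)]
    if d.size == 0:
        raise RegistrationError("no point pairs within gate; rmse undefined")
    return float(d.mean() * 100.0)
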