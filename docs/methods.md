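# Methods

`girthkit` measures the heart girth of a pig — the vertical chest
circumference just behind the forelimbs — from two depth-sensor views
(one above the weigh channel, one beside it). This note documents the
model assumptions, the algorithmic choices where the design was open,
the synthetic study conditions, and the known limitations.

## Pipeline model

1. **Foreground extraction.** Background differencing on the depth
   image (threshold 80 mm, above sensor noise and below the
   animal-to-background standoff), pinhole back-projection, pass-through
   cropping, voxel-grid downsampling (8 mm, centroid per cell), dynamic
   outlier removal (drop points whose mean k-NN distance exceeds
   μ + ασ of the cloud's own distribution; k = 8, α = 2), Euclidean
   clustering (tolerance 4 cm) keeping the largest cluster, and a
   density-based boundary trim (drop points whose neighbor count within
   2 voxels falls below 30% of the cloud median) that replaces manual
   editing of railing-occlusion fringes.

2. **Registration regions.** The two views overlap only on the upper
   near-side quarter of the body, so registration is restricted to
   informative regions. Source region P: the dorsal quarter of the side
   view (its back band is the one structure guaranteed to reappear in
   the top view) plus the M = 500 highest-curvature points — the ears
   and tail, whose PCA surface-variation curvature
   (λ_min / (λ1 + λ2 + λ3), k = 16 neighborhoods) is far above the
   torso's. Target region Q: the half of the top view facing the side
   sensor, split per body third (hip/trunk/head) along per-segment
   principal axes so a bent spine still splits correctly.

3. **Coarse registration (4-point congruent sets).** Coplanar
   four-point bases with span m = overlap × bbox-diagonal are sampled
   from P (randomized with a budget; exhaustive enumeration is O(N⁴)).
   Each basis carries affine-invariant cross-ratios r1, r2 of its
   segment intersection; congruent quadruples in Q are found by
   matching pair distances and intersection points within a tolerance
   widened by the subsample spacing. Candidates are scored by the
   largest-common-pointset rule (P points within δ = 1 cm of Q).
   Three additions proved necessary and are part of this package's
   design:
   - each finalist is polished by gated rigid refits (3 cm then 1.5 cm
     gates) before comparison — a raw 4-point fit is only as accurate
     as the ~2 cm congruence tolerance;
   - the final LCP sample is stratified by curvature (half ear/tail
     points) so spine-slid alignments, to which the smooth back band is
     nearly invariant, lose;
   - a rig prior rejects transforms that tilt the known vertical by
     more than 10°: both sensors are rigidly mounted, and the dominant
     failure mode — one quarter-shell rolled onto the other about the
     spine — tilts the mapped vertical directly.

4. **Fine registration (ICP).** Point-to-point ICP on the full view
   clouds with three robustness measures tuned for ~35% true overlap:
   an absolute correspondence gate annealed 4 cm → 1.5 cm on a *fixed*
   schedule (iterating to convergence at a wide gate has a biased fixed
   point: points past the target's coverage rim drag the fit), 10%
   trimming inside the gate, and weight 8 on the M highest-curvature
   source points (the band constrains sliding along the spine only
   weakly; the features pin it). The chain is restarted from up to six
   basis-sampling seeds; the transform with the best rig-vertical
   consistency wins, and a chordal-mean consensus of the near-best
   draws is used when it is more consistent still — per-draw errors are
   nearly independent, so averaging cancels much of the scatter.

5. **Pose normalization.** Centroid at the origin, vertical x from the
   top sensor's viewing axis (rig geometry; PCA shortest axis as
   fallback), spine z as the dominant horizontal principal direction.
   The head gets +z: among the highest-curvature points, the head end
   shows a larger *lateral spread about its own center* (two ears off
   the midline) than the tail end (one on-axis protrusion) — a statistic
   robust to a bent spine, unlike raw counts. Points below the centroid
   are excluded so legs cannot vote.

6. **Measurement point.** Within a front-body window (0–45% of body
   length ahead of the centroid; wide enough that the hoof-to-belly
   tangent is shallower than the rasterized hoof corner slopes), the
   lowest point is the front hoof T_A. A line through T_A is rotated
   from horizontal until tangent to the body contour (occupancy-grid
   silhouette at 1 cm cells; tangency candidates must sit at least 20%
   of the contour height above the hoof so the leg's own silhouette is
   skipped), then translated toward the tail; the last contact with the
   ventral contour between the tangency point and the hoof is the
   axillary point B1. Both steps are closed-form argmax operations over
   contour vertices — mathematically the line rotation/translation at
   vertex resolution, but deterministic.

7. **Slice, mirror, geodesics.** A 2 cm slab at z(B1) is projected onto
   the measurement plane; a connected-component filter drops forelimb
   fragments. The slab is re-centered on the sagittal plane estimated
   from the dorsal crown's lateral midrange — the centroid of a fused
   cloud missing one flank sits a few centimeters off the true
   mid-plane, and mirroring about the wrong plane biases the girth by
   several percent. Mirror reflection across that plane completes the
   ~3/4 ring. Anchors B2/B3 sit on the back surface ±10 cm laterally
   from the mid-plane; B1 is inserted as an explicit ventral-midline
   node. The circumference is the sum of the three geodesics
   B1→B2→B3→B1 over a symmetrized k-NN graph (k = 8, Euclidean
   weights, in-plane 8 mm averaging to suppress noise-induced path
   zigzag), each restricted to its angular sector and validated to be
   pairwise edge-disjoint (on failure the graph is rebuilt with doubled
   k). Ring-closure edges between angular neighbors bridge the
   underside sector that faces away from both sensors; the chord across
   that blind sector is the intended completion approximation. The
   shortest paths use a textbook Dijkstra (binary heap) written in this
   package; scipy's all-pairs routines serve only as test oracles.

## Synthetic study conditions

The generator emulates a market-weight pig (length 1.2 m, girth
~100 cm): elliptical cross-sections (0.30 × 0.34 m) with a longitudinal
stoutness profile (shoulder and rump bulges ±5%, a slight waist, a
narrowing neck — without it the torso is slide-symmetric along the
spine, which no real pig is, and the registration problem becomes
unidentifiable), a Gaussian axillary depression (18% radial, σ_z =
4 cm) just behind the forelegs, four stout near-cylindrical legs, two
elongated sharp ear flaps, a thin tail, and a 3% wider right flank
(real pigs are not perfectly bilateral; this is what limits
mirror-symmetry completion, and a symmetric phantom would make the
single-view comparison vacuous). Ground-truth girth is the densely
integrated perimeter of the analytic section at the axilla
(2 × 10⁵-gon; converged well below 0.01%).

Scans are rendered by spherical-flip hidden-point removal from each
sensor position (top camera 1.55 m above the channel; side camera at
0.50 m height, 1.05 m away — proportions follow a fixed weigh-channel
rig), with 2 mm Gaussian sensor noise by default (5 mm in the
registration stress experiments), railing-style occlusion stripes cut
from the side view at fixed rig positions, and 16 000 surface samples
per animal (roughly a decimated depth frame). True overlap between the
views is ~36% of the side cloud.

Problem sizes in the tests and the acceptance script (20 registration
scans, 20 measurement-point pigs, 10 end-to-end pigs, 3 degradation
pigs, 100 oracle graphs) were chosen so every experiment re-runs from
scratch in minutes on one CPU.

What the phantom does **not** model: articulated gait (only a static
mid-body bend up to 20°), skin folds and hair, depth-dependent and
correlated sensor noise, multi-path artifacts at the railing edges, and
truly free pig posture. Passing these experiments therefore shows the
chain is correct and robust under controlled geometry, not that field
accuracy on live animals is guaranteed.

## Numerical choices and degenerate inputs

- Segment intersection for the cross-ratios uses the closest-approach
  midpoint (noisy 3-D segments never cross exactly), gated at 1 cm, and
  requires the crossing interior to both segments.
- Kabsch fits correct reflections (det = +1) and reject collinear
  correspondence sets.
- Curvature of a degenerate (zero-spread) neighborhood is 0.
- Ties in the top-M curvature selection break by input order; the hoof
  minimum breaks ties by min z then min y; both make runs reproducible.
- Empty clouds, all-zero depth frames, inverted pass-through ranges,
  spherical (spine-less) clouds, one-sided slices and unreachable graph
  vertices all raise typed errors rather than returning garbage.
- All randomized stages (basis sampling, subsampling, restarts) derive
  from a single integer seed; fixed seed ⇒ identical results.

## Known limitations

- With 5 mm noise on both views and only the upper-quarter band
  overlapping, rotations about the spine of 2–5° score within noise of
  the truth under any point-distance criterion; the rig-vertical prior
  is what keeps the worst case near 1°/1 cm. A rig without a trusted
  vertical would need calibration spheres or denser cross-view
  features.
- The underside of the chest is invisible to both sensors; the girth
  there is a chord approximation (≲0.3% of the circumference for the
  observed 30–40° blind sector).
- Mirror completion transfers the near flank to the far side; the
  residual girth bias equals the animal's true asymmetry over the
  completed arc (≈0.5–1% at the default 3% asymmetry), consistent with
  the completed-side errors the two-sensor setup is designed to
  minimize.
- The measurement-point construction assumes the forelegs touch the
  ground and the axilla lies behind them; a leg lifted mid-stride can
  defeat the tangent construction (detected and reported as a frame
  failure, which the batch driver excludes from the per-animal mean).
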