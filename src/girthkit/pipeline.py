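"""End-to-end orchestration: preprocess -> regions -> register -> measure.

Batch driver over paired top/side captures of one animal: frames are
paired by nearest timestamp, every pair runs the full chain, failed
frames are logged and excluded, and the per-animal heart girth is the
mean over the successful frames.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import features, girth, preprocess, register
from .io import depth_to_cloud
from .synthpig import RIG_UP_IN_SIDE_FRAME, RIG_UP_IN_TOP_FRAME
from .types import (DepthFrame, GirthKitError, InvalidInputError,
                    PipelineConfig, PointCloud)

log = logging.getLogger("girthkit")

__all__ = ["FrameResult", "FrameSetResult", "pair_frames",
           "process_pair", "run_pipeline"]

# vertical direction of the rig expressed in each sensor frame, and the
# mounting tolerance (degrees) allowed when using it as a registration prior
RIG_UP_PRIOR = (RIG_UP_IN_SIDE_FRAME, RIG_UP_IN_TOP_FRAME, 10.0)


@dataclass
class FrameResult:
    index: int
    girth: girth.GirthResult = None
    registration: register.RegistrationResult = None
    error: str = ""

    @property
    def ok(self) -> bool:
        return self.girth is not None


@dataclass
class FrameSetResult:
    """Per-frame results and the per-animal aggregate."""

    frames: list = field(default_factory=list)
    mean_girth_cm: float = float("nan")
    failures: dict = field(default_factory=dict)   # stage -> count

    @property
    def n_ok(self) -> int:
        return sum(f.ok for f in self.frames)


def pair_frames(top_frames: list, side_frames: list,
                tolerance_s: float = 0.05) -> list[tuple]:
    """Match top and side frames by nearest timestamp within tolerance."""
    pairs = []
    side_ts = np.array([f.timestamp for f in side_frames])
    used = set()
    for tf in top_frames:
        if len(side_ts) == 0:
            break
        j = int(np.argmin(np.abs(side_ts - tf.timestamp)))
        if abs(side_ts[j] - tf.timestamp) <= tolerance_s and j not in used:
            pairs.append((tf, side_frames[j]))
            used.add(j)
    if not pairs:
        raise InvalidInputError("no frame pairs within the timestamp tolerance")
    return pairs


def process_pair(top: PointCloud | DepthFrame, side: PointCloud | DepthFrame,
                 cfg: PipelineConfig | None = None,
                 preprocessed: bool = False) -> FrameResult:
    """Run the full measurement chain on one top/side capture pair.

    Inputs may be depth frames (converted through the pinhole model) or
    point clouds in their sensor frames. Set ``preprocessed=True`` when
    the clouds are already clean single-pig clouds (skips clustering).
    """
    cfg = cfg or PipelineConfig()
    if isinstance(top, DepthFrame):
        top = depth_to_cloud(top)
    if isinstance(side, DepthFrame):
        side = depth_to_cloud(side)
    result = FrameResult(index=-1)
    stage = "preprocess"
    try:
        if preprocessed:
            top_c = preprocess.voxel_downsample(top, cfg.voxel_size)
            side_c = preprocess.voxel_downsample(side, cfg.voxel_size)
        else:
            top_c, side_c = preprocess.extract_pig(top, side, cfg)
        stage = "regions"
        side_c = features.curvature_pca(side_c, cfg.curvature_k)
        regions = features.build_regions(side_c, top_c, cfg)
        stage = "register"
        reg = register.register_views(side_c, top_c, regions, cfg,
                                      up_prior=RIG_UP_PRIOR)
        fused_pts = np.vstack([top_c.points,
                               reg.transform.apply(side_c.points)])
        fused = PointCloud(fused_pts, frame_label="registered")
        stage = "normalize"
        normalized, _ = girth.pose_normalize(fused,
                                             up_hint=RIG_UP_IN_TOP_FRAME)
        stage = "measure"
        result.girth = girth.measure_heart_girth(normalized, cfg)
        result.registration = reg
    except GirthKitError as exc:
        result.error = f"{stage}: {exc}"
        log.warning("frame failed at %s: %s", stage, exc)
    return result


def run_pipeline(top_inputs: list, side_inputs: list,
                 cfg: PipelineConfig | None = None,
                 preprocessed: bool = False) -> FrameSetResult:
    """Measure one animal from paired lists of captures.

    Depth-frame inputs are paired by timestamp; point-cloud inputs are
    paired positionally. A frame failure never aborts the batch — the
    animal's girth is the mean over the successful frames, and the
    failure log records which stage rejected each failed frame.
    """
    cfg = cfg or PipelineConfig()
    if len(top_inputs) == 0 or len(top_inputs) != len(side_inputs):
        raise InvalidInputError("need equal-length, nonempty input lists")
    if top_inputs and isinstance(top_inputs[0], DepthFrame):
        pairs = pair_frames(top_inputs, side_inputs, cfg.pairing_tolerance_s)
    else:
        pairs = list(zip(top_inputs, side_inputs))

    out = FrameSetResult()
    for i, (t, s) in enumerate(pairs):
        fr = process_pair(t, s, cfg, preprocessed=preprocessed)
        fr.index = i
        out.frames.append(fr)
        if not fr.ok:
            stage = fr.error.split(":", 1)[0]
            out.failures[stage] = out.failures.get(stage, 0) + 1
    girths = [f.girth.girth_cm for f in out.frames if f.ok]
    if girths:
        out.mean_girth_cm = float(np.mean(girths))
    log.info("run_pipeline: %d/%d frames ok, mean girth %.1f cm",
             out.n_ok, len(pairs), out.mean_girth_cm)
    return out
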