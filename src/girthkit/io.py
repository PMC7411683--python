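"""File and sensor I/O: depth images, point clouds, configuration.

Depth images are 16-bit single-channel PNGs in millimeters (a common
depth-camera dialect). PLY is the canonical on-disk cloud format (ASCII
and binary little-endian, via trimesh); PCD support is a best-effort
ASCII-only reader/writer. Configuration files are flat YAML key/value
mappings mirroring :class:`~girthkit.types.PipelineConfig`.
"""

from __future__ import annotations

import logging
import os
from dataclasses import fields

import numpy as np
import trimesh
import yaml

from .types import (DepthFrame, InvalidInputError, PipelineConfig, PointCloud)

log = logging.getLogger("girthkit")

__all__ = [
    "depth_to_cloud",
    "read_cloud",
    "write_cloud",
    "read_depth_png",
    "write_depth_png",
    "load_config",
    "save_config",
]


def depth_to_cloud(frame: DepthFrame, frame_label: str | None = None) -> PointCloud:
    """Back-project a depth frame through the pinhole model.

    Every pixel with depth > 0 becomes one point::

        x = (u - cx) * z / fx,   y = (v - cy) * z / fy,   z = depth

    with the millimeter depth converted to meters. An all-zero frame
    yields an empty cloud.
    """
    v, u = np.nonzero(frame.depth > 0)
    z = frame.depth[v, u] / 1000.0
    x = (u - frame.cx) * z / frame.fx
    y = (v - frame.cy) * z / frame.fy
    label = frame_label or f"sensor_{frame.view_label}"
    cloud = PointCloud(np.column_stack([x, y, z]), frame_label=label)
    log.debug("depth_to_cloud[%s]: %d/%d pixels valid", frame.view_label,
              len(cloud), frame.depth.size)
    return cloud


# ---------------------------------------------------------------------------
# point-cloud files

def write_cloud(cloud: PointCloud, path: str, binary: bool = True) -> None:
    """Write PLY (binary little-endian by default, or ASCII) or ASCII PCD."""
    ext = os.path.splitext(path)[1].lower()
    if ext == ".ply":
        if len(cloud) == 0:
            # trimesh rejects empty vertex arrays; write the header directly
            fmt = "binary_little_endian" if binary else "ascii"
            with open(path, "wb") as fh:
                fh.write((f"ply\nformat {fmt} 1.0\nelement vertex 0\n"
                          "property float x\nproperty float y\nproperty float z\n"
                          "end_header\n").encode())
            return
        pc = trimesh.PointCloud(cloud.points)
        pc.export(path, encoding="binary_little_endian" if binary else "ascii")
    elif ext == ".pcd":
        _write_pcd_ascii(cloud, path)
    else:
        raise InvalidInputError(f"unsupported cloud format: {ext!r}")


def read_cloud(path: str, frame_label: str = "sensor_top") -> PointCloud:
    """Read a PLY or ASCII PCD point cloud."""
    ext = os.path.splitext(path)[1].lower()
    if ext == ".ply":
        try:
            obj = trimesh.load(path, process=False)
        except Exception as exc:  # malformed header / truncated body
            raise InvalidInputError(f"cannot parse PLY {path!r}: {exc}") from exc
        verts = np.asarray(obj.vertices, dtype=float) if hasattr(obj, "vertices") else np.zeros((0, 3))
        return PointCloud(verts, frame_label=frame_label)
    if ext == ".pcd":
        return _read_pcd_ascii(path, frame_label)
    raise InvalidInputError(f"unsupported cloud format: {ext!r}")


def _write_pcd_ascii(cloud: PointCloud, path: str) -> None:
    n = len(cloud)
    header = ("# .PCD v0.7 - Point Cloud Data file format\nVERSION 0.7\n"
              "FIELDS x y z\nSIZE 4 4 4\nTYPE F F F\nCOUNT 1 1 1\n"
              f"WIDTH {n}\nHEIGHT 1\nVIEWPOINT 0 0 0 1 0 0 0\n"
              f"POINTS {n}\nDATA ascii\n")
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, cloud.points.astype(np.float32), fmt="%.7g")


def _read_pcd_ascii(path: str, frame_label: str) -> PointCloud:
    with open(path, "rb") as fh:
        raw = fh.read()
    lines = raw.decode("latin-1").splitlines()
    n = None
    data_at = None
    offset = 0
    cols = ["x", "y", "z"]
    for i, line in enumerate(lines):
        if line.startswith("FIELDS"):
            cols = line.split()[1:]
        elif line.startswith("POINTS"):
            n = int(line.split()[1])
        elif line.startswith("DATA"):
            if line.split()[1] != "ascii":
                raise InvalidInputError(
                    f"PCD parse error at byte {offset}: only ASCII data supported")
            data_at = i + 1
            break
        offset += len(line) + 1
    if n is None or data_at is None:
        raise InvalidInputError(f"PCD parse error at byte {offset}: incomplete header")
    try:
        body = np.loadtxt(lines[data_at:data_at + n], dtype=float, ndmin=2)
    except ValueError as exc:
        raise InvalidInputError(f"PCD parse error at byte {offset}: {exc}") from exc
    if body.size == 0:
        return PointCloud(np.zeros((0, 3)), frame_label=frame_label)
    ix = [cols.index(c) for c in ("x", "y", "z")]
    return PointCloud(body[:, ix], frame_label=frame_label)


# ---------------------------------------------------------------------------
# depth images

def write_depth_png(frame: DepthFrame, path: str) -> None:
    """Store a depth frame as 16-bit single-channel PNG (millimeters)."""
    import imageio.v3 as iio

    depth = np.clip(np.round(frame.depth), 0, 65535).astype(np.uint16)
    iio.imwrite(path, depth)


def read_depth_png(path: str, fx: float, fy: float, cx: float, cy: float,
                   view_label: str = "top", timestamp: float = 0.0) -> DepthFrame:
    """Load a 16-bit depth PNG; intrinsics must be supplied per rig."""
    import imageio.v3 as iio

    depth = iio.imread(path)
    if depth.ndim == 3:
        depth = depth[..., 0]
    return DepthFrame(depth.astype(float), fx=fx, fy=fy, cx=cx, cy=cy,
                      view_label=view_label, timestamp=timestamp)


# ---------------------------------------------------------------------------
# configuration

def save_config(cfg: PipelineConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def load_config(path: str) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise InvalidInputError(f"unknown config keys: {sorted(unknown)}")
    if "front_window" in raw:
        raw["front_window"] = tuple(raw["front_window"])
    return PipelineConfig(**raw)
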