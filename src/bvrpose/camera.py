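"""Calibrated pinhole x-ray projectors.

A camera is its 3x4 projection matrix ``P`` mapping homogeneous world
millimetres to homogeneous pixel coordinates ``(u, v, w)``; ``u`` is the
column (image x, rightward), ``v`` the row (image y, downward).  Pixel
centres sit at integer coordinates, 0-based.  ``P`` is normalised on
construction so that the third row of its left 3x3 block is a unit vector
and positive depth ``w`` means "in front of the source".
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np


@dataclass(frozen=True)
class CameraModel:
    projection: np.ndarray
    image_size: tuple  # (rows, cols)

    def __post_init__(self) -> None:
        p = np.asarray(self.projection, float).reshape(3, 4)
        m = p[:3, :3]
        if abs(np.linalg.det(m)) < 1e-12:
            raise ValueError("degenerate projection matrix")
        # normalise: ||m3|| = 1 and det(M) > 0 so w is a signed depth
        scale = np.linalg.norm(m[2])
        p = p / scale
        if np.linalg.det(p[:3, :3]) < 0:
            p = -p
        p.setflags(write=False)
        object.__setattr__(self, "projection", p)
        object.__setattr__(self, "image_size", tuple(int(s) for s in self.image_size))

    @property
    def source(self) -> np.ndarray:
        """Camera centre (x-ray source position, world mm): null space of P."""
        m = self.projection[:3, :3]
        return -np.linalg.solve(m, self.projection[:3, 3])

    @property
    def principal_point(self) -> np.ndarray:
        """(u, v) where the principal ray meets the detector."""
        m = self.projection[:3, :3]
        uvw = m @ m[2]
        return uvw[:2] / uvw[2]

    def project(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Project world points to pixel (u, v).

        Returns ``(uv, behind)`` where ``behind`` flags points at or behind
        the source plane (non-positive depth), for which uv is NaN.
        """
        pts = np.atleast_2d(np.asarray(points, float))
        h = pts @ self.projection[:, :3].T + self.projection[:, 3]
        w = h[:, 2]
        behind = w <= 1e-12
        uv = np.full((len(pts), 2), np.nan)
        ok = ~behind
        uv[ok] = h[ok, :2] / w[ok, None]
        if np.asarray(points).ndim == 1:
            return uv[0], bool(behind[0])
        return uv, behind

    def ray_directions(self, uv: np.ndarray) -> np.ndarray:
        """Unit world directions of the rays through pixel centres ``uv``,
        oriented from the source toward the detector."""
        uv = np.atleast_2d(np.asarray(uv, float))
        m = self.projection[:3, :3]
        d = np.linalg.solve(m, np.column_stack([uv, np.ones(len(uv))]).T).T
        # depth of source + d is m3 . d = 1 > 0 by construction of solve with
        # homogeneous (u, v, 1); already front-facing
        return d / np.linalg.norm(d, axis=1, keepdims=True)

    def resize(self, new_size: tuple) -> "CameraModel":
        """Camera for the same physical detector sampled at another grid.

        Uses the pixel-centre mapping ``u' = (u + 0.5) * s - 0.5`` per axis.
        """
        rows, cols = self.image_size
        nr, nc = int(new_size[0]), int(new_size[1])
        sr, sc = nr / rows, nc / cols
        s = np.array(
            [[sc, 0.0, (sc - 1) / 2.0], [0.0, sr, (sr - 1) / 2.0], [0.0, 0.0, 1.0]]
        )
        return CameraModel(s @ self.projection, (nr, nc))

    def decimate(self, factor: int) -> "CameraModel":
        """Camera whose pixel centres coincide with the native pixels kept
        by nearest-neighbour decimation (output pixel ``i`` reads native
        pixel ``factor*i + factor//2``)."""
        factor = int(factor)
        rows, cols = self.image_size
        if rows % factor or cols % factor:
            raise ValueError("decimation factor must divide the image size")
        off = factor // 2
        s = np.array(
            [
                [1.0 / factor, 0.0, -off / factor],
                [0.0, 1.0 / factor, -off / factor],
                [0.0, 0.0, 1.0],
            ]
        )
        return CameraModel(s @ self.projection, (rows // factor, cols // factor))


def project_point(camera: CameraModel, world_point: np.ndarray):
    """Single-point convenience wrapper around :meth:`CameraModel.project`."""
    return camera.project(np.asarray(world_point, float))


def make_camera(
    source: np.ndarray,
    look_at: np.ndarray,
    up: np.ndarray,
    image_size: tuple,
    pixel_pitch_mm: float,
    source_to_detector_mm: float,
) -> CameraModel:
    """Pinhole camera whose principal ray runs from ``source`` through
    ``look_at``; image rows increase opposite to ``up``."""
    source = np.asarray(source, float)
    z = np.asarray(look_at, float) - source
    z = z / np.linalg.norm(z)
    up = np.asarray(up, float)
    x = np.cross(z, up)
    nx = np.linalg.norm(x)
    if nx < 1e-12:
        raise ValueError("up vector parallel to viewing direction")
    x /= nx
    y = np.cross(z, x)  # points "down" in the image
    rows, cols = image_size
    f = source_to_detector_mm / pixel_pitch_mm  # focal length in pixels
    k = np.array(
        [[f, 0.0, (cols - 1) / 2.0], [0.0, f, (rows - 1) / 2.0], [0.0, 0.0, 1.0]]
    )
    r = np.vstack([x, y, z])
    p = k @ np.column_stack([r, -r @ source])
    return CameraModel(p, (rows, cols))


# ---------------------------------------------------------------------------
# Calibration files
# ---------------------------------------------------------------------------
# Dialect A: 3 lines x 4 numbers = the projection matrix (world mm -> px).
# Dialect B: "key = value" lines with explicit geometry, converted on read:
#   source, look_at, up (3 numbers each), rows, cols, pixel_pitch_mm,
#   source_to_detector_mm.

def write_calibration(path: str | Path, camera: CameraModel) -> None:
    lines = [f"# 3x4 projection matrix, world mm -> pixels; image {camera.image_size}"]
    for row in camera.projection:
        lines.append(" ".join(f"{v:.17g}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_calibration(path: str | Path, image_size: tuple | None = None) -> CameraModel:
    text = Path(path).read_text()
    body = [
        ln.strip()
        for ln in text.splitlines()
        if ln.strip() and not ln.strip().startswith("#")
    ]
    if any("=" in ln for ln in body):
        kv = {}
        for ln in body:
            key, val = ln.split("=", 1)
            kv[key.strip()] = np.array([float(v) for v in val.replace(",", " ").split()])
        size = (int(kv["rows"][0]), int(kv["cols"][0]))
        return make_camera(
            kv["source"],
            kv["look_at"],
            kv["up"],
            size,
            float(kv["pixel_pitch_mm"][0]),
            float(kv["source_to_detector_mm"][0]),
        )
    vals = np.array([float(v) for ln in body for v in ln.split()])
    if vals.size != 12:
        raise ValueError("calibration matrix must contain 12 numbers")
    if image_size is None:
        # files written by write_calibration carry the size in the header
        m = re.search(r"image \((\d+), (\d+)\)", text)
        if m is None:
            raise ValueError("image_size required for matrix-dialect calibration")
        image_size = (int(m.group(1)), int(m.group(2)))
    return CameraModel(vals.reshape(3, 4), image_size)
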