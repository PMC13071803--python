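"""Digitally reconstructed radiographs by fixed-step ray marching.

Each pixel of a DRR is the line integral of linear attenuation along the ray
from the x-ray source through that pixel centre.  Rays are clipped to the
posed volume's bounding box and sampled every ``step_mm`` (midpoint rule)
with trilinear interpolation; samples outside the grid contribute zero.
Only pixels inside the projected bounding box of the posed volume are cast —
all other rays miss the volume by construction and are left at zero.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .camera import CameraModel
from .geometry import RigidTransform
from .volume import VoxelVolume


@njit(cache=True, fastmath=True)
def _integrate_rays(vol, src, dirs, step, t_lo, t_hi, out):  # pragma: no cover
    # `vol` is the volume zero-padded by one voxel on every face and `src`
    # is expressed in padded-index coordinates, so rays are clipped to
    # [0.5, dim - 1.5] per axis (the original sampling box) and trilinear
    # interpolation never needs bounds checks.
    ni, nj, nk = vol.shape
    n_rays = dirs.shape[0]
    for r in range(n_rays):
        dx, dy, dz = dirs[r, 0], dirs[r, 1], dirs[r, 2]
        t0 = t_lo
        t1 = t_hi
        for ax in range(3):
            d = dirs[r, ax]
            o = src[ax]
            if ax == 0:
                hi = ni - 1.5
            elif ax == 1:
                hi = nj - 1.5
            else:
                hi = nk - 1.5
            lo = 0.5
            if abs(d) < 1e-12:
                if o < lo or o > hi:
                    t0 = 1.0
                    t1 = 0.0
                    break
            else:
                ta = (lo - o) / d
                tb = (hi - o) / d
                if ta > tb:
                    ta, tb = tb, ta
                if ta > t0:
                    t0 = ta
                if tb < t1:
                    t1 = tb
        if t1 <= t0:
            out[r] = 0.0
            continue
        acc = 0.0
        t = t0 + 0.5 * step
        while t < t1:
            x = src[0] + t * dx
            y = src[1] + t * dy
            z = src[2] + t * dz
            i0 = int(x)
            j0 = int(y)
            k0 = int(z)
            fx = x - i0
            fy = y - j0
            fz = z - k0
            c00 = vol[i0, j0, k0] * (1 - fz) + vol[i0, j0, k0 + 1] * fz
            c01 = vol[i0, j0 + 1, k0] * (1 - fz) + vol[i0, j0 + 1, k0 + 1] * fz
            c10 = vol[i0 + 1, j0, k0] * (1 - fz) + vol[i0 + 1, j0, k0 + 1] * fz
            c11 = vol[i0 + 1, j0 + 1, k0] * (1 - fz) + vol[i0 + 1, j0 + 1, k0 + 1] * fz
            c0 = c00 * (1 - fy) + c01 * fy
            c1 = c10 * (1 - fy) + c11 * fy
            acc += c0 * (1 - fx) + c1 * fx
            t += step
        out[r] = acc * step


def _padded_intensities(volume: VoxelVolume) -> np.ndarray:
    """Volume array zero-padded by one voxel per face, cached on the volume
    (the grid is immutable in practice; rendering reuses it heavily)."""
    cached = getattr(volume, "_padded_cache", None)
    if cached is not None and cached.shape == tuple(s + 2 for s in volume.shape):
        return cached
    padded = np.zeros(
        tuple(s + 2 for s in volume.shape), dtype=np.float32
    )
    padded[1:-1, 1:-1, 1:-1] = volume.intensities
    volume._padded_cache = padded
    return padded


def _world_to_index_affine(volume: VoxelVolume, pose: RigidTransform):
    """Affine (L, b) with index = L @ world + b for the posed volume."""
    dinv = np.diag(1.0 / volume.spacing)
    l = dinv @ volume.direction.T @ pose.rotation.T
    b = dinv @ volume.direction.T @ (
        pose.rotation.T @ (-pose.translation) - volume.origin
    )
    return l, b


def projected_bbox(
    volume: VoxelVolume, pose: RigidTransform, camera: CameraModel, pad: int = 1
):
    """Pixel bounding box (r0, r1, c0, c1), half-open, of the posed volume's
    projected corners, clipped to the image.  None if fully outside/behind."""
    corners = pose.apply(volume.world_corners())
    uv, behind = camera.project(corners)
    if np.any(behind):
        # conservative: cast the whole image when clipping is ill-defined
        return (0, camera.image_size[0], 0, camera.image_size[1])
    rows, cols = camera.image_size
    c0 = int(np.floor(uv[:, 0].min())) - pad
    c1 = int(np.ceil(uv[:, 0].max())) + pad + 1
    r0 = int(np.floor(uv[:, 1].min())) - pad
    r1 = int(np.ceil(uv[:, 1].max())) + pad + 1
    r0, r1 = max(r0, 0), min(r1, rows)
    c0, c1 = max(c0, 0), min(c1, cols)
    if r0 >= r1 or c0 >= c1:
        return None
    return (r0, r1, c0, c1)


def camera_ray_grid(camera: CameraModel) -> np.ndarray:
    """(rows, cols, 3) unit world ray directions through every pixel centre.

    Useful as a cache when many DRRs are rendered through the same camera
    (the registration loop); :func:`render_drr` accepts it via ``ray_grid``.
    """
    rows, cols = camera.image_size
    vv, uu = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    uv = np.column_stack([uu.ravel(), vv.ravel()]).astype(float)
    return camera.ray_directions(uv).reshape(rows, cols, 3)


def render_drr(
    volume: VoxelVolume,
    pose: RigidTransform,
    camera: CameraModel,
    step_mm: float | None = None,
    ray_grid: np.ndarray | None = None,
    bbox: tuple | None = None,
) -> np.ndarray:
    """Line-integral radiograph of ``volume`` at ``pose`` through ``camera``.

    ``step_mm`` defaults to half the smallest voxel spacing.  ``bbox``
    optionally overrides the cast region (half-open ``(r0, r1, c0, c1)``).
    """
    if step_mm is None:
        step_mm = 0.5 * float(volume.spacing.min())
    if step_mm <= 0:
        raise ValueError("step_mm must be positive")
    rows, cols = camera.image_size
    image = np.zeros((rows, cols))
    if bbox is None:
        bbox = projected_bbox(volume, pose, camera)
    if bbox is None:
        return image
    r0, r1, c0, c1 = bbox

    l, b = _world_to_index_affine(volume, pose)
    src_idx = l @ camera.source + b

    if ray_grid is not None:
        dirs_world = ray_grid[r0:r1, c0:c1].reshape(-1, 3)
    else:
        vv, uu = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
        uv = np.column_stack([uu.ravel(), vv.ravel()]).astype(float)
        dirs_world = camera.ray_directions(uv)  # unit, mm
    dirs_idx = dirs_world @ l.T  # index displacement per mm along the ray

    # generous world-distance window; slab clipping tightens it per ray
    diag = np.linalg.norm(
        np.array(volume.shape) * volume.spacing
    )
    centre_world = pose.apply(volume.index_to_world((np.array(volume.shape) - 1) / 2.0))
    dist = np.linalg.norm(centre_world - camera.source)
    t_lo = max(dist - diag, 0.0)
    t_hi = dist + diag

    out = np.empty(len(dirs_world))
    _integrate_rays(
        _padded_intensities(volume),
        (src_idx + 1.0).astype(np.float64),  # padded-index coordinates
        np.ascontiguousarray(dirs_idx, dtype=np.float64),
        float(step_mm),
        float(t_lo),
        float(t_hi),
        out,
    )
    image[r0:r1, c0:c1] = out.reshape(r1 - r0, c1 - c0)
    return image
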