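"""Attenuation volumes ("partial volumes") with world-space placement.

The voxel grid is indexed ``(i, j, k)``; the world position of voxel centre
``(i, j, k)`` is ``origin + direction @ (spacing * (i, j, k))``.  Attenuation
is linear (mm^-1).  Volumes read from or written to disk use MHA/NIfTI via
SimpleITK, which preserves spacing, origin and direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class VoxelVolume:
    intensities: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float32)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3-D array")
        if self.intensities.min() < 0:
            raise ValueError("attenuation values must be non-negative")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be strictly positive")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)
        if np.abs(self.direction @ self.direction.T - np.eye(3)).max() > 1e-9:
            raise ValueError("direction must be orthonormal")

    @property
    def shape(self) -> tuple:
        return self.intensities.shape

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, float)
        return (idx * self.spacing) @ self.direction.T + self.origin

    def world_to_index(self, world: np.ndarray) -> np.ndarray:
        world = np.asarray(world, float)
        return ((world - self.origin) @ self.direction) / self.spacing

    def world_corners(self) -> np.ndarray:
        """World coordinates of the 8 corners of the sampling region
        (half a voxel beyond the outermost voxel centres)."""
        n = np.array(self.shape, float)
        lo, hi = -0.5, n - 0.5
        corners = np.array(
            [[a, b, c] for a in (lo, hi[0]) for b in (lo, hi[1]) for c in (lo, hi[2])]
        )
        return self.index_to_world(corners)


def centered_volume(intensities: np.ndarray, spacing) -> VoxelVolume:
    """Volume whose voxel grid is centred on the world origin."""
    intensities = np.asarray(intensities)
    spacing = np.asarray(spacing, float) * np.ones(3)
    origin = -(np.array(intensities.shape) - 1) / 2.0 * spacing
    return VoxelVolume(intensities, spacing=spacing, origin=origin)


def write_volume(path: str | Path, volume: VoxelVolume) -> None:
    import SimpleITK as sitk

    # SimpleITK uses (x, y, z) index order; our arrays are (i, j, k) with i
    # the fastest-varying world axis, so transpose to put i last.
    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.intensities.T))
    img.SetSpacing(tuple(volume.spacing))
    img.SetOrigin(tuple(volume.origin))
    img.SetDirection(tuple(volume.direction.reshape(-1)))
    sitk.WriteImage(sitk.Cast(img, sitk.sitkFloat32), str(path))


def read_volume(path: str | Path) -> VoxelVolume:
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img).T.astype(np.float32)
    return VoxelVolume(
        np.ascontiguousarray(arr),
        spacing=np.array(img.GetSpacing()),
        origin=np.array(img.GetOrigin()),
        direction=np.array(img.GetDirection()).reshape(3, 3),
    )
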