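"""Rigid-body algebra, bone inertial coordinate systems and pose perturbation.

A bone pose is a proper rigid transform (rotation + translation, millimetres)
mapping bone-local coordinates to the world (lab) frame.  Initial-guess error
is emulated by pre-perturbing a gold-standard pose with pure rotations of
known magnitude about seven axes of the bone's inertial coordinate system:
the three principal axes and the four body diagonals of the unit cube.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

_ORTHO_TOL = 1e-9


def _project_to_rotation(m: np.ndarray) -> np.ndarray:
    """Nearest proper rotation matrix (Frobenius norm) via SVD."""
    u, _, vt = np.linalg.svd(m)
    r = u @ vt
    if np.linalg.det(r) < 0:
        u = u.copy()
        u[:, -1] *= -1.0
        r = u @ vt
    return r


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid transform: ``world = rotation @ local + translation``.

    The rotation is renormalised on construction so that round-off from long
    composition chains cannot accumulate past orthonormality tolerance.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.all(np.isfinite(r)) or not np.all(np.isfinite(t)):
            raise ValueError("non-finite rigid transform")
        err = np.abs(r @ r.T - np.eye(3)).max()
        if err > 1e-6:
            raise ValueError(f"rotation not orthonormal (max deviation {err:.3g})")
        if err > _ORTHO_TOL or np.linalg.det(r) < 0.999999:
            r = _project_to_rotation(r)
        r.setflags(write=False)
        t.setflags(write=False)
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    # -- constructors ------------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=float).reshape(4, 4)
        return cls(m[:3, :3], m[:3, 3])

    @classmethod
    def from_rotvec_deg(
        cls, rotvec_deg: np.ndarray, translation: np.ndarray | None = None
    ) -> "RigidTransform":
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_rotvec(np.asarray(rotvec_deg, float), degrees=True)
        t = np.zeros(3) if translation is None else translation
        return cls(rot.as_matrix(), t)

    @classmethod
    def rotation_about_point(
        cls, axis: np.ndarray, angle_deg: float, point: np.ndarray
    ) -> "RigidTransform":
        """Rotation of ``angle_deg`` about the world-space line through
        ``point`` with direction ``axis`` (need not be unit)."""
        axis = np.asarray(axis, float)
        n = np.linalg.norm(axis)
        if n == 0:
            raise ValueError("zero rotation axis")
        from scipy.spatial.transform import Rotation

        r = Rotation.from_rotvec(axis / n * np.deg2rad(angle_deg)).as_matrix()
        point = np.asarray(point, float)
        return cls(r, point - r @ point)

    # -- algebra -----------------------------------------------------------
    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, float)
        return points @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self ∘ other``: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def invert(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def almost_equal(self, other: "RigidTransform", tol: float = 1e-9) -> bool:
        return (
            np.abs(self.rotation - other.rotation).max() < tol
            and np.abs(self.translation - other.translation).max() < tol
        )


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Composition ``a ∘ b`` (apply ``b`` first)."""
    return a.compose(b)


def invert(t: RigidTransform) -> RigidTransform:
    return t.invert()


# ---------------------------------------------------------------------------
# Inertial coordinate systems
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InertialFrame:
    """Bone-fixed frame: origin at the intensity-weighted centroid, axes the
    principal axes of the intensity-weighted inertia tensor.

    Columns of ``axes`` are ordered by descending principal moment; each
    column's sign is fixed so its largest-magnitude component is positive,
    then the determinant is forced to +1 (see :func:`inertial_frame`).
    """

    origin: np.ndarray
    axes: np.ndarray


def _fix_axis_signs(axes: np.ndarray) -> np.ndarray:
    axes = axes.copy()
    for j in range(3):
        k = np.argmax(np.abs(axes[:, j]))
        if axes[k, j] < 0:
            axes[:, j] *= -1.0
    if np.linalg.det(axes) < 0:
        # restore a proper rotation; the middle axis carries the flip so the
        # dominant (first) and weakest (last) moments keep the sign rule
        axes[:, 1] *= -1.0
    return axes


def inertial_frame(volume) -> InertialFrame:
    """Principal-axis frame of a :class:`~bvrpose.volume.VoxelVolume`.

    Raises ``ValueError`` on an all-zero volume.  Degenerate (near-spherical
    or single-voxel) inertia falls back to world-aligned axes with a warning.
    """
    w = np.asarray(volume.intensities, dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError("empty volume")
    idx = np.indices(w.shape).reshape(3, -1).T.astype(float)
    world = volume.index_to_world(idx)
    wf = w.reshape(-1)
    origin = (world * wf[:, None]).sum(axis=0) / total

    r = world - origin
    r2 = (r * r).sum(axis=1)
    # inertia tensor about the centroid: sum_k w_k ((r.r) I - r r^T)
    outer = np.einsum("ki,kj,k->ij", r, r, wf)
    inertia = np.eye(3) * (wf * r2).sum() - outer

    moments, vecs = np.linalg.eigh(inertia)  # ascending
    order = np.argsort(moments)[::-1]
    moments = moments[order]
    vecs = vecs[:, order]

    scale = max(moments[0], 1.0)
    if (moments[0] - moments[2]) / scale < 1e-9:
        warnings.warn("degenerate inertia (spherical symmetry); using world axes")
        return InertialFrame(origin, np.eye(3))
    axes = _fix_axis_signs(vecs)
    return InertialFrame(origin, axes)


# ---------------------------------------------------------------------------
# Perturbation scheme
# ---------------------------------------------------------------------------

def perturbation_axes() -> np.ndarray:
    """The seven perturbation directions in the bone's inertial frame.

    X, Y, Z plus the four distinct body diagonals of the unit cube,
    normalised.  Both rotation signs are applied downstream, so each signed
    diagonal pair is represented once.
    """
    s = 1.0 / np.sqrt(3.0)
    axes = np.array(
        [
            [1.0, 0.0, 0.0],
            [0.0, 1.0, 0.0],
            [0.0, 0.0, 1.0],
            [s, s, s],
            [s, s, -s],
            [s, -s, s],
            [-s, s, s],
        ]
    )
    axes.setflags(write=False)
    return axes


AXIS_NAMES = ("X", "Y", "Z", "D1", "D2", "D3", "D4")


@dataclass(frozen=True)
class PerturbationSpec:
    magnitudes_deg: tuple = (2.0, 4.0, 8.0)
    axes: np.ndarray = field(default_factory=perturbation_axes)

    def __post_init__(self) -> None:
        mags = tuple(float(m) for m in self.magnitudes_deg)
        if any(m <= 0 for m in mags):
            raise ValueError("perturbation magnitudes must be positive")
        object.__setattr__(self, "magnitudes_deg", mags)
        axes = np.asarray(self.axes, float)
        norms = np.linalg.norm(axes, axis=1)
        if np.abs(norms - 1.0).max() > 1e-12:
            raise ValueError("perturbation axes must be unit vectors")
        object.__setattr__(self, "axes", axes)


@dataclass(frozen=True)
class PerturbationLabel:
    axis: str
    sign: int
    magnitude_deg: float

    def __str__(self) -> str:
        return f"{'+' if self.sign > 0 else '-'}{self.magnitude_deg:g}deg_{self.axis}"


def generate_perturbations(
    gold: RigidTransform,
    frame: InertialFrame,
    spec: PerturbationSpec | None = None,
) -> list[tuple[PerturbationLabel, RigidTransform]]:
    """Perturbed initial poses: ``perturbation ∘ gold`` for every axis,
    magnitude and rotation sign.

    Each perturbation is a pure rotation about the world-space line through
    ``frame.origin`` along ``frame.axes @ axis``, so the inertial centre is a
    fixed point and the pose delta relative to gold has zero helical
    translation by construction.
    """
    spec = spec or PerturbationSpec()
    out: list[tuple[PerturbationLabel, RigidTransform]] = []
    names = (
        AXIS_NAMES
        if len(spec.axes) == len(AXIS_NAMES)
        else tuple(f"A{i}" for i in range(len(spec.axes)))
    )
    for name, axis_local in zip(names, spec.axes):
        axis_world = frame.axes @ axis_local
        for mag in spec.magnitudes_deg:
            for sign in (+1, -1):
                p = RigidTransform.rotation_about_point(
                    axis_world, sign * mag, frame.origin
                )
                out.append((PerturbationLabel(name, sign, mag), p.compose(gold)))
    return out


# ---------------------------------------------------------------------------
# Transform CSV dialect
# ---------------------------------------------------------------------------
# One row per frame: 16 comma-separated values, the row-major 4x4 homogeneous
# matrix in world millimetres.  Lines starting with '#' are comments.

def write_transforms(path: str | Path, transforms: Iterable[RigidTransform]) -> None:
    path = Path(path)
    lines = ["# row-major 4x4 rigid transform, world mm, one frame per row"]
    for t in transforms:
        lines.append(",".join(f"{v:.17g}" for v in t.matrix.reshape(-1)))
    path.write_text("\n".join(lines) + "\n")


def read_transforms(path: str | Path) -> list[RigidTransform]:
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        vals = np.array([float(v) for v in line.split(",")])
        if vals.size != 16:
            raise ValueError(f"expected 16 values per row, got {vals.size}")
        out.append(RigidTransform.from_matrix(vals.reshape(4, 4)))
    return out
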