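"""Helical (screw) axis error metrics.

By Chasles' theorem any rigid displacement is a rotation ``phi`` about a
unique axis plus a translation along it.  Pose error between an estimated
and a gold-standard pose is summarised by ``phi`` (degrees, in [0, 180]) and
the absolute translation along the screw axis (mm); both are invariant to
the choice of world frame for the fixed composition convention used here
(``estimated ∘ gold⁻¹``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import RigidTransform

DEGENERATE_PHI_DEG = 1e-6


@dataclass(frozen=True)
class HelicalError:
    phi_deg: float
    translation_mm: float
    axis: np.ndarray
    axis_point: np.ndarray
    degenerate: bool = False


def helical_decompose(delta: RigidTransform) -> HelicalError:
    """Screw decomposition of a rigid displacement.

    Near-zero rotations (phi < 1e-6 deg) are flagged degenerate: the axis
    direction is taken from the translation and the full translation norm is
    reported.  ``axis_point`` is the point on the screw axis closest to the
    world origin.
    """
    r = delta.rotation
    t = delta.translation
    s = 0.5 * np.array([r[2, 1] - r[1, 2], r[0, 2] - r[2, 0], r[1, 0] - r[0, 1]])
    sin_phi = np.linalg.norm(s)
    cos_phi = 0.5 * (np.trace(r) - 1.0)
    phi = np.degrees(np.arctan2(sin_phi, cos_phi))

    if phi < DEGENERATE_PHI_DEG:
        norm_t = np.linalg.norm(t)
        axis = t / norm_t if norm_t > 0 else np.zeros(3)
        return HelicalError(float(phi), float(norm_t), axis, np.zeros(3), True)

    # rotation axis: unit kernel vector of (R - I); robust at phi near 180
    # where the skew part vanishes
    _, _, vt = np.linalg.svd(r - np.eye(3))
    axis = vt[-1]
    if sin_phi > 1e-12 and np.dot(axis, s) < 0:
        axis = -axis

    d = float(np.dot(t, axis))
    # axis point: (I - R) p = t - d * axis, minimum-norm solution is the
    # point on the axis closest to the origin (the solution set runs along
    # the axis, and lstsq returns the component orthogonal to it)
    p, *_ = np.linalg.lstsq(np.eye(3) - r, t - d * axis, rcond=None)
    return HelicalError(float(phi), abs(d), axis, p, False)


def pose_error(gold: RigidTransform, estimated: RigidTransform) -> HelicalError:
    """Helical error of ``estimated`` relative to ``gold``
    (delta composed in the world frame: ``estimated ∘ gold⁻¹``)."""
    return helical_decompose(estimated.compose(gold.invert()))
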