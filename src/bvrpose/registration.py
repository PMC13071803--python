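"""6-DOF pose refinement by particle swarm optimisation of DRR similarity.

The cost of a candidate pose is the sum over the two views of
``1 - NCC(preprocess(DRR), preprocess(target))`` evaluated inside the DRR's
projected region of interest, so it ranges over [0, 4] and lower is better.
Candidates are parameterised relative to the initial (perturbed) pose as a
3-component axis-angle rotation (degrees) about the bone's inertial centre
plus a 3-component translation (mm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation


from .drr import projected_bbox, render_drr
from .geometry import RigidTransform
from .imageops import (
    DEFAULT_DRR_CHAIN,
    DEFAULT_TARGET_CHAIN,
    downsample_bicubic,
    ncc_flagged,
    preprocess,
)
from .volume import VoxelVolume

WORST_COST = 4.0


@dataclass(frozen=True)
class PsoConfig:
    """Canonical global-best PSO settings.

    Defaults are standard inertia/acceleration values sized so the ±10°/±10mm
    search box comfortably contains the worst (±8°) initial-guess error.
    """

    n_particles: int = 40
    n_iterations: int = 100
    w: float = 0.7
    c1: float = 1.5
    c2: float = 1.5
    rot_bound_deg: float = 10.0
    trans_bound_mm: float = 10.0
    seed: int = 0
    early_stop_tol: float = 1e-9
    early_stop_patience: int = 40

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("need at least 2 particles")
        if not 0.0 < self.w < 1.0:
            raise ValueError("inertia weight must be in (0, 1)")
        if self.rot_bound_deg < 0 or self.trans_bound_mm < 0:
            raise ValueError("bounds must be non-negative")

    @property
    def bounds(self) -> np.ndarray:
        return np.array([self.rot_bound_deg] * 3 + [self.trans_bound_mm] * 3)


def params_to_pose(
    params: np.ndarray, init_pose: RigidTransform, centre: np.ndarray
) -> RigidTransform:
    """Candidate pose: rotate ``init_pose`` by the axis-angle offset about
    the world point ``centre`` (the bone's posed inertial centre), then
    translate."""
    params = np.asarray(params, float)
    rot = params[:3]
    angle = np.linalg.norm(rot)
    if angle > 0:
        delta = RigidTransform.rotation_about_point(rot / angle, angle, centre)
    else:
        delta = RigidTransform.identity()
    shifted = RigidTransform(delta.rotation, delta.translation + params[3:])
    return shifted.compose(init_pose)


@dataclass
class _CostContext:
    volume: VoxelVolume
    init_pose: RigidTransform
    centre: np.ndarray
    cameras: tuple
    targets_pp: tuple  # preprocessed target image per view
    drr_chain: tuple
    ray_grids: tuple  # cached per-camera pixel ray directions
    step_mm: float | None = None
    supersample: int = 1
    hi_cameras: tuple = ()
    hi_ray_grids: tuple = ()


def _render_candidate(ctx: _CostContext, pose, view: int, bbox: tuple):
    """DRR patch for one view at the target resolution.

    With ``supersample > 1`` the patch is rendered at a finer grid and
    reduced with the same antialiased cubic kernel used on the targets, so
    DRR and downsampled-target edge profiles see the same low-pass filter.
    """
    r0, r1, c0, c1 = bbox
    f = ctx.supersample
    if f <= 1:
        drr = render_drr(
            ctx.volume, pose, ctx.cameras[view], ctx.step_mm,
            ray_grid=ctx.ray_grids[view],
        )
        return drr[r0:r1, c0:c1]
    hi_bbox = (r0 * f, r1 * f, c0 * f, c1 * f)
    hi = render_drr(
        ctx.volume, pose, ctx.hi_cameras[view], ctx.step_mm,
        ray_grid=ctx.hi_ray_grids[view], bbox=hi_bbox,
    )
    patch = hi[hi_bbox[0] : hi_bbox[1], hi_bbox[2] : hi_bbox[3]]
    return downsample_bicubic(patch, (r1 - r0, c1 - c0))


def _cost(ctx: _CostContext, params: np.ndarray) -> tuple[float, bool]:
    pose = params_to_pose(params, ctx.init_pose, ctx.centre)
    total = 0.0
    out_of_view = True
    for view, (cam, target_pp) in enumerate(zip(ctx.cameras, ctx.targets_pp)):
        bbox = projected_bbox(ctx.volume, pose, cam, pad=3)
        if bbox is not None:
            r0, r1, c0, c1 = bbox
        if bbox is None or r1 - r0 < 5 or c1 - c0 < 5:
            # fully outside the image, or a sliver at its border
            total += 2.0
            continue
        patch = _render_candidate(ctx, pose, view, bbox)
        # the similarity mask is the DRR's own (dilated) silhouette: pixels
        # the model cannot explain — neighbouring bones, soft tissue — must
        # not dominate the correlation
        mask = binary_dilation(patch > 1e-6, iterations=1)
        if mask.sum() < 16:
            total += 2.0
            continue
        out_of_view = False
        # preprocessing is local to the ROI: NCC is evaluated there only,
        # and the DRR is identically zero outside it anyway
        drr_pp = preprocess(patch, ctx.drr_chain)
        value, flat = ncc_flagged(drr_pp, target_pp[r0:r1, c0:c1], mask)
        total += 1.0 - (0.0 if flat else value)
    return total, out_of_view


def registration_cost(
    params,
    init_pose: RigidTransform,
    volume: VoxelVolume,
    cameras,
    target_images,
    preprocess_chain=DEFAULT_TARGET_CHAIN,
    drr_chain=DEFAULT_DRR_CHAIN,
    centre: np.ndarray | None = None,
    step_mm: float | None = None,
    drr_supersample: int = 1,
) -> float:
    """One-shot cost evaluation (targets preprocessed internally).

    For repeated evaluation use :func:`optimize_pose`, which caches the
    preprocessed targets.
    """
    ctx = _make_context(
        volume, init_pose, cameras, target_images, preprocess_chain, drr_chain,
        centre, step_mm, drr_supersample,
    )
    cost, _ = _cost(ctx, np.asarray(params, float))
    return cost


def _make_context(
    volume, init_pose, cameras, target_images, preprocess_chain, drr_chain,
    centre, step_mm, supersample=1,
) -> _CostContext:
    if centre is None:
        from .geometry import inertial_frame

        centre = init_pose.apply(inertial_frame(volume).origin)
    targets_pp = tuple(
        preprocess(np.asarray(img, float), preprocess_chain) for img in target_images
    )
    from .drr import camera_ray_grid

    supersample = int(supersample)
    hi_cameras = ()
    hi_ray_grids = ()
    if supersample > 1:
        hi_cameras = tuple(
            c.resize((c.image_size[0] * supersample, c.image_size[1] * supersample))
            for c in cameras
        )
        hi_ray_grids = tuple(camera_ray_grid(c) for c in hi_cameras)
    return _CostContext(
        volume=volume,
        init_pose=init_pose,
        centre=np.asarray(centre, float),
        cameras=tuple(cameras),
        targets_pp=targets_pp,
        drr_chain=tuple(drr_chain),
        ray_grids=tuple(camera_ray_grid(c) for c in cameras),
        step_mm=step_mm,
        supersample=supersample,
        hi_cameras=hi_cameras,
        hi_ray_grids=hi_ray_grids,
    )


def optimize_pose(
    init_pose: RigidTransform,
    volume: VoxelVolume,
    cameras,
    target_images,
    pso: PsoConfig | None = None,
    preprocess_chain=DEFAULT_TARGET_CHAIN,
    drr_chain=DEFAULT_DRR_CHAIN,
    centre: np.ndarray | None = None,
    step_mm: float | None = None,
    drr_supersample: int = 1,
):
    """Refine ``init_pose`` by canonical global-best PSO.

    Particles start uniformly inside the bounds with one particle pinned at
    the zero offset (the initial pose itself); positions are clamped to the
    bounds each step.  Fully deterministic given ``pso.seed``.  Returns
    ``(refined_pose, best_cost, trace)`` where ``trace`` is the global-best
    cost per iteration (monotonically non-increasing).
    """
    pso = pso or PsoConfig()
    ctx = _make_context(
        volume, init_pose, cameras, target_images, preprocess_chain, drr_chain,
        centre, step_mm, drr_supersample,
    )
    bounds = pso.bounds
    rng = np.random.default_rng(pso.seed)
    n, d = pso.n_particles, 6

    x = rng.uniform(-bounds, bounds, size=(n, d))
    x[0] = 0.0  # pinned at the initial pose
    v = np.zeros((n, d))

    costs = np.array([_cost(ctx, xi)[0] for xi in x])
    pbest_x = x.copy()
    pbest_c = costs.copy()
    g = int(np.argmin(costs))
    gbest_x = x[g].copy()
    gbest_c = float(costs[g])
    trace = [gbest_c]

    stall = 0
    for _ in range(pso.n_iterations):
        r1 = rng.random((n, d))
        r2 = rng.random((n, d))
        v = pso.w * v + pso.c1 * r1 * (pbest_x - x) + pso.c2 * r2 * (gbest_x - x)
        x = np.clip(x + v, -bounds, bounds)
        costs = np.array([_cost(ctx, xi)[0] for xi in x])
        improved = costs < pbest_c
        pbest_x[improved] = x[improved]
        pbest_c[improved] = costs[improved]
        g = int(np.argmin(pbest_c))
        if pbest_c[g] < gbest_c - pso.early_stop_tol:
            stall = 0
        else:
            stall += 1
        if pbest_c[g] < gbest_c:
            gbest_c = float(pbest_c[g])
            gbest_x = pbest_x[g].copy()
        trace.append(gbest_c)
        if stall >= pso.early_stop_patience:
            break

    refined = params_to_pose(gbest_x, init_pose, ctx.centre)
    return refined, gbest_c, trace
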