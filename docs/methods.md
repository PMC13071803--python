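# Methods

`bvrpose` is a self-contained benchmark for studying how x-ray image
resolution affects model-based 2D–3D bone pose estimation in biplanar
videoradiography (BVR). Every stage of the real workflow — acquisition,
CT-derived bone models, DRR rendering, similarity optimisation, error
scoring, robust statistics — has a synthetic counterpart with an exactly
known ground truth, so the whole chain is testable on a desk with no data
download. This note records the models, the defaults and why they were
chosen, and what the synthetic results do and do not say about real data.

## Rigid poses and the perturbation scheme

A bone pose is a proper rigid transform `world = R x + t` (rotation matrix,
translation in mm). Initial-guess error is emulated by pre-composing the
gold pose with a pure rotation about a line through the bone's inertial
centre: for each of seven axes of the inertial frame (X, Y, Z and the four
normalised body diagonals of the unit cube), both signs, and each requested
magnitude (default ±2°, ±4°, ±8°), giving 42 perturbed starts for the
default three magnitudes. Because the axis passes through the inertial
centre, the pose delta relative to gold is a pure rotation: its helical
angle equals the requested magnitude and its helical translation is zero to
machine precision, which the test suite uses as a round-trip invariant.

The inertial frame is the intensity-weighted centroid and the eigenvectors
of the intensity-weighted inertia tensor, columns ordered by descending
principal moment. Eigenvector sign is fixed by making each column's
largest-magnitude component positive; if that leaves a left-handed triad
the middle column is negated (the first and last columns carry the most
physical meaning — largest and smallest moments — so the middle one absorbs
the handedness fix). Near-spherical inertia (relative eigenvalue spread
below 1e-9) falls back to world axes with a warning.

## Synthetic trial scene

`phantom.make_scene` builds an ankle-like cluster of three bones:

* **calcaneus-like** (`isolated`): a large superellipsoid blob below the
  cluster, little projected overlap;
* **talus-like** (`enclosed`): a rounded blob at the origin, overlapped in
  projection from above by the tibia's distal lobe and bordered below by
  the calcaneus;
* **tibia-like** (`long-bone`): an elongated shaft (>3:1) whose distal,
  malleolus-like lobe is displaced in the camera-depth direction and
  reaches down alongside the talus — so it overlaps the talus in both
  projections without 3-D interpenetration, as the malleoli do in lateral
  ankle views. Joint spaces of a few mm separate all bones in 3-D.

Bones are two-level attenuation blobs: a ~2-voxel cortical shell at
0.11 mm⁻¹ over a trabecular interior at 0.016 mm⁻¹ (representative linear
attenuation at ~60 keV), with the silhouette modulated by seeded
low-order angular harmonics (±15%) and the interior modulated by seeded
two-scale density texture (coarse ~5 mm and fine ~1 mm correlation
lengths, ±50% each). The fine scale matters: it is structure a
2048-class native radiograph resolves but a CT-fidelity bone model does
not (next section).

A soft-tissue envelope (water-like, 0.018 mm⁻¹, coarse 2 mm grid) encloses
the cluster. It is rendered into every capture but never given to the
optimiser, mirroring real model-based tracking where the partial volume
contains only the segmented bone. It follows the hop translation without
rotating (soft tissue deforms rather than moving rigidly with any bone).

The gold trajectory is a hop: half-sine vertical translation (default
10 mm) plus a plantarflexion-like rotation about x (default 6°), with small
seeded per-bone amplitude differences (±5%). Defaults keep adjacent-frame
pose changes below 3° and 5 mm at the desk default of 8 frames. An optional
`long_bone_exit` flag adds an extra upward shift to the tibia in the first
and last ~15% of frames so its proximal end leaves the field of view, the
failure mode long bones show in practice. With `n_frames=35` the trajectory
matches the length of a full hop acquisition.

### Cameras

Two pinhole projectors with principal rays through the world origin,
separated by 60° about the vertical; source–axis distance 1100 mm,
source–detector 1300 mm, detector width 120 mm (a joint-collimated field of
view ≈ 100 mm at the isocentre). These are plausible laboratory values, all
configurable; no specific system is being reconstructed. Each camera is its
3×4 projection matrix (normalised so the third row of the 3×3 block is a
unit vector and positive w means in front of the source); pixel centres are
0-based integers, row 0 at the top.

### Detector counts and noise

Captures are `I = photon_scale * exp(-integral)`, Poisson-sampled, plus
Gaussian read noise (σ = 5 counts), clipped at zero, at the native capture
resolution. High-speed radiography is photon-starved — at hundreds of
frames per second a native pixel collects only a few hundred quanta — so
the default `photon_scale` is 150 counts on the unattenuated background
(SNR ≈ 12 in air and far lower behind tissue and bone). Downsampled
conditions derived from these captures genuinely gain SNR: a 4× bicubic
reduction averages ~16 native pixels and cuts noise roughly 4-fold,
while nearest-neighbour decimation keeps native per-pixel noise.

### CT-fidelity bone models

The optimiser never sees the ground-truth anatomy. `make_scene` hands it
`model_bones`: the true volumes degraded by a 1.5 mm Gaussian point-spread
(`ct_blur_mm`), emulating the effective fidelity of partial volumes
segmented from a clinical CT (sub-millimetre voxels, but blurred by the
scanner PSF and the segmentation itself).
This is essential for the benchmark to be faithful: with a pixel-perfect
model, full-resolution registration is unrealistically robust at any noise
level, because white detector noise averages out of the NCC over thousands
of pixels. What degrades real full-resolution matching is *structured*
residue — fine trabecular and edge detail present in the radiograph but
absent from the model — and that only exists if the model's fidelity is
finite. Setting `ct_blur_mm=0` restores the idealised self-match case the
unit tests use.

## DRR rendering

A DRR pixel is the line integral of attenuation from the source through
the pixel centre: fixed-step midpoint ray marching (default step = half
the smallest voxel spacing) with trilinear interpolation, zero outside the
grid, rays clipped to the volume's world bounding box. Only pixels inside
the projected bounding box of the posed volume are cast; the rest are
exactly zero (the projection of a convex box is contained in the convex
hull of its projected corners, so no intersecting ray is missed). The
integrator is a numba kernel over a zero-padded copy of the volume so the
inner trilinear loop needs no bounds checks. Accuracy contracts: an
axis-perpendicular ray through a uniform cube reproduces μ·side within
2·step·μ; halving the step changes pixels by <1%; the integral is exactly
linear in attenuation.

## Resolution treatments

* **bicubic**: separable cubic convolution with the Keys a = −0.5 kernel;
  output pixel centre `i` maps to input coordinate `(i+0.5)·scale − 0.5`;
  antialiasing (default on for shrinking) widens the kernel support by the
  scale factor; boundary taps clamp to the edge pixel; weights are
  normalised. Interior pixels agree with an independent reference cubic
  resampler to 1e-6 and reproduce linear ramps exactly.
* **nearest**: the same centre mapping rounded to the closest input pixel;
  no filtering, no new values.

A pinned convention matters more than the choice itself: cross-
implementation agreement on "bicubic" is only possible with the kernel,
mapping and edge rule fixed, which is why they are spelled out here.

## Registration

The cost of a candidate pose is `Σ_views (1 − NCC)` between the
edge-preprocessed DRR and the edge-preprocessed target, range [0, 4], with
three deliberate conventions:

1. **Intensity domain.** Targets pass through `-log(counts)` first: by
   Beer–Lambert this equals the attenuation line integral up to an affine
   offset, putting target and DRR in the same domain before Sobel. (A plain
   intensity inversion leaves an exponential nonlinearity that measurably
   displaces the cost optimum from the true pose.) An affine percentile
   stretch is applied to cached targets for numerical hygiene; it is
   omitted from the per-evaluation DRR chain because NCC is
   affine-invariant.
2. **Similarity mask.** NCC is evaluated over the DRR's own silhouette
   (nonzero region dilated by 1 px), not its bounding rectangle. Pixels the
   single-bone model cannot explain — neighbouring bones, soft tissue —
   otherwise dominate the correlation and pull the optimum several degrees
   away for the enclosed bone. A pose whose silhouette leaves the image
   contributes the worst cost (2 per view) and is flagged out-of-view.
3. **Condition-matched DRR sampling.** The DRR must receive the same
   sampling/filter treatment as that condition's targets. For the bicubic
   condition DRRs are rendered 2× supersampled and reduced with the same
   antialiased Keys kernel (`drr_supersample`, exact at the full ratio via
   `drr_policy="downsample_rendered"`); for the nearest condition the
   camera's pixel centres are placed exactly on the native pixels that
   decimation keeps (`CameraModel.decimate`). Without this, each
   downsampled condition carries a built-in 0.3–0.8° bias from filter/grid
   mismatch.

The optimiser is canonical global-best PSO: positions uniform in a
±10°/±10 mm box around the initial pose (axis-angle about the posed
inertial centre + translation), one particle pinned at the initial pose,
velocity update `v ← 0.7 v + 1.5 r1 (pbest − x) + 1.5 r2 (gbest − x)`,
positions clamped to the box, fully deterministic given the seed. Defaults
are 40 particles × 100 iterations with early stop (no gbest improvement
>1e-9 for 40 iterations); ~100 iterations are needed for the swarm to
contract from a ±10° box to the sub-0.1° scale of the noiseless optimum.
Smaller, documented budgets are used in the test-suite experiments.

## Error metric

Pose error is the Chasles screw decomposition of `estimated ∘ gold⁻¹`
composed in the world frame: `phi` (0–180°) is the rotation about the
helical axis, and the reported translation is the absolute translation
along that axis. `phi` is invariant to the frame convention; the axis is
the unit kernel vector of `R − I` (robust near 180°), and the axis point is
the minimum-norm solution of the pitch equations (the point on the axis
closest to the origin). Rotations below 1e-6° are flagged degenerate and
report the full translation norm. Both error components are absolute
values, consistent with summarising distributions of absolute differences.

## Robust statistics

Per condition the pooled absolute errors are summarised by: median; limits
of agreement `median ± 1.45·IQR` (linear-interpolation quantiles, lower
bound truncated at 0 since the data are absolute errors — truncation means
LOA endpoints are a descriptive convention, and upper bounds can exceed the
180° range of `phi` itself); cumulative error `Σ|x|`; unscaled MAD
(`median |x − median|`, no 1.4826 factor); and the Hampel outlier count
with the modified z-score form `0.6745·|x − med|/MAD > 3.5` (the standard
pairing with a 3.5 threshold; an unscaled variant sits behind a flag).
With MAD = 0 exactly the off-median values are flagged. Note the
interaction that makes outlier counts non-monotone in error magnitude:
when a condition fails broadly, its median and MAD are large and even huge
errors stay inside the threshold, so heavily failing conditions can report
*zero* outliers.

Between conditions: tie-corrected Kruskal–Wallis (via scipy) per
bone × magnitude × metric, and — only when the omnibus p < 0.05 — Dunn's
pairwise rank test with Bonferroni correction over the three pairs within
that family (no cross-family correction). Dunn is implemented in-package
(`z = (R̄_a − R̄_b) / sqrt[(N(N+1)/12 − ΣT/(12(N−1)))(1/n_a + 1/n_b)]`)
and verified against a hand enumeration of ranks.

## Experiment pipeline and problem sizes

`run_experiment` renders one noisy trial, then for every tracked bone ×
frame × perturbation × condition refines the perturbed pose and scores the
helical error, writing JSON-lines records plus the summary and test tables
as CSV. The three conditions consume the *same* noisy native captures;
downsampled conditions differ only by the resampling operator. Per-task
PSO seeds derive deterministically (FNV hash) from the scene seed and the
task identity, so a re-run overwrites byte-identical results.

Desk-scale defaults: native 256×256, downsampled 64×64 (preserving the 4×
ratio of a 2048 → 512 study), 64³ bone grids at 1 mm, 8 frames, three
bones with the calcaneus- and talus-like bones tracked.
`paper_scale_config()` raises these to 2048/512, 35 frames and all three
bones for users with the compute budget. The test suite and the
acceptance script scale further down, as recorded in each test: the
pose-recovery checks use a 64×64 single-bone noiseless scene, and the
resolution-mechanism experiment uses one frame, the ±8° magnitude with
six of the fourteen signed perturbation starts (both signs of X, Y and
Z), 16 particles × 50 iterations, and ten scene seeds — sizes chosen so the full study of the
headline effect remains a routine desk run.

## What passing tests show — and what they do not

The phantom reproduces the *mechanisms* of the resolution effect: noise
that averages away under bicubic reduction, edge maps that strengthen when
adjacent pixels are combined, neighbour-bone overlap that corrupts an
enclosed bone's silhouette, fine image structure beyond the bone model's
fidelity, and a long bone leaving the field of view. Passing the suite
shows the full chain — perturbation, rendering, optimisation, screw-axis
scoring, robust summaries — behaves correctly and that the qualitative
resolution ranking emerges under these mechanisms. It does not certify
quantitative error magnitudes for any real system: real bones have far
richer shape and internal structure than seeded superellipsoids, real
detectors have PSFs, scatter and beam hardening that are out of scope here,
and a real study's absolute numbers depend on its specific anatomy,
geometry and exposure.

## Numerical details worth knowing

* Transform CSVs store 17 significant digits and round-trip bit-exactly.
* `RigidTransform` re-orthonormalises via SVD on construction; 500-fold
  composition chains stay orthonormal to 1e-9.
* The helical decomposition's degeneracy threshold (1e-6°) is the numerical
  floor of axis extraction from `R − I`.
* `kruskal_wallis` returns (0, 1) for all-identical data, where the tie
  correction would otherwise divide by zero.
* `neglog` clamps counts at 1e-4 of the image maximum so zero-count pixels
  cannot produce unbounded spikes.
* Bicubic downsampling may overshoot the input range (cubic ringing); it is
  deliberately not clipped. Nearest never introduces new values.
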