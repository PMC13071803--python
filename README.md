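# bvrpose

**How does x-ray image resolution affect model-based bone pose estimation?**

Biplanar videoradiography (BVR) tracks individual bones during dynamic
movement by aligning a CT-derived bone model with two calibrated high-speed
x-ray views: digitally reconstructed radiographs (DRRs) of the model are
compared with the x-ray images via normalised cross-correlation (NCC), and
a particle swarm optimiser (PSO) refines the 6-DOF pose. A counterintuitive
practical finding in this field is that *downsampling* the x-ray images —
e.g. 2048×2048 → 512×512 with bicubic interpolation — can make tracking
more accurate: downsampling averages detector noise, consolidates bone
edges, and brings the images to a fidelity comparable to the CT model.

`bvrpose` is a self-contained, fully synthetic benchmark of this effect for
researchers who develop or tune BVR tracking pipelines. It generates
ankle-like phantom trials with exactly known gold-standard poses, renders
noisy biplanar radiographs, perturbs the gold poses to emulate initial-
guess error, re-optimises them under three image-resolution conditions
(native, bicubic-downsampled, nearest-downsampled), and scores errors with
helical (screw) axis metrics and robust nonparametric statistics — no data
download, one desk, one CPU.

## The model in brief

* **Pose**: rigid transform (R, t); initial error is a pure rotation of
  ±2°, ±4° or ±8° about one of 7 axes of the bone's inertial frame (X, Y,
  Z and the 4 unit-cube diagonals) — 42 perturbed starts per bone.
* **Cost**: `Σ_views (1 − NCC(Sobel(DRR), Sobel(−log counts)))` over the
  DRR's silhouette; minimised by canonical global-best PSO in a ±10°/±10 mm
  box about the initial pose.
* **Error**: Chasles decomposition of `estimated ∘ gold⁻¹`; rotation error
  is the helical angle φ, translation error the translation along the
  helical axis.
* **Statistics**: median, limits of agreement (median ± 1.45·IQR, lower
  bound truncated at 0), cumulative error, unscaled MAD, Hampel outliers
  (modified z-score, threshold 3.5); Kruskal–Wallis across conditions with
  Dunn/Bonferroni post-hoc tests.

## A worked example

```bash
python examples/02_perturb_and_recover.py
```

```
initial guess: gold pose perturbed by +2deg_X
PSO ran 100 iterations, final cost 6.19e-09
residual error: 0.001 deg about the helical axis, 0.000 mm along it (started at 2 deg)
```

A noiseless single-bone trial is rendered, the known pose is rotated 2°
about the bone's inertial X axis (a careful manual initial guess), and the
swarm recovers it to a millidegree: on an idealised phantom the whole
chain — rendering, preprocessing, similarity, optimisation, screw-axis
scoring — is exact. The interesting science appears when realism is
switched on (`examples/03_resolution_conditions.py`):

```
 fullres (256x256): residual noise sd =  10.86 counts, mean normalised Sobel magnitude = 0.296
   bicubic (64x64): residual noise sd =   2.25 counts, mean normalised Sobel magnitude = 0.322
   nearest (64x64): residual noise sd =  11.03 counts, mean normalised Sobel magnitude = 0.430
```

Bicubic downsampling cuts detector noise ~5-fold and strengthens the edge
map the optimiser relies on — the mechanism behind the headline result
that downsampled images track better than native ones.

Other entry points: `examples/01_render_drr.py` (DRR rendering),
`examples/04_robust_stats.py` (the summary/statistics tables), and the CLI

```bash
bvrpose fixtures --outdir fx --size tiny     # phantom trial on disk
bvrpose run --outdir out --seed 1            # full desk-scale experiment
bvrpose summarize out/records.jsonl --out summaries.csv
bvrpose stats out/records.jsonl --out tests.csv
```

## Layout

* `src/bvrpose/geometry.py` — rigid transforms, inertial frames, the
  7-axis perturbation scheme, transform CSV I/O
* `src/bvrpose/volume.py`, `camera.py` — attenuation volumes (MHA/NIfTI),
  calibrated pinhole projectors (3×4 matrix text files)
* `src/bvrpose/drr.py` — ray-marched DRR rendering (numba)
* `src/bvrpose/imageops.py` — bicubic/nearest downsampling, Sobel, NCC,
  preprocessing chains
* `src/bvrpose/registration.py` — the PSO pose refiner
* `src/bvrpose/helical.py` — screw-axis error metrics
* `src/bvrpose/robust.py` — robust summaries and nonparametric tests
* `src/bvrpose/phantom.py` — the synthetic trial generator
* `src/bvrpose/pipeline.py` — experiment orchestration, fixtures
* `src/bvrpose/cli.py` — thin command-line wrapper
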