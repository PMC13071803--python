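"""End-to-end resolution experiment: generate → perturb → downsample →
register → score → summarise → test.

The three resolution conditions share the SAME noisy native-resolution
captures; the downsampled conditions differ only by the resampling operator
(no fresh noise draw).  DRRs are by default rendered directly at each
condition's image size through a rescaled camera (``render_at_target``); the
alternative ``downsample_rendered`` policy renders at native size and
resamples the DRR every evaluation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import phantom
from .camera import write_calibration
from .geometry import (
    PerturbationLabel,
    PerturbationSpec,
    RigidTransform,
    generate_perturbations,
    inertial_frame,
    write_transforms,
)
from .helical import pose_error
from .imageops import (
    DEFAULT_DRR_CHAIN,
    DEFAULT_TARGET_CHAIN,
    downsample_bicubic,
    downsample_nearest,
)
from .registration import PsoConfig, optimize_pose
from .robust import dunn_posthoc, kruskal_wallis, summarize_errors
from .volume import write_volume

logger = logging.getLogger(__name__)

CONDITIONS = ("fullres", "bicubic", "nearest")


@dataclass
class ExperimentConfig:
    """Everything that defines one run; fully determines the outputs."""

    # scene
    bone_names: tuple = ("calcaneus", "talus", "tibia")
    track_bones: tuple = ("calcaneus", "talus")
    image_size: int = 256
    downsample_size: int = 64
    volume_size: int = 64
    voxel_mm: float = 1.0
    n_frames: int = 8
    detector_width_mm: float = 120.0
    noise: phantom.NoiseSpec = field(default_factory=phantom.NoiseSpec)
    long_bone_exit: bool = False
    # perturbation
    magnitudes_deg: tuple = (2.0, 4.0, 8.0)
    # registration
    pso: PsoConfig = field(default_factory=PsoConfig)
    target_chain: tuple = DEFAULT_TARGET_CHAIN
    drr_chain: tuple = DEFAULT_DRR_CHAIN
    conditions: tuple = CONDITIONS
    drr_policy: str = "render_at_target"  # or "downsample_rendered"
    # antialias supersampling for the bicubic condition's DRRs (the targets
    # were low-passed by the resampler; the DRR must see the same filter)
    drr_supersample: int = 2
    ct_blur_mm: float = 1.5
    soft_tissue: bool = True
    # ray-march step for registration DRRs; None = renderer default
    # (half the smallest voxel spacing, matching the capture renders)
    step_mm: float | None = None
    # seeds
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.image_size % self.downsample_size != 0:
            raise ValueError("downsample size must divide the native size")
        if self.drr_policy not in ("render_at_target", "downsample_rendered"):
            raise ValueError(f"unknown drr_policy {self.drr_policy!r}")
        for c in self.conditions:
            if c not in CONDITIONS:
                raise ValueError(f"unknown condition {c!r}")

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        def clean(v):
            if isinstance(v, tuple):
                return [clean(x) for x in v]
            if isinstance(v, dict):
                return {k: clean(x) for k, x in v.items()}
            return v

        return clean(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "noise" in d and isinstance(d["noise"], dict):
            d["noise"] = phantom.NoiseSpec(**d["noise"])
        if "pso" in d and isinstance(d["pso"], dict):
            d["pso"] = PsoConfig(**d["pso"])
        for key in ("bone_names", "track_bones", "magnitudes_deg", "conditions",
                    "target_chain", "drr_chain"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def paper_scale_config(**overrides) -> ExperimentConfig:
    """Full-scale configuration (2048 native, 512 downsampled, 35 frames)
    for users with the compute budget for it."""
    base = dict(image_size=2048, downsample_size=512, volume_size=128,
                voxel_mm=0.5, n_frames=35,
                track_bones=("calcaneus", "talus", "tibia"))
    base.update(overrides)
    return ExperimentConfig(**base)


@dataclass
class TrialRecord:
    bone: str
    frame: int
    condition: str
    label: PerturbationLabel
    refined: RigidTransform
    cost: float
    rotation_err_deg: float
    translation_err_mm: float
    flags: tuple = ()

    def to_json_dict(self) -> dict:
        return {
            "bone": self.bone,
            "frame": self.frame,
            "condition": self.condition,
            "axis": self.label.axis,
            "sign": self.label.sign,
            "magnitude_deg": self.label.magnitude_deg,
            "refined_matrix": self.refined.matrix.reshape(-1).tolist(),
            "cost": self.cost,
            "rotation_err_deg": self.rotation_err_deg,
            "translation_err_mm": self.translation_err_mm,
            "flags": list(self.flags),
        }


def _derived_seed(base: int, *parts) -> int:
    """Stable small sub-seed for one registration task."""
    h = np.uint32(2166136261)
    for part in parts + (base,):
        for byte in str(part).encode():
            h = np.uint32((int(h) ^ byte) * 16777619 & 0xFFFFFFFF)
    return int(h) % (2**31 - 1)


def prepare_condition_images(images, condition: str, out_size: int):
    """Targets for one condition from the shared native noisy captures."""
    if condition == "fullres":
        return tuple(np.asarray(im, float) for im in images)
    if condition == "bicubic":
        return tuple(downsample_bicubic(im, (out_size, out_size)) for im in images)
    if condition == "nearest":
        return tuple(downsample_nearest(im, (out_size, out_size)) for im in images)
    raise ValueError(f"unknown condition {condition!r}")


def run_experiment(config: ExperimentConfig):
    """Run the full study; returns (records, summaries, tests) and writes
    them to ``config.outdir`` when set.

    Per-record failures (e.g. a pose drifting fully out of view) are flagged
    on the record, never abort the batch.
    """
    scene = phantom.make_scene(
        bone_names=config.bone_names,
        image_size=(config.image_size, config.image_size),
        volume_size=config.volume_size,
        voxel_mm=config.voxel_mm,
        n_frames=config.n_frames,
        noise=config.noise,
        seed=config.seed,
        detector_width_mm=config.detector_width_mm,
        long_bone_exit=config.long_bone_exit,
        ct_blur_mm=config.ct_blur_mm,
        soft_tissue=config.soft_tissue,
    )
    frames = phantom.render_trial(scene)

    ds = config.downsample_size
    ratio = config.image_size // ds
    # per-condition cameras and DRR supersampling: the DRR must get the same
    # sampling/filter treatment as that condition's target images
    cond_cameras = {}
    cond_supersample = {}
    for cond in config.conditions:
        if cond == "fullres":
            cond_cameras[cond] = scene.cameras
            cond_supersample[cond] = 1
        elif cond == "bicubic":
            cond_cameras[cond] = tuple(c.resize((ds, ds)) for c in scene.cameras)
            cond_supersample[cond] = (
                ratio if config.drr_policy == "downsample_rendered"
                else max(1, int(config.drr_supersample))
            )
        else:  # nearest: pixel centres coincide with the kept native pixels
            cond_cameras[cond] = tuple(c.decimate(ratio) for c in scene.cameras)
            cond_supersample[cond] = 1

    spec = PerturbationSpec(magnitudes_deg=config.magnitudes_deg)
    records: list[TrialRecord] = []
    for bone in config.track_bones:
        volume = scene.model_volume(bone)
        local_frame = inertial_frame(volume)
        for f in range(scene.n_frames):
            gold = scene.trajectory[bone][f]
            world_frame = dataclasses.replace(
                local_frame,
                origin=gold.apply(local_frame.origin),
                axes=gold.rotation @ local_frame.axes,
            )
            perturbed = generate_perturbations(gold, world_frame, spec)
            cond_targets = {
                cond: prepare_condition_images(frames[f].images, cond, ds)
                for cond in config.conditions
            }
            for label, init_pose in perturbed:
                for cond in config.conditions:
                    pso = dataclasses.replace(
                        config.pso,
                        seed=_derived_seed(config.seed, bone, f, str(label), cond),
                    )
                    flags: list = []
                    try:
                        refined, cost, _ = optimize_pose(
                            init_pose,
                            volume,
                            cond_cameras[cond],
                            cond_targets[cond],
                            pso=pso,
                            preprocess_chain=config.target_chain,
                            drr_chain=config.drr_chain,
                            centre=world_frame.origin,
                            step_mm=config.step_mm,
                            drr_supersample=cond_supersample[cond],
                        )
                        err = pose_error(gold, refined)
                    except Exception as exc:  # pragma: no cover - robustness
                        logger.warning("registration failed: %s", exc)
                        refined, cost = init_pose, float("nan")
                        err = pose_error(gold, init_pose)
                        flags.append(f"failed:{type(exc).__name__}")
                    records.append(
                        TrialRecord(
                            bone=bone,
                            frame=f,
                            condition=cond,
                            label=label,
                            refined=refined,
                            cost=cost,
                            rotation_err_deg=err.phi_deg,
                            translation_err_mm=err.translation_mm,
                            flags=tuple(flags),
                        )
                    )
            logger.info("bone %s frame %d: %d records", bone, f, len(records))

    summaries = summarize_records(records)
    tests = test_records(records)

    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_records(outdir / "records.jsonl", records)
        summaries.to_csv(outdir / "summaries.csv", index=False)
        tests.to_csv(outdir / "tests.csv", index=False)
        config.to_yaml(outdir / "config.yaml")
    return records, summaries, tests


def resolution_trial(
    seed: int,
    bone: str = "talus",
    image_size: int = 256,
    downsample_size: int = 64,
    volume_size: int = 64,
    magnitude_deg: float = 8.0,
    n_starts: int = 6,
    pso: PsoConfig | None = None,
    noise: phantom.NoiseSpec | None = None,
    detector_width_mm: float = 120.0,
    step_mm: float = 1.0,
    drr_supersample: int = 2,
) -> dict:
    """One scene seed of the resolution experiment for a single bone.

    Renders a one-frame noisy trial, perturbs the bone's gold pose by
    ``magnitude_deg`` about the first ``n_starts`` of the 14 signed
    perturbation axes, refines each start under the three resolution
    conditions, and returns ``{condition: array of helical rotation errors
    (deg)}``.  Deterministic given ``seed``.
    """
    scene = phantom.make_scene(
        image_size=(image_size, image_size),
        volume_size=volume_size,
        n_frames=1,
        noise=noise,
        seed=seed,
        detector_width_mm=detector_width_mm,
    )
    frames = phantom.render_trial(scene)
    volume = scene.model_volume(bone)
    gold = scene.trajectory[bone][0]
    local = inertial_frame(volume)
    world = dataclasses.replace(
        local, origin=gold.apply(local.origin), axes=gold.rotation @ local.axes
    )
    perturbed = generate_perturbations(
        gold, world, PerturbationSpec(magnitudes_deg=(magnitude_deg,))
    )[:n_starts]
    ratio = image_size // downsample_size
    pso = pso or PsoConfig(n_particles=16, n_iterations=50)

    out = {}
    for cond in CONDITIONS:
        targets = prepare_condition_images(frames[0].images, cond, downsample_size)
        if cond == "fullres":
            cams, supersample = scene.cameras, 1
        elif cond == "bicubic":
            cams = tuple(c.resize((downsample_size,) * 2) for c in scene.cameras)
            supersample = drr_supersample
        else:
            cams, supersample = tuple(c.decimate(ratio) for c in scene.cameras), 1
        errors = []
        for i, (label, init_pose) in enumerate(perturbed):
            cfg = dataclasses.replace(
                pso, seed=_derived_seed(seed, bone, str(label), cond, i)
            )
            refined, _, _ = optimize_pose(
                init_pose, volume, cams, targets, pso=cfg,
                centre=world.origin, step_mm=step_mm,
                drr_supersample=supersample,
            )
            errors.append(pose_error(gold, refined).phi_deg)
        out[cond] = np.array(errors)
    return out


# ---------------------------------------------------------------------------
# Summaries and statistics over records
# ---------------------------------------------------------------------------

def records_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "bone": r.bone,
            "frame": r.frame,
            "condition": r.condition,
            "magnitude_deg": r.label.magnitude_deg,
            "rotation": r.rotation_err_deg,
            "translation": r.translation_err_mm,
        }
        for r in records
    )


def summarize_records(records) -> pd.DataFrame:
    """Descriptive table: one row per bone × magnitude × condition × metric,
    errors pooled across frames and perturbation axes/signs."""
    df = records_frame(records)
    rows = []
    for (bone, mag, cond), g in df.groupby(
        ["bone", "magnitude_deg", "condition"], sort=True
    ):
        for metric in ("rotation", "translation"):
            row = {
                "bone": bone,
                "perturbation_deg": mag,
                "condition": cond,
                "metric": metric,
            }
            row.update(summarize_errors(g[metric].to_numpy()))
            rows.append(row)
    return pd.DataFrame(rows)


def test_records(records, alpha: float = 0.05) -> pd.DataFrame:
    """Kruskal–Wallis across conditions per bone × magnitude × metric, with
    Dunn/Bonferroni pairwise rows only where the omnibus test is
    significant."""
    df = records_frame(records)
    rows = []
    for (bone, mag), g in df.groupby(["bone", "magnitude_deg"], sort=True):
        conditions = sorted(g["condition"].unique())
        if len(conditions) < 2:
            continue
        for metric in ("rotation", "translation"):
            groups = [
                g.loc[g["condition"] == c, metric].to_numpy() for c in conditions
            ]
            h, p = kruskal_wallis(groups)
            base = {
                "bone": bone,
                "perturbation_deg": mag,
                "metric": metric,
                "kw_h": h,
                "kw_p": p,
            }
            if p < alpha:
                for pt in dunn_posthoc(groups, labels=conditions):
                    rows.append(
                        {
                            **base,
                            "group_a": pt.group_a,
                            "group_b": pt.group_b,
                            "z": pt.z,
                            "p_adjusted": pt.p_adjusted,
                        }
                    )
            else:
                rows.append(
                    {**base, "group_a": None, "group_b": None,
                     "z": None, "p_adjusted": None}
                )
    return pd.DataFrame(rows)


def write_records(path, records) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(json.dumps(r.to_json_dict()) + "\n")


def read_records_frame(path) -> pd.DataFrame:
    rows = [json.loads(line) for line in Path(path).read_text().splitlines() if line]
    df = pd.DataFrame(rows)
    return df


# ---------------------------------------------------------------------------
# Fixture generation
# ---------------------------------------------------------------------------

FIXTURE_SIZES = {
    "tiny": dict(image_size=64, downsample_size=16, volume_size=32, n_frames=3),
    "desk": dict(image_size=256, downsample_size=64, volume_size=64, n_frames=8),
}


def generate_fixtures(outdir, size: str = "tiny", seed: int = 0) -> Path:
    """Write a reproducible phantom trial to disk through the real-data
    formats: MHA volumes, 16-bit TIFF stacks per camera, transform CSVs,
    calibration text files and a YAML config."""
    import tifffile

    if size not in FIXTURE_SIZES:
        raise ValueError(f"unknown fixture size {size!r}")
    params = FIXTURE_SIZES[size]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = ExperimentConfig(seed=seed, **params)
    scene = phantom.make_scene(
        bone_names=config.bone_names,
        image_size=(config.image_size, config.image_size),
        volume_size=config.volume_size,
        voxel_mm=config.voxel_mm,
        n_frames=config.n_frames,
        noise=config.noise,
        seed=seed,
        detector_width_mm=config.detector_width_mm,
    )
    frames = phantom.render_trial(scene)

    for name, vol in scene.bones.items():
        write_volume(outdir / f"{name}.mha", vol)
        write_transforms(outdir / f"{name}_gold.csv", scene.trajectory[name])
    for i, cam in enumerate(scene.cameras):
        write_calibration(outdir / f"camera{i}.txt", cam)
        stack = np.stack([fr.images[i] for fr in frames])
        peak = stack.max()
        scaled = np.clip(stack / peak * 65535.0, 0, 65535).astype(np.uint16)
        tifffile.imwrite(outdir / f"camera{i}.tif", scaled, photometric="minisblack")
    config.to_yaml(outdir / "config.yaml")
    return outdir
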