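"""Synthetic biplanar trial generation.

Stands in for a real acquisition: two calibrated high-speed x-ray views of
an ankle-like cluster of bones performing a hop, with exactly known
("gold-standard") poses.  Three bone archetypes mirror the tracking
difficulty classes seen in practice:

* ``isolated`` — a calcaneus-like blob with little overlap from neighbours;
* ``enclosed`` — a talus-like blob sandwiched between the other two bones,
  so its projected edges are contaminated by overlap;
* ``long-bone`` — a tibia-like elongated shaft whose proximal end can leave
  the field of view.

Radiographs are detector-count images ``I = photon_scale * exp(-integral)``
with Poisson photon noise and Gaussian read noise applied at the native
capture resolution, so lower-resolution conditions obtained by averaging
genuinely gain signal-to-noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .camera import CameraModel, make_camera
from .drr import render_drr
from .geometry import RigidTransform
from .volume import VoxelVolume, centered_volume

BONE_KINDS = ("isolated", "enclosed", "long-bone")

#: attenuation of dense cortical shell vs trabecular interior at
#: fluoroscopic beam energies (~60 keV), mm^-1
MU_CORTICAL = 0.11
MU_TRABECULAR = 0.016


@dataclass(frozen=True)
class NoiseSpec:
    """Detector noise at the native capture resolution.

    ``photon_scale`` is the expected count at zero attenuation.  High-speed
    radiography is photon-starved: at hundreds of frames per second the
    per-frame exposure leaves only some hundred detected quanta per native
    pixel, so 150 counts on the unattenuated background (SNR ~ 12, and far
    lower behind tissue and bone) is representative.
    """

    photon_scale: float = 150.0
    read_sigma: float = 5.0
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.photon_scale <= 0:
            raise ValueError("photon_scale must be positive")
        if self.read_sigma < 0:
            raise ValueError("read_sigma must be non-negative")


@dataclass
class BiplanarFrame:
    """The pair of radiographs for one time sample, one per camera."""

    images: tuple


@dataclass
class TrialScene:
    bones: dict  # name -> VoxelVolume (ground-truth anatomy, renders captures)
    kinds: dict  # name -> bone kind
    trajectory: dict  # name -> list[RigidTransform], one per frame
    cameras: tuple  # pair of CameraModel
    noise: NoiseSpec
    seed: int
    # unmodelled structure: a soft-tissue envelope rendered into the
    # captures but absent from the per-bone partial volumes the optimiser
    # sees, as in real model-based tracking
    soft_tissue: object = None  # VoxelVolume | None
    soft_trajectory: list = None  # list[RigidTransform] | None
    # CT-fidelity partial volumes handed to the optimiser: the true anatomy
    # degraded by the CT point-spread function, so full-resolution
    # radiographs contain real structure the model cannot reproduce
    model_bones: dict = None  # name -> VoxelVolume | None
    frame_count: int = 0  # authoritative when there are no bones

    def model_volume(self, name: str):
        """Partial volume the tracking model is allowed to use."""
        if self.model_bones is not None and name in self.model_bones:
            return self.model_bones[name]
        return self.bones[name]

    @property
    def n_frames(self) -> int:
        counts = {len(v) for v in self.trajectory.values()}
        if not counts:
            return self.frame_count
        if len(counts) != 1:
            raise ValueError("all bones must share the same frame count")
        return counts.pop()


# ---------------------------------------------------------------------------
# Bone volumes
# ---------------------------------------------------------------------------

def make_bone_volume(
    kind: str,
    grid_size=(64, 64, 64),
    spacing: float = 1.0,
    seed: int = 0,
) -> VoxelVolume:
    """A smooth superellipsoid blob with a bright ~2-voxel cortical shell
    and dimmer trabecular interior; deterministic given ``seed``.

    ``long-bone`` is elongated at least 3:1 along the k (world z) axis.
    """
    if kind not in BONE_KINDS:
        raise ValueError(f"unknown bone kind {kind!r}")
    grid_size = tuple(int(g) for g in grid_size)
    if min(grid_size) < 16:
        raise ValueError("grid_size must be at least 16 per axis")
    rng = np.random.default_rng(seed)

    n = np.array(grid_size, float)
    half = (n - 1) / 2.0
    # semi-axes as fractions of the half-extent, per archetype
    centre_off = np.zeros(3)
    if kind == "isolated":
        semi = np.array([0.80, 0.62, 0.52])
        power = 2.4
    elif kind == "enclosed":
        semi = np.array([0.70, 0.60, 0.55])
        power = 2.0
    else:  # long-bone: shaft in the upper part, malleolus-like distal lobe
        semi = np.array([0.34, 0.30, 0.78])
        power = 2.6
        centre_off = np.array([0.0, 0.0, 0.15]) * half
    semi = semi * half

    idx = np.indices(grid_size, dtype=float)
    x = (idx[0] - half[0] - centre_off[0]) / semi[0]
    y = (idx[1] - half[1] - centre_off[1]) / semi[1]
    z = (idx[2] - half[2] - centre_off[2]) / semi[2]

    # low-frequency lumpy modulation of the radius (seeded)
    theta = np.arctan2(np.hypot(x, y), z)
    phi_a = np.arctan2(y, x)
    coeffs = rng.uniform(-1.0, 1.0, size=6)
    bump = (
        coeffs[0] * np.sin(2 * theta)
        + coeffs[1] * np.cos(2 * theta) * np.sin(phi_a)
        + coeffs[2] * np.sin(3 * theta) * np.cos(phi_a)
        + coeffs[3] * np.cos(2 * phi_a) * np.sin(theta)
        + coeffs[4] * np.sin(2 * phi_a + theta)
        + coeffs[5] * np.cos(3 * phi_a) * np.sin(2 * theta)
    )
    rho = (
        np.abs(x) ** power + np.abs(y) ** power + np.abs(z) ** power
    ) ** (1.0 / power)
    rho = rho * (1.0 + 0.15 * bump)

    mean_semi = float(np.exp(np.log(semi).mean()))
    shell_width = 2.0 * spacing / (mean_semi * spacing)  # ~2 voxels of rho

    inside = rho < 1.0
    shell_lo = 1.0 - shell_width

    if kind == "long-bone":
        # distal malleolus-like lobe: displaced toward +y and extending
        # below the shaft, so the projected silhouette overlaps a bone
        # sitting under the shaft without 3-D interpenetration
        lobe_centre = np.array([0.0, 0.52, -0.60]) * half
        lobe_semi = np.array([0.22, 0.15, 0.26]) * half
        lx = (idx[0] - half[0] - lobe_centre[0]) / lobe_semi[0]
        ly = (idx[1] - half[1] - lobe_centre[1]) / lobe_semi[1]
        lz = (idx[2] - half[2] - lobe_centre[2]) / lobe_semi[2]
        rho_lobe = np.sqrt(lx**2 + ly**2 + lz**2) * (1.0 + 0.08 * bump)
        inside = inside | (rho_lobe < 1.0)
        shell_mask = (inside & (rho > shell_lo) & (rho_lobe > 1.0)) | (
            (rho_lobe < 1.0) & (rho_lobe > shell_lo) & (rho > 1.0)
        )
    else:
        shell_mask = inside & (rho > shell_lo)

    vol = np.zeros(grid_size, dtype=np.float32)
    vol[inside] = MU_TRABECULAR
    vol[shell_mask] = MU_CORTICAL
    # trabecular inhomogeneity: seeded density modulation of the interior at
    # two correlation lengths.  The coarse component gives DRRs their
    # rotational signature; the fine component emulates sub-millimetre
    # trabecular structure that only high-resolution radiographs resolve
    from scipy.ndimage import gaussian_filter

    coarse = gaussian_filter(
        rng.standard_normal(grid_size), sigma=max(2.0, min(grid_size) / 12.0)
    )
    coarse /= max(np.abs(coarse).max(), 1e-12)
    fine = gaussian_filter(rng.standard_normal(grid_size), sigma=1.0)
    fine /= max(np.abs(fine).max(), 1e-12)
    interior = inside & ~shell_mask
    modulation = 1.0 + 0.5 * coarse + 0.5 * fine
    vol[interior] *= modulation[interior].astype(np.float32)
    vol = np.maximum(vol, 0.0)
    # crop to the blob's support (one empty voxel of margin): ray casting
    # cost scales with the volume's bounding box, not the blob
    nz = np.nonzero(vol)
    lo = [max(int(a.min()) - 1, 0) for a in nz]
    hi = [min(int(a.max()) + 2, s) for a, s in zip(nz, grid_size)]
    cropped = vol[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    return centered_volume(np.ascontiguousarray(cropped), spacing)


# ---------------------------------------------------------------------------
# Camera rig
# ---------------------------------------------------------------------------

def make_camera_rig(
    image_size=(256, 256),
    pixel_pitch_mm: float = 0.7,
    source_to_detector_mm: float = 1300.0,
    source_to_origin_mm: float = 1100.0,
    inter_view_angle_deg: float = 60.0,
) -> tuple[CameraModel, CameraModel]:
    """Two pinhole projectors whose principal rays intersect at the world
    origin, separated by ``inter_view_angle_deg`` about the world vertical
    (+z).  Defaults are plausible laboratory values, not a reconstruction of
    any specific system."""
    if not 0.0 < inter_view_angle_deg < 180.0:
        raise ValueError("inter_view_angle must be in (0, 180) degrees")
    cams = []
    for sign in (-1.0, +1.0):
        a = np.deg2rad(sign * inter_view_angle_deg / 2.0)
        source = source_to_origin_mm * np.array([np.sin(a), -np.cos(a), 0.0])
        cams.append(
            make_camera(
                source,
                look_at=np.zeros(3),
                up=np.array([0.0, 0.0, 1.0]),
                image_size=image_size,
                pixel_pitch_mm=pixel_pitch_mm,
                source_to_detector_mm=source_to_detector_mm,
            )
        )
    return tuple(cams)


# ---------------------------------------------------------------------------
# Gold-standard trajectory
# ---------------------------------------------------------------------------

#: anatomical-ish scene layout: world-mm offset of each bone's volume centre.
#: Joint spaces of a few mm separate the bones in 3-D; the tibia's distal
#: lobe and the calcaneus still overlap the talus in projection.
DEFAULT_OFFSETS = {
    "calcaneus": np.array([0.0, 10.0, -36.0]),
    "talus": np.array([0.0, 0.0, 0.0]),
    "tibia": np.array([0.0, -2.0, 54.0]),
}


def make_trajectory(
    n_frames: int,
    bone_names=("calcaneus", "talus", "tibia"),
    pattern: str = "hop",
    amplitude_mm: float = 10.0,
    amplitude_deg: float = 6.0,
    seed: int = 0,
    offsets: dict | None = None,
    long_bone_exit: bool = False,
    exit_bones=("tibia",),
    exit_shift_mm: float = 40.0,
) -> dict:
    """Per-bone smooth hop-like pose lists.

    A half-sine vertical translation plus a plantarflexion-like rotation
    about the x axis; bones move near-rigidly together with small seeded
    relative amplitude differences (±5%).  With ``long_bone_exit`` the exit
    bones get an extra upward shift in the first and last ~15% of frames so
    their proximal end leaves the field of view.
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    if pattern != "hop":
        raise ValueError(f"unknown pattern {pattern!r}")
    offsets = dict(DEFAULT_OFFSETS if offsets is None else offsets)
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, n_frames) if n_frames > 1 else np.array([0.5])
    hop = np.sin(np.pi * t)

    edge = np.zeros(n_frames)
    if long_bone_exit and n_frames > 1:
        width = max(0.15, 1.5 / n_frames)
        edge = np.clip(1.0 - t / width, 0.0, 1.0) + np.clip(
            1.0 - (1.0 - t) / width, 0.0, 1.0
        )

    out: dict = {}
    for name in bone_names:
        base = offsets.get(name, np.zeros(3))
        scale_t = 1.0 + 0.05 * rng.standard_normal()
        scale_r = 1.0 + 0.05 * rng.standard_normal()
        phase = 0.1 * rng.standard_normal()
        poses = []
        for f in range(n_frames):
            dz = amplitude_mm * scale_t * hop[f]
            ang = amplitude_deg * scale_r * np.sin(np.pi * t[f] + phase)
            if long_bone_exit and name in exit_bones:
                dz += exit_shift_mm * edge[f]
            rot = RigidTransform.from_rotvec_deg([ang, 0.0, 0.0])
            pose = RigidTransform(
                rot.rotation, base + np.array([0.0, 0.0, dz])
            )
            poses.append(pose)
        out[name] = poses
    return out


# ---------------------------------------------------------------------------
# Scene assembly and rendering
# ---------------------------------------------------------------------------

DEFAULT_BONE_KINDS = {
    "calcaneus": "isolated",
    "talus": "enclosed",
    "tibia": "long-bone",
}

#: soft tissue attenuation (water-like at diagnostic energies), mm^-1
MU_SOFT = 0.018


def make_soft_tissue(seed: int = 0, spacing: float = 2.0):
    """Smooth soft-tissue envelope enclosing the default bone cluster.

    Coarsely sampled (the envelope has no fine structure) and slightly
    lumpy; attenuation is water-like.  The envelope is rendered into the
    captures but never given to the optimiser.
    """
    rng = np.random.default_rng(seed + 977)
    grid = (40, 36, 96)
    half = (np.array(grid, float) - 1) / 2.0
    idx = np.indices(grid, dtype=float)
    semi = np.array([0.82, 0.80, 0.94]) * half
    x = (idx[0] - half[0]) / semi[0]
    y = (idx[1] - half[1]) / semi[1]
    z = (idx[2] - half[2]) / semi[2]
    r = np.sqrt(x**2 + y**2 + z**2)
    r = r * (1.0 + 0.05 * np.sin(3 * np.arctan2(y, x) + rng.uniform(0, 2 * np.pi)))
    vol = np.where(r < 1.0, MU_SOFT, 0.0).astype(np.float32)
    out = centered_volume(vol, spacing)
    # shift the envelope so it brackets calcaneus through distal tibia
    out.origin = out.origin + np.array([0.0, 2.0, 10.0])
    return out


def make_scene(
    bone_names=("calcaneus", "talus", "tibia"),
    image_size=(256, 256),
    volume_size: int = 64,
    voxel_mm: float = 1.0,
    n_frames: int = 8,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    detector_width_mm: float = 120.0,
    long_bone_exit: bool = False,
    amplitude_mm: float = 10.0,
    amplitude_deg: float = 6.0,
    soft_tissue: bool = True,
    ct_blur_mm: float = 1.5,
) -> TrialScene:
    """Assemble the default desk-scale trial scene.

    ``ct_blur_mm`` is the point-spread width of the emulated CT scan that
    produces the tracking model's partial volumes; 0 hands the optimiser the
    ground-truth anatomy (an idealisation real studies cannot reach).
    """
    from scipy.ndimage import gaussian_filter

    rows, cols = (int(image_size[0]), int(image_size[1]))
    bones = {}
    model_bones = {}
    kinds = {}
    for i, name in enumerate(bone_names):
        kind = DEFAULT_BONE_KINDS.get(name, "isolated")
        gs = (volume_size,) * 3
        if kind == "long-bone":
            gs = (volume_size, volume_size, int(volume_size * 1.6))
        vol = make_bone_volume(kind, gs, voxel_mm, seed=seed * 101 + i)
        bones[name] = vol
        kinds[name] = kind
        if ct_blur_mm > 0:
            blurred = gaussian_filter(
                vol.intensities, sigma=ct_blur_mm / np.asarray(vol.spacing)
            ).astype(np.float32)
            model_bones[name] = VoxelVolume(
                blurred, vol.spacing, vol.origin, vol.direction
            )
        else:
            model_bones[name] = vol
    cameras = make_camera_rig(
        image_size=(rows, cols), pixel_pitch_mm=detector_width_mm / cols
    )
    trajectory = make_trajectory(
        n_frames,
        bone_names=bone_names,
        seed=seed,
        long_bone_exit=long_bone_exit,
        amplitude_mm=amplitude_mm,
        amplitude_deg=amplitude_deg,
    )
    soft_vol = None
    soft_traj = None
    if soft_tissue:
        soft_vol = make_soft_tissue(seed=seed)
        # the envelope follows the hop translation (no rotation): soft
        # tissue deforms rather than rotating rigidly with any one bone
        t = np.linspace(0.0, 1.0, n_frames) if n_frames > 1 else np.array([0.5])
        soft_traj = [
            RigidTransform(
                np.eye(3), np.array([0.0, 0.0, amplitude_mm * np.sin(np.pi * tf)])
            )
            for tf in t
        ]
    return TrialScene(
        bones=bones,
        kinds=kinds,
        trajectory=trajectory,
        cameras=cameras,
        noise=noise if noise is not None else NoiseSpec(),
        seed=seed,
        soft_tissue=soft_vol,
        soft_trajectory=soft_traj,
        model_bones=model_bones,
        frame_count=n_frames,
    )


def render_clean_integral(
    scene: TrialScene, frame: int, camera: CameraModel
) -> np.ndarray:
    """Noiseless line-integral image of all bones (plus the soft-tissue
    envelope, when present) at their gold poses."""
    total = np.zeros(camera.image_size)
    for name, vol in scene.bones.items():
        total += render_drr(vol, scene.trajectory[name][frame], camera)
    if scene.soft_tissue is not None:
        total += render_drr(
            scene.soft_tissue, scene.soft_trajectory[frame], camera
        )
    return total


def render_trial(scene: TrialScene) -> list:
    """Noisy captured radiographs for every frame and camera.

    Counts ``photon_scale * exp(-integral)`` are Poisson-sampled, Gaussian
    read noise added, and the result clipped at zero; fully deterministic
    given ``scene.seed``.
    """
    rng = np.random.default_rng(scene.seed)
    noise = scene.noise
    frames = []
    for f in range(scene.n_frames):
        images = []
        for cam in scene.cameras:
            integral = render_clean_integral(scene, f, cam)
            counts = noise.photon_scale * np.exp(-integral)
            if noise.enabled:
                counts = rng.poisson(counts).astype(float)
                counts += rng.normal(0.0, noise.read_sigma, size=counts.shape)
                counts = np.maximum(counts, 0.0)
            images.append(counts)
        frames.append(BiplanarFrame(images=tuple(images)))
    return frames
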