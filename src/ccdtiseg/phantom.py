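"""Synthetic diffusion-tensor phantom of the corpus callosum.

The phantom emulates the anatomy the segmentation relies on: an arch-shaped
commissural bundle in the sagittal plane whose principal diffusion
direction is dominantly left-right through the body and tilts toward
anterior-posterior at the genu/splenium ends, an inferior-anterior recurve
(rostrum), plus adjacent distractor bundles designed to each violate one
admission gate at the interface:

  * cingulum  - straight anterior-posterior tube just superior to the
                body (fails the PDD collinearity and PDD_x gates),
  * forceps   - smooth fanning continuations beyond both arch ends whose
                PDD tilts past the left-right cone (|PDD_x| < 0.55); the
                gradual transition mimics the real difficulty of the
                CC/forceps boundary and makes the PDD_x gate the active
                separator there,
  * tapetum   - low-anisotropy sheet posterior-inferior to the splenium
                with corpus-callosum-like orientation (fails the FA gate),

all embedded in an isotropic background. Tensors are axially symmetric,
lambda = (1.7, 0.3, 0.3) x 1e-3 mm^2/s in the bundles (FA = 0.799) and
0.8e-3 isotropic outside. Optional zero-mean Gaussian perturbation of the
six tensor components models measurement noise; eigenvalues are re-clamped
to keep tensors PSD. Everything is reproducible from the integer seed.
"""

from __future__ import annotations

import dataclasses
import json
import os

import numpy as np
from scipy.ndimage import binary_dilation

from .dti_io import (
    TensorVolume,
    _clamp_psd,
    write_mask_nifti,
    write_tensor_nifti,
)
from .levelset import SeedSet
from .witelson import LABEL_NAMES, MidSagittalPlane, WitelsonLabels, witelson_subdivide

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "generate_cc_phantom",
    "write_fixture_bundle",
    "DISTRACTOR_LABELS",
]

DISTRACTOR_LABELS = {1: "cingulum", 2: "forceps", 3: "tapetum"}

CC_EIGENVALUES = (1.7e-3, 0.3e-3, 0.3e-3)
BACKGROUND_EIGENVALUE = 0.8e-3
TAPETUM_EIGENVALUES = (0.85e-3, 0.775e-3, 0.775e-3)  # FA ~ 0.054, below gate

# PDD fan at the arch ends: fibers tilt away from left-right toward a
# fixed oblique direction with anterior-posterior (outward) and
# systematically inferior dorsoventral components, reaching CC_MAX_TILT
# at the arch termination while still passing the default |PDD_x| gate.
CC_MAX_TILT_DEG = 52.0
FAN_DV_WEIGHT = np.sin(np.radians(75.0))  # dorsoventral share of the fan
FAN_AP_WEIGHT = np.cos(np.radians(75.0))
FAN_RAMP_START = 0.25  # fraction of the half-angle where the fan begins
ARC_HALF_ANGLE_DEG = 100.0
# beyond the arch the fan continues smoothly into the forceps with a
# steeper tilt slope (deg of tilt per deg of arc); the transition ring
# whose tilt still passes the default |PDD_x| gate belongs to neither
# ground-truth label (partial-volume-like ambiguous tissue)
FORCEPS_TILT_SLOPE = 2.0
FORCEPS_LABEL_START_DEG = 108.0
FORCEPS_EXTRA_ANGLE_DEG = 35.0
FORCEPS_MAX_TILT_DEG = 115.0


@dataclasses.dataclass
class PhantomSpec:
    """Geometry, tensor and noise parameters of the phantom."""

    grid_shape: tuple = (64, 96, 64)
    arch_radius: float | None = None  # default: scaled to the grid
    tube_radius: float = 3.0
    lateral_halfwidth: float | None = None
    cc_eigenvalues: tuple = CC_EIGENVALUES
    background_eigenvalue: float = BACKGROUND_EIGENVALUE
    distractors: tuple = ("cingulum", "forceps", "tapetum")
    noise_sd: float = 0.0
    seed: int = 0
    voxel_size_mm: float = 1.9

    def __post_init__(self):
        if self.tube_radius < 2:
            raise ValueError("tube_radius must be >= 2 voxels")
        lam = tuple(self.cc_eigenvalues)
        if not (lam[0] >= lam[1] >= lam[2] > 0):
            raise ValueError("cc_eigenvalues must be descending positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.arch_radius is None:
            self.arch_radius = 0.23 * self.grid_shape[1]
        if self.lateral_halfwidth is None:
            self.lateral_halfwidth = max(3.0, 0.07 * self.grid_shape[0])
        ztop = 0.47 * self.grid_shape[2] + self.arch_radius + self.tube_radius
        if ztop >= self.grid_shape[2] - 5:
            raise ValueError("arch geometry exceeds the grid")


@dataclasses.dataclass
class PhantomTruth:
    """Phantom volume plus every ground-truth object tests score against."""

    tensors: TensorVolume
    cc_mask: np.ndarray
    witelson_truth: WitelsonLabels
    distractor_labels: np.ndarray
    seeds_suggested: SeedSet
    critical_point: tuple
    midsagittal_index: int
    spec: PhantomSpec


def _axisymmetric_tensor_field(e1, lam_long, lam_perp):
    """D = (l1 - l2) e1 e1^T + l2 I for unit direction field e1 (..., 3)."""
    outer = np.einsum("...i,...j->...ij", e1, e1)
    return (lam_long - lam_perp) * outer + lam_perp * np.eye(3)


def generate_cc_phantom(spec: PhantomSpec | None = None) -> PhantomTruth:
    """Build the phantom and its ground truth; deterministic given the seed."""
    if spec is None:
        spec = PhantomSpec()
    nx, ny, nz = spec.grid_shape
    cx = (nx - 1) / 2.0
    cy, cz = 0.49 * ny, 0.47 * nz
    R = float(spec.arch_radius)
    rt = float(spec.tube_radius)
    hx = float(spec.lateral_halfwidth)

    X, Y, Z = np.meshgrid(
        np.arange(nx, dtype=float),
        np.arange(ny, dtype=float),
        np.arange(nz, dtype=float),
        indexing="ij",
    )
    lateral = np.abs(X - cx) <= hx
    dy, dz = Y - cy, Z - cz
    rad = np.sqrt(dy * dy + dz * dz)
    # polar angle from superior (+z of center), signed toward anterior (+y)
    theta = np.degrees(np.arctan2(dy, dz))
    in_ring = np.abs(rad - R) <= rt

    half = ARC_HALF_ANGLE_DEG
    arch = lateral & in_ring & (np.abs(theta) <= half)

    # rostrum: straight tube from the genu tip heading posterior-inferior
    gy = cy + R * np.sin(np.radians(half))
    gz = cz + R * np.cos(np.radians(half))
    d_arm = np.array([-0.87, -0.5])
    arm_len = 0.4 * R
    s = (Y - gy) * d_arm[0] + (Z - gz) * d_arm[1]
    py, pz = gy + np.clip(s, 0, arm_len) * d_arm[0], gz + np.clip(s, 0, arm_len) * d_arm[1]
    arm_dist = np.sqrt((Y - py) ** 2 + (Z - pz) ** 2)
    rostrum_arm = lateral & (arm_dist <= rt)

    cc_mask = arch | rostrum_arm

    # --- distractors ---------------------------------------------------
    dist = np.zeros(spec.grid_shape, dtype=np.uint8)
    ztop = cz + R
    if "cingulum" in spec.distractors:
        r_cing = max(2.0, rt - 1.0)
        z_cing = ztop + rt + 2.0 + r_cing
        # slab-shaped tube along y, 2 voxels above the arch apex
        in_cing = (
            lateral
            & (np.abs(Z - z_cing) <= r_cing)
            & (np.abs(Y - cy) <= R + rt)
        )
        dist[in_cing & ~cc_mask] = 1
    fan_extension = (
        lateral
        & in_ring
        & (np.abs(theta) > half)
        & (np.abs(theta) <= half + FORCEPS_EXTRA_ANGLE_DEG)
    )
    if "forceps" in spec.distractors:
        # a 2-voxel buffer around the rostrum arm stays unlabeled: fiber
        # orientations there grade between arm and fan (partial volume)
        near_arm = binary_dilation(rostrum_arm, iterations=2)
        dist[
            fan_extension
            & (np.abs(theta) >= FORCEPS_LABEL_START_DEG)
            & ~cc_mask
            & ~near_arm
        ] = 2
    if "tapetum" in spec.distractors:
        sy = cy + R * np.sin(np.radians(-half))
        sz = gz
        tap = (
            lateral
            & (Y >= sy - 0.6 * R)
            & (Y <= sy - 0.1 * R)
            & (np.abs(Z - (sz - 0.3 * R)) <= rt)
        )
        dist[tap & ~cc_mask] = 3

    # --- tensor field --------------------------------------------------
    l1, l2, _ = spec.cc_eigenvalues
    tensors = np.zeros(spec.grid_shape + (3, 3))
    tensors[...] = spec.background_eigenvalue * np.eye(3)

    # CC orientation: left-right through the body, fanning toward a
    # y-z cone near the arch ends
    ramp_start = FAN_RAMP_START * half
    absth = np.abs(theta)
    ramp = np.clip((absth - ramp_start) / (half - ramp_start), 0.0, 1.0)
    tilt_deg = np.where(
        absth <= half,
        CC_MAX_TILT_DEG * ramp,
        np.minimum(
            CC_MAX_TILT_DEG + FORCEPS_TILT_SLOPE * (absth - half),
            FORCEPS_MAX_TILT_DEG,
        ),
    )
    tilt = np.radians(tilt_deg)
    # unit fan direction: anterior-posterior (outward, sign of theta) mixed
    # with a systematic inferior (dorsoventral) bend at both ends
    u_y = FAN_AP_WEIGHT * np.sign(theta)
    u_z = -FAN_DV_WEIGHT
    e1_cc = np.stack(
        [
            np.cos(tilt),
            np.sin(tilt) * u_y,
            np.sin(tilt) * u_z * np.ones_like(tilt),
        ],
        axis=-1,
    )
    e1_cc /= np.linalg.norm(e1_cc, axis=-1, keepdims=True)
    cc_field = _axisymmetric_tensor_field(e1_cc, l1, l2)
    tensors[cc_mask] = cc_field[cc_mask]
    # rostrum arm: orientation bends smoothly from the genu-end fan
    # direction back to pure left-right along the arm
    s_arm = np.clip(s, 0.0, arm_len)
    arm_tilt = np.radians(CC_MAX_TILT_DEG) * np.clip(
        1.0 - s_arm / (0.5 * arm_len), 0.0, 1.0
    )
    e1_arm = np.stack(
        [
            np.cos(arm_tilt),
            np.sin(arm_tilt) * FAN_AP_WEIGHT,
            -np.sin(arm_tilt) * FAN_DV_WEIGHT,
        ],
        axis=-1,
    )
    e1_arm /= np.linalg.norm(e1_arm, axis=-1, keepdims=True)
    arm_field = _axisymmetric_tensor_field(e1_arm, l1, l2)
    tensors[rostrum_arm] = arm_field[rostrum_arm]

    if "cingulum" in spec.distractors:
        tensors[dist == 1] = _axisymmetric_tensor_field(
            np.array([0.0, 1.0, 0.0]), l1, l2
        )
    if "forceps" in spec.distractors:
        # the fan continues smoothly past the arch end (gradual CC-to-
        # forceps transition); same direction field, steeper tilt; the
        # rostrum arm crossing this ring band keeps its own orientation
        ext = fan_extension & ~cc_mask
        tensors[ext] = cc_field[ext]
    if "tapetum" in spec.distractors:
        tl1, tl2, _ = TAPETUM_EIGENVALUES
        tensors[dist == 3] = _axisymmetric_tensor_field(
            np.array([1.0, 0.0, 0.0]), tl1, tl2
        )

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        noise = rng.normal(0.0, spec.noise_sd, spec.grid_shape + (3, 3))
        noise = 0.5 * (noise + np.swapaxes(noise, 3, 4))
        tensors = _clamp_psd(tensors + noise)

    volume = TensorVolume(
        tensors=tensors, voxel_size=np.full(3, spec.voxel_size_mm)
    )

    # --- ground-truth parcellation and seeds ---------------------------
    mid = int(round(cx))
    crit = (float(gy), float(gz))
    plane = MidSagittalPlane(axis=0, slice_index=mid)
    wit = witelson_subdivide(cc_mask, plane, critical_point=crit)

    seed_pts = []
    for th in (-80.0, -40.0, 0.0, 40.0, 80.0):
        sy_ = cy + R * np.sin(np.radians(th))
        sz_ = cz + R * np.cos(np.radians(th))
        seed_pts.append([mid, round(sy_), round(sz_)])
    seeds = SeedSet(points=np.array(seed_pts, dtype=float), sphere_radius=2.0)

    return PhantomTruth(
        tensors=volume,
        cc_mask=cc_mask,
        witelson_truth=wit,
        distractor_labels=dist,
        seeds_suggested=seeds,
        critical_point=crit,
        midsagittal_index=mid,
        spec=spec,
    )


def analytic_cc_volume(spec: PhantomSpec) -> float:
    """Closed-form voxel count of the constructed bundle (arch sector slab
    + rostrum arm), for validating the generated mask."""
    cx = (spec.grid_shape[0] - 1) / 2.0
    hx = spec.lateral_halfwidth
    width = np.floor(cx + hx) - np.ceil(cx - hx) + 1  # lattice slab width
    arc = 2.0 * np.radians(ARC_HALF_ANGLE_DEG) * spec.arch_radius
    ring_area = arc * 2.0 * spec.tube_radius
    arm_area = (0.4 * spec.arch_radius - spec.tube_radius) * 2.0 * spec.tube_radius
    return width * (ring_area + arm_area)


def write_fixture_bundle(truth: PhantomTruth, directory) -> dict:
    """Write tensors, masks, labels (NIfTI), seeds.txt and spec JSON.

    Refuses to overwrite an existing directory.
    """
    directory = str(directory)
    if os.path.exists(directory):
        raise FileExistsError(f"{directory} already exists")
    os.makedirs(directory)
    vs = truth.tensors.voxel_size
    paths = {
        "tensors": os.path.join(directory, "tensors.nii.gz"),
        "cc_mask": os.path.join(directory, "cc_mask.nii.gz"),
        "witelson": os.path.join(directory, "witelson_labels.nii.gz"),
        "distractors": os.path.join(directory, "distractor_labels.nii.gz"),
        "seeds": os.path.join(directory, "seeds.txt"),
        "spec": os.path.join(directory, "phantom_spec.json"),
        "label_map": os.path.join(directory, "label_map.json"),
    }
    write_tensor_nifti(truth.tensors, paths["tensors"])
    write_mask_nifti(truth.cc_mask, vs, paths["cc_mask"])
    write_mask_nifti(truth.witelson_truth.labels, vs, paths["witelson"])
    write_mask_nifti(truth.distractor_labels, vs, paths["distractors"])
    np.savetxt(paths["seeds"], truth.seeds_suggested.points, fmt="%d")
    sp = dataclasses.asdict(truth.spec)
    sp["grid_shape"] = list(sp["grid_shape"])
    sp["cc_eigenvalues"] = list(sp["cc_eigenvalues"])
    sp["distractors"] = list(sp["distractors"])
    with open(paths["spec"], "w") as fh:
        json.dump(sp, fh, indent=2)
    with open(paths["label_map"], "w") as fh:
        json.dump(
            {
                "witelson": {str(k): v for k, v in LABEL_NAMES.items() if k},
                "distractors": {str(k): v for k, v in DISTRACTOR_LABELS.items()},
            },
            fh,
            indent=2,
        )
    return paths
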