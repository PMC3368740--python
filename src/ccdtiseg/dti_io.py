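"""Diffusion-weighted image I/O, tensor fitting, and isotropic resampling.

Coordinate convention used throughout the package: 0-based voxel indices,
axis 0 = left-right (x), axis 1 = anterior-posterior (y),
axis 2 = inferior-superior (z).

Tensors are stored on disk as 6-component NIfTI volumes in lower-triangular
order (Dxx, Dxy, Dyy, Dxz, Dyz, Dzz); gradient tables as FSL-style
plain-text bval/bvec files.
"""

from __future__ import annotations

import dataclasses
import os

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "GradientTable",
    "TensorVolume",
    "ScalarVolume",
    "read_dwi",
    "read_gradient_table",
    "fit_tensors",
    "resample_isotropic",
    "read_tensor_nifti",
    "write_tensor_nifti",
    "write_scalar_nifti",
    "read_mask_nifti",
    "write_mask_nifti",
    "tensors_to_lower_tri",
    "lower_tri_to_tensors",
]

_LOWER_TRI_INDEX = [(0, 0), (0, 1), (1, 1), (0, 2), (1, 2), (2, 2)]


@dataclasses.dataclass(frozen=True)
class GradientTable:
    """Diffusion gradient scheme: b-values (s/mm^2) and unit directions.

    ``bvecs`` rows are zero for b=0 volumes and unit-norm otherwise
    (validated to 1e-6).
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self):
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise ValueError(f"bvecs must be (n, 3), got {bvecs.shape}")
        if bvals.shape[0] != bvecs.shape[0]:
            raise ValueError(
                f"bvals ({bvals.shape[0]}) and bvecs ({bvecs.shape[0]}) "
                "row counts differ"
            )
        if not np.any(bvals == 0):
            raise ValueError("gradient table has no b=0 reference volume")
        nz = bvals > 0
        norms = np.linalg.norm(bvecs[nz], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("nonzero-b gradient directions must be unit norm")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    def __len__(self) -> int:
        return self.bvals.shape[0]

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0


@dataclasses.dataclass
class TensorVolume:
    """3D grid of symmetric PSD 3x3 diffusion tensors, shape (X, Y, Z, 3, 3).

    ``voxel_size`` is in mm. Symmetry is enforced at construction;
    eigenvalues are expected >= 0 (fitting clamps them).
    """

    tensors: np.ndarray
    voxel_size: np.ndarray = dataclasses.field(
        default_factory=lambda: np.ones(3)
    )

    def __post_init__(self):
        t = np.asarray(self.tensors, dtype=float)
        if t.ndim != 5 or t.shape[3:] != (3, 3):
            raise ValueError(f"tensors must be (X, Y, Z, 3, 3), got {t.shape}")
        if not np.all(np.isfinite(t)):
            raise ValueError("tensor volume contains non-finite values")
        asym = np.max(np.abs(t - np.swapaxes(t, 3, 4)))
        if asym > 1e-10:
            raise ValueError(f"tensors not symmetric (max asymmetry {asym:g})")
        # exact symmetrization so downstream eigh sees clean input
        self.tensors = 0.5 * (t + np.swapaxes(t, 3, 4))
        self.voxel_size = np.asarray(self.voxel_size, dtype=float).ravel()
        if self.voxel_size.shape != (3,) or np.any(self.voxel_size <= 0):
            raise ValueError("voxel_size must be 3 positive numbers")

    @property
    def shape(self) -> tuple:
        return self.tensors.shape[:3]


@dataclasses.dataclass
class ScalarVolume:
    """3D scalar grid (FA map, phi snapshot, ...) sharing a tensor grid."""

    values: np.ndarray
    voxel_size: np.ndarray = dataclasses.field(
        default_factory=lambda: np.ones(3)
    )

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D grid")
        self.voxel_size = np.asarray(self.voxel_size, dtype=float).ravel()

    @property
    def shape(self) -> tuple:
        return self.values.shape


def read_gradient_table(bvals_path, bvecs_path) -> GradientTable:
    """Read FSL-style bval/bvec text files.

    bval: one row of n values. bvec: 3 rows of n values (or n rows of 3).
    """
    bvals = np.loadtxt(bvals_path, dtype=float).ravel()
    bvecs = np.loadtxt(bvecs_path, dtype=float)
    if bvecs.ndim == 1:
        bvecs = bvecs.reshape(1, -1)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape[0] == 3 and bvecs.shape[1] == 3 and bvals.size != 3:
        raise ValueError("ambiguous 3x3 bvec table")
    return GradientTable(bvals=bvals, bvecs=bvecs)


def read_dwi(path, bvals_path, bvecs_path):
    """Load a 4D DWI NIfTI and its gradient table, validated against each other.

    Returns ``(data, gtab, voxel_size)`` with data shaped (X, Y, Z, n).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected 4D DWI volume, got shape {data.shape}")
    gtab = read_gradient_table(bvals_path, bvecs_path)
    if len(gtab) != data.shape[3]:
        raise ValueError(
            f"gradient table has {len(gtab)} rows but DWI has "
            f"{data.shape[3]} volumes"
        )
    voxel_size = np.asarray(img.header.get_zooms()[:3], dtype=float)
    return data, gtab, voxel_size


def fit_tensors(dwi, gtab: GradientTable, voxel_size=(1.0, 1.0, 1.0)) -> TensorVolume:
    """Log-linear least-squares tensor fit.

    Solves, per voxel, ``log(S_i / S0) = -b_i g_i^T D g_i`` for the six
    unique components of D, then clamps negative eigenvalues to zero.
    Voxels with S0 <= 0 (or any nonpositive DWI sample) get the zero tensor.
    """
    dwi = np.asarray(dwi, dtype=float)
    nz = ~gtab.b0_mask
    bvecs = gtab.bvecs[nz]
    bvals = gtab.bvals[nz]
    uniq = np.unique(np.round(np.abs(bvecs), 6), axis=0)
    if uniq.shape[0] < 6:
        raise ValueError(
            f"need >= 6 distinct nonzero gradient directions, got {uniq.shape[0]}"
        )

    # design matrix rows: b * (gx^2, 2 gx gy, gy^2, 2 gx gz, 2 gy gz, gz^2)
    gx, gy, gz = bvecs[:, 0], bvecs[:, 1], bvecs[:, 2]
    design = bvals[:, None] * np.stack(
        [gx * gx, 2 * gx * gy, gy * gy, 2 * gx * gz, 2 * gy * gz, gz * gz],
        axis=1,
    )

    s0 = dwi[..., gtab.b0_mask].mean(axis=-1)
    sig = dwi[..., nz]
    valid = (s0 > 0) & np.all(sig > 0, axis=-1)

    shape = dwi.shape[:3]
    coeffs = np.zeros(shape + (6,))
    if np.any(valid):
        y = -np.log(sig[valid] / s0[valid, None])  # (nvox, ndir)
        sol, *_ = np.linalg.lstsq(design, y.T, rcond=None)
        coeffs[valid] = sol.T

    tensors = lower_tri_to_tensors(coeffs)
    tensors = _clamp_psd(tensors)
    return TensorVolume(tensors=tensors, voxel_size=np.asarray(voxel_size))


def _clamp_psd(tensors: np.ndarray) -> np.ndarray:
    """Clamp negative eigenvalues of a (..., 3, 3) symmetric field to zero."""
    t = 0.5 * (tensors + np.swapaxes(tensors, -1, -2))
    w, v = np.linalg.eigh(t)
    if np.all(w >= 0):
        return t
    w = np.clip(w, 0.0, None)
    return np.einsum("...ij,...j,...kj->...ik", v, w, v)


def tensors_to_lower_tri(tensors: np.ndarray) -> np.ndarray:
    """(..., 3, 3) symmetric -> (..., 6) in (Dxx, Dxy, Dyy, Dxz, Dyz, Dzz)."""
    out = np.empty(tensors.shape[:-2] + (6,), dtype=tensors.dtype)
    for k, (i, j) in enumerate(_LOWER_TRI_INDEX):
        out[..., k] = tensors[..., i, j]
    return out


def lower_tri_to_tensors(tri: np.ndarray) -> np.ndarray:
    """(..., 6) lower-triangular components -> (..., 3, 3) symmetric."""
    out = np.zeros(tri.shape[:-1] + (3, 3), dtype=float)
    for k, (i, j) in enumerate(_LOWER_TRI_INDEX):
        out[..., i, j] = tri[..., k]
        out[..., j, i] = tri[..., k]
    return out


def resample_isotropic(volume, target_voxel_mm: float = 1.9):
    """Resample a TensorVolume or ScalarVolume to an isotropic grid.

    Component-wise trilinear interpolation; tensors are re-symmetrized.
    The default 1.9 mm spacing matches a typical clinical DTI working grid.
    Returns the same kind of volume. Identity when spacing already matches.
    """
    if target_voxel_mm <= 0:
        raise ValueError("target_voxel_mm must be positive")
    if isinstance(volume, TensorVolume):
        field = tensors_to_lower_tri(volume.tensors)
        is_tensor = True
    elif isinstance(volume, ScalarVolume):
        field = volume.values[..., None]
        is_tensor = False
    else:
        raise TypeError("volume must be TensorVolume or ScalarVolume")

    src_spacing = volume.voxel_size
    if np.allclose(src_spacing, target_voxel_mm):
        return volume

    shape = np.array(field.shape[:3])
    extent = (shape - 1) * src_spacing
    new_shape = np.maximum(np.floor(extent / target_voxel_mm).astype(int) + 1, 1)
    grids = np.meshgrid(
        *[np.arange(n) * target_voxel_mm / s for n, s in zip(new_shape, src_spacing)],
        indexing="ij",
    )
    coords = np.stack([g.ravel() for g in grids])

    out = np.empty(tuple(new_shape) + (field.shape[3],))
    for c in range(field.shape[3]):
        out[..., c] = map_coordinates(
            field[..., c], coords, order=1, mode="nearest"
        ).reshape(tuple(new_shape))

    vs = np.full(3, float(target_voxel_mm))
    if is_tensor:
        t = lower_tri_to_tensors(out)
        return TensorVolume(tensors=t, voxel_size=vs)
    return ScalarVolume(values=out[..., 0], voxel_size=vs)


# ---------------------------------------------------------------- NIfTI I/O

def _affine(voxel_size) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def write_tensor_nifti(volume: TensorVolume, path) -> None:
    tri = tensors_to_lower_tri(volume.tensors).astype(np.float32)
    nib.save(nib.Nifti1Image(tri, _affine(volume.voxel_size)), str(path))


def read_tensor_nifti(path) -> TensorVolume:
    img = nib.load(str(path))
    tri = np.asarray(img.dataobj, dtype=float)
    if tri.ndim != 4 or tri.shape[3] != 6:
        raise ValueError(f"expected 6-component tensor NIfTI, got {tri.shape}")
    vs = np.asarray(img.header.get_zooms()[:3], dtype=float)
    return TensorVolume(tensors=lower_tri_to_tensors(tri), voxel_size=vs)


def write_scalar_nifti(values, voxel_size, path) -> None:
    arr = np.asarray(values, dtype=np.float32)
    nib.save(nib.Nifti1Image(arr, _affine(voxel_size)), str(path))


def write_mask_nifti(mask, voxel_size, path) -> None:
    arr = np.asarray(mask).astype(np.uint8)
    nib.save(nib.Nifti1Image(arr, _affine(voxel_size)), str(path))


def read_mask_nifti(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj) > 0
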