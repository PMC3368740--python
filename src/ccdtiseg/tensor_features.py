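"""Per-voxel tensor eigen-analysis: fractional anisotropy and principal
diffusion direction fields.

The principal diffusion direction (PDD) is the eigenvector of the largest
eigenvalue. Eigenvectors are sign-indeterminate, so stored PDDs are
sign-canonicalized: x-component >= 0; if |x| < 1e-12 then y >= 0, then
z >= 0. Gating logic downstream additionally uses absolute dot products,
making it independent of this convention.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .dti_io import TensorVolume

__all__ = [
    "FAField",
    "PDDField",
    "eigendecompose",
    "fractional_anisotropy",
    "principal_direction",
    "compute_feature_fields",
]

_DEGENERATE_GAP = 1e-9


@dataclasses.dataclass
class FAField:
    """Fractional anisotropy per voxel, in [0, 1]; 0 where the tensor is zero."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)


@dataclasses.dataclass
class PDDField:
    """Principal diffusion directions per voxel, shape (X, Y, Z, 3).

    Zero vector marks voxels where the PDD is undefined (zero tensor).
    ``unstable`` flags voxels whose two leading eigenvalues are degenerate,
    where the PDD is numerically arbitrary.
    """

    directions: np.ndarray
    unstable: np.ndarray | None = None
    canonical_sign: str = "x>=0,then y>=0,then z>=0"

    def __post_init__(self):
        self.directions = np.asarray(self.directions, dtype=float)
        if self.unstable is None:
            self.unstable = np.zeros(self.directions.shape[:-1], dtype=bool)


def eigendecompose(tensor: np.ndarray):
    """Eigen-decompose a symmetric 3x3 tensor.

    Returns ``(eigenvalues, eigenvectors)`` with eigenvalues descending and
    eigenvectors as columns of a right-handed orthonormal matrix.
    """
    t = np.asarray(tensor, dtype=float)
    if t.shape != (3, 3):
        raise ValueError("tensor must be 3x3")
    if np.max(np.abs(t - t.T)) > 1e-8:
        raise ValueError("tensor must be symmetric")
    w, v = np.linalg.eigh(t)
    order = np.argsort(w, kind="stable")[::-1]
    w = w[order]
    v = v[:, order]
    if np.linalg.det(v) < 0:
        v[:, 2] = -v[:, 2]
    return w, v


def fractional_anisotropy(l1, l2, l3) -> float:
    """Standard FA of three eigenvalues; all-zero input returns 0.

    FA = sqrt(3/2) * ||lambda - mean||| / ||lambda||.
    """
    lam = np.array([l1, l2, l3], dtype=float)
    norm2 = np.dot(lam, lam)
    if norm2 <= 0:
        return 0.0
    dev = lam - lam.mean()
    fa = np.sqrt(1.5 * np.dot(dev, dev) / norm2)
    return float(min(fa, 1.0))


def _canonicalize_sign(vecs: np.ndarray) -> np.ndarray:
    """Flip (...,3) vectors so x>=0; ties broken by y then z."""
    v = np.array(vecs, dtype=float)
    x, y, z = v[..., 0], v[..., 1], v[..., 2]
    flip = (x < -1e-12) | (
        (np.abs(x) <= 1e-12) & ((y < -1e-12) | ((np.abs(y) <= 1e-12) & (z < 0)))
    )
    v[flip] = -v[flip]
    return v


def principal_direction(tensor: np.ndarray) -> np.ndarray:
    """Sign-canonicalized unit eigenvector of the largest eigenvalue.

    Returns the zero vector for a zero tensor (PDD undefined).
    """
    w, v = eigendecompose(tensor)
    if w[0] <= 0:
        return np.zeros(3)
    return _canonicalize_sign(v[:, 0])


def compute_feature_fields(volume: TensorVolume):
    """Vectorized FA and PDD over a TensorVolume -> (FAField, PDDField)."""
    t = volume.tensors
    w, v = np.linalg.eigh(t)  # ascending
    w = w[..., ::-1]
    v = v[..., ::-1]  # columns reordered to descending eigenvalues

    norm2 = np.sum(w * w, axis=-1)
    dev = w - w.mean(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * np.sum(dev * dev, axis=-1) / norm2)
    fa = np.where(norm2 > 0, fa, 0.0)
    fa = np.clip(np.nan_to_num(fa), 0.0, 1.0)

    pdd = v[..., :, 0]
    defined = w[..., 0] > 0
    pdd = np.where(defined[..., None], _canonicalize_sign(pdd), 0.0)
    unstable = defined & ((w[..., 0] - w[..., 1]) < _DEGENERATE_GAP)

    return FAField(values=fa), PDDField(directions=pdd, unstable=unstable)
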