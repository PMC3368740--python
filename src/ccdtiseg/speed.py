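"""Tensor-similarity speed function driving the level-set front.

For each voxel r on the propagating surface, the speed is a sum over the
gated 26-neighborhood neighbors n_r lying in the propagation direction:

    F(r) = sum_{n_r} FA(r) * FA(n_r) * tr(D(r) D(n_r)) / (tr D(r) * tr D(n_r))

where D is the diffusion tensor and FA the fractional anisotropy. A
neighbor contributes only if it passes three gates encoding the left-right
diffusion pattern of the corpus callosum:

    |PDD(r) . PDD(n_r)| > collinearity_threshold
    FA(n_r)            > fa_threshold
    |PDD_x(r)|         > pdd_x_threshold

Each summand lies in [0, 1] for PSD tensors (tr(A B) <= tr A * tr B).
Speeds at or below ``f_threshold`` are zeroed to suppress negligible
propagation. Gates use absolute values because eigenvector sign is
arbitrary.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np

from .dti_io import TensorVolume
from .levelset import LevelSetState, _central_gradients
from .tensor_features import FAField, PDDField

__all__ = [
    "SpeedParams",
    "SpeedField",
    "surface_normals",
    "collinear_neighbors",
    "gate",
    "similarity_speed",
    "compute_speed_field",
    "NEIGHBOR_OFFSETS",
]

# the 26-neighborhood offsets, fixed order for determinism
NEIGHBOR_OFFSETS = np.array(
    [o for o in itertools.product((-1, 0, 1), repeat=3) if o != (0, 0, 0)],
    dtype=int,
)
_UNIT_OFFSETS = NEIGHBOR_OFFSETS / np.linalg.norm(NEIGHBOR_OFFSETS, axis=1, keepdims=True)

_TRACE_GUARD = 1e-20
_GRAD_EPS = 1e-8


@dataclasses.dataclass
class SpeedParams:
    """Thresholds and curvature weight governing front propagation.

    Defaults are the operating point found optimal for corpus callosum:
    pdd_x 0.55, collinearity 0.7, FA 0.1, speed floor 0.05. The
    neighbor-to-normal cone is cos 60 deg = 0.5 (forward half-cone keeping
    face, edge and corner neighbors in the propagation direction).
    """

    pdd_x_threshold: float = 0.55
    collinearity_threshold: float = 0.7
    fa_threshold: float = 0.1
    f_threshold: float = 0.05
    normal_collinearity_cos: float = 0.5
    curvature_weight: float = 0.1

    def __post_init__(self):
        for name in (
            "pdd_x_threshold",
            "collinearity_threshold",
            "fa_threshold",
            "normal_collinearity_cos",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.f_threshold < 0:
            raise ValueError("f_threshold must be >= 0")


@dataclasses.dataclass
class SpeedField:
    """Speed values on the grid; nonzero only on the computed band."""

    values: np.ndarray
    support: np.ndarray  # boolean grid of voxels where speed was evaluated


def surface_normals(phi: np.ndarray, surface_voxels: np.ndarray):
    """Outward unit normals n = grad phi / |grad phi| at given voxels.

    ``surface_voxels`` is an (N, 3) integer index array. Returns (N, 3)
    normals; rows with degenerate gradient are zero (caller skips them).
    """
    g = np.stack(_central_gradients(np.asarray(phi, dtype=float)), axis=-1)
    idx = tuple(np.asarray(surface_voxels, dtype=int).T)
    vecs = g[idx]
    norms = np.linalg.norm(vecs, axis=1)
    ok = norms > _GRAD_EPS
    out = np.zeros_like(vecs)
    out[ok] = vecs[ok] / norms[ok, None]
    return out


def collinear_neighbors(
    voxel, normal, params: SpeedParams, grid_shape=None
) -> np.ndarray:
    """Neighbors of ``voxel`` whose offset direction lies in the forward cone.

    Keeps offsets o with unit(o) . normal > normal_collinearity_cos;
    out-of-bounds neighbors are dropped when grid_shape is given.
    Returns an (M, 3) array of absolute neighbor coordinates.
    """
    voxel = np.asarray(voxel, dtype=int)
    keep = _UNIT_OFFSETS @ np.asarray(normal, dtype=float) > params.normal_collinearity_cos
    nbrs = voxel[None, :] + NEIGHBOR_OFFSETS[keep]
    if grid_shape is not None:
        shape = np.asarray(grid_shape)
        inb = np.all((nbrs >= 0) & (nbrs < shape[None, :]), axis=1)
        nbrs = nbrs[inb]
    return nbrs


def gate(r, n_r, fa: FAField, pdd: PDDField, params: SpeedParams) -> bool:
    """Three-way admission test for neighbor n_r of surface voxel r."""
    r = tuple(np.asarray(r, dtype=int))
    n = tuple(np.asarray(n_r, dtype=int))
    p_r = pdd.directions[r]
    p_n = pdd.directions[n]
    if not (np.any(p_r) and np.any(p_n)):  # undefined PDD
        return False
    return bool(
        abs(float(p_r @ p_n)) > params.collinearity_threshold
        and fa.values[n] > params.fa_threshold
        and abs(p_r[0]) > params.pdd_x_threshold
    )


def _summand(D_r, D_n, fa_r, fa_n):
    tr_prod = float(np.tensordot(D_r, D_n))  # tr(D_r D_n) for symmetric D
    denom = float(np.trace(D_r)) * float(np.trace(D_n))
    if denom < _TRACE_GUARD:
        return 0.0
    return fa_r * fa_n * tr_prod / denom


def similarity_speed(
    r, neighbors, tensors: TensorVolume, fa: FAField, params: SpeedParams
) -> float:
    """Speed at voxel r given its gate-filtered neighbors.

    Sum of trace-normalized tensor products weighted by the FA pair;
    values <= f_threshold are zeroed.
    """
    r = tuple(np.asarray(r, dtype=int))
    D_r = tensors.tensors[r]
    fa_r = float(fa.values[r])
    total = 0.0
    for nb in np.atleast_2d(np.asarray(neighbors, dtype=int)):
        n = tuple(nb)
        total += _summand(D_r, tensors.tensors[n], fa_r, float(fa.values[n]))
    if total <= params.f_threshold:
        return 0.0
    return total


def compute_speed_field(
    state: LevelSetState,
    tensors: TensorVolume,
    fa: FAField,
    pdd: PDDField,
    params: SpeedParams,
    band_halfwidth: float = 1.5,
) -> SpeedField:
    """Vectorized speed over the narrow band |phi| < band_halfwidth.

    Combines surface normals, forward-cone neighbor selection, the three
    gates, and the trace-similarity sum for every band voxel at once. Each
    band voxel is evaluated with its own normal and neighborhood, which
    realizes the constant extension of boundary speeds into the band.
    Empty band -> all-zero field (evolution halts).
    """
    phi = state.phi
    shape = phi.shape
    band = np.abs(phi) < band_halfwidth
    values = np.zeros(shape)
    if not np.any(band):
        return SpeedField(values=values, support=band)

    # hyper-surface voxels: inside (phi < 0) with an outside face neighbor
    inside = phi < 0
    surf = np.zeros(shape, dtype=bool)
    for axis in range(3):
        outs = ~inside
        surf |= inside & (
            np.roll(outs, 1, axis=axis) | np.roll(outs, -1, axis=axis)
        )
    # roll wraps around the grid; voxels on the grid faces count as surface
    for axis in range(3):
        sl0 = [slice(None)] * 3
        sl0[axis] = 0
        sl1 = [slice(None)] * 3
        sl1[axis] = -1
        surf[tuple(sl0)] |= inside[tuple(sl0)]
        surf[tuple(sl1)] |= inside[tuple(sl1)]
    if not np.any(surf):
        return SpeedField(values=values, support=band)

    vox = np.argwhere(surf)
    normals = surface_normals(phi, vox)
    ok = np.any(normals != 0, axis=1)
    vox = vox[ok]
    normals = normals[ok]
    if vox.shape[0] == 0:
        return SpeedField(values=values, support=band)

    idx_r = tuple(vox.T)
    p_r = pdd.directions[idx_r]  # (N, 3)
    fa_r = fa.values[idx_r]
    D_r = tensors.tensors[idx_r]  # (N, 3, 3)
    tr_r = np.trace(D_r, axis1=1, axis2=2)
    pddx_ok = np.abs(p_r[:, 0]) > params.pdd_x_threshold
    r_defined = np.any(p_r != 0, axis=1)

    total = np.zeros(vox.shape[0])
    admitted_pairs = []  # (surface-row selector, neighbor index tuple)
    shape_arr = np.asarray(shape)
    for off, u in zip(NEIGHBOR_OFFSETS, _UNIT_OFFSETS):
        cone = normals @ u > params.normal_collinearity_cos
        if not np.any(cone):
            continue
        nb = vox + off[None, :]
        inb = np.all((nb >= 0) & (nb < shape_arr[None, :]), axis=1)
        sel = cone & inb
        if not np.any(sel):
            continue
        idx_n = tuple(nb[sel].T)
        p_n = pdd.directions[idx_n]
        collin = np.abs(np.einsum("ij,ij->i", p_r[sel], p_n)) > params.collinearity_threshold
        n_defined = np.any(p_n != 0, axis=1)
        fa_n = fa.values[idx_n]
        admit = (
            collin
            & n_defined
            & r_defined[sel]
            & (fa_n > params.fa_threshold)
            & pddx_ok[sel]
        )
        if not np.any(admit):
            continue
        D_n = tensors.tensors[idx_n]
        tr_prod = np.einsum("ijk,ijk->i", D_r[sel], D_n)
        denom = tr_r[sel] * np.trace(D_n, axis1=1, axis2=2)
        summand = np.where(
            denom >= _TRACE_GUARD, fa_r[sel] * fa_n * tr_prod / np.maximum(denom, _TRACE_GUARD), 0.0
        )
        contrib = np.zeros(vox.shape[0])
        contrib[sel] = np.where(admit, summand, 0.0)
        total += contrib
        rows = np.nonzero(sel)[0][admit]
        if rows.size:
            admitted_pairs.append((rows, tuple(nb[rows].T)))

    total[total <= params.f_threshold] = 0.0
    values[idx_r] = total

    # extension velocity: each gated neighbor being claimed by the front
    # inherits the speed of the claiming surface voxel (max over claimants),
    # so the advection stencil sees the speed on both sides of the zero
    # crossing; voxels no surface point admits keep speed 0 and the front
    # freezes there
    ext = values.copy()
    for rows, idx_n in admitted_pairs:
        np.maximum.at(ext, idx_n, total[rows])
    ext[~band] = 0.0
    return SpeedField(values=ext, support=band)
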