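"""Top-level corpus-callosum segmentation driver.

Pipeline: manual seeds in the structure -> initial surface as a union of
small spheres -> iterate (speed field on the boundary band, one upwind
evolution step, periodic redistancing) until the zero-level-set voxel set
is stable -> binary mask.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np

from .dti_io import TensorVolume
from .levelset import (
    LevelSetState,
    SeedSet,
    evolve_step,
    extract_zero_levelset,
    init_phi,
    mean_curvature,
    reinitialize,
)
from .speed import SpeedParams, compute_speed_field
from .tensor_features import compute_feature_fields

__all__ = ["SegmentationResult", "segment_corpus_callosum", "suggest_seeds"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class SegmentationResult:
    """Binary mask plus run bookkeeping."""

    mask: np.ndarray
    iterations_run: int
    converged: bool
    params_used: SpeedParams
    final_state: LevelSetState | None = None

    @property
    def volume_voxels(self) -> int:
        return int(self.mask.sum())


def _band_box(phi: np.ndarray, band_width: float, pad: int = 3):
    """Bounding-box slices of the active band |phi| < band_width, padded."""
    band = np.abs(phi) < band_width
    if not np.any(band):
        return tuple(slice(0, s) for s in phi.shape)
    slices = []
    for axis, n in enumerate(phi.shape):
        proj = np.any(band, axis=tuple(a for a in range(3) if a != axis))
        idx = np.nonzero(proj)[0]
        slices.append(slice(max(0, idx[0] - pad), min(n, idx[-1] + 1 + pad)))
    return tuple(slices)


def segment_corpus_callosum(
    tensors: TensorVolume,
    seeds: SeedSet,
    params: SpeedParams | None = None,
    max_iters: int = 500,
    stable_iters: int = 5,
    stable_time: float = 4.0,
    reinit_every: int = 20,
) -> SegmentationResult:
    """Segment the corpus callosum by gated front propagation.

    Convergence: the zero-level-set voxel set unchanged for at least
    ``stable_iters`` consecutive iterations spanning ``stable_time``
    units of evolution time (CFL steps are small, so an iteration count
    alone would declare victory while the front is still creeping).
    Evolution and redistancing are restricted to the bounding box of the
    active band, which leaves the result identical (speed is zero outside
    the band) but skips far-field arithmetic. Raises if the front dies
    leaving an empty mask (mis-placed seeds); returns converged=False on
    max_iters exhaustion.
    """
    if params is None:
        params = SpeedParams()

    fa, pdd = compute_feature_fields(tensors)

    # seed sanity: warn when a seed does not itself satisfy the gates
    for p in seeds.points:
        v = tuple(np.round(p).astype(int))
        if fa.values[v] <= params.fa_threshold or (
            abs(pdd.directions[v][0]) <= params.pdd_x_threshold
        ):
            warnings.warn(
                f"seed {v} has FA={fa.values[v]:.3f}, "
                f"|PDD_x|={abs(pdd.directions[v][0]):.3f}; gates may not pass",
                stacklevel=2,
            )

    full = init_phi(seeds, tensors.shape)
    phi = full.phi
    band_width = full.band_width
    prev_mask = phi < 0
    stable = 0
    stable_t = 0.0
    converged = False
    it = 0
    sub_tensors_cache: dict = {}
    for it in range(1, max_iters + 1):
        box = _band_box(phi, band_width)
        key = tuple((s.start, s.stop) for s in box)
        if key not in sub_tensors_cache:
            sub_tensors_cache.clear()  # box only grows; keep one entry
            sub_tensors_cache[key] = TensorVolume(
                tensors=tensors.tensors[box], voxel_size=tensors.voxel_size
            )
        sub_tv = sub_tensors_cache[key]
        sub_state = LevelSetState(phi=phi[box], band_width=band_width)
        sub_fa = dataclasses.replace(fa, values=fa.values[box])
        sub_pdd = dataclasses.replace(
            pdd, directions=pdd.directions[box], unstable=pdd.unstable[box]
        )
        field = compute_speed_field(sub_state, sub_tv, sub_fa, sub_pdd, params)
        f_eff = field.values
        if params.curvature_weight > 0 and np.any(f_eff > 0):
            # curvature modulates the moving front (speed-weighted
            # smoothing): a gate-frozen boundary stays frozen, so the
            # regularizer cannot creep into concavities on its own
            kappa = np.clip(mean_curvature(sub_state.phi), -1.0, 1.0)
            f_eff = np.maximum(f_eff * (1.0 - params.curvature_weight * kappa), 0.0)
        sub_state = evolve_step(sub_state, f_eff, 0.0)
        if reinit_every and it % reinit_every == 0:
            sub_state = reinitialize(sub_state)
        phi[box] = sub_state.phi
        dt = sub_state.time_step

        mask = phi < 0
        if np.array_equal(mask, prev_mask):
            stable += 1
            stable_t += dt
            if stable >= stable_iters and stable_t >= stable_time:
                converged = True
                break
        else:
            stable = 0
            stable_t = 0.0
        prev_mask = mask
        if it % 10 == 0:
            logger.info("iter %d: %d voxels inside", it, int(mask.sum()))

    state = LevelSetState(phi=phi, iteration=it, band_width=band_width)
    mask = extract_zero_levelset(state)
    if converged and not np.any(mask):
        raise RuntimeError(
            "segmentation converged to an empty mask; check seed placement "
            "(seeds must lie in high-FA, left-right-oriented tissue)"
        )
    return SegmentationResult(
        mask=mask,
        iterations_run=it,
        converged=converged,
        params_used=params,
        final_state=state,
    )


def suggest_seeds(
    tensors: TensorVolume,
    sagittal_slice: int,
    n_seeds: int = 3,
    sphere_radius: float = 2.0,
) -> SeedSet:
    """Convenience extension (not part of the core algorithm): propose the
    ``n_seeds`` voxels of highest |PDD_x| * FA on a chosen sagittal slice.

    Seeding is manual by design; this helper only ranks candidates.
    """
    fa, pdd = compute_feature_fields(tensors)
    score = np.abs(pdd.directions[sagittal_slice, :, :, 0]) * fa.values[sagittal_slice]
    flat = np.argsort(score.ravel())[::-1][:n_seeds]
    yz = np.stack(np.unravel_index(flat, score.shape), axis=1)
    pts = np.column_stack([np.full(len(yz), sagittal_slice), yz])
    return SeedSet(points=pts, sphere_radius=sphere_radius)
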