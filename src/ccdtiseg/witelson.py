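"""Witelson parcellation of a segmented corpus callosum.

The canonical 7-region scheme cuts the structure's anterior-posterior
extent L (measured on the mid-sagittal bounding box) at anterior fractions
1/3, 1/2, 2/3 and 4/5:

    anterior third  [0, L/3)   -> rostrum + genu + rostral body
    [L/3, L/2)                 -> anterior mid-body
    [L/2, 2L/3)                -> posterior mid-body
    [2L/3, 4L/5)               -> isthmus
    [4L/5, L]                  -> splenium

Within the anterior third, the rostrum is the recurved arm
inferior to the genu/rostrum critical point (the boundary point where the
contour curvature changes sign); the remainder is split at the strip's
own midpoint (L/6) into genu (anterior) and rostral body (posterior),
since that internal boundary is anatomical rather than fractional in the
original scheme. Labels are extended uniformly along the left-right axis,
so every 3D mask voxel inherits the label of its anterior-posterior bin.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.ndimage import gaussian_filter1d
from skimage import measure

__all__ = [
    "WitelsonLabels",
    "MidSagittalPlane",
    "LABEL_NAMES",
    "detect_midsagittal_plane",
    "find_rostrum_genu_critical_point",
    "witelson_subdivide",
]

LABEL_NAMES = {
    0: "background",
    1: "rostrum",
    2: "genu",
    3: "rostral body",
    4: "anterior mid-body",
    5: "posterior mid-body",
    6: "isthmus",
    7: "splenium",
}

# anterior-fraction cut-points of the parcellation
CUT_FRACTIONS = (1.0 / 3.0, 0.5, 2.0 / 3.0, 4.0 / 5.0)


@dataclasses.dataclass
class WitelsonLabels:
    """uint8 label volume; nonzero labels exactly partition the input mask."""

    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels).astype(np.uint8)

    def region_mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def counts(self) -> dict:
        return {
            LABEL_NAMES[k]: int(np.sum(self.labels == k)) for k in range(1, 8)
        }


@dataclasses.dataclass
class MidSagittalPlane:
    """Left-right axis slice index separating the hemispheres."""

    axis: int
    slice_index: int
    user_confirmed: bool = False


def detect_midsagittal_plane(
    fa_values: np.ndarray,
    mask: np.ndarray | None = None,
    user_index: int | None = None,
) -> MidSagittalPlane:
    """Find the sagittal slice maximizing left-right mirror symmetry of FA.

    Scores each candidate slice s in the central third of the x-range by
    the normalized cross-correlation between the FA volume and its
    reflection about s; ties resolve to the most central slice. A user
    override returns immediately with user_confirmed=True.
    """
    fa = np.asarray(fa_values, dtype=float)
    nx = fa.shape[0]
    if user_index is not None:
        if not 0 <= user_index < nx:
            raise ValueError(f"plane index {user_index} outside x-range [0, {nx})")
        return MidSagittalPlane(axis=0, slice_index=int(user_index), user_confirmed=True)
    if mask is not None and not np.any(mask):
        raise ValueError("mask is empty")

    lo, hi = nx // 3, nx - nx // 3
    center = (nx - 1) / 2.0
    best, best_score = lo, -np.inf
    for s in range(lo, hi):
        half = min(s, nx - 1 - s)
        if half < 1:
            continue
        left = fa[s - half : s]
        right = fa[s + 1 : s + 1 + half][::-1]
        a = left - left.mean()
        b = right - right.mean()
        denom = np.sqrt((a * a).sum() * (b * b).sum())
        score = (a * b).sum() / denom if denom > 0 else 0.0
        if score > best_score + 1e-12 or (
            abs(score - best_score) <= 1e-12 and abs(s - center) < abs(best - center)
        ):
            best, best_score = s, score
    return MidSagittalPlane(axis=0, slice_index=int(best), user_confirmed=False)


def _contour_curvature(contour: np.ndarray) -> np.ndarray:
    """Signed curvature of a closed 2D contour (rows = points)."""
    d1 = 0.5 * (np.roll(contour, -1, axis=0) - np.roll(contour, 1, axis=0))
    d2 = np.roll(contour, -1, axis=0) - 2 * contour + np.roll(contour, 1, axis=0)
    num = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
    den = (d1[:, 0] ** 2 + d1[:, 1] ** 2) ** 1.5
    with np.errstate(invalid="ignore", divide="ignore"):
        k = num / den
    return np.nan_to_num(k)


def _resample_smooth_closed(
    contour: np.ndarray, n_points: int = 256, sigma: float = 4.0
) -> np.ndarray:
    """Uniform-arclength resampling + circular Gaussian smoothing.

    Suppresses voxel-staircase jitter so the signed curvature reflects the
    shape, not the rasterization.
    """
    # normalize to counter-clockwise so convex boundary has positive k
    area = 0.5 * np.sum(
        contour[:, 0] * np.roll(contour[:, 1], -1)
        - np.roll(contour[:, 0], -1) * contour[:, 1]
    )
    if area < 0:
        contour = contour[::-1]
    closed = np.vstack([contour, contour[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    si = np.linspace(0.0, total, n_points, endpoint=False)
    out = np.column_stack(
        [np.interp(si, s, closed[:, c]) for c in range(2)]
    )
    return gaussian_filter1d(out, sigma=sigma, axis=0, mode="wrap")


def find_rostrum_genu_critical_point(slice_mask: np.ndarray, manual_point=None):
    """Locate the genu/rostrum critical point on a mid-sagittal slice mask.

    The point where the boundary curvature changes sign (concave-to-convex
    recurve) in the anterior-inferior quadrant, found on the 5-point
    smoothed boundary contour. ``slice_mask`` axes are (y, z) =
    (anterior-posterior, inferior-superior); anterior = larger y, inferior
    = smaller z. A ``manual_point`` passes through unchanged (close
    supervision). Raises when no curvature sign change exists (no recurve).
    """
    if manual_point is not None:
        return (float(manual_point[0]), float(manual_point[1]))
    m = np.asarray(slice_mask).astype(float)
    if not np.any(m):
        raise ValueError("empty slice mask")
    contours = measure.find_contours(m, 0.5)
    contour = max(contours, key=len)
    if len(contour) < 10:
        raise ValueError("boundary contour too short for curvature analysis")
    contour = _resample_smooth_closed(contour)
    k = _contour_curvature(contour)

    ys, zs = np.nonzero(m)
    y_mid = 0.5 * (ys.min() + ys.max())
    z_mid = 0.5 * (zs.min() + zs.max())
    quadrant = (contour[:, 0] > y_mid) & (contour[:, 1] < z_mid)

    # a recurve is a genuinely concave notch; rasterization jitter on a
    # smooth convex boundary stays above about -0.06 after smoothing,
    # while a true notch dips far below
    concave_thr = -0.1
    cand = np.nonzero((k < concave_thr) & quadrant)[0]
    if cand.size == 0:
        raise ValueError(
            "no concave-to-convex curvature transition in the "
            "anterior-inferior quadrant; supply the critical point manually"
        )
    i = cand[np.argmin(k[cand])]
    return (float(contour[i, 0]), float(contour[i, 1]))


def witelson_subdivide(
    mask: np.ndarray,
    plane: MidSagittalPlane,
    critical_point=None,
) -> WitelsonLabels:
    """Partition a corpus-callosum mask into the 7 Witelson regions.

    ``critical_point`` is the (y, z) genu/rostrum boundary point on the
    mid-sagittal slice; when None the rostrum is left empty (no recurve).
    Raises on degenerate anterior-posterior extent (< 7 voxels).
    """
    mask = np.asarray(mask).astype(bool)
    if not np.any(mask):
        raise ValueError("mask is empty")
    # anterior-posterior extent on the full-mask bounding box: equals the
    # mid-sagittal extent for untilted anatomy and stays meaningful when
    # the structure is tilted out of the slice plane
    ref = np.any(mask, axis=0)
    ys = np.nonzero(np.any(ref, axis=1))[0]
    y_min, y_max = int(ys.min()), int(ys.max())
    L = y_max - y_min
    if L < 7:
        raise ValueError(f"anterior-posterior extent {L} voxels is too small")

    # anterior = y_max; distance from the anterior end as a fraction of L
    yy = np.nonzero(mask)[1].astype(float)
    frac = (y_max - yy) / L

    c1, c2, c3, c4 = CUT_FRACTIONS
    labels_flat = np.empty(yy.shape, dtype=np.uint8)
    labels_flat[frac < c1] = 2  # anterior third: genu for now
    labels_flat[(frac >= c1) & (frac < c2)] = 4
    labels_flat[(frac >= c2) & (frac < c3)] = 5
    labels_flat[(frac >= c3) & (frac < c4)] = 6
    labels_flat[frac >= c4] = 7

    vox = np.nonzero(mask)
    anterior_third = frac < c1
    # genu/rostral-body split at the anterior sixth (midpoint of the strip)
    labels_flat[anterior_third & (frac >= c1 / 2.0)] = 3
    if critical_point is not None:
        _, z_crit = critical_point
        zz = vox[2].astype(float)
        labels_flat[anterior_third & (zz < z_crit)] = 1  # rostrum

    labels = np.zeros(mask.shape, dtype=np.uint8)
    labels[vox] = labels_flat
    return WitelsonLabels(labels=labels)
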