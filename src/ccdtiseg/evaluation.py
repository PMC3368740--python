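"""Segmentation scoring: Dice overlap, threshold-sensitivity sweeps, and
the paired Wilcoxon signed-rank comparison of outer vs inner subdivisions.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np

from .dti_io import TensorVolume
from .levelset import SeedSet
from .segmentation import segment_corpus_callosum
from .speed import SpeedParams
from .witelson import LABEL_NAMES, MidSagittalPlane, witelson_subdivide

__all__ = [
    "DiceReport",
    "SweepResult",
    "dice",
    "threshold_sweep",
    "wilcoxon_signed_rank",
    "inner_outer_comparison",
    "OUTER_SUBDIVISIONS",
    "INNER_SUBDIVISIONS",
]

OUTER_SUBDIVISIONS = ("rostrum", "genu", "splenium")
INNER_SUBDIVISIONS = (
    "rostral body",
    "anterior mid-body",
    "posterior mid-body",
    "isthmus",
)


@dataclasses.dataclass
class DiceReport:
    """Overlap counts and the Dice coefficient 2 TP / (2 TP + FP + FN)."""

    true_positives: int
    false_positives: int
    false_negatives: int
    dice: float


def dice(mask_auto: np.ndarray, mask_ref: np.ndarray) -> DiceReport:
    """Dice overlap between two same-shape binary masks.

    dice = |A n B| / ((|A| + |B|) / 2). Both masks empty is defined as
    dice 1 (agreement that nothing is present), with a warning.
    """
    a = np.asarray(mask_auto).astype(bool)
    b = np.asarray(mask_ref).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    tp = int(np.sum(a & b))
    fp = int(np.sum(a & ~b))
    fn = int(np.sum(~a & b))
    if tp + fp + fn == 0:
        warnings.warn("both masks empty; Dice defined as 1", stacklevel=2)
        return DiceReport(0, 0, 0, 1.0)
    return DiceReport(tp, fp, fn, 2.0 * tp / (2.0 * tp + fp + fn))


@dataclasses.dataclass
class SweepResult:
    """Per-threshold-value segmentation scores.

    Arrays are aligned with ``values``; per-subdivision metrics are dicts
    name -> array. ``tp``/``fp`` are whole-mask counts vs the reference.
    """

    param_name: str
    values: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    dice_overall: np.ndarray
    dice_by_subdivision: dict
    tp_by_subdivision: dict
    fp_by_subdivision: dict

    def dice_range(self) -> float:
        """max - min of the overall Dice curve (sweep sensitivity)."""
        return float(self.dice_overall.max() - self.dice_overall.min())


def threshold_sweep(
    tensors: TensorVolume,
    seeds: SeedSet,
    ref_labels: np.ndarray,
    param_name: str,
    value_grid,
    fixed_params: SpeedParams | None = None,
    plane_index: int | None = None,
    max_iters: int = 500,
) -> SweepResult:
    """Segment at each value of one gate threshold and score vs reference.

    ``ref_labels`` is a Witelson label volume (0 = background); the
    reference mask is its nonzero support. Scores are recorded overall and
    per subdivision.
    """
    values = np.asarray(value_grid, dtype=float)
    if param_name not in (
        "pdd_x_threshold",
        "collinearity_threshold",
        "fa_threshold",
        "f_threshold",
    ):
        raise ValueError(f"unknown sweep parameter {param_name!r}")
    if param_name != "f_threshold" and (np.any(values < 0) or np.any(values > 1)):
        raise ValueError("threshold grid must lie in [0, 1]")
    base = fixed_params if fixed_params is not None else SpeedParams()
    ref_labels = np.asarray(ref_labels)
    ref_mask = ref_labels > 0
    if plane_index is None:
        plane_index = tensors.shape[0] // 2
    plane = MidSagittalPlane(axis=0, slice_index=plane_index)

    n = len(values)
    tp = np.zeros(n, dtype=int)
    fp = np.zeros(n, dtype=int)
    overall = np.zeros(n)
    by_sub = {LABEL_NAMES[k]: np.zeros(n) for k in range(1, 8)}
    tp_sub = {LABEL_NAMES[k]: np.zeros(n, dtype=int) for k in range(1, 8)}
    fp_sub = {LABEL_NAMES[k]: np.zeros(n, dtype=int) for k in range(1, 8)}

    for i, v in enumerate(values):
        params = dataclasses.replace(base, **{param_name: float(v)})
        seg = segment_corpus_callosum(tensors, seeds, params, max_iters=max_iters)
        rep = dice(seg.mask, ref_mask)
        tp[i], fp[i], overall[i] = rep.true_positives, rep.false_positives, rep.dice
        auto_lab = witelson_subdivide(seg.mask, plane) if np.any(seg.mask) else None
        for k in range(1, 8):
            name = LABEL_NAMES[k]
            auto_k = (auto_lab.labels == k) if auto_lab is not None else np.zeros_like(ref_mask)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r = dice(auto_k, ref_labels == k)
            by_sub[name][i] = r.dice
            tp_sub[name][i] = r.true_positives
            fp_sub[name][i] = r.false_positives

    return SweepResult(
        param_name=param_name,
        values=values,
        tp=tp,
        fp=fp,
        dice_overall=overall,
        dice_by_subdivision=by_sub,
        tp_by_subdivision=tp_sub,
        fp_by_subdivision=fp_sub,
    )


# ----------------------------------------------------------- Wilcoxon test

def _signed_rank_statistic(diffs: np.ndarray):
    """(W+, doubled midranks, n) after dropping zero differences."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    absd = np.abs(d)
    order = np.argsort(absd, kind="stable")
    ranks = np.empty(n)
    sorted_abs = absd[order]
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sorted_abs[j + 1] == sorted_abs[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0  # midrank
        i = j + 1
    w_plus = float(ranks[d > 0].sum())
    return w_plus, ranks, n


def wilcoxon_signed_rank(paired_a, paired_b) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Exact null distribution (dynamic programming over the 2^n equally
    likely sign assignments, tied |differences| midranked) for n <= 25
    nonzero differences; normal approximation with continuity and tie
    corrections above. Zero differences are dropped. Raises when all
    differences are zero or fewer than 5 nonzero pairs remain.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    w_plus, ranks, n = _signed_rank_statistic(a - b)
    if n == 0:
        raise ValueError("all paired differences are zero; test undefined")
    if n < 5:
        raise ValueError(f"need >= 5 nonzero differences, got {n}")

    if n <= 25:
        # doubled midranks are integers; exact distribution of 2*W+ by DP
        r2 = np.round(2.0 * ranks).astype(int)
        total = int(r2.sum())
        pmf = np.zeros(total + 1)
        pmf[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(pmf)
            shifted[r:] = pmf[: total + 1 - r]
            pmf = 0.5 * (pmf + shifted)
        w2 = int(round(2.0 * w_plus))
        p_le = float(pmf[: w2 + 1].sum())
        p_ge = float(pmf[w2:].sum())
        return min(1.0, 2.0 * min(p_le, p_ge))

    mean = n * (n + 1) / 4.0
    # tie correction on the variance
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / math.sqrt(var)
    return float(min(1.0, 2.0 * (1.0 - _norm_cdf(abs(z)))))


def _norm_cdf(x: float) -> float:
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


def inner_outer_comparison(rotation_report, alpha: float = 0.01) -> dict:
    """Paired Wilcoxon tests of outer vs inner subdivision Dice per cell.

    Outer = rostrum, genu, splenium; inner = rostral body, anterior and
    posterior mid-body, isthmus. For each (axis, angle) cell the replicate
    means of the two groups are paired and tested; p < alpha flags
    significance. Cells with all-zero differences report p = NaN.
    """
    out = {}
    for key, cell in sorted(rotation_report.dice.items()):
        missing = [s for s in OUTER_SUBDIVISIONS + INNER_SUBDIVISIONS if s not in cell]
        if missing:
            raise ValueError(f"cell {key} missing subdivisions: {missing}")
        outer = np.mean([cell[s] for s in OUTER_SUBDIVISIONS], axis=0)
        inner = np.mean([cell[s] for s in INNER_SUBDIVISIONS], axis=0)
        try:
            p = wilcoxon_signed_rank(outer, inner)
        except ValueError:
            p = float("nan")
        out[key] = {
            "p_value": p,
            "significant": bool(p < alpha) if not math.isnan(p) else False,
            "outer_mean": float(np.mean(outer)),
            "inner_mean": float(np.mean(inner)),
        }
    return out
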