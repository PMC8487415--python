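"""Lesion-level matching and performance metrics.

A predicted component counts as a true positive when its intersection over
union with a gold-standard lesion region exceeds 0.05.  Matching is greedy
one-to-one by descending IoU; unmatched predictions are false positives and
unmatched gold regions false negatives.  Because the network scores each
trans-axial slice independently, both predictions and gold regions are
in-slice 2D components on a shared (slice, row, col) grid — a prediction on
the slice next to a lesion's true extent therefore scores IoU 0 and counts
as a false positive, reproducing the characteristic "edge of a true
positive" error mode of slice-wise detection.

Headline metrics are PPV (precision), sensitivity (recall), their harmonic
mean F1, and the area under the precision–recall curve traced by sweeping
the binarization threshold at a fixed area filter.  Replicate runs are
aggregated as mean ± sample SD per (metric, filter) cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .detect import (ComponentSet, DetectionConfig, area_filter, binarize,
                     stack_components)

IOU_MIN_DEFAULT = 0.05


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    pairs: list[tuple[int, int, float]]          # (pred id, gold id, IoU)
    unmatched_pred: list[int]
    unmatched_gold: list[int]

    def __post_init__(self) -> None:
        assert self.tp == len(self.pairs)
        assert self.fp == len(self.unmatched_pred)
        assert self.fn == len(self.unmatched_gold)

    def __add__(self, other: "MatchResult") -> "MatchResult":
        return MatchResult(self.tp + other.tp, self.fp + other.fp,
                           self.fn + other.fn, self.pairs + other.pairs,
                           self.unmatched_pred + other.unmatched_pred,
                           self.unmatched_gold + other.unmatched_gold)


@dataclass(frozen=True)
class MetricsRecord:
    ppv: float
    sensitivity: float
    f1: float
    pr_auc: float | None
    filter_px: int
    binarize_threshold: float
    replicate: int


def iou(a: Iterable[tuple], b: Iterable[tuple]) -> float:
    """|a ∩ b| / |a ∪ b| over pixel-coordinate sets; empty–empty is 0."""
    sa, sb = set(a), set(b)
    union = len(sa | sb)
    if union == 0:
        return 0.0
    return len(sa & sb) / union


def match_lesions(pred: ComponentSet, gold: ComponentSet,
                  iou_min: float = IOU_MIN_DEFAULT) -> MatchResult:
    """Greedy one-to-one matching by descending IoU; accept only IoU > iou_min."""
    pred_sets = {c.component_id: c.voxels for c in pred}
    gold_sets = {c.component_id: c.voxels for c in gold}
    candidates = []
    for pid, pv in pred_sets.items():
        for gid, gv in gold_sets.items():
            inter = len(pv & gv)
            if inter == 0:
                continue
            val = inter / len(pv | gv)
            if val > iou_min:
                candidates.append((val, pid, gid))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_p: set[int] = set()
    used_g: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for val, pid, gid in candidates:
        if pid in used_p or gid in used_g:
            continue
        used_p.add(pid)
        used_g.add(gid)
        pairs.append((pid, gid, val))
    un_p = sorted(set(pred_sets) - used_p)
    un_g = sorted(set(gold_sets) - used_g)
    return MatchResult(len(pairs), len(un_p), len(un_g), pairs, un_p, un_g)


def ppv_sensitivity_f1(m: MatchResult) -> tuple[float, float, float]:
    """PPV, sensitivity and F1 with the degenerate-count convention:
    when there are no predictions and no gold lesions at all, every ratio
    is 1.0 (a perfect empty answer); otherwise an undefined ratio is 0.0."""
    if m.tp + m.fp + m.fn == 0:
        return 1.0, 1.0, 1.0
    ppv = m.tp / (m.tp + m.fp) if (m.tp + m.fp) else 0.0
    sens = m.tp / (m.tp + m.fn) if (m.tp + m.fn) else 0.0
    f1 = 2 * ppv * sens / (ppv + sens) if (ppv + sens) else 0.0
    return ppv, sens, f1


def gold_components(lesion_labels: np.ndarray, connectivity: int = 8) -> ComponentSet:
    """Gold lesion map → per-slice 2D components, the unit of matching."""
    return stack_components(lesion_labels > 0, connectivity)


def lesion_components_3d(lesion_labels: np.ndarray) -> ComponentSet:
    """Label map → one 3D component per lesion id (annotation-stage matching)."""
    from .detect import Component

    comps = []
    for lid in np.unique(lesion_labels):
        if lid == 0:
            continue
        coords = tuple(tuple(int(x) for x in zrc)
                       for zrc in np.argwhere(lesion_labels == lid))
        comps.append(Component(int(lid), -1, coords, 1.0, 1.0))
    return ComponentSet(comps)


def evaluate_detections(pred: ComponentSet, gold: ComponentSet,
                        iou_min: float = IOU_MIN_DEFAULT) -> MatchResult:
    return match_lesions(pred, gold, iou_min)


def _match_counts(per_study: Sequence[MatchResult]) -> tuple[int, int, int]:
    return (sum(m.tp for m in per_study), sum(m.fp for m in per_study),
            sum(m.fn for m in per_study))


def pooled_metrics(per_study: Sequence[MatchResult]) -> tuple[float, float, float]:
    """Micro-averaged PPV/sensitivity/F1 over a study collection."""
    tp, fp, fn = _match_counts(per_study)
    dummy = MatchResult(tp, fp, fn, [(0, 0, 1.0)] * tp,
                        list(range(fp)), list(range(fn)))
    return ppv_sensitivity_f1(dummy)


DEFAULT_PR_THRESHOLDS = tuple(np.round(np.linspace(0.01, 0.99, 50), 6))


def pr_curve(score_stacks: Sequence[np.ndarray],
             gold_sets: Sequence[ComponentSet],
             area_filter_px: int,
             thresholds: Sequence[float] = DEFAULT_PR_THRESHOLDS,
             iou_min: float = IOU_MIN_DEFAULT,
             connectivity: int = 8) -> tuple[np.ndarray, float]:
    """Precision–recall curve by sweeping the binarization threshold.

    At each threshold the full detection pipeline (binarize → components →
    area filter) runs on every study and matches are pooled.  Points are
    sorted by recall; the AUC is the trapezoidal area over the recall axis
    with the curve anchored at recall 0 by the precision of its
    lowest-recall point.
    """
    points = []
    for thr in thresholds:
        per_study = []
        for scores, gold in zip(score_stacks, gold_sets):
            comps = area_filter(
                stack_components(binarize(scores, thr), connectivity, scores),
                area_filter_px)
            per_study.append(match_lesions(comps, gold, iou_min))
        ppv, sens, _ = pooled_metrics(per_study)
        points.append((sens, ppv))
    pts = np.array(sorted(points, key=lambda t: (t[0], t[1])))
    recall = np.concatenate([[0.0], pts[:, 0]])
    precision = np.concatenate([[pts[0, 1]], pts[:, 1]])
    auc = float(np.trapezoid(precision, recall))
    return pts, auc


def aggregate_runs(records: Sequence[MetricsRecord],
                   filters: Sequence[int] | None = None) -> pd.DataFrame:
    """Mean and sample SD (n−1) per metric across replicates, filters as
    columns.  Reports F1 both as the mean of per-run F1 and as the harmonic
    mean of the mean PPV and mean sensitivity (the two readings of a
    'weighted mean' summary); single replicates get NaN SDs."""
    if not records:
        raise ValueError("no records to aggregate")
    df = pd.DataFrame([r.__dict__ for r in records])
    if filters is None:
        filters = sorted(df["filter_px"].unique())
    rows = {}
    for metric in ("ppv", "sensitivity", "f1", "pr_auc"):
        means, sds = [], []
        for f in filters:
            cell = df.loc[df["filter_px"] == f, metric].dropna()
            if len(cell) == 0:
                means.append(np.nan)
                sds.append(np.nan)
                continue
            means.append(cell.mean())
            sds.append(cell.std(ddof=1) if len(cell) > 1 else np.nan)
        rows[f"{metric}_mean"] = means
        rows[f"{metric}_sd"] = sds
    f1_of_means = []
    for f, p, s in zip(filters, rows["ppv_mean"], rows["sensitivity_mean"]):
        f1_of_means.append(2 * p * s / (p + s) if (p + s) else 0.0)
    rows["f1_of_mean_ppv_sens"] = f1_of_means
    out = pd.DataFrame(rows, index=pd.Index(filters, name="filter_px")).T
    missing = [f for f in filters
               if (df["filter_px"] == f).sum() == 0]
    out.attrs["missing_filters"] = missing
    return out
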