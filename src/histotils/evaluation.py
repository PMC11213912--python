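"""Segmentation/classification metrics, hospital-stratified folds, summaries.

Validation follows an internal-external cross-validation convention: slides
are split into folds by hospital, so no site contributes to both training and
testing, and fold 1 (used for hyperparameter tuning) is excluded from the
mean/standard-deviation summaries.  Summaries use the sample (n-1) standard
deviation and half-away-from-zero rounding to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, roc_auc_score

METRIC_NAMES = ("auroc", "f1", "mcc", "sensitivity", "specificity",
                "precision", "recall", "accuracy")


# --- segmentation ------------------------------------------------------------

def dice_per_class(pred_mask: np.ndarray, gt_mask: np.ndarray, class_code: int) -> float:
    """Sorensen-Dice overlap for one class; gt code 0 pixels are ignored.

    Returns NaN when the class is absent from both masks.
    """
    pred_mask = np.asarray(pred_mask)
    gt_mask = np.asarray(gt_mask)
    if pred_mask.shape != gt_mask.shape:
        raise ValueError("mask shapes differ")
    valid = gt_mask != 0
    p = (pred_mask == class_code) & valid
    g = (gt_mask == class_code) & valid
    denom = p.sum() + g.sum()
    if denom == 0:
        return float("nan")
    return float(2.0 * (p & g).sum() / denom)


# --- instance matching -------------------------------------------------------

@dataclass
class GroundTruthNucleus:
    """One annotated nucleus: a class plus a box and/or a segment mask."""

    instance_id: int
    class_code: int
    centroid_xy: tuple
    box: tuple | None = None        # (x0, y0, x1, y1), half-open
    segment: np.ndarray | None = None  # boolean mask in ROI coordinates

    def contains(self, x: float, y: float) -> bool:
        if self.segment is not None:
            xi, yi = int(round(x)), int(round(y))
            h, w = self.segment.shape
            return 0 <= yi < h and 0 <= xi < w and bool(self.segment[yi, xi])
        if self.box is not None:
            x0, y0, x1, y1 = self.box
            return x0 <= x < x1 and y0 <= y < y1
        return False


def match_instances(pred_instances, gt_nuclei):
    """Greedy one-to-one matching of predictions to ground-truth nuclei.

    A prediction matches the annotation whose box/segment contains its
    centroid; when several do, the nearest annotation centroid wins.
    Returns ``(matches, unmatched_pred, unmatched_gt)`` with matches as
    (prediction, annotation) pairs.
    """
    taken = set()
    matches, unmatched_pred = [], []
    for inst in pred_instances:
        x, y = inst.centroid_xy
        candidates = [
            g for g in gt_nuclei
            if g.instance_id not in taken and g.contains(x, y)
        ]
        if not candidates:
            unmatched_pred.append(inst)
            continue
        best = min(
            candidates,
            key=lambda g: (g.centroid_xy[0] - x) ** 2 + (g.centroid_xy[1] - y) ** 2,
        )
        taken.add(best.instance_id)
        matches.append((inst, best))
    unmatched_gt = [g for g in gt_nuclei if g.instance_id not in taken]
    return matches, unmatched_pred, unmatched_gt


# --- classification metrics --------------------------------------------------

def _binary_metrics(tp, fp, fn, tn):
    def safe(a, b):
        return float(a) / b if b > 0 else float("nan")

    sens = safe(tp, tp + fn)
    spec = safe(tn, tn + fp)
    prec = safe(tp, tp + fp)
    acc = safe(tp + tn, tp + fp + fn + tn)
    f1 = safe(2 * tp, 2 * tp + fp + fn)
    mcc_den = np.sqrt(
        float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    mcc = float((tp * tn - fp * fn) / mcc_den) if mcc_den > 0 else float("nan")
    return {"sensitivity": sens, "specificity": spec, "precision": prec,
            "recall": sens, "accuracy": acc, "f1": f1, "mcc": mcc}


def nucleus_metrics(class_probs: np.ndarray, true_classes, n_classes: int | None = None):
    """Per-class one-vs-rest metrics plus micro and macro averages.

    ``class_probs`` is (n_instances, n_classes) with columns ordered by class
    code 1..C; ``true_classes`` are 1-based codes.  AUROC is the rank
    statistic with midrank ties; discrete metrics come from the argmax
    confusion matrix.  Classes absent from the ground truth get NaN AUROC and
    are excluded from the macro average.
    """
    probs = np.asarray(class_probs, dtype=np.float64)
    y = np.asarray(true_classes, dtype=int)
    if n_classes is None:
        n_classes = probs.shape[1]
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes present in ground truth")
    pred = probs.argmax(axis=1) + 1
    labels = np.arange(1, n_classes + 1)
    cm = confusion_matrix(y, pred, labels=labels)

    rows = {}
    micro_scores, micro_labels = [], []
    for k in labels:
        pos = y == k
        tp = int(cm[k - 1, k - 1])
        fp = int(cm[:, k - 1].sum() - tp)
        fn = int(cm[k - 1].sum() - tp)
        tn = int(cm.sum() - tp - fp - fn)
        m = _binary_metrics(tp, fp, fn, tn)
        if pos.any() and (~pos).any():
            m["auroc"] = float(roc_auc_score(pos, probs[:, k - 1]))
        else:
            m["auroc"] = float("nan")
        rows[int(k)] = m
        micro_scores.append(probs[:, k - 1])
        micro_labels.append(pos)

    # micro: pool binary indicators across classes
    pooled_y = np.concatenate(micro_labels)
    pooled_s = np.concatenate(micro_scores)
    pooled_pred = np.concatenate([pred == k for k in labels])
    tp = int((pooled_pred & pooled_y).sum())
    fp = int((pooled_pred & ~pooled_y).sum())
    fn = int((~pooled_pred & pooled_y).sum())
    tn = int((~pooled_pred & ~pooled_y).sum())
    micro = _binary_metrics(tp, fp, fn, tn)
    micro["auroc"] = float(roc_auc_score(pooled_y, pooled_s))

    macro = {}
    for name in METRIC_NAMES:
        vals = [rows[k][name] for k in rows if not np.isnan(rows[k][name])]
        macro[name] = float(np.mean(vals)) if vals else float("nan")
    return {"per_class": rows, "micro": micro, "macro": macro}


# --- folds -------------------------------------------------------------------

@dataclass
class FoldAssignment:
    hospital_to_fold: dict
    slide_to_fold: dict
    n_folds: int


def make_folds(slide_to_hospital: dict, n_folds: int = 5, seed: int = 0) -> FoldAssignment:
    """Hospital-stratified folds: all slides of a hospital share one fold.

    Hospitals are shuffled (seeded) then greedily assigned to the currently
    smallest fold by slide count, which bounds the fold-size spread by the
    largest hospital's size.
    """
    hospitals = sorted({h for h in slide_to_hospital.values()})
    if len(hospitals) < n_folds:
        raise ValueError(
            f"need >= {n_folds} hospitals for {n_folds} folds, got {len(hospitals)}"
        )
    rng = np.random.default_rng(seed)
    order = [hospitals[i] for i in rng.permutation(len(hospitals))]
    sizes = {h: sum(1 for v in slide_to_hospital.values() if v == h) for h in hospitals}
    fold_load = [0] * n_folds
    hospital_to_fold = {}
    # first deal one hospital per fold, then balance greedily
    for i, h in enumerate(order):
        if i < n_folds:
            fold = i
        else:
            fold = int(np.argmin(fold_load))
        hospital_to_fold[h] = fold + 1
        fold_load[fold] += sizes[h]
    slide_to_fold = {s: hospital_to_fold[h] for s, h in slide_to_hospital.items()}
    return FoldAssignment(hospital_to_fold, slide_to_fold, n_folds)


# --- fold summaries ----------------------------------------------------------

def _round_half_away(x: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    # pre-round far below the target precision to strip float noise like
    # 91.14999999999999 before the exact half-away-from-zero quantize
    return float(Decimal(repr(round(x, decimals + 9))).quantize(q, rounding=ROUND_HALF_UP))


def summarize_folds(fold_values, exclude_first: bool = True, decimals: int = 1) -> tuple:
    """(mean, sample sd) over folds 2..n, rounded half-away-from-zero.

    Fold 1 is excluded because it participates in hyperparameter tuning.
    """
    vals = [float(v) for v in fold_values]
    if len(vals) < 3 or any(np.isnan(vals)):
        raise ValueError("need a complete list of per-fold values")
    use = np.array(vals[1:] if exclude_first else vals)
    return (
        _round_half_away(float(use.mean()), decimals),
        _round_half_away(float(use.std(ddof=1)), decimals),
    )


def fold_summary_table(per_fold: dict, exclude_first: bool = True) -> pd.DataFrame:
    """Benchmark-style summary: one row per class with folds, mean, std."""
    rows = []
    for name, vals in per_fold.items():
        mean, std = summarize_folds(vals, exclude_first=exclude_first)
        row = {"class": name}
        row.update({f"fold{i + 1}": v for i, v in enumerate(vals)})
        row.update({"mean": mean, "std": std})
        rows.append(row)
    return pd.DataFrame(rows)
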