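"""Instance-segmentation evaluation against ground truth.

Predicted and true instances are compared by pixel-count IoU; at each IoU
threshold a one-to-one matching of maximum cardinality (and, among those,
maximum total IoU) defines TP/FP/FN, from which precision, recall and F1
follow.  A categorical XOR overlay visualizes where the prediction agrees,
hallucinates, misses, or confuses instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .errors import ShapeMismatchError
from .types import as_label_array

__all__ = ["EvalResult", "iou_matrix", "match_instances", "evaluate", "xor_overlay", "OVERLAY_CODES"]

#: Pixel categories of the XOR overlay raster.
OVERLAY_CODES = {
    "background": 0,
    "correct": 1,
    "false_positive": 2,
    "false_negative": 3,
    "mismatch": 4,
}

# Cardinality bonus: any eligible pair outweighs the total IoU of all
# others, so the assignment maximizes match count first, total IoU second.
_BONUS = 1e6


@dataclass
class EvalResult:
    """TP/FP/FN and derived metrics at one IoU threshold.

    Metrics with a zero denominator are NaN ("missing") rather than 0, so
    empty masks do not produce spurious perfect or zero scores.
    """

    iou_threshold: float
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    matches: list[tuple[int, int, float]] = field(default_factory=list)


def iou_matrix(truth, pred) -> pd.DataFrame:
    """Pairwise IoU of every truth instance against every predicted one.

    Returns a DataFrame indexed by truth labels with predicted labels as
    columns; entries are ``|Ti n Pj| / |Ti u Pj|`` by pixel counting
    (0 for non-overlapping pairs).
    """
    t = as_label_array(truth)
    p = as_label_array(pred)
    if t.shape != p.shape:
        raise ShapeMismatchError(f"mask shapes differ: {t.shape} vs {p.shape}")
    t_labels = np.unique(t[t > 0])
    p_labels = np.unique(p[p > 0])
    if t_labels.size == 0 or p_labels.size == 0:
        return pd.DataFrame(
            np.zeros((t_labels.size, p_labels.size)), index=t_labels, columns=p_labels
        )
    # contingency table via a joint histogram of (truth, pred) label codes
    t_idx = np.searchsorted(t_labels, t.ravel())
    p_idx = np.searchsorted(p_labels, p.ravel())
    fg = (t.ravel() > 0) & (p.ravel() > 0)
    joint = np.bincount(
        t_idx[fg] * p_labels.size + p_idx[fg],
        minlength=t_labels.size * p_labels.size,
    ).reshape(t_labels.size, p_labels.size)
    t_areas = np.array([(t == lab).sum() for lab in t_labels])[:, None]
    p_areas = np.array([(p == lab).sum() for lab in p_labels])[None, :]
    union = t_areas + p_areas - joint
    with np.errstate(divide="ignore", invalid="ignore"):
        iou = np.where(union > 0, joint / union, 0.0)
    return pd.DataFrame(iou, index=t_labels, columns=p_labels)


def match_instances(
    iou: pd.DataFrame, iou_threshold: float
) -> list[tuple[int, int, float]]:
    """One-to-one matching over pairs with IoU >= threshold.

    Maximum cardinality first; among maximum-cardinality matchings, the one
    with the largest total IoU.  Returns ``(truth_label, pred_label, iou)``
    triples sorted by ascending (truth_label, pred_label).
    """
    if not 0 < iou_threshold <= 1:
        raise ValueError("iou_threshold must be in (0, 1]")
    values = iou.to_numpy(dtype=float)
    if values.size == 0:
        return []
    eligible = values >= iou_threshold
    score = np.where(eligible, values + _BONUS, 0.0)
    rows, cols = linear_sum_assignment(score, maximize=True)
    matches = [
        (int(iou.index[i]), int(iou.columns[j]), float(values[i, j]))
        for i, j in zip(rows, cols)
        if eligible[i, j]
    ]
    matches.sort(key=lambda m: (m[0], m[1]))
    return matches


def _metrics(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    precision = tp / (tp + fp) if tp + fp > 0 else float("nan")
    recall = tp / (tp + fn) if tp + fn > 0 else float("nan")
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        f1 = float("nan") if np.isnan(precision) or np.isnan(recall) else 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def evaluate(
    truth, pred, thresholds: tuple[float, ...] = (0.5, 0.6, 0.7, 0.8, 0.9)
) -> list[EvalResult]:
    """Evaluate one prediction against ground truth at several IoU
    thresholds, reusing a single IoU matrix."""
    iou = iou_matrix(truth, pred)
    n_truth, n_pred = iou.shape
    results = []
    for thr in thresholds:
        matches = match_instances(iou, thr)
        tp = len(matches)
        fp = n_pred - tp
        fn = n_truth - tp
        precision, recall, f1 = _metrics(tp, fp, fn)
        results.append(
            EvalResult(
                iou_threshold=float(thr),
                tp=tp,
                fp=fp,
                fn=fn,
                precision=precision,
                recall=recall,
                f1=f1,
                matches=matches,
            )
        )
    return results


def results_frame(results: list[EvalResult], field_id: str = "") -> pd.DataFrame:
    """Tabular form of an evaluation sweep (one row per threshold)."""
    return pd.DataFrame(
        [
            {
                "field_id": field_id,
                "iou_threshold": r.iou_threshold,
                "tp": r.tp,
                "fp": r.fp,
                "fn": r.fn,
                "precision": r.precision,
                "recall": r.recall,
                "f1": r.f1,
            }
            for r in results
        ]
    )


def xor_overlay(truth, pred, matches: list[tuple[int, int, float]]) -> np.ndarray:
    """Categorical error overlay for a matched mask pair.

    Per pixel: ``correct`` where truth and prediction overlap and the two
    instances are matched to each other; ``false_positive`` where the
    prediction covers truth background; ``false_negative`` where truth is
    missed; ``mismatch`` where both are foreground but the instances are
    not matched.  Codes per :data:`OVERLAY_CODES`.
    """
    t = as_label_array(truth)
    p = as_label_array(pred)
    if t.shape != p.shape:
        raise ShapeMismatchError(f"mask shapes differ: {t.shape} vs {p.shape}")
    # lookup: truth label -> matched pred label (0 = unmatched)
    max_t = int(t.max())
    partner = np.zeros(max_t + 1, dtype=np.int64)
    for gt, pr, _ in matches:
        partner[gt] = pr
    out = np.zeros(t.shape, dtype=np.uint8)
    t_fg = t > 0
    p_fg = p > 0
    out[p_fg & ~t_fg] = OVERLAY_CODES["false_positive"]
    out[t_fg & ~p_fg] = OVERLAY_CODES["false_negative"]
    both = t_fg & p_fg
    agree = np.zeros(t.shape, dtype=bool)
    agree[both] = partner[t[both]] == p[both]
    out[both & agree] = OVERLAY_CODES["correct"]
    out[both & ~agree] = OVERLAY_CODES["mismatch"]
    return out
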