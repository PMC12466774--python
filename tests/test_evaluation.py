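import itertools
import math

import numpy as np
import pandas as pd
import pytest

from metaspread.errors import ShapeMismatchError
from metaspread.evaluation import (
    OVERLAY_CODES,
    evaluate,
    iou_matrix,
    match_instances,
    xor_overlay,
)
from metaspread.synthetic import generate_degraded_mask

from conftest import make_blobs


def brute_force_match(values, threshold):
    """Exhaustive optimum over all one-to-one assignments: maximum match
    count, then maximum total IoU."""
    n_t, n_p = values.shape
    best = (0, 0.0)
    k = min(n_t, n_p)
    for size in range(k, -1, -1):
        found = False
        for rows in itertools.combinations(range(n_t), size):
            for cols in itertools.permutations(range(n_p), size):
                ious = [values[i, j] for i, j in zip(rows, cols)]
                if all(v >= threshold for v in ious):
                    found = True
                    best = max(best, (size, sum(ious)))
        if found:
            return best
    return (0, 0.0)


def test_identity_masks_give_perfect_scores(clean_field):
    mask = clean_field.mask
    iou = iou_matrix(mask, mask)
    np.testing.assert_allclose(np.diag(iou.to_numpy()), 1.0)
    for result in evaluate(mask, mask):
        assert (result.precision, result.recall, result.f1) == (1.0, 1.0, 1.0)
        assert (result.fp, result.fn) == (0, 0)


def test_disjoint_masks_have_zero_iou():
    truth = make_blobs((2, 10, 2, 10))
    pred = make_blobs((30, 40, 40, 50))
    iou = iou_matrix(truth, pred)
    assert (iou.to_numpy() == 0).all()


def test_iou_by_explicit_pixel_counting():
    # Ti: 100 px, Pj: 80 px, intersection 60 px -> IoU = 60/120
    truth = np.zeros((32, 32), np.int32)
    truth[0:10, 0:10] = 1
    pred = np.zeros((32, 32), np.int32)
    pred[0:10, 4:12] = 1
    iou = iou_matrix(truth, pred)
    assert iou.loc[1, 1] == pytest.approx(60 / 120)


def test_split_instance_across_thresholds():
    truth = np.zeros((20, 40), np.int32)
    truth[5:15, 4:36] = 1  # 10x32 rod
    pred = np.zeros_like(truth)
    pred[5:15, 4:20] = 1  # left half
    pred[5:15, 20:36] = 2  # right half, each IoU = 0.5
    (res_07,) = evaluate(truth, pred, (0.7,))
    assert (res_07.tp, res_07.fp, res_07.fn) == (0, 2, 1)
    (res_04,) = evaluate(truth, pred, (0.4,))
    assert (res_04.tp, res_04.fp, res_04.fn) == (1, 1, 0)


def test_deleting_one_instance_costs_recall_only(clean_field):
    k = clean_field.mask.instance_count
    degraded = generate_degraded_mask(clean_field.mask, [("drop", 5)])
    for result in evaluate(clean_field.mask, degraded):
        assert result.precision == 1.0
        assert result.recall == pytest.approx((k - 1) / k)


def test_matcher_equals_exhaustive_enumeration():
    rng = np.random.default_rng(17)
    for _ in range(60):
        n_t, n_p = rng.integers(1, 7, size=2)
        values = np.round(rng.uniform(0, 1, (n_t, n_p)), 3)
        frame = pd.DataFrame(values, index=range(1, n_t + 1), columns=range(1, n_p + 1))
        threshold = float(rng.choice([0.3, 0.5, 0.7]))
        matches = match_instances(frame, threshold)
        size, total = brute_force_match(values, threshold)
        assert len(matches) == size
        assert sum(m[2] for m in matches) == pytest.approx(total)


def test_f1_non_increasing_in_threshold(clean_field):
    degraded = generate_degraded_mask(
        clean_field.mask, [("erode", 1), ("drop", 2), ("merge", 3, 4)]
    )
    results = evaluate(clean_field.mask, degraded, (0.5, 0.6, 0.7, 0.8, 0.9))
    f1s = [r.f1 for r in results]
    f1s = [0.0 if math.isnan(v) else v for v in f1s]
    assert all(a >= b - 1e-12 for a, b in zip(f1s, f1s[1:]))
    for r in results:
        if not math.isnan(r.f1):
            assert 0 <= r.f1 <= max(r.precision, r.recall) + 1e-12


def test_empty_masks_yield_missing_metrics():
    empty = np.zeros((8, 8), np.int32)
    (result,) = evaluate(empty, empty, (0.5,))
    assert math.isnan(result.precision) and math.isnan(result.recall)
    assert (result.tp, result.fp, result.fn) == (0, 0, 0)


def test_shape_mismatch_is_an_error():
    with pytest.raises(ShapeMismatchError):
        iou_matrix(np.zeros((4, 4), np.int32), np.zeros((5, 5), np.int32))


class TestOverlay:
    def test_identity_is_all_correct(self, clean_field):
        mask = clean_field.mask
        matches = match_instances(iou_matrix(mask, mask), 0.5)
        overlay = xor_overlay(mask, mask, matches)
        fg = mask.labels > 0
        assert np.all(overlay[fg] == OVERLAY_CODES["correct"])
        assert np.all(overlay[~fg] == OVERLAY_CODES["background"])

    def test_empty_prediction_is_all_false_negative(self, clean_field):
        mask = clean_field.mask
        empty = np.zeros_like(mask.labels)
        overlay = xor_overlay(mask, empty, [])
        assert np.all(overlay[mask.labels > 0] == OVERLAY_CODES["false_negative"])

    def test_swapped_instances_are_mismatch(self):
        truth = make_blobs((2, 10, 2, 10), (2, 10, 20, 28))
        pred = make_blobs((2, 10, 20, 28), (2, 10, 2, 10))  # labels swapped
        matches = match_instances(iou_matrix(truth, pred), 0.5)
        overlay = xor_overlay(truth, pred, matches)
        # every overlapping pixel belongs to correctly matched instances:
        # (1<->2) and (2<->1) are matched pairs, so pixels are "correct"
        assert np.all(overlay[truth > 0] == OVERLAY_CODES["correct"])
        # below threshold nothing matches and overlap becomes mismatch
        overlay_strict = xor_overlay(truth, pred, [])
        assert np.all(overlay_strict[truth > 0] == OVERLAY_CODES["mismatch"])

    def test_fp_and_fn_pixels(self):
        truth = make_blobs((2, 10, 2, 10))
        pred = make_blobs((20, 28, 20, 28))
        overlay = xor_overlay(truth, pred, [])
        assert np.all(overlay[truth > 0] == OVERLAY_CODES["false_negative"])
        assert np.all(overlay[pred > 0] == OVERLAY_CODES["false_positive"])
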