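"""Metric correctness against exhaustive pixel-level oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msfnet import (
    MaskPair,
    assd,
    boundary_points,
    dice_score,
    evaluate,
    iou_score,
    precision_score,
    soft_dice_loss,
    soft_dice_loss_np,
)
from msfnet.metrics import SOFT_DICE_EPS
from msfnet.nn.autograd import Tensor

from conftest import random_binary_mask


# ---------------------------------------------------------------------------
# brute-force oracles


def brute_force_assd(a, b):
    """All-pairs Euclidean oracle over the two boundary point sets."""
    pa = boundary_points(a).astype(float)
    pb = boundary_points(b).astype(float)
    d_ab = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1)).min(axis=1).sum()
    d_ba = np.sqrt(((pb[:, None, :] - pa[None, :, :]) ** 2).sum(-1)).min(axis=1).sum()
    return (d_ab + d_ba) / (len(pa) + len(pb))


def counting_metrics(pred, truth):
    tp = int((pred & truth).sum())
    fp = int((pred & ~truth).sum())
    fn = int((~pred & truth).sum())
    dice = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 1.0
    iou = tp / (tp + fp + fn) if tp + fp + fn else 1.0
    prec = tp / (tp + fp) if tp + fp else (1.0 if truth.sum() == 0 else 0.0)
    return dice, iou, prec


# ---------------------------------------------------------------------------
# overlap metrics


def test_overlap_metrics_hand_counted_examples():
    a = np.zeros((4, 4), dtype=np.uint8)
    b = np.zeros((4, 4), dtype=np.uint8)
    a[0, :4] = 1          # |A| = 4
    b[0, 2:4] = 1
    b[1, 0:2] = 1         # |B| = 4, overlap = 2, union = 6
    assert dice_score(a, b) == pytest.approx(0.5)
    assert iou_score(a, b) == pytest.approx(1 / 3)


def test_overlap_metrics_degenerate_cases():
    z = np.zeros((5, 5), dtype=np.uint8)
    o = np.ones((5, 5), dtype=np.uint8)
    assert dice_score(o, o) == 1.0
    assert iou_score(z, z) == 1.0 and dice_score(z, z) == 1.0
    disjoint = z.copy()
    disjoint[0, 0] = 1
    other = z.copy()
    other[4, 4] = 1
    assert dice_score(disjoint, other) == 0.0
    assert precision_score(z, o) == 0.0      # empty prediction, nonempty truth
    assert precision_score(z, z) == 1.0
    assert precision_score(1 - o, o) == pytest.approx(0.0)  # complement


def test_precision_direct_counts():
    pred = np.zeros((3, 3), dtype=np.uint8)
    truth = np.zeros((3, 3), dtype=np.uint8)
    pred[0, :3] = 1
    pred[1, 0] = 1        # 4 positives
    truth[0, :3] = 1      # 3 of them true
    assert precision_score(pred, truth) == pytest.approx(0.75)
    sub = truth.copy()
    sub[0, 2] = 0         # pred subset of truth
    assert precision_score(sub, truth) == 1.0


def test_metrics_reject_nonbinary_input():
    with pytest.raises(ValueError, match="binary"):
        dice_score(np.full((2, 2), 0.5), np.zeros((2, 2)))


@settings(max_examples=40, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_overlap_metrics_match_counting_oracle(seed):
    rng = np.random.default_rng(seed)
    a = random_binary_mask(rng, (16, 16))
    b = random_binary_mask(rng, (16, 16))
    dice, iou, prec = counting_metrics(a.astype(bool), b.astype(bool))
    assert dice_score(a, b) == pytest.approx(dice)
    assert iou_score(a, b) == pytest.approx(iou)
    assert precision_score(a, b) == pytest.approx(prec)
    # algebraic identity between the two overlap measures
    assert iou_score(a, b) == pytest.approx(dice_score(a, b) / (2 - dice_score(a, b)))


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_growing_overlap_never_decreases_dice_or_iou(seed):
    """Moving one false-positive pixel onto a missed truth pixel (mask sizes
    fixed, overlap + 1) can only raise both overlap scores."""
    rng = np.random.default_rng(seed)
    truth = random_binary_mask(rng, (16, 16))
    pred = random_binary_mask(rng, (16, 16))
    fp = np.argwhere(pred & ~truth)
    fn = np.argwhere(~pred & truth)
    if len(fp) == 0 or len(fn) == 0:
        return
    better = pred.copy()
    better[tuple(fp[0])] = 0
    better[tuple(fn[0])] = 1
    assert dice_score(better, truth) >= dice_score(pred, truth)
    assert iou_score(better, truth) >= iou_score(pred, truth)


# ---------------------------------------------------------------------------
# ASSD


def test_assd_identical_masks_is_zero(rng):
    m = random_binary_mask(rng, (20, 20))
    if m.sum() == 0:
        m[5, 5] = 1
    assert assd(m, m) == 0.0


def test_assd_unit_shift_oracle():
    a = np.zeros((14, 14), dtype=np.uint8)
    a[2:12, 2:12] = 1
    b = np.roll(a, 1, axis=1)  # same square shifted one pixel right
    expected = brute_force_assd(a, b)
    assert assd(a, b) == pytest.approx(expected, abs=1e-9)


def test_assd_symmetry_and_empty_errors(rng):
    a = random_binary_mask(rng, (18, 18))
    b = random_binary_mask(rng, (18, 18))
    a[4, 4] = 1
    b[9, 9] = 1
    assert assd(a, b) == pytest.approx(assd(b, a))
    with pytest.raises(ValueError, match="prediction"):
        assd(np.zeros_like(a), b)
    with pytest.raises(ValueError, match="truth"):
        assd(a, np.zeros_like(b))


def test_assd_matches_brute_force_on_many_random_masks():
    """Distance-transform ASSD equals the all-pairs oracle on 200 random
    mask pairs up to 32x32."""
    rng = np.random.default_rng(99)
    checked = 0
    while checked < 200:
        h = int(rng.integers(8, 33))
        w = int(rng.integers(8, 33))
        a = random_binary_mask(rng, (h, w), p=float(rng.uniform(0.1, 0.6)))
        b = random_binary_mask(rng, (h, w), p=float(rng.uniform(0.1, 0.6)))
        if a.sum() == 0 or b.sum() == 0:
            continue
        assert assd(a, b) == pytest.approx(brute_force_assd(a, b), abs=1e-9)
        checked += 1


def test_boundary_uses_four_connectivity_and_border():
    """A 3x3 solid block keeps only its centre as interior; a full-image
    mask is all boundary because the image border counts as background."""
    m = np.zeros((5, 5), dtype=np.uint8)
    m[1:4, 1:4] = 1
    pts = {tuple(p) for p in boundary_points(m)}
    assert (2, 2) not in pts and len(pts) == 8
    # the border of a full-image mask is boundary because out-of-image
    # neighbours count as background; only the 2 inner pixels are interior
    full = np.ones((3, 4), dtype=np.uint8)
    assert len(boundary_points(full)) == 10


# ---------------------------------------------------------------------------
# soft dice loss


def test_soft_dice_perfect_and_empty_cases():
    truth = np.zeros((4, 4), dtype=np.float32)
    truth[1:3, 1:3] = 1
    assert soft_dice_loss_np(truth, truth) == pytest.approx(0.0, abs=1e-5)
    zeros = np.zeros((4, 4), dtype=np.float32)
    assert soft_dice_loss_np(zeros, zeros) == pytest.approx(0.0, abs=1e-12)


def test_soft_dice_hand_substitution():
    """pred = 0.5 everywhere on 2x2, truth has one foreground pixel."""
    pred = np.full((2, 2), 0.5, dtype=np.float32)
    truth = np.zeros((2, 2), dtype=np.float32)
    truth[0, 0] = 1.0
    eps = SOFT_DICE_EPS
    expected = -np.log((2 * 0.5 + eps) / (2.0 + 1.0 + eps))
    assert soft_dice_loss_np(pred, truth) == pytest.approx(expected, rel=1e-9)
    t = Tensor(pred, requires_grad=True)
    assert float(soft_dice_loss(t, truth).data) == pytest.approx(expected, rel=1e-5)


def test_soft_dice_equals_neg_log_dice_for_binary_pred(rng):
    pred = random_binary_mask(rng, (12, 12)).astype(np.float32)
    truth = random_binary_mask(rng, (12, 12)).astype(np.float32)
    if pred.sum() == 0 or truth.sum() == 0:
        pred[3, 3] = truth[3, 3] = 1
    d = dice_score(pred.astype(np.uint8), truth.astype(np.uint8))
    if d > 0:
        assert soft_dice_loss_np(pred, truth) == pytest.approx(-np.log(d), abs=1e-4)


def test_soft_dice_gradient_sign_on_true_foreground(rng):
    """Raising the prediction on a true-foreground pixel never increases
    the loss: the gradient there is non-positive."""
    truth = random_binary_mask(rng, (10, 10)).astype(np.float32)
    truth[4, 4] = 1
    pred = Tensor(rng.uniform(0.05, 0.95, (10, 10)).astype(np.float32), requires_grad=True)
    soft_dice_loss(pred, truth).backward()
    assert (pred.grad[truth == 1] <= 1e-7).all()


def test_soft_dice_rejects_out_of_range():
    t = Tensor(np.full((2, 2), 1.5, dtype=np.float32))
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        soft_dice_loss(t, np.zeros((2, 2)))


# ---------------------------------------------------------------------------
# evaluate


def test_evaluate_perfect_pair_and_aggregation(rng):
    truth = random_binary_mask(rng, (16, 16))
    truth[8, 8] = 1
    pair = MaskPair(prediction=truth.astype(float), truth=truth, id="x")
    report = evaluate([pair] * 5)
    assert report.mean["dice"] == 1.0 and report.std["dice"] == 0.0
    assert report.mean["iou"] == 1.0
    assert report.mean["precision"] == 1.0
    assert report.mean["assd"] == 0.0


def test_evaluate_mean_matches_independent_recomputation(rng):
    pairs = []
    for _ in range(6):
        truth = random_binary_mask(rng, (16, 16))
        pred = np.clip(truth + rng.normal(0, 0.4, truth.shape), 0, 1)
        pairs.append(MaskPair(prediction=pred, truth=truth))
    report = evaluate(pairs, threshold=0.5)
    manual = np.mean([
        dice_score((np.asarray(p.prediction) >= 0.5).astype(np.uint8), p.truth)
        for p in pairs
    ])
    assert report.mean["dice"] == pytest.approx(manual)


def test_evaluate_flags_empty_predictions_and_writes_reports(rng, tmp_path):
    truth = random_binary_mask(rng, (12, 12))
    truth[6, 6] = 1
    pairs = [
        MaskPair(prediction=np.zeros((12, 12)), truth=truth, id="empty"),
        MaskPair(prediction=truth.astype(float), truth=truth, id="perfect"),
    ]
    report = evaluate(pairs)
    assert report.n_empty_predictions == 1
    assert np.isnan(report.per_image[0]["assd"])
    report.write_csv(tmp_path / "per_image.csv")
    report.write_json(tmp_path / "summary.json")
    assert (tmp_path / "per_image.csv").read_text().count("\n") == 3
    assert "dice" in (tmp_path / "summary.json").read_text()


def test_evaluate_rejects_empty_list_and_bad_threshold():
    with pytest.raises(ValueError):
        evaluate([])
    with pytest.raises(ValueError):
        evaluate([MaskPair(np.zeros((2, 2)), np.zeros((2, 2)))], threshold=1.5)
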