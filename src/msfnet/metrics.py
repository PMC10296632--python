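"""Training loss and evaluation metrics for binary lesion segmentation.

The training objective is the Soft Dice loss, -ln of the
epsilon-smoothed Dice coefficient between the predicted probability map
and the binary ground truth.  Evaluation reports four quantities per
image: Dice, IoU (Jaccard), Precision, and the average symmetric surface
distance (ASSD) between the two mask boundaries in pixels.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .nn.autograd import Tensor

__all__ = [
    "SOFT_DICE_EPS",
    "soft_dice_loss",
    "soft_dice_loss_np",
    "dice_score",
    "iou_score",
    "precision_score",
    "boundary_points",
    "assd",
    "MaskPair",
    "MetricReport",
    "evaluate",
]

#: smoothing constant guarding the empty-empty case
SOFT_DICE_EPS = 1e-5

# 4-connectivity structuring element for boundary extraction
_CROSS = ndimage.generate_binary_structure(2, 1)


def _check_binary(m: np.ndarray, name: str):
    if not np.isin(m, (0, 1)).all():
        raise ValueError(f"{name} must be strictly binary (0/1)")


def soft_dice_loss(pred: Tensor, truth: np.ndarray, eps: float = SOFT_DICE_EPS) -> Tensor:
    """Differentiable Soft Dice loss -ln((2*sum(x*y)+eps) / (sum(x)+sum(y)+eps)).

    ``pred`` holds probabilities in [0, 1]; ``truth`` is a binary array of
    the same shape.  Zero when the prediction reproduces the truth exactly
    (including the all-empty case, where the eps guard gives Dice = 1).
    """
    t = np.asarray(truth, dtype=np.float32)
    if pred.data.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {pred.data.shape} vs truth {t.shape}")
    if pred.data.min() < -1e-6 or pred.data.max() > 1.0 + 1e-6:
        raise ValueError("predictions must lie in [0, 1]")
    inter = (pred * Tensor(t)).sum()
    denom = pred.sum() + Tensor(np.float32(t.sum() + eps))
    dice = (inter * 2.0 + eps) / denom
    return -dice.log()


def soft_dice_loss_np(pred: np.ndarray, truth: np.ndarray, eps: float = SOFT_DICE_EPS) -> float:
    """Plain-array Soft Dice loss (no gradient)."""
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    dice = (2.0 * (pred * truth).sum() + eps) / (pred.sum() + truth.sum() + eps)
    return float(-np.log(dice))


def dice_score(a: np.ndarray, b: np.ndarray) -> float:
    """2|A∩B| / (|A|+|B|) for binary masks; 1.0 when both are empty."""
    a = np.asarray(a); b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    _check_binary(a, "a"); _check_binary(b, "b")
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        return 1.0
    return 2.0 * int((a * b).sum()) / (sa + sb)


def iou_score(a: np.ndarray, b: np.ndarray) -> float:
    """|A∩B| / |A∪B| for binary masks; 1.0 when both are empty."""
    a = np.asarray(a); b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    _check_binary(a, "a"); _check_binary(b, "b")
    inter = int((a * b).sum())
    union = int(a.sum()) + int(b.sum()) - inter
    if union == 0:
        return 1.0
    return inter / union


def precision_score(pred: np.ndarray, truth: np.ndarray) -> float:
    """TP / (TP + FP); 1.0 for empty-pred/empty-truth, 0.0 for an empty
    prediction against a nonempty truth."""
    pred = np.asarray(pred); truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("mask shapes differ")
    _check_binary(pred, "pred"); _check_binary(truth, "truth")
    positives = int(pred.sum())
    if positives == 0:
        return 1.0 if int(truth.sum()) == 0 else 0.0
    tp = int((pred * truth).sum())
    return tp / positives


def boundary_points(mask: np.ndarray) -> np.ndarray:
    """Foreground pixels with at least one background 4-neighbour; the image
    border counts as background.  Returns an (N, 2) array of (row, col)."""
    m = np.asarray(mask).astype(bool)
    interior = ndimage.binary_erosion(m, structure=_CROSS, border_value=0)
    return np.argwhere(m & ~interior)


def assd(pred: np.ndarray, truth: np.ndarray) -> float:
    """Average symmetric surface distance between two mask boundaries, in
    pixels: the sum of each boundary point's Euclidean distance to the other
    boundary, divided by the total number of boundary points."""
    pred = np.asarray(pred); truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("mask shapes differ")
    _check_binary(pred, "pred"); _check_binary(truth, "truth")
    if pred.sum() == 0:
        raise ValueError("prediction mask is empty; ASSD undefined")
    if truth.sum() == 0:
        raise ValueError("truth mask is empty; ASSD undefined")
    bp = boundary_points(pred)
    bt = boundary_points(truth)
    # distance transform of the complement of each boundary set gives the
    # distance from any pixel to that set
    on_p = np.ones(pred.shape, dtype=bool)
    on_p[tuple(bp.T)] = False
    on_t = np.ones(truth.shape, dtype=bool)
    on_t[tuple(bt.T)] = False
    d_to_t = ndimage.distance_transform_edt(on_t)
    d_to_p = ndimage.distance_transform_edt(on_p)
    total = d_to_t[tuple(bp.T)].sum() + d_to_p[tuple(bt.T)].sum()
    return float(total / (len(bp) + len(bt)))


@dataclass
class MaskPair:
    prediction: np.ndarray  # probabilities in [0, 1]
    truth: np.ndarray       # binary
    id: str = ""


@dataclass
class MetricReport:
    per_image: list[dict] = field(default_factory=list)
    mean: dict = field(default_factory=dict)
    std: dict = field(default_factory=dict)
    n_images: int = 0
    n_empty_predictions: int = 0

    def write_csv(self, path):
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["image_id", "dice", "iou", "precision", "assd"])
            writer.writeheader()
            for row in self.per_image:
                writer.writerow({k: row[k] for k in writer.fieldnames})

    def write_json(self, path):
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "n_images": self.n_images,
            "n_empty_predictions": self.n_empty_predictions,
            "mean": self.mean,
            "std": self.std,
        }
        path.write_text(json.dumps(payload, indent=2))


def evaluate(pairs: list[MaskPair], threshold: float = 0.5) -> MetricReport:
    """Binarise each prediction at ``threshold`` and report the four
    metrics per image plus their mean and standard deviation.

    ASSD is skipped (recorded as NaN and flagged) for images where either
    binarised mask is empty; the mean/std for ASSD cover the remaining
    images.  Metrics are averaged over images, not pooled over pixels.
    """
    if not pairs:
        raise ValueError("evaluate() needs at least one mask pair")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    report = MetricReport(n_images=len(pairs))
    for idx, pair in enumerate(pairs):
        pred = (np.asarray(pair.prediction) >= threshold).astype(np.uint8)
        truth = np.asarray(pair.truth).astype(np.uint8)
        row = {
            "image_id": pair.id or str(idx),
            "dice": dice_score(pred, truth),
            "iou": iou_score(pred, truth),
            "precision": precision_score(pred, truth),
        }
        if pred.sum() == 0 or truth.sum() == 0:
            row["assd"] = float("nan")
            row["assd_skipped"] = True
            report.n_empty_predictions += 1
        else:
            row["assd"] = assd(pred, truth)
            row["assd_skipped"] = False
        report.per_image.append(row)
    for key in ("dice", "iou", "precision"):
        vals = np.array([r[key] for r in report.per_image])
        report.mean[key] = float(vals.mean())
        report.std[key] = float(vals.std())
    assd_vals = np.array([r["assd"] for r in report.per_image if not r["assd_skipped"]])
    report.mean["assd"] = float(assd_vals.mean()) if assd_vals.size else float("nan")
    report.std["assd"] = float(assd_vals.std()) if assd_vals.size else float("nan")
    return report
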