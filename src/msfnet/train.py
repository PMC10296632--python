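"""Training and evaluation protocol.

Adam on the Soft Dice loss: initial learning rate 1e-4, weight decay 1e-8,
batch size 16, 300 epochs, with the learning rate halved once after epoch
256.  Validation runs after every epoch and the checkpoint with the best
validation Dice is retained for testing.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .data import AugmentConfig, Sample, preprocess_eval, preprocess_train
from .metrics import MaskPair, MetricReport, dice_score, evaluate, soft_dice_loss
from .network import MSFNet, NetConfig
from .nn import Adam, step_lr
from .nn.autograd import Tensor

__all__ = [
    "TrainConfig",
    "RunLog",
    "train",
    "predict",
    "evaluate_run",
    "render_overlay",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    weight_decay: float = 1e-8
    batch_size: int = 16
    epochs: int = 300
    lr_drop_epoch: int = 256
    lr_drop_factor: float = 0.5
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if min(self.learning_rate, self.batch_size, self.epochs) <= 0:
            raise ValueError("learning rate, batch size and epochs must be positive")
        if self.lr_drop_epoch > self.epochs:
            raise ValueError("lr_drop_epoch must not exceed epochs")


@dataclass
class RunLog:
    epochs: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_dice: float = -1.0
    best_checkpoint: str = ""

    def write_csv(self, path):
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["epoch", "lr", "train_loss", "train_dice", "val_dice", "n_updates"])
            writer.writeheader()
            for row in self.epochs:
                writer.writerow(row)


def _to_batch(samples: list[Sample]) -> tuple[Tensor, np.ndarray]:
    images = np.stack([s.image.transpose(2, 0, 1) for s in samples]).astype(np.float32)
    masks = np.stack([s.mask for s in samples]).astype(np.float32)[:, None]
    return Tensor(images), masks


def save_checkpoint(net: MSFNet, path):
    """Weights as an .npz archive, configuration as a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **net.state_dict())
    cfg = asdict(net.cfg)
    cfg["dilation_set"] = list(net.cfg.dilation_set.rates)
    path.with_suffix(".json").write_text(json.dumps(cfg, indent=2))


def load_checkpoint(path) -> MSFNet:
    path = Path(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"checkpoint sidecar {sidecar} not found")
    raw = json.loads(sidecar.read_text())
    from .blocks import DilationSet

    raw["dilation_set"] = DilationSet(tuple(raw["dilation_set"]))
    raw["encoder_widths"] = tuple(raw["encoder_widths"])
    net = MSFNet(NetConfig(**raw))
    with np.load(path) as data:
        state = {k: data[k] for k in data.files}
    try:
        net.load_state_dict(state)
    except (KeyError, ValueError) as exc:
        raise ValueError(f"checkpoint {path} does not match its configuration: {exc}") from exc
    return net


def predict(net: MSFNet, samples: list[Sample]) -> list[np.ndarray]:
    """Per-image probability maps in evaluation mode."""
    net.eval()
    out = []
    for s in samples:
        x, _ = _to_batch([s])
        out.append(net(x).data[0, 0])
    return out


def _validation_dice(net: MSFNet, samples: list[Sample], threshold: float) -> float:
    probs = predict(net, samples)
    scores = [
        dice_score((p >= threshold).astype(np.uint8), s.mask.astype(np.uint8))
        for p, s in zip(probs, samples)
    ]
    return float(np.mean(scores))


def train(
    net_cfg: NetConfig,
    train_cfg: TrainConfig,
    train_samples: list[Sample],
    val_samples: list[Sample],
    out_dir,
    augment: AugmentConfig | None = None,
) -> RunLog:
    """Run the full protocol and return the per-epoch log.

    ``augment`` enables the stochastic resize/crop/flip/rotate pipeline on
    the training split (validation always uses the deterministic resize +
    centre crop).  With ``augment=None`` samples are used as provided.
    Aborts with a state dump if the loss goes non-finite.
    """
    if not train_samples or not val_samples:
        raise ValueError("train and validation splits must be nonempty")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(train_cfg.seed)
    net = MSFNet(net_cfg)
    net.reseed_dropout(train_cfg.seed + 7)
    opt = Adam(net.parameters(), lr=train_cfg.learning_rate,
               weight_decay=train_cfg.weight_decay)
    if augment is not None:
        val_samples = [preprocess_eval(s, augment) for s in val_samples]
    log = RunLog()
    for epoch in range(1, train_cfg.epochs + 1):
        opt.lr = step_lr(train_cfg.learning_rate, epoch,
                         train_cfg.lr_drop_epoch, train_cfg.lr_drop_factor)
        net.train()
        order = rng.permutation(len(train_samples))
        losses, dices = [], []
        for start in range(0, len(order), train_cfg.batch_size):
            batch_idx = order[start: start + train_cfg.batch_size]
            batch = [train_samples[i] for i in batch_idx]
            if augment is not None:
                batch = [preprocess_train(s, augment, rng) for s in batch]
            x, masks = _to_batch(batch)
            pred = net(x)
            loss = soft_dice_loss(pred, masks)
            value = float(loss.data)
            if not np.isfinite(value):
                dump = out_dir / "diverged.npz"
                save_checkpoint(net, dump)
                raise RuntimeError(
                    f"non-finite loss {value} at epoch {epoch}; state dumped to {dump}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(value)
            binar = (pred.data[:, 0] >= train_cfg.threshold).astype(np.uint8)
            dices.extend(
                dice_score(binar[i], batch[i].mask.astype(np.uint8)) for i in range(len(batch))
            )
        val_dice = _validation_dice(net, val_samples, train_cfg.threshold)
        row = {
            "epoch": epoch,
            "lr": opt.lr,
            "train_loss": float(np.mean(losses)),
            "train_dice": float(np.mean(dices)),
            "val_dice": val_dice,
            "n_updates": len(losses),
        }
        log.epochs.append(row)
        if val_dice > log.best_val_dice:
            log.best_val_dice = val_dice
            log.best_epoch = epoch
            log.best_checkpoint = str(out_dir / "best.npz")
            save_checkpoint(net, log.best_checkpoint)
    log.write_csv(out_dir / "train_log.csv")
    return log


def evaluate_run(checkpoint, samples: list[Sample], out_dir,
                 threshold: float = 0.5,
                 augment: AugmentConfig | None = None) -> MetricReport:
    """Evaluate a checkpoint on a split: per-image CSV plus JSON summary."""
    if not samples:
        raise ValueError("evaluation split is empty")
    out_dir = Path(out_dir)
    net = load_checkpoint(checkpoint)
    if augment is not None:
        samples = [preprocess_eval(s, augment) for s in samples]
    probs = predict(net, samples)
    pairs = [MaskPair(prediction=p, truth=s.mask, id=s.id) for p, s in zip(probs, samples)]
    report = evaluate(pairs, threshold=threshold)
    report.write_csv(out_dir / "metrics_per_image.csv")
    report.write_json(out_dir / "metrics_summary.json")
    return report


_DARK_GREEN = np.array([0.0, 0.42, 0.0], dtype=np.float32)
_RED = np.array([1.0, 0.0, 0.0], dtype=np.float32)
_GREEN = np.array([0.0, 1.0, 0.0], dtype=np.float32)


def render_overlay(pred: np.ndarray, truth: np.ndarray, image: np.ndarray) -> np.ndarray:
    """Colour-coded agreement overlay: dark green where prediction and truth
    agree on lesion, red for missed lesion (under-segmentation), green for
    false lesion (over-segmentation); the source image elsewhere."""
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape or image.shape[:2] != pred.shape:
        raise ValueError("overlay inputs must be spatially aligned")
    out = np.asarray(image, dtype=np.float32).copy()
    out[pred & truth] = _DARK_GREEN
    out[~pred & truth] = _RED
    out[pred & ~truth] = _GREEN
    return out
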