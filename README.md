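# msfnet

Lightweight multi-scale feature-fusion segmentation of skin lesions in
dermoscopy images, for researchers who need a fully inspectable,
CPU-runnable reference of the MSF-Net architecture: its three building
blocks, the assembled encoder–decoder with ablation switches, the Soft
Dice objective, boundary-aware evaluation metrics, the ISIC-2018 data
pipeline, and a synthetic lesion generator so everything is testable
without downloading challenge data.  The network runs on a small NumPy
reverse-mode autograd engine (`msfnet.nn`) — no GPU framework required.

## The model

A five-level U-shaped network (widths 16/32/64/128/256) built on an
attention-U-Net backbone, extended by three independently switchable
modules:

* **S-conv** — the encoder's double-3×3 block gated by a sigmoid spatial
  attention map from a 1×1 convolution of the block input:
  `Y_out = Y_r1 ⊙ σ(w_g * x)`.
* **MDC** — four 3×3 branches sharing *one* kernel at dilation rates
  r = 1, 2, 4, 10 (receptive fields `2(r−1)+3` = 3, 5, 9, 21), fused
  pairwise by an attention unit that mixes each pair with per-pixel
  softmax weights (Ma1 + Ma2 = 1) and recalibrates the concatenated pair
  with a sigmoid map, plus a residual connection.
* **MFF** — an Inception-style block with branch widths C/4, C/2, C/4 of
  increasing depth (the deepest stacks two 3×3 convs — a 5×5 receptive
  field at 18C² instead of 25C² weights), concatenated, smoothed by a 1×1
  conv, and residual-added; one per skip connection.

Training minimises the Soft Dice loss `L = −ln[(2Σxy+ε)/(Σx+Σy+ε)]`
(ε = 10⁻⁵) with Adam (lr 10⁻⁴, weight decay 10⁻⁸, batch 16, 300 epochs,
lr halved once after epoch 256), selecting the checkpoint with the best
validation Dice.  Evaluation reports Dice, IoU, Precision and the average
symmetric surface distance (ASSD) in pixels.  See `docs/methods.md` for
the complete model description, conventions and design choices.

## Worked example

Generate a small synthetic dataset, overfit the full three-module network
at reduced scale, and evaluate it on its own training images:

```python
from msfnet import (SynthConfig, generate_synthetic, NetConfig, TrainConfig,
                    DilationSet, train, load_checkpoint, predict, evaluate, MaskPair)

samples = generate_synthetic(SynthConfig(n_images=10, image_size=(96, 128), seed=7))
net_cfg = NetConfig(encoder_widths=(8, 16, 32, 64, 128), use_sconv=True,
                    use_mff=True, use_mdc=True, dilation_set=DilationSet((1, 2, 4)), seed=3)
run_cfg = TrainConfig(learning_rate=2e-3, batch_size=4, epochs=30, lr_drop_epoch=30, seed=3)
log = train(net_cfg, run_cfg, samples[:8], samples[8:], "runs/demo")
print(f"best validation Dice {log.best_val_dice:.3f} at epoch {log.best_epoch}")

net = load_checkpoint(log.best_checkpoint)
probs = predict(net, samples[:8])
report = evaluate([MaskPair(p, s.mask, s.id) for p, s in zip(probs, samples[:8])])
for k in ("dice", "iou", "precision", "assd"):
    print(f"{k:9s} {report.mean[k]:.4f} +/- {report.std[k]:.4f}")
```

Output (about a minute on one CPU core):

```
best validation Dice 0.953 at epoch 20
dice      0.9500 +/- 0.0153
iou       0.9051 +/- 0.0273
precision 0.9078 +/- 0.0279
assd      1.0873 +/- 0.1516
```

A training Dice of 0.95 on eight easy synthetic lesions shows the whole
pipeline — generator, network, loss, optimiser, checkpointing, metrics —
learns end to end; the ASSD of ~1.1 px says the predicted boundaries sit
about one pixel from the truth on average.

The same workflow is available from the shell:

```bash
msfnet synth --n 32 --seed 7 --out data/synth
msfnet train --images data/synth/images --masks data/synth/masks \
             --use-sconv --use-mdc --use-mff --seed 3 --out runs/full
msfnet eval  --checkpoint runs/full/best.npz \
             --images data/synth/images --masks data/synth/masks
msfnet params --grid
```

`msfnet params` prints the trainable-parameter accounting: the baseline
backbone at 2.7884 M, the S-conv gates adding 0.0002 M, the MFF modules
0.1191 M, and the MDC modules 0.4764 M (3.3842 M total).  `docs/methods.md`
explains why the MDC figure measured here differs from the originally
reported 0.5519 M: that number is only consistent with fusion units whose
attention convolutions were left out of the count.

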