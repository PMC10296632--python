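# Methods

## The model

MSF-Net is a five-level U-shaped encoder–decoder for binary dermoscopy
lesion segmentation.  An RGB image `x ∈ [0,1]^{3×H×W}` is mapped to a
per-pixel lesion probability map by an encoder at widths 16/32/64/128/256
(2×2 max-pooling between levels), a decoder that mirrors it with bilinear
upsampling, and a 1×1 sigmoid head.  Three modules ride on an
attention-U-Net backbone and can be switched independently (the ablation
grid is the 2³ on/off combinations):

**S-conv block.**  The standard double-3×3 convolution block, gated by a
spatial attention map computed from the block input:

    Y_out = Y_r1 ⊙ σ(w_g * x),

where `Y_r1` is the two-conv feature branch, `w_g` a 1×1 convolution to one
channel, and the sigmoid map broadcasts across channels.  The gate reads
the **block input** (a genuine second branch), not the feature output; with
zero gate weights the block reduces to `0.5·Y_r1`.  The gate costs
`C_in + 1` parameters per block — 248 over the five encoder blocks.

**MDC (multi-scale dilated convolution).**  One 3×3 kernel applied at
dilation rates r = 1, 2, 4, 10 (receptive field `2(r−1)+3` = 3, 5, 9, 21;
padding equal to the rate preserves the spatial size).  The kernel tensor
is *shared* across the four branches — a larger receptive field costs no
extra parameters — while each branch keeps its own batch normalisation.
Branch outputs are fused pairwise by the attention fusion unit F in a
binary tree, (Y1,Y2)→Y12, (Y3,Y4)→Y34, (Y12,Y34)→Y1234, and added to the
module input (residual).  F concatenates a pair to 2C channels and runs
two branches: a softmax branch (1×1 conv to C with BN+ReLU, 3×3 conv to 2,
per-pixel softmax) giving two convex mixing maps Ma1+Ma2=1 applied to the
pair, and a sigmoid branch (1×1 conv to one channel) that recalibrates the
concatenated pair before a 1×1 channel-recovery conv; the two paths are
summed.  The pre-softmax, pre-sigmoid and recovery convolutions carry no
BN/ReLU so their logits stay unsquashed (ReLU in front of a softmax or
sigmoid would forbid negative logits and halve the usable range).
MDC modules sit after encoder blocks 1–4 (widths 16/32/64/128), before
pooling; the 256-wide bottleneck is excluded because a 224×300 input
leaves only a 14×18 map there, smaller than the 21×21 receptive field at
rate 10.  A forward pass refuses feature maps smaller than the largest
receptive field, naming the offending rate.

**MFF (multi-scale feature fusion).**  An Inception-style three-branch
block at channel width C (divisible by 4): a 1×1 branch to C/4, a
1×1→3×3 branch to C/2, and a 1×1→3×3→3×3 branch to C/4 whose stacked
3×3 pair realises a 5×5 receptive field at 18C² instead of 25C² weights.
Outputs are concatenated back to C channels, smoothed by a 1×1 conv
(all convs carry bias + BN + ReLU) and residual-added.  One MFF sits on
each of the four skip paths, just before concatenation into the decoder.

## The backbone and its parameter budget

The backbone follows the comprehensive-attention network family: encoder
conv blocks as above; decoder levels that bilinearly upsample, project
with a 1×1 conv + BN to the skip width, apply **dual-gate spatial
attention** on the three deepest skips (two additive attention gates over
the same skip, recombined by a 1×1 conv), concatenate, apply
squeeze-and-excitation channel attention on the concatenated feature, and
refine with a wide double-3×3 block (2C→2C→C).  Dropout (rate 0.5)
regularises the last two decoder levels; the head is a 1×1 conv + sigmoid.

The published description of this backbone fixes its topology but not the
attention gates' inner widths or the SE bottleneck widths.  Those widths
are therefore **calibrated once against the published trainable-parameter
budget of 2.7884 M**: inner attention widths 256/128/34 at skip widths
128/64/32, SE bottlenecks 64/32/16/9 at skip widths 128/64/32/16, giving
2 788 392 trainable parameters exactly.  For non-reference widths the
nominal rules (inner = 2×skip, bottleneck = skip/2) apply.  The parameter
count is treated as an architectural identity, not a fitted quantity; no
other property of the network was tuned against it.

### A discrepancy in the published MDC increment

With the structure described above, the four MDC modules add
`Σ_C (21C² + 81C + 9)` = 476 436 ≈ **0.4764 M** trainable parameters over
widths C ∈ {16, 32, 64, 128} (9C²+9C for the shared dilated kernel and its
four BNs, three F units of 4C²+24C+3 each).  The originally reported
increment is 0.5519 M.  That number decomposes *exactly* as
`Σ_C (25C² + 33C)` = 551 920 — consistent only with **four** fusion units
per module each containing just the two 1×1 2C→C convolutions, i.e. with
the softmax/sigmoid attention convolutions absent from the count, which
contradicts the fusion unit's own published description.  We implement the
described structure and report the count it actually has; consequently the
full-network total here is 3 384 196 ≈ **3.3842 M** rather than the
published 3.4596 M.  The S-conv (0.0002 M) and MFF (0.1191 M) increments
and the baseline budget (2.7884 M) are reproduced exactly.

## Objective and metrics

Training minimises the Soft Dice loss with ε = 10⁻⁵:

    Dice(x, y) = (2 Σ xᵢyᵢ + ε) / (Σ xᵢ + Σ yᵢ + ε),   L = −ln Dice,

averaged per image over each batch.  The ε guard makes the empty–empty
case exact (Dice = 1, loss = 0) and the loss differentiable everywhere;
raising a prediction on a true-foreground pixel can never increase it.

Evaluation binarises predictions at 0.5 and reports per image:
Dice `2|A∩B|/(|A|+|B|)`, IoU `|A∩B|/|A∪B|` (algebraically
`Dice/(2−Dice)`), Precision `TP/(TP+FP)`, and ASSD — boundary point sets
are foreground pixels with a background 4-neighbour (the image border
counts as background), and the metric is the symmetrised sum of Euclidean
point-to-set distances divided by the total number of boundary points, in
pixels at evaluation resolution.  Point-to-set distances come from a
Euclidean distance transform and are verified against an all-pairs
brute-force oracle in the tests.  Conventions for degenerate masks:
both-empty gives Dice = IoU = Precision = 1; an empty prediction against a
nonempty truth gives Precision 0 and ASSD is skipped and flagged (the
aggregate covers the remaining images).  Aggregation is mean ± std over
images, never pooled over pixels.

## Data pipeline

`load_isic_folder` reads the ISIC-2018 Task-1 layout (`ISIC_<id>.jpg`,
`ISIC_<id>_segmentation.png`), binarising masks at 128/255.
`split_dataset` shuffles under a seed and cuts at `ceil(n·cumulative
ratio)`; at 7:1:2 this reproduces the canonical 2594 → (1816, 260, 518)
division and is an exact partition for every n.  Training preprocessing:
resize to 256×342 (bilinear image, nearest mask), random 224×300 crop,
random horizontal/vertical flips, random rotation uniform in (−30°, +30°)
(edge-reflection fill for images, zero fill for masks) — one transform
applied identically to image and mask, so masks stay strictly binary.
Evaluation preprocessing is the deterministic resize + centre crop.
Flips and rotation are independently toggleable because the published
augmentation phrasing ("rotated in the horizontal or vertical direction")
admits both readings; both default on.

## The synthetic generator

Each sample is a warm skin-tone background with smooth low-frequency
texture and mild pixel noise, plus one lesion: an ellipse whose radius is
perturbed by a random low-order sinusoidal series in the polar angle
(`irregularity` sets the amplitude), darkened by `contrast`, with painted
edges blurred by a Gaussian of `boundary_blur_sigma` pixels.  The mask is
the *unblurred* support, so large sigmas emulate blurred boundaries and
`contrast=0` produces the adversarial case of an invisible lesion with a
nonempty mask.  Areas are rejection-sampled into
`lesion_area_fraction_range` (default 3–35% of the image, spanning the
small- and large-lesion regimes).  Everything is deterministic under the
seed.  The generator does **not** emulate hair, rulers, colour-calibration
stickers, vignetting, multiple lesions or real dermoscopic texture;
passing tests show the pipeline learns and measures correctly on separable
imagery, not that it reaches any particular accuracy on clinical data.

## Training protocol

Adam (β = 0.9/0.999, ε = 10⁻⁸) with initial learning rate 10⁻⁴, classic-L2
weight decay 10⁻⁸, batch size 16 (last partial batch kept), 300 epochs,
and a single halving of the learning rate after epoch 256 (the published
"decrease by 0.5 after 256" read as one late step — a per-iteration decay
would extinguish the rate).  Validation Dice is computed after every epoch
and the best-validation checkpoint (weights as `.npz`, configuration as a
JSON sidecar) is retained; model selection uses Dice.  Training aborts
with a state dump if the loss goes non-finite.  Runs are fully seeded:
weight init, batch order, augmentation and dropout all derive from the
configured seeds, and evaluation-mode forwards are bitwise deterministic.

## Numerical choices

* All tensors are float32; convolutions are stride-1 sums of k² shifted
  BLAS matmuls (the input gradient is the full correlation with the
  flipped kernel, so no scatter-adds occur on the conv path).
* He-normal weight init, zero biases; BN momentum 0.1, eps 10⁻⁵, biased
  batch variance for normalisation and an unbiased update for the running
  estimate.
* Bilinear resampling uses the half-pixel-centre convention with clamped
  edges; max-pooling floors odd sizes and the decoder upsamples to each
  skip's exact recorded size, so any input geometry round-trips without
  padding (224×300 → 112×150 → 56×75 → 28×37 → 14×18).
* Softmax is computed with max-subtraction; sigmoid exponentiates only
  non-positive arguments.
* Every backward formula is validated against central-difference oracles
  with symmetry-breaking weighted losses.

## Problem sizes used by the test suite

The engine runs on one CPU core, so the suite exercises full 224×300
geometry only where the contract demands it (single forward passes).  The
learning smoke test trains the full three-module network at reduced scale:
8 training + 2 validation synthetic images at 96×128, encoder widths
8/16/32/64/128, dilation rates (1, 2, 4) (rate 10's 21×21 field does not
fit the 12×16 stage-4 map at this size), Adam 2×10⁻³, batch 4, 30 epochs —
reaching training Dice ≈ 0.95 in about a minute, with the 5-epoch moving
average of the loss decreasing throughout (asserted at a 3-epoch lag to
look past single-batch dropout noise).

## Known limitations

* The NumPy engine is single-threaded-BLAS CPU code: full-resolution
  training is possible but orders of magnitude slower than a GPU
  framework; the protocol defaults (300 epochs, batch 16, 224×300) are
  faithful but impractical to run to completion on one core.
* Only stride-1 convolutions are provided; downsampling is max-pooling and
  upsampling bilinear, matching the architecture but excluding
  transposed-conv variants.
* The backbone is a reconstruction: its topology follows the published
  comprehensive-attention design and its free widths are fixed by the
  published parameter budget, but it is not weight-compatible with any
  original implementation.
* Binary (single-lesion) segmentation only; no colour constancy or
  hair-removal preprocessing.
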