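# Methods

## Model

The segmenter maps a clip $x \in \mathbb{R}^{B \times F \times 3 \times H
\times W}$ to per-frame mask logits of the same spatial size. Three parts:

**Pruned ConvNeXt-Tiny encoder.** The standard four-stage ConvNeXt-Tiny
feature extractor, with the fourth stage (the $384\to768$ downsample and
its three blocks) and all classification layers removed. Concretely:
patch embedding ($4\times4$ conv, stride 4, $3\to96$, followed by channel
layer norm), stage 1 (3 blocks @ 96), downsample (layer norm +
$2\times2$-stride-2 conv, $96\to192$), stage 2 (3 blocks @ 192),
downsample $192\to384$, stage 3 (9 blocks @ 384). A block is: depthwise
$7\times7$ conv (padding 3), layer norm over channels, $1\times1$ conv
$C\to4C$, GELU, $1\times1$ conv $4C\to C$, multiplication by a learnable
per-channel scale (initialized to $10^{-6}$, the ConvNeXt convention),
plus the residual. Skip connections are taken from the stage outputs
(post-blocks, pre-downsample) at $/4$ and $/8$; the $/16$ stage-3 output
is the bottleneck. Frames never interact here: the batch and frame axes
are flattened to $B\cdot F$ before the encoder and decoder.

**Bidirectional ConvLSTM bottleneck.** The only temporal module. One
ConvLSTM cell (input 384, hidden 192, $3\times3$ kernels, padding 1, all
four gates from a single convolution over the concatenated input and
hidden state, biases included, no peephole connections) scans frames
$1\to F$; a second, independently parameterized cell scans $F\to1$.
Hidden and cell states start at zero. The per-frame output concatenates
the forward and backward hidden states (forward half first), restoring
384 channels. Note that with independent direction cells, reversing the
input frames is *not* equivalent to swapping the output halves — that
symmetry holds exactly only when the two cells share weights, which is
how the scan logic is verified in the tests.

**UNet-style decoder.** On the flattened batch:
`Up(384→192)` → concat $/8$ skip → `DoubleConv(384→192)` →
`Up(192→96)` → concat $/4$ skip → `DoubleConv(192→96)` →
`Up(96→48)` → `Up(48→24)` → $1\times1$ conv $24\to1$. `Up` is a
$2\times2$ transposed convolution with stride 2; `DoubleConv` is two
$3\times3$ conv + batch norm + ReLU layers, the first halving channels.
The tail ($96\to48\to24$) has no skip inputs and no DoubleConv: the
channel progression between the $/4$ skip merge and the stated final
$24\to1$ layer is not uniquely determined by the architecture
description, and this progression is the simple one whose parameter sum
(1.64 M) makes the three component budgets (12.35 M encoder + 7.96 M
fusion + decoder) add up to the published 21.95 M total.

**Parameter accounting.** Counting every trainable scalar (convolution
weights and biases, normalization affine pairs, layer scales):
encoder 12,348,000; unpruned four-stage extractor 27,818,592 (this
equals the torchvision ConvNeXt-Tiny feature extractor exactly); fusion
7,964,160; decoder 1,637,953; total 21,950,113. Rounded half-up to two
decimals these give 12.35 M, 27.82 M and 21.95 M. Whether the published
figures include every normalization affine parameter cannot be resolved
beyond rounding agreement; the fully inclusive count is used.

## Numerical core

The network runs on a small reverse-mode autodiff engine over numpy
(`polypnextlstm.nn`): a taped `Tensor`, grouped/strided 2-D
convolution (im2col + BLAS matmul; depthwise stride-1 convolutions use
shift-and-add over kernel taps; strided convolutions require
stride = kernel, which covers patchify and downsampling), stride-matched
transposed convolution, channel layer norm, batch norm (biased batch
variance in the graph, unbiased running estimates), GELU (exact, via
erf), sigmoid/tanh/ReLU, and Adam with bias correction. Parameters are
float32; every operation is verified against central-difference
gradients in the test suite at ~1e-6 relative tolerance. All
initialization (truncated normal, std 0.02, for encoder weights —
the ConvNeXt convention — He-normal elsewhere; zero biases) is drawn
from a single seeded generator walked in registration order, so model
construction, training and inference are bit-reproducible under a seed
on a given platform.

## Objective and metrics

Loss: `dice_loss + bce_loss`, equally weighted. The Dice term is
computed per frame over the flattened batch·frame axis and averaged,
with smoothing constant $s = 1$:
$1 - (2\sum pt + s)/(\sum p + \sum t + s)$; $s$ cancels for an exact
binary prediction, so perfect predictions score 0. BCE is the mean
pixelwise cross-entropy with probabilities clipped at $10^{-7}$.

Evaluation metrics on masks binarized at 0.5: Dice $2|P\cap G|/(|P|+|G|)$
and IoU $|P\cap G|/|P\cup G|$ (both-empty pairs score 1), recall
$TP/(TP+FN)$ (empty ground truth scores 1), and HD95 — the maximum over
both directions of the 95th percentile (linear interpolation) of
boundary-to-boundary nearest-neighbour Euclidean distances, in pixels at
evaluation resolution. Boundary pixels are foreground pixels with a
4-neighbour in background or on the image edge. If exactly one mask is
empty, HD95 returns the image diagonal as a finite sentinel. Clip-level
scores are means of per-frame scores; the test-set aggregate is the
unweighted mean over clips; attribute-stratified Dice averages clip
scores over all clips carrying each attribute.

## Data pipeline

Clips are directories of frame images with 1:1 mask images plus a CSV of
clip-level attribute labels (semicolon-separated). Where a training set
contains several clips of the same polyp case, only the
lexicographically first clip per case is kept. Clips are chunked into
non-overlapping windows of $F$ consecutive frames (default $F=5$); when
$F$ does not divide the clip length, a final window anchored at the clip
end is added so every frame is covered (the published protocol does not
state the chunking rule; strides are configurable). Frames are resized
bilinearly, masks nearest-neighbour then thresholded; intensities are
scaled to $[0,1]$ by default, or standardized with the ImageNet channel
statistics when a pretrained backbone is used. One augmentation draw per
window — rotation within ±20°, horizontal/vertical flips, centre crop
at scale 0.8–1.0 resized back — is applied identically to all $F$ frames
(bilinear) and masks (nearest). The magnitudes are not part of the
published recipe; they are package defaults and configurable.
Cross-validation folds partition at clip level, deterministically under
the seed. Pretrained backbone weights are supported only via explicit
checkpoint loading; default initialization is random so nothing needs
downloading.

## Synthetic clips

The generator renders a brighter soft-edged ellipse (the "polyp") over
smoothed pink-noise texture (the "mucosa"), with per-frame centre,
semi-axes and orientation; masks are the exact ellipse interiors,
clipped at the canvas. Optional artifacts: an occlusion band that zeroes
an image/mask stripe, and a colour fringe shifted off the blob boundary
(ghosting). Attribute labels FM/SO/LO/SV are computed from the mask
sequence by the numeric rules (thresholds 20 px, 0.05, 0.15, 0.5;
empty frames excluded from the means); the "scale variation" rule reads
"ratio among any pair" as the minimum over frame pairs. OCC/GH/OV are
tagged from the generator's construction flags rather than detected from
pixels; SI/IB/HO (surgical instruments, indefinable boundaries,
heterogeneous object) are qualitative appearance phenomena the generator
does not emulate.

What passing tests on these clips do and do not show: they verify the
geometry, bookkeeping and optimization machinery end to end (the blob is
learnable, the labels obey the rules, the metrics agree with oracles);
they say nothing about segmentation quality on real colonoscopy, which
has specularities, instrument clutter, fluid, texture-camouflaged flat
polyps and camera artifacts far beyond this model of a bright ellipse.

## Problem sizes and runtime choices

The published training protocol (100 epochs of 5-fold cross-validation
at 256×256 on ~10k frames) is a GPU-scale undertaking and is not re-run
here; the package's own verification uses desk-scale sizes chosen to
exercise every code path on one CPU core: property checks at 256×256
forward passes, training runs at 32–64 px canvases (any size divisible
by 16 is valid), and the learning smoke test — overfitting one 5-frame
32×32 synthetic clip to Dice ≥ 0.95 with Adam at $10^{-4}$ — which
converges in roughly 90–120 steps. Checkpoints store all weights,
buffers and the model configuration in one `.npz` archive.

## Known limitations

* CPU-only numpy execution: throughput claims of the original system
  (FPS on GPU hardware) are out of scope and not measured.
* Evaluation uses a single fold's best-validation-Dice checkpoint; no
  ensembling across folds.
* The convolution backward supports exactly the stride patterns the
  architecture uses (stride 1, or stride = kernel); it is not a general
  conv library.
* No learning-rate schedule (only the initial rate is published);
  constant learning rate throughout.
* Bit-reproducibility holds per platform/BLAS build, matching the usual
  deterministic-execution caveats of deep learning frameworks.
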