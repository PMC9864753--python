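# Methods

## Problem and model

The package segments the left-ventricle (LV) cavity in 2-D grayscale
echocardiography-like images. The model is a proposal-free, single-stage
convolutional network: a residual backbone feeds a feature pyramid whose
levels are fused into two streams — a high-resolution *low-level* stream
(stride 4, detail) and a coarse *high-level* stream (stride 32, context)
— refined in parallel by spatial and channel attention and merged by an
integration unit into a dense foreground-probability map. The design
assumes a single connected foreground class with a roughly elliptical
shape surrounded by brighter myocardium; no shape prior is encoded, the
network must learn the appearance.

## Architecture choices

- **Backbone.** Two profiles share one implementation: `resnet50`
  (bottleneck stages 3-4-6-3, widths 256/512/1024/2048 at `base_width`
  64) and `tiny` (one basic block per stage, widths w/2w/4w/8w). The
  stride-4 stage starts with a stride-2 convolution in its first block
  rather than a 3×3 max-pool; stride arithmetic and widths are unchanged
  and the engine needs one less primitive. C1 is computed but, as usual
  for pyramids, laterals start at C2.
- **Pyramid.** Lateral 1×1 projections to `pyramid_width` channels
  (default 256; 32 in the desk profile), nearest ×2 top-down upsampling
  with element-wise addition, 3×3 smoothing per merged level. P6 is a
  stride-2 3×3 convolution of the projected C5, P7 of P6.
- **Stream merging.** "Merged" is implemented as upsample-to-finest +
  element-wise sum, which preserves the channel count so the attention
  units see a uniform width; concatenation is available via
  `merge_mode="concat"` for the standalone function. The high-level
  stream is taken at stride 32 (P5's grid), the finest grid the three
  coarse levels share.
- **SFU.** Channel-axis mean and max pooling, 2-channel concatenation, a
  k×k convolution (k = 7, the standard kernel for this spatial-attention
  form; configurable), batch normalization, sigmoid, multiplication into
  the input. Batch norm uses batch statistics during training and running
  averages (momentum 0.1) at inference.
- **CFU.** Spatial mean and max pooling, one shared MLP C → C/r → C with
  ReLU hidden activation (r = 16 full-scale, 4 desk so the hidden layer
  is non-trivial at width 32), element-wise sum, sigmoid, per-channel
  multiplication. A non-shared variant (`shared=False`) exists.
- **FIU.** `F_H = σ(1×1 conv(GAP(C')))` — a per-channel gate, since it
  starts from global average pooling. The low-level branch is
  `F_L = 1×1 conv(BN(S'))`, computed from the spatial-attention output
  (the unit's purpose is to adjust and normalize the *low-level* scale).
  Output: `O_s = up₈(C') + F_H ⊙ F_L` at stride 4. No extra convolution
  is applied between the sum and the prediction head.
- **Head.** 1×1 convolution to one channel, sigmoid, bilinear ×4
  upsampling (half-pixel-centre convention), crop of any padding,
  threshold at 0.5 with the `≥` rule (ties are foreground — fixed so
  tests are bit-exact).
- **Padding.** Inputs are symmetrically zero-padded to the next multiple
  of 128 (P7's stride) and predictions cropped back; training pads the
  same way, with padded mask pixels counted as background.

## Numerical engine

No tensor/autodiff framework ships with the package's environment
dependencies, so `lvseg.nn` provides a small reverse-mode autodiff on
float64 numpy arrays: im2col convolutions, batch norm composed from
primitive ops, mean/max reductions (max splits gradients equally among
ties), nearest and bilinear upsampling, and SGD with classical momentum
(`v ← μv + g + λw`, `w ← w − ηv`). Every operation's gradient is checked
against central differences in the test suite, as is the assembled
network end-to-end. Weight init is He-normal; biases start at zero.

## Training

Full-scale defaults: SGD momentum 0.9, learning rate 1e-4, weight decay
0.001, 50 epochs, batch 32, reshuffle each epoch, 512-px inputs. The
recipe quotes both a "weight decay" of 0.001 and an "L2 regularization"
of 1e-4; these are the same mechanism in SGD, so a single optimizer decay
of 0.001 is applied (the alternative value can be set in the config).
The loss is soft dice with `smooth = 1.0` during training (guards 0/0 on
empty masks; exactness tests use `smooth = 0`). Model selection keeps the
epoch with the highest validation DSC (lowest training loss if no
validation set). All randomness — weight init, shuffling, phantom
geometry — derives from explicit seeds, so CPU runs are bit-reproducible.

The desk profile (tiny backbone, width 16, pyramid 32, 128-px images,
batch 4, learning rate 0.05, weight decay 1e-4) exists so that training
converges in a few hundred steps on one CPU; the full-scale learning rate
of 1e-4 is sized for a much larger network, batch and corpus and barely
moves the small model in 200 steps. Both profiles run the same code.

## Synthetic phantoms

The generator emulates the qualitative challenges of apical four-chamber
echocardiography — low contrast, brightness inhomogeneity, speckle — not
its physics. Each sample is: a dark sector field of view (apex up, default
75° opening) on a darker exterior; an elliptical cavity (semi-axes
10–20% of the image side, jittered centre/rotation) whose outline is
perturbed by 3–5 random radial harmonics of 1–6% amplitude so the shape
is not a fixed template; a brighter myocardial ring (thickness
2.5–5.5% of the side); multiplicative speckle (per-pixel Rayleigh with
unit mean, lightly blurred, scaled by `speckle_scale = 0.35`); and a
smooth multiplicative bias field of random Gaussian bumps scaled to
±`inhomogeneity_strength = 0.3`. Region intensities are fixed (exterior
0.05, tissue 0.35, ring 0.75, cavity 0.12) before the multiplicative
fields. Geometry is rejection-sampled (bounded, seed-deterministic) so
the cavity plus ring sits strictly inside the sector and off the image
border, mirroring the clinical practice of cropping irrelevant
background, and so the foreground fraction stays in [0.01, 0.30].

What passing tests on phantoms do show: the architecture, loss, optimizer
and evaluation pipeline are implemented correctly and can learn a
non-trivial boundary from image evidence at small scale. What they do not
show: performance on real echocardiograms, whose speckle statistics,
anatomy (four chambers, valves, papillary muscles) and operator
variability the phantom does not model.

## Evaluation

Per image: confusion counts of predicted vs. ground-truth masks, then
DSC, IoU, accuracy, recall, precision, specificity. 0/0 conventions are
fixed for reproducibility: a ratio with zero denominator scores 1.0 when
the corresponding target class is also empty (perfect agreement on an
absent class), else 0.0. Aggregates are the mean and the sample (n−1)
standard deviation, plus five-number boxplot summaries (min, Q1, median,
Q3, max) with the 1.5×IQR outlier rule. DSC = 2·IoU/(1+IoU) holds
identically and is asserted in tests.

## Split arithmetic

70/15/15 train/test/validation by seeded shuffle. Test and validation
sizes are the fractions rounded to the nearest integer with ties rounded
down; every remaining id goes to train (6,000 → 4,200/900/900;
10 → 8/1/1). The split file is a plain-text three-section list.

## Problem sizes used in checks

The self-contained pipeline runs (tests and `scripts/acceptance.py`) use
the desk profile: 16 training and 8 held-out 128-px phantoms, batch 4,
at most 200 optimizer steps — a size at which the overfitting-style
learnability check (training DSC ≥ 0.90, held-out DSC ≥ 0.80) completes
in about a minute while exercising every module at full fidelity.
Full-scale rehearsal (6,000 phantoms at 512 px, `--preset paper`) uses
the same code paths.

## Known limitations

- The phantom is 2-D and static; no cine sequences, no other chambers.
- No augmentation, learning-rate schedule or early stopping beyond
  best-validation selection.
- Instance post-processing (connected components, contour smoothing) is
  deliberately absent; the output is the thresholded probability map.
- The numpy engine is single-threaded apart from BLAS matmuls; it is
  sized for desk-scale work, not GPU-scale training.
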