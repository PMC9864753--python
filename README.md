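# lvseg — bilateral lightweight left-ventricle segmentation

Delineating the left-ventricle (LV) cavity in 2-D echocardiography is the
first step toward quantitative cardiac measures such as area, volume and
ejection fraction, and is still often done semi-automatically in the
clinic. `lvseg` implements a single-stage, lightweight convolutional
segmentation network for this task, together with everything needed to
train and evaluate it end-to-end on a CPU: a synthetic echocardiography
phantom generator (real clinical corpora are private), dataset I/O and
splitting, dice-loss training, and a six-metric evaluation suite.

## The model

A residual backbone produces multi-scale activations C1–C5 (strides
2–32). A feature pyramid network (FPN) with lateral 1×1 projections and a
nearest-neighbour top-down pathway turns C2–C5 into uniform-channel levels
P2–P5; stride-2 convolutions add P6 and P7 (strides 64, 128). P2–P5 are
merged (upsample + element-wise sum) into a *low-level* stream at stride 4
and P5–P7 into a *high-level* stream at stride 32. Two attention units
refine the streams in parallel:

- **Spatial feature unit (SFU)** — channel-axis mean/max pooling,
  concatenation, a 7×7 convolution, batch norm and a sigmoid give a
  per-position gate `S_I ∈ (0,1)`; the refined stream is `S' = S · S_I`.
- **Channel feature unit (CFU)** — spatial mean/max pooling, a shared
  one-hidden-layer MLP (C → C/r → C), element-wise sum and a sigmoid give
  a per-channel gate `C_I`; the refined stream is `C' = C · C_I`.

A **feature integration unit (FIU)** merges the two: a per-channel
indicator `F_H = σ(conv(GAP(C')))` gates the normalized low-level
projection `F_L = conv(BN(S'))`, and the integrated map is
`O_s = up(C') + F_H ⊙ F_L`. A 1×1 head, sigmoid and bilinear ×4
upsampling give a full-resolution probability map, thresholded at 0.5
(`≥` rule). Training minimizes the soft dice loss

    L = 1 − (2 Σ g·s + ε) / (Σ g + Σ s + ε)

with SGD (momentum 0.9, weight decay), reshuffling every epoch and
keeping the best-validation-DSC model. Evaluation reports DSC, IoU,
accuracy, recall, precision and specificity per image, with mean ± SD and
boxplot five-number summaries.

The network runs on a small numpy reverse-mode autodiff engine included
in the package (`lvseg.nn`) — no GPU framework is required; gradients are
verified against numerical differentiation in the test suite.

## Worked example

Train the desk-scale profile (small backbone, 128-px phantoms) on 16
synthetic phantoms and evaluate on 8 held-out ones:

```python
from dataclasses import replace
from lvseg import LVSegmentationModel, PhantomConfig, generate_phantom
from lvseg.training import desk_config

base = PhantomConfig(image_size=128, seed=123)
train_s = [generate_phantom(replace(base, seed=1000 + i)) for i in range(16)]
hold_s  = [generate_phantom(replace(base, seed=2000 + i)) for i in range(8)]

model = LVSegmentationModel(train_s, arch="desk", seed=0)
fit = model.fit(desk_config(seed=0), max_steps=200)
print(fit.summary(fit.evaluate(hold_s)))
```

which prints (about two minutes on one CPU):

```
Left-ventricle segmentation fit
==================================
optimizer steps      200
epochs completed     50
final train loss     0.0817
best epoch           47

evaluation (mean +/- SD over images)
  dsc         0.9417 +/- 0.0233
  iou         0.8907 +/- 0.0409
  accuracy    0.9912 +/- 0.0024
  recall      0.9261 +/- 0.0399
  precision   0.9605 +/- 0.0456
  specificity 0.9970 +/- 0.0028
```

After 200 optimizer steps the network segments unseen phantoms with a
mean dice overlap of 0.94: the predicted cavity masks agree with the
ground truth on ~94% of their combined area, with the remaining errors
concentrated at the perturbed cavity boundary (recall a little below
precision means the network slightly under-segments).

The same pipeline is available from the shell:

```bash
lvseg generate --n 100 --size 512 --seed 7 --out data/
lvseg train    --data data/ --preset desk --out run/ --seed 7
lvseg segment  --checkpoint run/checkpoint.npz --image data/img_00000.png --out seg/
lvseg evaluate --checkpoint run/checkpoint.npz --data data/ --split run/split.txt --out eval/
```

The full-scale profile (`--preset paper`: ResNet-50-like backbone,
256-channel pyramid, 512-px images, batch 32, learning rate 1e-4, 50
epochs) is configured identically but is sized for GPU-scale corpora.

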