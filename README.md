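# mgmtnet

End-to-end deep-learning pipeline for glioblastoma MR slices: automatic
whole-tumor segmentation followed by MGMT promoter-methylation status
classification, with all the supporting machinery — methylation-array
label derivation, case-level splitting, MR intensity standardization,
rotation augmentation, cross-validated training and confusion-matrix /
ROC reporting — as tested, reusable components.

**Who it is for.** MGMT promoter methylation predicts response to
temozolomide in glioblastoma, but assessing it requires tissue. This
package implements a radiogenomic alternative: predict the status from
routine MR images (CE-T1WI or FLAIR), with tumor delineation done
automatically rather than by manual annotation. A built-in phantom
generator provides brain-like synthetic slices with the statistical
structure the pipeline assumes, so every stage runs and is verifiable
without any clinical data.

## The model

**Segmentation.** A 2D encoder-decoder fully convolutional network with a
variational-autoencoder branch regularizing the shared encoder. ResNet
blocks (two 3×3 convolutions with GroupNorm/ReLU and an additive skip) at
every level; stride-2 convolutions halve resolution and double channels on
the way down, nearest-neighbour upsampling with additive encoder skips on
the way up, sigmoid head at input resolution. The VAE branch compresses
the encoder endpoint to a 256-dimensional diagonal Gaussian (prior
N(0, 1)) and reconstructs the input without skip connections. Trained
with

&nbsp;&nbsp;&nbsp;&nbsp;*L* = *L*<sub>Dice</sub> + 0.1 · *L*<sub>L2</sub> + 0.1 · *L*<sub>KL</sub>,&nbsp;&nbsp;
Dice = 2Σ*p·p̂* / (Σ*p*² + Σ*p̂*² + ε),&nbsp; ε = 1e−8,

Adam at 1e−4 halved after 5 epochs without validation-loss improvement,
batch 8.

**Classification.** A deliberately shallow CNN — conv 3×3 ×16 →
LeakyReLU(0.3) → BatchNorm → maxpool 4×4, conv 3×3 ×4 → LeakyReLU →
BatchNorm → maxpool 4×4, FC(4, ReLU) → FC(2, softmax), He-normal
initialized; exactly **3,498 trainable parameters** at the 208×208
reference geometry. It is cascaded on the segmenter: its input is the
normalized slice masked by the predicted tumor, cropped to the tumor
bounding box and resampled. Adam at 2e−4, batch 32, early-stopped when
validation accuracy is stable for 10 epochs.

**Preprocessing.** MR scans have no standard intensity scale, so scans are
standardized by piece-wise linear histogram matching (foreground
percentile landmarks, default {1, 99}, averaged over the training set)
followed by zero-mean/unit-sd normalization on valued pixels only, and
augmented by rotations every 5° from −20° to +20° (9 orientations per
slice). Labels come from a cohort-median cutoff on mean probe
beta-values; splits are by case (8 : 2 by default) with 10-fold
cross-validation reported as mean ± standard deviation over folds.

The networks run on `mgmtnet.nn`, a compact reverse-mode autodiff engine
over numpy written for this package (conv/pool/norm layers, Adam);
every primitive is verified against central differences in the test
suite, and runs are bit-reproducible from explicit seeds.

## Worked example

Train the full cascade on a synthetic cohort (40 cases × 3 slices at
96×96, a scaled-down segmenter with 8 base channels) and score the
held-out cases:

```python
from mgmtnet import (ClsConfig, ClsTrainConfig, SegConfig, SegTrainConfig,
                     PhantomConfig, run_experiment, split_cases,
                     CaseRecord, DatasetManifest)
from mgmtnet.pipeline import SliceDataset
from mgmtnet.synthetic_data import generate_case_arrays

cfg = PhantomConfig(n_cases=40, slices_per_case=3, seed=0)
images, masks, labels, case_ids = generate_case_arrays(cfg)
dataset = SliceDataset(images, masks, labels, case_ids)

uniq = sorted(set(case_ids))
manifest = DatasetManifest(
    cases=[CaseRecord(c, cfg.modality, [f"{c}_s"], [f"{c}_m"],
                      labels[case_ids.index(c)]) for c in uniq],
    modality=cfg.modality)
split = split_cases(manifest, 0.2, seed=0)
train = sorted(split.train_ids)
val, train = train[:len(train) // 5], train[len(train) // 5:]

result = run_experiment(
    dataset, train, val, sorted(split.test_ids),
    SegConfig(input_height=96, input_width=96, base_channels=8, depth=3,
              latent_dim=32, vae_reduce_channels=8),
    SegTrainConfig(lr0=1e-3, max_epochs=15, seed=0),
    ClsConfig(input_height=96, input_width=96),
    ClsTrainConfig(seed=0))
print(result.summary())
```

Output:

```
== segmentation ==
model: SegmentationNet
epochs run: 15
seed: 0
final train loss: 0.2180
final val loss: 0.2553
final lr: 1.00e-03
test Dice: 0.893
== classification ==
model: MethylationCNN
epochs run: 27
seed: 0
final train loss: 0.1991
final val loss: 0.4308
final val accuracy: 0.8333
final lr: 2.00e-04
test accuracy: 0.875
test recall: 1.000
test precision: 0.800
test f1: 0.889
test AUC: 1.000
```

Reading the numbers: the segmenter recovers the tumor on unseen cases
with a mean Dice of 0.893 (overlap between predicted and true masks); the
cascaded classifier recovers the methylation-linked necrosis signal on
held-out slices with 0.875 accuracy (recall is the fraction of truly
methylated slices called methylated; AUC is threshold-free ranking
quality). The learning-rate line reflects the plateau scheduler (no
halving fired here); the classifier stopped at epoch 27 under the
accuracy-stability rule.

The same pipeline is scriptable from the shell:

```bash
mgmtnet simulate -c config.yaml -o data/
mgmtnet split --manifest data/manifest.csv --k 10 -o split.json
mgmtnet crossval -c config.yaml --manifest data/manifest.csv \
        --split split.json -o cv/        # Table-style mean ± std CSV
mgmtnet predict --image data/case_000_slice0.png \
        --scale run/standard_scale.json --seg run/seg.npz \
        --cls run/cls.npz -o pred/       # mask PNG + JSON verdict
```

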