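# camgrade

Unsupervised maturity grading and identification of oil-tea (*Camellia
oleifera*) fruit from RGB images.

Oil-tea fruit has no visual maturity grading standard: harvest windows are
traditionally set by calendar rules, while the ground truth (seed oil
content) requires destructive laboratory assays.  `camgrade` implements a
deep-clustering approach to this problem: a convolutional network and a
K-Means grouping of its features are learned jointly, without any labels,
so that the clusters themselves become the maturity stages (unripe, ripe,
overripe).  Around that core the package provides the conjoint statistics
used to validate image-derived stages against physical and quality
measurements, the standard identification metrics, Grad-CAM heatmaps, and
a synthetic fruit-image/property generator so the whole pipeline can be
exercised and tested without access to orchard data.

## The method

Each image `x_i` is mapped to a feature vector by a randomly initialised
VGG-style convnet `f_θ` (the activations of the penultimate fully
connected layer).  After PCA reduction and L2 normalisation, K-Means
finds the centroid matrix `C` (d × k) and one-hot assignments `y_i`
minimising

    min_C  (1/N) Σ_i  min_{y_i}  ‖ f_θ(x_i) − C y_i ‖²

The assignments are then used as *pseudo-labels* to update the network: a
linear classifier head `g_W` on the shared features is trained by
mini-batch SGD with momentum on the negative log-softmax loss

    min_{θ,W}  (1/N) Σ_i  ℓ( g_W(f_θ(x_i)), y_i )

and the two steps alternate (re-cluster, re-train) until the assignments
stabilise.  Identification of new fruit is the argmax of the trained
head's logits.  Stages are named (unripe/ripe/overripe) from anchor
labels via Hungarian matching or from a scalar maturity proxy such as
crack area.  Per-stage evaluation uses one-vs-rest precision, recall and
F1 plus overall accuracy from a true-by-predicted confusion matrix, and
the conjoint analysis runs a one-way ANOVA with Duncan's multiple range
test (p ≤ 0.05) on each physical/quality property across the graded
stages.

The convnet (tiny 3-block backbone or the full VGG16-D layout with the
last fully connected layer removed), its SGD training, and Grad-CAM are
implemented in NumPy with explicit forward/backward passes.

## Worked example

```python
import numpy as np
import camgrade as cg

# 150 synthetic fruit images (50 per stage) with well-separated phenotypes
images = cg.generate_dataset(50, size=64, rng_seed=7, separation=1.5)

model = cg.DeepClusterModel(images, k=3,
                            train_config=cg.TrainConfig(epochs=20, rng_seed=3))
results = model.fit()
print(results.summary())
```

prints (about one minute on a laptop CPU):

```
Deep clustering maturity grading
========================================
images:               150
clusters (k):         3
backbone:             tiny (512-d features)
epochs:               20 (reassign every 1)
learning rate:        0.1
momentum:             0.9
final loss:           0.8098
final objective:      0.025350
cluster sizes:        50, 50, 50
empty-cluster repairs: 0
last assignment NMI:  1.0000
```

The three clusters of 50 exactly recover the three planted stages
(normalized mutual information vs. truth 1.0 on this run).  Naming the
clusters and scoring identification:

```python
naming = cg.map_clusters_to_stages(
    results.assignments,
    anchor_stages=[img.truth_stage for img in images])
predicted = naming.apply(results.identify(images))
cm = cg.build_confusion([img.truth_stage for img in images], predicted)
print(cg.compute_metrics(cm).summary())
```

```
Maturity      Prec (%)   Rec (%)    F1 (%)     OAcc (%)
unripe        100.00     100.00     100.00     100.00
ripe          100.00     100.00     100.00
overripe      100.00     100.00     100.00
```

Conjoint analysis of a matching property table (triplicate-determination
design, `n_effective=3`):

```python
records = cg.generate_property_table(30, rng_seed=0)
print(cg.conjoint_report(records, n_effective=3).summary())
```

```
Property                          unripe              ripe          overripe
----------------------------------------------------------------------------
transverse_diameter_mm    46.27 ± 1.32 b     47.40 ± 1.31 ab    49.21 ± 1.46 a
vertical_diameter_mm      39.06 ± 1.20 a     40.20 ± 1.71 a     40.43 ± 1.61 a
dry_seed_weight_g          7.95 ± 0.44 c     12.38 ± 0.84 a     10.99 ± 0.27 b
moisture_pct              70.09 ± 4.46 a     59.17 ± 2.14 b     48.14 ± 0.66 c
oil_pct                   38.89 ± 0.95 c     45.99 ± 0.58 a     44.57 ± 0.49 b
soluble_protein_pct        5.19 ± 0.20 c      5.59 ± 0.16 b      6.11 ± 0.07 a
soluble_sugar_pct         25.46 ± 1.21 a     18.23 ± 5.07 b     13.88 ± 1.13 b
starch_pct                 3.37 ± 0.60 a      2.32 ± 0.28 b      1.44 ± 0.59 b
Different letters in a row differ at p <= 0.05 (Duncan's multiple range test).
```

Oil peaks at the ripe stage and the diameters do not separate cleanly,
while moisture, weights and the seed quality assays do — the pattern that
justifies harvesting at the ripe stage.

A command-line interface mirrors the library
(`camgrade simulate / train / grade / identify / evaluate / conjoint /
gradcam`); every run writes a manifest JSON with its configuration and
seed.

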