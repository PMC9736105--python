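# Methods

## Model

`camgrade` grades fruit maturity by deep clustering.  A convnet `f_θ`
maps each image to a feature vector; K-Means on the reduced, normalised
features yields assignments `y_i` and a d×k centroid matrix minimising
the mean squared distance `(1/N) Σ_i min_y ‖f_θ(x_i) − C y_i‖²`; the
assignments then serve as pseudo-labels for one (or more) epochs of
mini-batch SGD on the negative log-softmax loss of a linear classifier
head `g_W` over the shared features, and the two steps alternate.  The
assumptions are the ones deep clustering always makes: the convolutional
prior of a randomly initialised network already organises images by
colour and local texture well enough for K-Means to find meaningful
groups, and alternating clustering with supervised fitting on the
resulting pseudo-labels sharpens the features around that group
structure instead of collapsing it.  Collapse is held off by two
standard devices, both on by default: batches are sampled uniformly over
pseudo-labels, and empty clusters are repaired by splitting the largest
cluster.

The network, its training, and Grad-CAM are implemented in NumPy with
explicit forward/backward passes (im2col convolutions, 2×2 max pooling,
ReLU, fully connected layers; gradients verified against finite
differences in the test suite).

## Tunable parameters

| parameter | default | why |
|---|---|---|
| `k` (stages) | 3 | the biology: unripe / ripe / overripe |
| backbone `scale` | `tiny` (32/64/128-channel blocks, 512-d features) | CPU-scale runs; `full` is the VGG16-D layout without its last FC layer (4096-d) |
| `input_size` | 64 (tiny), 224 (full) | tiny images keep a full run under a minute on one CPU |
| preprocessing | scale to [0,1], standardise with fixed mean 0.5 / sd 0.25 | dataset-independent, hence reproducible |
| PCA components | min(256, N−1, D) | the customary reduction for deep-clustering features; whitening off by default |
| K-Means | k-means++, 5 restarts, tol 1e−4 relative, max 100 Lloyd iterations | robustness at negligible cost |
| `learning_rate` / `momentum` | 0.1 / 0.9 | the published training setting for this pipeline |
| `grad_clip` | 5.0 (global norm) | momentum SGD at rate 0.1 on an unnormalised float32 net diverges without it |
| `epochs` / `reassign_every` | 20 / 1 | training length is not pinned by the source method; 20 rounds suffice for assignment NMI to plateau on the synthetic data |
| Duncan `alpha` | 0.05 | the conventional significance level |
| Duncan `n_effective` | none (harmonic mean of group sizes) | see below |

A backbone width note: random-feature quality grows with width.  Narrow
tiny backbones (8–32 channels) cluster the synthetic stages inconsistently
across initialisation seeds; at 32/64/128 channels with 512-d features the
first-round clustering is reliable, which is why those are the tiny
defaults.

## Design choices where the design was open

* **PCA is refit at every reassignment round.**  The features move every
  epoch, so a stale basis would mix training rounds.
* **The classifier head is reinitialised after every reassignment** and
  its optimiser state reset: cluster ids are arbitrary per round, and
  stale label-to-logit bindings fight the new labels.
* **The reported grading is the final round's clustering** (the one the
  trained head was last fitted to), so head predictions and assignments
  share a label space.
* **Sign convention for PCA**: each component's largest-magnitude
  loading is made positive, making fits deterministic.
* **Ties in nearest-centroid assignment** break to the lowest centroid
  index; empty-cluster repairs are counted and reported.
* **Zero feature rows** (dead features can occur under random backbones)
  pass through L2 normalisation unchanged, with a warning count, rather
  than erroring — clustering still proceeds.
* **Sobel preprocessing is off by default** (exposed as a flag); the
  grading problem here is largely chromatic, and the source pipeline
  does not mention it.
* **Overall accuracy** is computed as diagonal sum over total count,
  which is exactly what the one-vs-rest (TP+TN)/(TP+FP+FN+TN) formula
  micro-averages to in a multiclass confusion matrix.  Metrics are kept
  at full precision and displayed half-up at 2 decimals.
* **Stage naming**: with anchor labels, Hungarian matching; with a
  scalar proxy, clusters are ranked by mean proxy.  Crack/seed area is
  monotone in maturity (unripe < ripe < overripe); seed oil content is
  not (low → high → mid), so the oil rule is applied explicitly and the
  naming flagged.

## Conjoint analysis

For each property a one-way ANOVA (between/within decomposition)
provides MSE and error df, then Duncan's multiple range test compares
descending-sorted stage means against least significant ranges
`R_p = q(1−α_p, p, df)·√(MSE/n_h)` with protection level
`α_p = 1−(1−α)^(p−1)`.  Studentized-range quantiles come from
`scipy.stats.studentized_range.ppf` (numerically accurate well beyond 4
significant figures; the test suite pins them against published Duncan
tables at df 10 and 20).  Homogeneity of a span protects all contained
spans (classical step-down), and compact letters are the maximal
homogeneous stretches.  `n_h` is the harmonic mean group size for
unequal groups.

Quality assays of this kind are typically reported as means of three
replicate determinations per stage rather than per-fruit measurements.
The `n_effective`/`df_effective` parameters of `duncan_mrt` and
`conjoint_report` analyse the data under that replicate design
(`n_effective=3` → df 6); this is the setting under which the reference
letter patterns — diameters not separating, the six other properties
splitting into 2–3 letters — are recovered.  With the per-fruit n
(30–60), differences of a millimetre exceed the ranges and the diameters
separate too.

## The synthetic generator

The generator emulates the visual phenotype a grader uses: an elliptical
fruit (jittered position/size) on a mottled foliage background; peel hue
drawn from a stage band; peel texture roughness; a dark crack wedge
through the fruit centre whose area is `crack_fraction` of the fruit
area; a bright exposed-seed strip inside the crack covering
`seed_exposure` of the fruit area (capped at 0.8 of the crack); additive
Gaussian pixel noise.  Unripe fruit are indehiscent (`crack_fraction` =
0) by construction.  A single `separation` knob scales the hue bands
about their common centre; at the default 1.0 adjacent stage bands
overlap slightly, as real adjacent maturities do, and at 1.5 the stages
are cleanly separated.

Property tables are drawn Normal(stage mean, stage SD) from a per-stage
reference table of the Huaxin cultivar (diameters, dry seed weight,
moisture, oil, soluble protein, soluble sugar, starch).  Moisture is
drawn first and fresh seed weight derived as `W_f = W_d/(1 − M_c/100)`,
so the moisture identity `M_c = 100(W_f−W_d)/W_f` holds exactly on every
record.

What the generator does **not** model: photorealistic peels, lighting
and camera effects, multi-fruit scenes, occlusion, or any correlation
between a fruit's image and its property record beyond the shared stage.
Passing tests therefore show that the pipeline recovers planted,
colour-and-crack-expressed stage structure — not that it would reach the
same accuracy on orchard photographs.

## Problem sizes used in tests and the acceptance script

The recovery experiment uses 150 images (50/stage) at 64×64, tiny
backbone, 20 rounds — about a minute on one CPU.  The crack-localization
experiment trains 15 supervised epochs on 120 crack-informative images
and evaluates 20 held-out cracked images.  Conjoint recovery simulates
20 tables of 30 records/stage.  K-Means/exhaustive-search equivalence
uses 25 instances with N ≤ 8, k = 2 and 24 restarts (restarts matter:
Lloyd from a handful of seedings can miss the global optimum even at
N = 8).  The full VGG16-D backbone is exercised once as a forward-pass
smoke test.

## Known limitations

* **Grad-CAM and negative evidence.**  A class whose evidence is the
  *absence* of bright structure (a dark crack on an otherwise uniform
  peel) can yield channel weights that are negative almost everywhere;
  the rectified weighted sum is then identically zero and the map is
  flagged rather than renormalised.  The crack-localization experiment
  renders exposed seeds brightly so that crack-bearing classes carry
  positive evidence, and localization is strong in most runs, but
  occasional training runs still encode a stage chiefly by negative
  evidence and localize poorly.  This is a property of standard Grad-CAM,
  not of the renderer.
* **Random-feature variance.**  First-round clustering quality varies
  with the backbone initialisation seed, especially for narrow networks.
* **Instant convergence on easy data.**  On widely separated synthetic
  stages the loop can be correct from round one, in which case the
  round-to-round NMI starts near 1 and has no room to trend upward.
* Training uses no augmentation, weight decay, or pretraining; the full
  VGG16-D scale is supported but not tuned for CPU-scale training.
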