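# Methods

This note documents the model implemented by `tripletmetric`, the numerical
choices behind it, what the synthetic data does and does not emulate, and the
package's known limitations.

## Model

### Embedding network

Images are embedded by a residual convolutional network: an initial
large-kernel convolution (7×7) with 2×2 max pooling, four stages of
bottleneck residual blocks (1×1 reduce → 3×3 → 1×1 expand, ReLU after every
convolution, projection shortcut where the shape changes), a spatial pyramid
pooling (SPP) layer, a fully connected embedding layer, and row-wise L2
normalization.

SPP partitions the final C×H×W feature map, for each level l, into l×l
adaptive half-open cells with edges ⌊iH/l⌋ (so cells tile the whole map for
any H, W ≥ l) and max-pools each cell per channel. Concatenation over levels
gives a fixed C·Σl² vector regardless of input size. Max is used as the
pooling operator, the standard choice for SPP. The full-scale preset uses
levels [1, 2, 4, 8] (85 bins) on a 2048-channel map and an 800-d embedding,
with stride 2×2 at the first block of stages 2–3 and the non-square 2×1 at
stage 4; the desk preset keeps the same topology at widths 16/32/64/128 with
one block per stage, levels [1, 2, 4] (its final map is 4×4, smaller than an
8×8 grid), a 32-d embedding, and the non-square stride mapped to 2×2 since
desk inputs are square. Weight initialization is He-scaled Gaussian under an
explicit seed; construction, inference and training are deterministic given
the seed.

The whole network is implemented in numpy with explicit forward and backward
passes (im2col convolutions, argmax-routed pooling gradients, the exact
Jacobian of L2 normalization). The backward pass is verified against central
finite differences on random parameter entries in the test suite.

### Loss and learned metric

Embedding similarity is the quadratic form
D_M(i, j) = (f_i − f_j)ᵀ M (f_i − f_j) with M ∈ S₊ (symmetric PSD).
Per triplet (a, p, n), with A = D_M(a, n), B = D_M(a, p):

    L = mean over triplets of  max(0, D_x) + μ · D_p,
    D_x = 1 − A / (B + α),     D_p = B.

The ratio hinge is active exactly when A < B + α, i.e. when the negative is
not separated from the anchor by at least the positive distance plus the
margin. The pairwise term penalizes intraclass spread unconditionally.

Gradients are closed-form. With M̃ = M + Mᵀ, g₁ = −1/(B + α) and
g₂ = A/(B + α)²:

    ∂D_x/∂f_a = g₁ M̃ (f_a − f_n) + g₂ M̃ (f_a − f_p),
    ∂D_x/∂f_n = −g₁ M̃ (f_a − f_n),   ∂D_x/∂f_p = −g₂ M̃ (f_a − f_p),
    ∂D_x/∂M   = g₁ C⁻ + g₂ C⁺,       ∂D_p/∂M   = C⁺,

where C⁻ and C⁺ are the outer products of the anchor–negative and
anchor–positive differences. The triplet term contributes only when
D_x > 0; the pairwise term always contributes. Agreement of both gradient
routes with central finite differences (relative error < 1e-4 on randomized
fixtures away from the hinge kink, where the loss is not differentiable) is
the module's ground truth and is asserted in the tests and recomputed by the
acceptance script.

### Optimization

Training alternates two stages per outer iteration, starting from M = I:

1. **Weights stage.** M fixed. For each of `inner_batches` mini-batches:
   draw K classes × L images, embed, mine batch-hard triplets under the
   current M, and take one momentum-SGD step on all network parameters
   through full backpropagation.
2. **Metric stage.** Weights fixed, all embeddings recomputed. For each of
   `metric_steps` steps: mine a fresh batch, take a gradient step on M, and
   project onto the PSD cone (symmetrize, eigendecompose, zero negative
   eigenvalues — the Frobenius-nearest PSD matrix for symmetric input).

Batch-hard mining selects, for every image in the batch, the farthest
same-class member and the nearest different-class member under the current
M, with ties broken to the lowest index (making mining deterministic even in
degenerate all-equal batches). Classes with fewer than L members are sampled
with replacement and de-duplicated at mining time; an anchor whose class has
no second batch member is skipped.

Optionally (`average_metric_tail`), the metric iterates from the second half
of training are Polyak–Ruppert averaged and the average is returned after a
final projection. Plain projected stochastic gradient leaves the final M
with batch-to-batch noise aligned to whichever extreme pairs were mined
last; iterate averaging removes most of that variance. The planted-direction
recovery experiment uses it.

### Classification heads

The default head is nearest class centroid: class centroids are the means of
the training embeddings per class, queries are assigned to the centroid with
the smallest learned Mahalanobis distance, ties to the lowest class id.

An alternative attention head is available (`classifier_head="attention"`):
the final conv map's spatial positions form a visual fact memory (one row
per region — 196 rows for a 14×14 map at full scale), a learned table with
one row per class forms the category memory, and a recurrent (LSTM) encoder
followed by r rounds of alternating softmax-attention projections into the
two memories produces a code e_c = tanh(W_e u_r + b_e). A discriminative
decoder encodes each candidate class-token sequence with a shared LSTM and
ranks candidates by the softmax of dot-product similarities with e_c; a
generative decoder that emits a token distribution per step is also
provided. All attention weight vectors are probability vectors by
construction; the additive state updates add convex combinations of memory
rows, so each round moves the state by at most the largest memory-row norm.
The attention parameters are seeded uniform [−0.1, 0.1] and are not trained
by the desk pipeline; the head is a forward architecture provided for
completeness and the centroid head is the default. How the attention
encoder couples to the triplet-trained CNN is a genuinely open design point;
this package couples them through the shared conv map behind a config
switch.

## Parameters and defaults

| parameter | default (desk) | meaning / rationale |
|---|---|---|
| `margin` (α) | 0.2 | ratio-loss margin. Embeddings are unit-norm, so squared distances start around 0.01–0.1; α of order 1 makes the ratio nearly flat there and training stalls on many seeds, while α = 0.2 keeps curvature at sphere scale. `LossConfig`'s generic default is 1.0 for unnormalized feature spaces. |
| `balance_mu` (μ) | 0.5 | pairwise weight. Sized for the nearest-centroid readout: a stronger intraclass penalty tightens clusters and measurably stabilizes held-out accuracy (0.95–0.98 over eight seeds vs a 0.94 tail at 0.1–0.3). |
| `lr_w`, `momentum` | 0.02, 0.5 | weights-stage SGD. Batch-hard training collapses the embedding (loss → 1, all distances → 0) at aggressive settings such as 0.05/0.9; the gentler pair trains the desk net from ~0.7 to ~0.01 loss in 20 iterations without collapse. |
| `lr_M`, `metric_steps` | 0.01, 5 | metric-stage projected gradient descent; step size is a plain constant, as no schedule is prescribed for the metric. |
| `outer_iters`, `inner_batches` | 20, 16 | 320 weight steps total — the smallest budget at which desk training reliably converges. |
| `batch_K`, `batch_L` | 2, 8 | K·L = 16-image batches; every image anchors one mined triplet. |
| `rounds` (r) | 2 | attention rounds. |
| `enhance` | off (desk) | global histogram equalization before resizing. On in the full-scale radiograph preset, where it raises nodule/tissue contrast. Off at desk scale: equalization maps every image to a near-uniform histogram, which removes exactly the class-defining intensity statistics of the synthetic blob generator (the class-mean pixel difference collapses from 0.021 to 0.001). |
| `input_size` | 64 | desk input edge; any size whose final conv map is at least max(SPP level) works. |

Full-scale presets (`jsrt-paper`, `wbcd-paper`) ship the reported training
settings of the radiograph and cytology studies (lr 0.01 with ×0.1 decays /
batch 128, and lr 0.001 / batch 16 / momentum 0.3 / weight decay 4e-4
respectively) for fidelity; running them requires the external data and
GPU-scale compute and is outside the desk tests.

## Synthetic data

`generate_blob_images` emulates a nodule-screening contrast: textured
backgrounds (low-frequency Gaussian random field, mean ≈ 90, sd ≈ 20, plus
fine grain) with 1–3 bright Gaussian blobs for positive classes (amplitude
≈ 80–115 × `contrast`, radius ≈ size/14–size/8) and none for class 0.
Classes therefore differ in both mean intensity and spatial structure. It
does **not** emulate anatomy, acquisition physics, rib/vessel clutter,
label noise, or inter-reader ambiguity — passing desk tests shows the
machinery optimizes and generalizes on a controlled contrast, not that it
reaches any particular accuracy on clinical radiographs.

`generate_tabular` emulates a two-class ordinal cytology table: 9 features
in {1..10}, benign rows drawn near 2.5, malignant near 7 (clipped rounded
Gaussians). `inject_missing` blanks 1–2 features in exactly k rows;
`drop_missing` removes every incomplete row, preserving order — the
invalid-data exclusion used on such tables (699 rows with 16 incomplete →
683 retained). CSV serialization follows the public WBCD dialect (id, 9
features, class 2/4, `?` for missing).

## Validation experiments

* **Planted-direction recovery** (`experiments.metric_recovery`): two
  classes of 200 six-dimensional points whose means differ only along a
  random unit vector v (offset ±1.5 v, isotropic within-class sd 0.6), so v
  is the only discriminative axis. The optimizer runs metric-stage only
  (identity extractor; 200 iterations × 5 steps, step 0.1, 2×16 batches,
  tail averaging) and the angle between M's dominant eigenvector and v is
  measured. Typical angles are 5–13°; smaller sample sizes leave a larger
  angle because batch-hard mining repeatedly selects the same extreme pairs
  (a finite-sample bias of the estimator, not optimizer noise — it does not
  average out with more iterations).
* **Desk end-to-end** (`experiments.desk_end_to_end`): 2 classes × 100 blob
  images at contrast 1.0, split 50/50 by class, desk preset, 20 alternating
  iterations; reports held-out accuracy (≈ 0.95–0.98 across seeds) and the
  loss trajectory, which decreases on average.

## Numerical notes and edge cases

* The loss denominator B + α must be positive; α = 0 with a coincident
  anchor/positive raises a division-guard error rather than returning inf.
* Gradient fixtures are rejected within 1e-2 of the hinge kink, where the
  loss is not differentiable and finite differences are meaningless.
* `psd_project` symmetrizes before eigendecomposition, so asymmetric input
  is first mapped to its symmetric part (the quadratic form only sees that
  part anyway); projection is idempotent to 1e-10.
* Equalization uses the integer 256-bin CDF map
  round((cdf(v) − cdf_min)/(n − cdf_min)·255); it is monotone and
  idempotent to within one intensity level. Constant images map to
  themselves. Downscaling by an integer factor is exact block averaging;
  other geometry uses antialiased bilinear resampling.
* Mining ties (equal distances) resolve to the lowest index; batches where
  no anchor has a positive yield an empty triplet list and the optimizer
  skips that step.
* All randomness flows through explicit `numpy.random.default_rng` seeds;
  model archives are bytewise reproducible for a fixed seed and data.

## Limitations

* The attention encoder/decoders are forward computations with seeded
  initialization; no gradient path trains them end to end with the triplet
  objective, mirroring the fact that the two components' training coupling
  is unspecified in the underlying design.
* The full-scale preset is shape-checked, not trained, in this environment;
  desk-scale results do not predict clinical-dataset accuracy.
* Nearest-centroid assumes roughly unimodal classes in embedding space;
  strongly multimodal classes would need a k-NN or per-mode centroid
  readout.
* The metric is a single global d×d matrix; no low-rank or local metric
  variants are provided.
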