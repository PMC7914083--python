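# tripletmetric

Metric-learning classification for medical-style grayscale images:
a triplet-trained convolutional embedding network with spatial pyramid
pooling, a jointly learned Mahalanobis distance, and a multi-round
cross-modal attention memory encoder.

## The problem and the method

Computer-aided diagnosis pipelines (lung-nodule screening on chest
radiographs, cytology-based breast-tumour grading) need classifiers that
discriminate subtle appearance differences from modest amounts of labelled
data. This package implements a metric-learning approach to that problem:
instead of learning class boundaries directly, it learns an embedding
f_w(y) of each image together with a distance in embedding space under which
same-class images are close and different-class images are far, and then
classifies by nearest class centroid under that learned distance.

The core pieces:

* **Embedding network.** A residual bottleneck CNN (1×1 / 3×3 / 1×1 conv
  stacks with shortcut connections, ReLU after every convolution) whose last
  feature map is pooled by a **spatial pyramid pooling** (SPP) layer over
  1×1, 2×2, 4×4, 8×8 grids, yielding a fixed-length vector for any input
  size (with C channels and 85 bins, a C·85-dimensional vector), followed by
  a fully connected embedding layer and **L2 normalization**, so embeddings
  live on the unit sphere. A full-scale preset (128 7×7 initial kernels,
  stage widths 256–2048, 800-d embedding) is shipped alongside a desk-scale
  preset (64×64 inputs, widths 16–128, 32-d embedding) that trains in CPU
  minutes.

* **Learned Mahalanobis distance.** Similarity between embeddings is the
  quadratic form D_M(i, j) = (f_i − f_j)ᵀ M (f_i − f_j) with M symmetric
  positive semidefinite. For a triplet (anchor a, positive p, negative n)
  with A = D_M(a, n) and B = D_M(a, p), the training loss is the mean of

      max(0, 1 − A / (B + α))  +  μ · B

  a **ratio triplet term** that activates exactly when the negative is
  insufficiently separated (A < B + α), plus a **pairwise term** shrinking
  intraclass variance. Gradients with respect to the features and with
  respect to M are analytic (chain rule through the ratio; outer products of
  feature differences for M) and are validated against central finite
  differences.

* **Alternating optimization with PSD projection.** Training alternates:
  (1) with M fixed, momentum SGD on the network weights through explicit
  backpropagation; (2) with the weights fixed, projected gradient descent
  on M, where after every step M is symmetrized, eigendecomposed, and its
  negative eigenvalues zeroed (projection onto the PSD cone).

* **Batch-hard triplet mining.** A balanced set of N classes × M images
  admits N(N−1)M²(M−1) triplets — far too many to materialize. Batches of
  K classes × L images are drawn and each image anchors one triplet built
  from its farthest same-class and nearest different-class batch member
  under the *current* metric.

* **Attention memory encoder.** A multi-round encoder that alternately
  projects a query state into a per-class category memory and into a visual
  memory built from the CNN's final conv-map regions (softmax attention,
  additive updates), with generative and discriminative LSTM decoders. The
  discriminative decoder is available as an alternative classification head.

A seeded synthetic-data module generates both study-like inputs: textured
grayscale images whose classes differ by bright Gaussian-blob statistics,
and 9-feature ordinal tables (values 1–10, benign low / malignant high) with
controlled missing values, in the public WBCD file dialect.

## Worked example

```python
import tripletmetric as tm

data = tm.generate_blob_images(n_classes=2, n_per_class=100, size=64,
                               contrast=1.0, seed=0)
train_idx, test_idx = tm.stratified_split(data.labels, test_fraction=0.5, seed=0)

model = tm.TripletMetricClassifier.from_image_set(
    data.subset(train_idx), config=tm.TrainConfig(seed=0))
results = model.fit()
print(results.summary())

report = results.evaluate(data.subset(test_idx))
print(report)
```

Output (about a minute on one CPU core):

```
Triplet Mahalanobis Metric Classifier Results
=============================================
classes:            2
training images:    100
embedding dim:      32
backbone preset:    desk
outer iterations:   20
margin alpha:       0.2
pairwise weight mu: 0.5
initial loss:       0.686503
final loss:         0.013009
active triplets:    0 (last batch)
metric eigenvalues: top 5 = 1.0258, 1.0050, 1.0015, 1.0014, 1.0010
metric min eig:     9.94e-01

accuracy: 0.9700  (n=100)
  class 0: 1.0000
  class 1: 0.9400
```

The training loss falls from 0.69 to 0.013 over 20 alternating iterations
(an "active triplet" count of 0 means every mined triplet ends up satisfying
the ratio margin), and the held-out accuracy is 0.97 on 50 + 50 unseen
images. `results.save("model.npz")` writes a single self-contained archive;
the same workflow is available from the shell via the `tripletmetric`
CLI (`generate-data`, `train`, `evaluate`, `classify`).

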