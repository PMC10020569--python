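# Methods

## Problem setting

Single-cell RNA-seq batches measured on different platforms or at different
sites show systematic technical differences (batch effects) that confound
the biological signal. When per-cell cell-type annotations are available,
integration can be *supervised*: the labels say which cells across batches
ought to coincide in a joint representation. This package learns such a
representation with a Siamese domain-adaptation network, evaluates it with
six standard integration metrics, converts it back to gene space through
mutual-nearest-neighbor anchors so it can serve as a mapping reference, and
ships a synthetic-data generator so the whole pipeline is testable with
known ground truth.

## Preprocessing

Pipeline order is fixed: label consolidation → gene intersection →
library-size normalization + log1p (for count data) → per-batch PCA.

* **Label consolidation** is driven by an explicit user-supplied mapping
  from raw annotation strings to consolidated labels (most general shared
  level, e.g. "CD14 monocytes" and "CD16 monocytes" both → "monocytes";
  "DC"/"DCs"/"Dendritic Cells" → one name). The mapping is validated for
  completeness rather than guessed, so the manual harmonization step is
  reproducible.
* **Gene intersection** keeps exactly the genes present in every batch,
  matched by identifier string, in sorted order.
* **Normalization**: each cell scaled to a total of 10,000 (the field's
  conventional pseudo-count-per-ten-thousand), then log1p. Both the scale
  and the transform are configurable. Data already on log scale
  (`DataCollection.is_log`) skips this step; applying it twice raises.
* **Per-batch PCA**: each batch is centered on its own gene means and
  reduced to its own top 50 components via exact SVD, with no unit-variance
  scaling (configurable). The per-batch PC coordinate systems are *not*
  mutually aligned — aligning them is the network's job, and independently
  computed PCs are the harder setting compared to a shared
  highly-variable-gene space. Component signs follow a deterministic
  convention (largest-magnitude loading positive) so runs are reproducible
  across platforms. If a batch cannot support 50 components the number is
  lowered globally with a warning.

## Pair generation

Training operates on cross-batch cell pairs. Cells are first subsampled to
at most `cells_per_type` per (batch, type) — default 400, matching typical
practice for collections of this size — which equalizes type abundances.
Ordered batch pairs are visited in a rotated cycle: for batches 1..n, all
unordered pairs with the first element as source, then the reversed pairs
((1,2), (1,3), (2,3), (2,1), (3,1), (3,2) for three batches), repeating for
the length of training. Every batch therefore serves as the source domain,
which is what lets the classifier see batch-specific cell types.

Each minibatch draws `batch_size` pairs (default 64): positive pairs (same
consolidated type, drawn only from types present in both batches of the
step) and negative pairs, stratified by type so rare types stay
represented. The positive fraction defaults to 0.5 (standard contrastive
practice); the standard small-fixture training condition lowers it to 0.3,
since extra negative pairs are the only contrastive signal batch-specific
types receive. Types unique to the source batch appear in negative pairs
and in the classification labels, never in positive pairs.

## Network and objective

Two weight-sharing branches `g` map the 50 PC coordinates of each cell of a
pair into a common feature space; a two-layer feed-forward classifier `h`
(hidden width 128) with a linear softmax head sits on the source branch.
The integrated embedding is the output of `h`'s second feature layer
(default width 64 — the embedding layer is where all evaluation happens,
and giving it room measurably improves neighborhood purity).

Default `g` treats the 50 PCs as a length-50 single-channel sequence: two
1-D convolutions (kernel 3, channels 16 and 32, ReLU) → flatten → linear to
64 features. Convolution over PC index has no privileged meaning, so a
plain two-layer perceptron is available as `arch="mlp"`; the convolutional
default honors the feature-extractor design this method family uses.

The objective is the classification + contrastive semantic alignment
(CCSA) loss, `α_SA·L_SA + α_S·L_S + α_C·L_C` with default weights (1,1,1):

* **Semantic alignment** `L_SA`: mean over same-type cross-batch pairs of
  half the squared Euclidean distance between their `g` outputs (the
  classic contrastive semantic-alignment form, default
  `sa_squared=True`). The non-squared variant — half the plain distance —
  is available as `sa_squared=False`. The squared form penalizes distant
  same-type pairs more strongly and produces visibly tighter, more stable
  type clusters, which is why it is the default; the two differ only in
  how hard distant positives are pulled.
* **Separation** `L_S`: mean over different-type pairs of
  `½·max(0, m − d)²` with margin `m = 1` by default; zero once all
  negative pairs sit beyond the margin, bounded by `m²/2`.
* **Classification** `L_C`: softmax cross-entropy of `h(g(x_source))`
  against the source cell's consolidated type.

The network is implemented directly in numpy with hand-derived gradients
(the model has only a few thousand parameters; exact, dependency-free,
bit-reproducible CPU training outweighs a framework). Optimization is Adam
(step size 3e-3 decaying linearly to one tenth over training, minibatch
64 pairs, 3,000 steps by default; 8,000 on the standard `small` fixture
condition), initialization is fan-in-scaled normal
with a fixed seed, and every random draw (subsampling, pair sampling,
initialization) descends from the single config seed, so identical seeds
give bit-identical loss traces and embeddings. Training aborts with a
diagnostic on non-finite loss; an optional plateau-based early stop
(`patience`) is off by default to keep run length deterministic.

Numerical details: distance gradients use an epsilon floor (1e-12) at zero
distance, where the non-squared alignment gradient and the hinge gradient
are otherwise undefined; softmax is max-shifted; cross-entropy adds 1e-12
inside the log.

## Evaluation metrics

All six metrics work on an embedding with per-cell type and batch labels.
kNN conventions throughout: Euclidean distance, self excluded, distances
rounded to 9 decimals and ties broken by cell index via stable sort, so
every kNN-based metric is exactly reproducible and brute-force checkable.

* **Positive rate**: fraction of cells with ≥95% same-type neighbors among
  their k = 50 nearest.
* **True-positive rate**: a positive cell of type t is a true positive if,
  for every batch i, its neighbor count from batch i lies within the
  three-sigma binomial band `k·p_i ± 3√(k·p_i(1−p_i))` (clipped at 0),
  where `p_i` is batch i's share of the type-t population. Denominator is
  all cells, so TPR ≤ PR by construction.
* **kBET**: for a seeded 10% sample of cells, a Pearson χ² goodness-of-fit
  test (df = #batches − 1, no continuity correction) of the neighborhood's
  batch counts against the global batch proportions; the score is
  1 − rejection rate at α = 0.05. Batches absent from the data contribute
  no χ² category.
* **LISI**: per cell, Gaussian neighbor weights calibrated by bisection to
  a fixed perplexity (default 30, over 3×perplexity nearest neighbors),
  then the inverse Simpson index `1/Σ_b p(b)²` of the weighted label
  composition — 1 for a single category, B for a uniform mixture over B.
  The *squared*-probability form is the standard inverse Simpson index and
  is what this package computes. iLISI (batch labels, higher better) and
  cLISI (type labels, lower better) are rescaled to [0,1] via
  `(LISI−1)/(B−1)` before entering
  `F1 = 2(1−cLISI)(iLISI)/(1−cLISI+iLISI)`; without rescaling the F1 can
  leave [0,1] since raw LISI lives in [1,B]. Raw sub-scores are reported
  alongside.
* **ASW**: mean silhouette width (scikit-learn) under type labels (higher
  better) and batch labels (lower better), each rescaled from [−1,1] to
  [0,1] by `(s+1)/2` before the same harmonic-mean F1 — the convention of
  the integration-benchmark literature.
* **ARI**: seeded k-means (k = number of cell types, 10 restarts, best
  inertia) in the embedding; adjusted Rand index of the clustering against
  type labels and against batch labels, clamped at 0 (chance-level ARI can
  be slightly negative) before the harmonic-mean F1.

## Gene-space reference and cell-type mapping

To act as a mapping reference the embedding is converted back to gene
space against a chosen target batch. Anchors are mutual-kNN pairs across
each (other batch, target) boundary in the embedding (`k_anchor = 5`),
scored by the shared-neighbor overlap fraction of the two cells'
20-nearest-neighbor sets in the joint embedding. Each non-target cell then
subtracts a weighted average of its `n_correct = 10` nearest anchors'
gene-space differences (other-batch anchor minus target anchor), weighted
by a Gaussian kernel on embedding distance with bandwidth equal to the
mean of those distances; target cells pass through unchanged. This anchor
weighting is this package's own documented operator: the published
procedure specifies mutual nearest neighbors and weighted anchor
differences but not the kernel or neighbor counts, so those are declared
defaults here, not inferred ones. A constant additive batch shift is
recovered exactly in the limit of correct anchors.

Label transfer fits on the reference only: dispersion-based
highly-variable-gene selection (2,000 genes via scanpy's mean-dispersion
binning), PCA (50 components) on the reference HVG space, query projected
into that space, and each query cell assigned the
inverse-distance-weighted majority label of its `k_map = 15` nearest
reference cells. Distance weighting (rather than a plain vote count) makes
self-mapping exact — a query cell identical to a reference cell always
recovers that cell's label — while agreeing with the unweighted vote away
from ties; with `k_map = 1` it reduces to nearest-neighbor.

The leave-one-batch-out harness holds out each batch as query, integrates
the rest, projects to every retained target space in turn, and maps; the
baseline uses each retained batch alone as reference. Output is a long
table (left_out, method, target_space, accuracy).

## Synthetic data

The generator emulates the structural obstacles of multi-batch
integration, not the moments of any real tissue:

* each cell type's mean sits at a base log-expression (2.0) plus a scaled
  orthonormal direction, so all pairwise type-mean distances equal
  `effect_size × noise_sd` exactly (defaults 4.0 × 1.0 — clusters whose
  Bayes-optimal confusion is a few percent: separable but not trivial);
* batch effects are `none`, an exact nonnegative additive `shift` (norm =
  `batch_magnitude × noise_sd`, default 6), or `affine`: a non-orthogonal
  linear distortion `I + γG/√G` (γ = 0.15) with 5% per-gene scale jitter
  plus the shift. The affine form matters: a pure shift — and likewise any
  orthogonal rotation — is removed exactly by per-batch PCA centering, so
  only a genuinely non-orthogonal distortion leaves the unintegrated
  baseline misaligned the way real cross-platform data is;
* types are shared across all batches except a configurable number of
  batch-specific ones, assigned round-robin;
* `gaussian-log` (default) emits log-scale values directly (clipped at 0,
  consistent with the post-log pipeline); `negative-binomial` emits raw
  counts via a gamma–Poisson mixture to exercise normalization;
* optional vocabulary noise emits per-batch spelling variants of the type
  names together with the correct consolidation map.

What this does *not* emulate: gene–gene correlation structure, dropout
patterns tied to expression level, library-size variation across cell
types, nonlinear (e.g. cell-state-dependent) batch effects, or ambient
RNA. Passing tests on these fixtures therefore demonstrate that the
machinery behaves as specified under controlled geometry, not that any
particular real collection would integrate equally well.

Presets: `tiny` (2 batches × 3 types × 60 cells × 120 genes, shift) runs
the full pipeline in seconds; `small` (3 batches × 6 types with one
batch-specific × 200 cells × 500 genes, affine) is the standard test
condition; `pancreas-like` (5 batches, 4 shared + 4 batch-specific types,
vocabulary noise) mirrors the structure of a multi-study organ atlas.

## Problem sizes and seeds

Tests and the acceptance script run at desk scale: the `small` fixture
(3,200 cells) for integration efficacy and seed-robustness checks, a
4-batch collection (≈1,900 cells) for leave-one-batch-out mapping, and
≤300-cell fixtures for brute-force oracle comparisons. These sizes were
chosen so the full suite runs on a single CPU in minutes while all
qualitative contrasts (integrated vs unintegrated, batch-specific type
handling, shift recovery) remain decisive. All stochastic steps take
explicit seeds; identical seeds reproduce results bit-for-bit.

## Known limitations

* The network input is per-batch PCs, so a trained model cannot embed a
  new, unseen batch without recomputing that batch's own PCA — consistent
  with the integration-then-reference workflow, but not a general
  projector for streaming data.
* Supervision is required: unlabeled batches cannot be integrated.
* The anchor correction assumes locally additive batch effects in gene
  space; strongly nonlinear effects would need more anchors than the
  defaults and are not modeled by the simulator.
* Brute-force kNN is quadratic in cell count; fine for the tens of
  thousands of cells this package targets, not for atlas-scale millions.
* kBET's χ² approximation needs expected neighborhood counts of a few
  cells per batch; with many batches and small k the test becomes
  conservative.
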