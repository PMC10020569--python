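# sida

Supervised integration of multi-batch single-cell RNA-seq data with a
Siamese domain-adaptation network, plus the surrounding toolchain: a
six-metric integration evaluation suite, mutual-nearest-neighbor
back-projection of the integrated embedding to gene space, leave-one-
batch-out cell-type mapping, and a synthetic-data generator with ground
truth.

## Who this is for

Anyone assembling a joint representation of several annotated scRNA-seq
batches (e.g. building an organ atlas from multiple studies). Unsupervised
integration tools ignore the annotations those studies already carry; when
labels exist, using them gives markedly better batch mixing and cell-type
separation. The price is that every batch must be labeled and the label
vocabularies consolidated first.

## The method

Each batch is reduced independently to its top 50 principal components
(after gene intersection, library-size normalization and log1p). Pairs of
cells from different batches — visited in a rotated schedule so every
batch serves as the source domain — are fed through two weight-sharing
network branches `g` into a common feature space, with a two-layer
classifier `h` on the source branch. Training minimizes the
classification + contrastive semantic alignment (CCSA) objective

    L = α_SA · L_SA(g) + α_S · L_S(g) + α_C · L_C(h∘g)

where the semantic alignment term `L_SA = Σ ½‖g(xₐˢ) − g(xₐᵗ)‖²` pulls
same-type cross-batch pairs together, the separation term
`L_S = Σ ½ max(0, m − ‖g(xₐˢ) − g(x_bᵗ)‖)²` pushes different-type pairs
beyond a margin `m`, and `L_C` is softmax cross-entropy on the source
cell's type. The integrated embedding is the output of `h`'s second
feature layer. Batch-specific cell types participate through negative
pairs and classification, so they form their own clusters instead of
being forced onto shared types.

Integration quality is scored on the embedding by six standard metrics:
kNN positive rate and true-positive rate (type purity and three-sigma
batch-composition consistency of 50-nearest-neighbor neighborhoods), kBET
(1 − χ² rejection rate of local vs global batch composition), and
harmonic-mean F1 combinations of LISI, ASW and ARI computed on the batch
axis (mixing) and the cell-type axis (separation). See
`docs/methods.md` for exact definitions and conventions.

To use the integrated data as a reference for annotating new datasets,
the embedding is converted back to gene space against a chosen target
batch via mutual-nearest-neighbor anchors and Gaussian-weighted anchor
differences; label transfer then runs highly-variable-gene selection and
PCA on the reference and classifies query cells by weighted kNN vote.

## Worked example

```python
import numpy as np
from sida import (smoke_fixture, preprocess_collection, SidaConfig,
                  train, embed, evaluate_all)
from sida.datatypes import Embedding

coll = smoke_fixture("tiny", seed=1)          # 2 batches x 3 types x 60 cells
prepped, view = preprocess_collection(coll, n_pcs=30)

model = train(view, config=SidaConfig(n_steps=600, cells_per_type=60, seed=1))
emb = embed(model, view)

X, ids, types, batches = view.stacked()        # unintegrated baseline
for name, e in [("raw", Embedding(X, ids, types, batches)), ("sida", emb)]:
    r = evaluate_all(e, seed=1)
    print(name, {k: round(v, 3) for k, v in r.headline().items()})
```

prints (exact values; the pipeline is deterministic given the seeds):

```
raw  {'positive_rate': 0.0, 'true_positive_rate': 0.0, 'kbet': 1.0,
      'f1_lisi': 0.491, 'f1_asw': 0.502, 'f1_ari': 0.348}
sida {'positive_rate': 0.997, 'true_positive_rate': 0.989, 'kbet': 0.806,
      'f1_lisi': 0.944, 'f1_asw': 0.625, 'f1_ari': 1.0}
```

Reading this: in the raw concatenated per-batch PC space no cell has a
type-pure neighborhood (positive rate 0) because the two batches' PC
coordinate systems are unaligned — type clusters from one batch land on
other types from the other batch (which is also why kBET is high there:
batches overlap, just wrongly). After integration nearly every
neighborhood is type-pure and batch-balanced, k-means recovers the type
partition exactly (F1_ARI = 1.0), and kBET stays high because batches now
overlap *within* types.

The same workflow is available from the shell:

```sh
sida simulate --preset tiny --seed 1 --out sim/
sida integrate --config cfg.yaml          # writes embedding.tsv
sida evaluate --embedding embedding.tsv --out metrics.json
sida map --reference sim/batch0.csv --query sim/batch1.csv --out pred.tsv
```

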