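# essprot

Essential proteins are those a cell cannot survive or reproduce without.
Identifying them computationally — instead of by gene-knockout screens — is a
long-standing problem in systems biology: classical approaches rank proteins
by a single topological centrality score of the protein–protein interaction
(PPI) network, which ignores everything else we know about a protein.

`essprot` implements a multi-input deep learning classifier that predicts
protein essentiality from three complementary data sources, plus the full
evaluation and baseline protocol around it, and a synthetic-data generator so
the whole pipeline runs and is tested without any external downloads. It is
aimed at computational biologists who want a transparent, dependency-light
(NumPy/numba) reference implementation of this architecture.

## The model

Each protein *u* is described by three feature blocks, processed by
dedicated branches that each emit a 16-dimensional feature vector:

1. **PPI topology — node2vec.** Second-order biased random walks (return
   parameter *p*, in-out parameter *q*; transition weight
   `α_pq(t,x)·w_vx` with `α = 1/p, 1, 1/q` for `d(t,x) = 0, 1, 2`) generate
   a corpus of node sequences; skip-gram with negative sampling embeds every
   protein into ℝ⁶⁴ (walk length 20, 10 walks per node, window 10,
   `p = q = 1`). Two dense layers (64 → 64 → 16, ReLU) condense the vector.
2. **Time-course gene expression — depthwise separable convolution.** Per
   protein the expression values form a `(condition × replicate × timestep)`
   tensor (2 × 3 × 8 by default). Each experimental condition is convolved
   separately over time (kernel 3, 64 filters, replicates as input
   channels), batch-normalized and max-pooled (size 2); the two condition
   streams are concatenated and mixed by a pointwise (kernel-1) convolution,
   globally max-pooled and condensed to 16 ReLU units.
3. **Subcellular localization — ranked top-K sparse vector.** Localization
   terms are ranked by the number of network proteins they annotate; the top
   K = 1024 terms form the feature space and entries are confidence scores
   normalized to [0, 1]. Three dense layers (1024 → 64 → 64 → BN → 16)
   encode the row.

The concatenated 48-vector passes through a dense head
(48 → 16 → 1, sigmoid) to an essentiality probability. Training uses binary
cross-entropy with RMSprop (learning rate 0.001, batch 64, 20 epochs) on a
60/20/20 train/validation/test split.

Because only ~19% of yeast proteins are essential, each training epoch uses
**balanced undersampling**: all *E* training positives plus *E* freshly
drawn negatives. Over *n* epochs a given negative is never seen with
probability `p₁ = (1 − E/NE)ⁿ` — about 0.005 for the yeast-scale class sizes
(E = 1132, NE = 4856, n = 20), so nearly every negative participates.
Class-weighted and uniform-subsampling (`p₂ = (1 − 2E/(E+NE))ⁿ`) training
modes are provided for comparison, as are ten centrality baselines
(DC, BC, CC, EC, SC, ClusterC, SoECC, MNC, LAC, LID) evaluated by the
top-fraction ranking protocol (top 19% declared essential for yeast-like
prevalence, 11% for human-like).

## Worked example

Generate the default synthetic study conditions (2000 proteins, 18.9%
essential, degree-enriched and assortative essential nodes, calibrated
expression noise, enriched localization annotations), embed the network,
train, and evaluate:

```python
from essprot.synthetic_data import SyntheticSpec, generate_dataset
from essprot.graph_embedding import WalkParams, embed_network
from essprot.localization_features import rank_localization_terms, build_localization_matrix
from essprot.model_core import (TrainingConfig, build_feature_bundle, build_model,
                                train_model, split_dataset, predict)
from essprot.evaluation import roc_auc, pr_ap, confusion_counts, classification_metrics

spec = SyntheticSpec(n_proteins=2000, seed=1)
dataset = generate_dataset(spec)
embedding = embed_network(dataset.graph, WalkParams(seed=1), dim=64)
ranking = rank_localization_terms(dataset.localization, dataset.graph)
loc_matrix = build_localization_matrix(dataset.localization, ranking, dataset.proteins, K=1024)
bundle = build_feature_bundle(dataset.proteins, dataset.tensors, loc_matrix,
                              embedding, dataset.labels)

config = TrainingConfig(seed=1)  # 20 epochs, batch 64, RMSprop 0.001, balanced sampling
model = build_model(config, bundle.expression.shape[1:], 1024, 64)
model, history = train_model(model, bundle, config)

_, _, test = split_dataset(bundle, config.split_fractions, config.seed)
prob, hard = predict(model, test)
report = classification_metrics(confusion_counts(test.labels, hard))
print(f"test AUC = {roc_auc(test.labels, prob):.3f}")
print(f"test AP  = {pr_ap(test.labels, prob):.3f}  (prevalence {test.labels.mean():.3f})")
print(f"accuracy = {report.accuracy:.3f}, precision = {report.precision:.3f}, recall = {report.recall:.3f}")
```

Output (about half a minute on one CPU):

```
test AUC = 0.989
test AP  = 0.974  (prevalence 0.210)
accuracy = 0.948, precision = 0.985, recall = 0.762
```

The AUC of 0.989 and AP of 0.974 sit far above their chance floors (0.5 and
the 0.21 test prevalence): the model recovers the planted essentiality
signal from all three branches. At the default 0.5 decision threshold
precision is high (0.985) while recall is 0.762 — the ranking is excellent
but the threshold is conservative; the top-fraction protocol or a lower
threshold trades these off.

The same pipeline is available from the shell:

```bash
essprot simulate --n 2000 --seed 1 --out-dir data/
essprot train --data-dir data/ --seed 1 --out-dir run/
essprot baseline --edges data/edges.tsv --labels data/essential.txt \
    --top-fraction 0.19 --out run/centrality.tsv
```

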