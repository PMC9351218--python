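# Methods

This note documents the model, the synthetic study conditions, the numerical
choices, and the limits of what the tests demonstrate.

## Classifier

Three branches, one per data source, each ending in a 16-unit ReLU layer so
no source dominates the head by width alone:

* **Expression branch.** Input `(2 conditions × 3 replicates × 8
  timesteps)`. Per condition: 1-D convolution over time (kernel 3,
  same-padding, stride 1, 64 filters, replicates as input channels, ReLU) →
  batch norm → max pool (size 2). The two streams are concatenated on the
  channel axis (4 × 128), mixed by a pointwise kernel-1 convolution (64
  filters), globally max-pooled over time, and condensed by a dense 64 → 16
  layer. The kernel size 3 is the smallest non-trivial temporal kernel and
  keeps the pooled length at 4 for 8 timesteps; it is configurable.
  Expression values are used as read from the matrix (no per-gene
  standardization). Shorter time courses (e.g. 5 timepoints) are zero-padded
  at the tail; proteins without measurements enter as all-zero tensors with
  a recorded presence flag.
* **Localization branch.** Dense 1024 → 64 → 64 → batch norm → 16, ReLU
  throughout. The feature space is the top-1024 localization terms ranked by
  the number of distinct network proteins annotated (ties broken
  lexicographically by term id for reproducibility); entries are confidence
  scores divided by 5 — the integrated-channel score ceiling — and clipped
  at 1. K is configurable with presets {11, 64, 128, 256, 512, 1024}.
* **Embedding branch.** Dense 64 → 64 → 16 over the node2vec vector.

Head: dense 48 → 16 (ReLU) → 1 (sigmoid). Any subset of branches can be
enabled for ablations; the head input width is 16 per enabled branch.

### Training

Binary cross-entropy, RMSprop (lr 0.001, ρ 0.9, ε 1e-7), batch size 64,
20 epochs, Glorot-uniform initialization, 60/20/20 split (shuffle under
seed, contiguous partition; the test split is never touched during
training). Imbalance handling, applied to the training split only:

* `sampling` (default): every epoch takes all E positives plus E negatives
  drawn uniformly without replacement, fresh per epoch (epoch index folded
  into the random stream). Survival probability of a negative over n
  epochs: `(1 − E/NE)ⁿ`.
* `class_weight`: full training split; positive-class loss weighted by a
  factor in [1, 10] (default 8).
* `raw`: 2E examples per epoch drawn uniformly regardless of class;
  survival probability `(1 − 2E/(E+NE))ⁿ`.

The decision threshold is 0.5 with `≥` at the boundary. The closed forms
accept either the global class counts or the training-split counts; the
acceptance script uses the global yeast-scale counts (E = 1132, NE = 4856).

### Batch normalization

Normalization is over all axes except the feature axis (per-filter across
batch and time for convolutional inputs), ε = 1e-3, train mode requires
batch size ≥ 2, and inference uses exponential running statistics. The
running-stat momentum is **0.9**: under per-epoch balanced undersampling a
run sees only ~160 optimizer steps, and a slower momentum (0.99) leaves the
inference statistics so far from the batch statistics that test AUC drops
by ~0.04 relative to the same network evaluated with batch statistics.
With momentum 0.9 the gap vanishes.

## Graph embedding

Second-order biased walks: from edge (t, v) the next node x among v's
neighbours has unnormalized weight `α_pq(t, x) · w(v, x)` with α = 1/p, 1,
1/q for shortest-path distance d(t, x) = 0, 1, 2; the first step is uniform
over neighbours; the graph is treated as unweighted. Defaults: walk length
20, 10 walks per node, dimension 64, window 10, p = q = 1 (at which the
procedure reduces to a first-order simple random walk — verified against
the degree/2|E| stationary law in the tests). Walk order is shuffled per
pass; everything is reproducible under the seed.

Skip-gram with negative sampling is implemented from scratch: 5 negatives
per pair from the unigram³ᐟ⁴ distribution, 5 passes over the corpus,
per-token reduced window (uniform 1..window), step size decaying linearly
from 0.025 to 1e-4, input vectors initialized uniform ±0.5/dim and output
vectors at zero. The inner sequential-SGD loop is JIT-compiled with numba
in float32 and runs single-threaded, so results are bit-reproducible for a
fixed seed. Isolated nodes never enter the corpus and receive zero vectors
(logged) to preserve alignment with the other feature blocks.

## Evaluation

Confusion-matrix metrics (accuracy, precision, recall, F1, specificity,
NPV) report NaN for zero denominators rather than silently coercing to 0.
ROC-AUC is the rank statistic (ties averaged); AP uses step interpolation —
the conservative convention for precision–recall curves. The top-fraction
protocol sorts by score descending with a stable id tie-break and declares
the top ⌊fraction·N⌋ proteins essential; 0.19 and 0.11 match yeast-like and
human-like prevalence scales. Centrality baselines: DC, BC, CC (component
scaled), EC (power iteration, tol 1e-10 so that scores agree with the dense
spectral solution to well below test tolerance), SC (spectral matrix
exponential), ClusterC via NetworkX; SoECC, MNC, LAC and LID implemented
directly from their standard definitions (see module docstring).

## Synthetic study conditions

The generator produces aligned blocks for n = 2000 proteins by default,
every piece a pure function of (spec, seed):

* **Labels:** exactly round(0.189·n) essential proteins.
* **Network:** Chung-Lu random graph, base mean degree 20. Essential nodes
  get twice the expected degree (hub-lethality), and essential–essential
  edge probabilities are additionally multiplied by 3 (assortativity: the
  dense complexes essential proteins tend to form), with a fixed-point
  weight rescale so the realized essential/non-essential mean-degree ratio
  stays at the degree_signal value. Without the assortative component a
  skip-gram embedding of a degree-inhomogeneous but otherwise unstructured
  random graph carries almost no linearly decodable label signal, and the
  embedding branch would be untrainable noise.
* **Expression:** per protein, a standardized smooth base curve (order-2
  Fourier basis, random coefficients) shared by both conditions plus an
  independent condition-specific response curve; essential proteins respond
  with amplitude 1 + expression_signal (default 2× non-essential).
  Replicates add Gaussian noise with sd 0.8, calibrated so the median
  within-condition replicate correlation falls mid-band in 0.6–0.9 and the
  median cross-condition correlation in 0.1–0.6 (at sd 0.6 the replicate
  median sits at the 0.9 band edge). A baseline offset ~N(7, 1) mimics
  log-scale microarray levels. 8.5% of proteins (Bernoulli) have no
  measurements.
* **Localization:** 1200 terms with Zipf(1.1) popularity; each
  (protein, term) annotation is an independent Bernoulli draw proportional
  to popularity (mean 6 annotations per protein), with the probability of
  top-decile terms multiplied by 3 for essential proteins. Confidences are
  5·Beta(5, 2), label-independent.

At the null settings (degree_signal = 1, assortativity = 1,
expression_signal = 0, enrichment = 1) the labels are independent of every
block and a trained model scores at chance — the suite checks both the
null and the planted direction.

What the generator deliberately does **not** emulate: realistic
transcriptional dynamics or condition semantics, structured missingness,
identifier noise and cross-source aliasing, the heavy-tailed degree
distribution of curated interactomes, or correlated annotation evidence.
Passing tests therefore demonstrate that the pipeline recovers signal with
the stated statistical shape, not that it attains any particular accuracy
on real interactome data.

## Numerical and interface choices

* Duplicate (protein, term) localization rows keep the maximum confidence.
* Identifier matching is exact string equality after whitespace trimming.
* Missing expression cells stay NaN through parsing and are zero-filled
  only at tensor assembly.
* Probe-to-gene aggregation keeps the probe with the maximal mean across
  samples; a `per_sample_max` alternative is exposed behind a switch since
  the convention is genuinely ambiguous in the field.
* "Average degree" of a network is reported under both conventions
  (|E|/|V| and 2|E|/|V|), labeled, because public interactome reports use
  either.
* Splits of size n use ⌊f·n⌋ for train and validation, remainder test.
* Embedding/prediction tables round-trip at 6 decimal places; expression
  files written by the generator round-trip exactly (repr precision,
  `float_precision="round_trip"` on read).

## Known limitations

* The skip-gram trainer is single-threaded by design (reproducibility);
  embedding a 20k-node network takes minutes, not seconds.
* Subgraph centrality uses the dense spectral form; it is exact but
  quadratic in memory, so graphs beyond ~10⁴ nodes need the truncated
  eigenpair variant (not implemented).
* Batch-norm inference statistics are exponential moving averages, not the
  exact all-batch expectation, so very short runs retain some
  initialization bias.
* Cross-species transfer of trained weights is out of scope; the model is
  trained and evaluated within one organism's data at a time.
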