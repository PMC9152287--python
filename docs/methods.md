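# Methods

## Model and assumptions

The framework rests on guilt-by-association: miRNAs functionally similar to
known disease miRNAs, or regulating the same mRNAs, are likelier to be
disease-associated. Two networks carry that signal:

* a **miRNA functional-similarity network** — a symmetric matrix of scores
  in [0, 1]; walked as a weighted graph where transition probabilities are
  proportional to edge weight. Zero-weight pairs are simply absent from the
  graph (a zero transition probability is equivalent and cheaper). An
  optional pruning threshold exists but defaults to 0, since the weights'
  role is to bias the walk, not to define topology.
* a **miRNA–mRNA interaction network** — a bipartite edge list walked as a
  single homogeneous unweighted undirected graph. Gene nodes are embedded
  like any other node and then discarded; only miRNA vectors feed the
  classifier. Negatives during skip-gram training are drawn from the full
  vocabulary (including gene nodes); the embedding objective is agnostic to
  node type once the graph is homogeneous.

Identifiers are matched across resources case-insensitively after trimming
whitespace; no precursor/mature (-5p/-3p) mapping is attempted — ids must
match as given. The miRNA universe is the union of both networks' miRNA
sets, and a miRNA present in only one network carries zeros in the other
network's 512-column feature block, with presence flags recorded.

## Walks and skip-gram

Second-order bias: from current node *v* with previous node *t*, neighbor
*x* is scored w(v,x)·α with α = 1/p (return), 1 (common neighbor of *t*),
1/q (outward). Defaults p = 10, q = 0.5; the first step of each walk is
plain weight-proportional (there is no previous node). p = q = 1 is exactly
DeepWalk, verified against an independent weight-proportional oracle.
Walk-corpus and training defaults follow the reference node2vec/word2vec
values — 10 walks of length 80 per node, window 10, 5 negatives, 5 epochs,
initial learning rate 0.025 with linear decay — since the source protocol
leaves them "in default". Input vectors start uniform in [−0.5/d, 0.5/d],
context vectors at zero.

Training batches pair-gradients for vectorization. A batch is capped at 1/50
of an epoch's pairs: gradients inside a batch are accumulated at fixed
parameters, so on a tiny corpus a batch containing a node dozens of times
would take an oversized, divergent step. With the cap, batched updates stay
close to the sequential per-pair SGD they approximate. The exact softmax
objective is implemented separately as a small-graph oracle (O(V²)) used
only in tests; production training always uses negative sampling.

## Encoder

The stack (conv 16×(1×3) same-padding → dense ReLU FC of the conv-output
size → 1×2/stride-2 max-pool → linear 256-d code FC → 50% dropout → 2-way
softmax head) is implemented with explicit forward/backward passes in
numpy. Design points:

* The ReLU FC "of the same neuron size as the conv output" is read
  literally as a dense 16w → 16w map on the flattened conv output (a
  per-position channels-map variant is available behind
  `hidden_mode="per_position"`).
* Convolution is linear ('same' zero-padding, stride 1 — the only choice
  that keeps the printed 16×w map); the ReLU nonlinearity lives in the FC
  hidden layer, as described.
* Pooling halves the length axis per channel; ties in max-pooling break to
  the first element (argmax convention), making the pass deterministic.
* Dropout uses inverted scaling at train time; class index 1 is the
  disease-associated class.
* Optimizer: Adam, lr 1e-3, batch 32, up to 100 epochs with early stopping
  on a training-loss plateau (patience 10, tol 1e-4). The training
  procedure is named only as backpropagation in the source protocol; these
  are declared defaults, all overridable.
* Parameters and activations are float32 by default; gradient-check tests
  run the same code in float64.
* Inputs are consumed raw (no standardization), matching the protocol's
  silence; `standardize=True` enables z-scoring.

Ablation variants each remove exactly one named layer and keep the 256-d
code and head: `relu_fc_ablation` (conv feeds pooling), `pool_ablation`
(the flattened 16×w hidden map feeds the code FC), `conv_ablation` (the raw
width-w input feeds the ReLU FC, resized accordingly).

## Classifier

Gaussian Naive Bayes on the 256-d codes with the standard defaults:
priors = class frequencies, per-class sample moments, variance smoothing
1e-9 × (largest feature variance). Posteriors are evaluated in log space
with log-sum-exp, so far-from-mean inputs cannot underflow to NaN. The
stage is pluggable: any estimator with fit/predict_proba over codes can be
passed to `CnnGnbClassifier(classifier=...)`, but only GaussianNB ships.

## Evaluation protocol

Positive-unlabeled: negatives are sampled uniformly without replacement
from the unlabeled miRNAs, once per experiment (not per fold), at ratio×
the positive count, or the entire pool for ratio "all". Folds are
stratified (with ~100 positives against thousands of negatives,
unstratified folds can lack positives entirely). Embedding happens once on
the full networks, not per fold: labels play no role in the embedding
stage, so no label information leaks into the features. F1 thresholds the
positive posterior at 0.5 — the classifier's own decision rule. ROC-AUC
uses the Mann–Whitney tie convention (ties count ½); PR-AUC is the
average-precision step sum Σ(Rₖ−Rₖ₋₁)Pₖ, not a trapezoidal interpolation.
These conventions are fixed and tested because they move third-decimal
results. Mean curves (ROC on a 101-point FPR grid, PR on a 101-point recall
grid) with std bands across folds are exported for plotting. Candidate
ranking trains on all labeled data, scores every unlabeled miRNA, and
breaks posterior ties lexicographically by id.

## Synthetic data

The generator plants the exact structure the method assumes: positives
form a similarity block (`sim_within`, default 0.6) over a background
(`sim_background`, 0.15) with mirrored upper-triangle Gaussian noise
(σ = 0.05) clipped to [0,1] and unit diagonal — symmetry is exact by
construction. Every miRNA receives `targets_per_mirna` (40) distinct
targets; positives draw each target from a shared pool of 200 genes with
probability 0.7. A `missing_frac` (10%) of miRNAs is removed from exactly
one network so zero-padding is exercised. The standard benchmark is 500
miRNAs / 2000 genes / 100 positives (seed 42), mimicking the scale of the
real similarity resource (~500 miRNAs, ~100 disease positives).

What the generator does **not** emulate: real degree distributions (target
counts are uniform per miRNA), the long-tailed similarity spectrum of real
MISIM matrices, correlated evidence between the two networks beyond the
shared positive set, and label noise (real disease annotations are
incomplete — the PU protocol addresses that at evaluation time, not in the
generator). Passing tests therefore demonstrate that the pipeline recovers
the kind of community-plus-shared-target signal the method is built for;
they do not certify performance levels on real databases.

## Problem sizes in tests and the acceptance script

The benchmark experiments run with 32 dimensions per network (fused 64),
4 walks of length 40, window 5, 3 skip-gram epochs, and encoder training of
up to 15 epochs (batch 64, patience 4). These are the package's standard
benchmark-scale settings; library defaults remain the full-scale values
above. The planted signal at benchmark scale is strong, so the pipeline's
cross-validated ROC-AUC sits near 1.0 and the permuted-label null near 0.5.

The negative-ratio trend experiment needs a 50× negative sample, which the
500-miRNA benchmark cannot supply (its unlabeled pool is 400); it runs on a
planted-signal dataset with the same generative parameters but 2400 miRNAs
and 30 positives, where ratios 2, 10, 50 and "all" are all feasible and
prevalence spans 0.33 down to 0.013.

## Known limitations

* The similarity graph is dense, so walk generation is O(n) per step; very
  large similarity matrices (≫10⁴ nodes) would need alias tables or edge
  pruning.
* The dense ReLU FC layer is quadratic in the fused width (a 1024-wide
  input gives a 16384² weight matrix, ~1 GiB in float32); training at full
  width on large datasets is CPU- and memory-hungry. The encoder is
  architecture-faithful rather than optimized.
* Only binary classification is supported; the classifier head and NB
  stage assume exactly two classes.
* Determinism guarantees hold in single-threaded execution; multi-threaded
  BLAS may reorder floating-point reductions.
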