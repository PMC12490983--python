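# Methods

## The prioritization model

`hyperad` casts disease-gene prioritization as transductive node
classification on a hypergraph. The hypergraph is built from annotated
gene-set collections (GMT lines): the gene universe is the union of the
retained sets' members, each set becomes one hyperedge, and the sparse
binary incidence matrix `H` (genes × sets) is the only structural input.
Gene rows are ordered lexicographically and set columns keep input order,
so every derived matrix is deterministic.

The working assumption is guilt-by-association lifted to higher order:
genes that repeatedly co-occur with known disease genes inside
functionally coherent sets are themselves candidates. Two design elements
encode this:

1. **Disease-specific hyperedge weights** `w(e) = |N(e) ∩ V_d| / δ(e)` —
   the fraction of a hyperedge's members that are known disease genes.
   Hyperedges representing disease-relevant biology get weights near 1 and
   dominate the set→gene messages; irrelevant hyperedges are damped toward
   0. The denominator is the hyperedge degree over the *constructed*
   universe, so genes dropped by the size filter never inflate it. In
   cross-validation the weights are recomputed from each training fold's
   positives only; held-out labels have no channel into the fit.
2. **Two-stage message passing with a residual.** Each block first pools
   degree-normalized gene embeddings into a hyperedge embedding, then
   pools weighted hyperedge embeddings back into genes, adding the gene's
   previous embedding before the nonlinearity. The residual preserves
   gene-specific information when all incident hyperedges are
   down-weighted; a gene incident only to zero-weight hyperedges reduces
   to `relu` of its own embedding.

The one-hot input layer is realized as an embedding-table lookup — with
one-hot rows, `x·Θ₀` selects rows of `Θ₀`, so the two are algebraically
identical and the N×N input matrix is never materialized.

### Numerical and optimization choices

* The network, gradients and Adam are implemented directly in numpy. All
  gradients are analytic (softmax–cross-entropy head, relu masks, sparse
  adjoints of the two aggregation operators); this keeps runs bit-for-bit
  reproducible on one device under a fixed seed, which the evaluation
  protocol relies on.
* Loss: mean cross-entropy over the labeled training genes. Adam makes
  the mean/sum distinction a pure rescaling of the learning rate; the
  mean keeps the default rate independent of label-set size.
* Degree normalization in the gene→set stage defaults to **unweighted**
  node degrees (count of incident hyperedges). Weighted degrees
  `Σ_e w(e)H(v,e)` are available (`degree_norm_mode="weighted"`) but can
  vanish when a disease weighting zeroes every hyperedge at a node, which
  would divide by zero mid-forward; the unweighted count is strictly
  positive for any constructed hypergraph. The Laplacian and the HGNN
  baseline layer, whose normalizations are intrinsically weight-coupled,
  instead raise an informative error on zero degrees.
* Defaults: embedding dimension 128, 2 message-passing blocks, relu,
  learning rate 1e-3, 200 epochs, Adam(β₁=0.9, β₂=0.999), Xavier-uniform
  initialization, zero biases, no dropout, no early stopping. A seed is
  part of the model configuration, not an optional extra.
* Class imbalance is left to plain unweighted cross-entropy (an optional
  rebalancing is deliberately not a default); the evaluation instead
  controls the positive:negative ratio by sampling the negative set.

### Evaluation protocol

Repeated stratified k-fold cross-validation (default 10 repetitions × 5
folds). Per repetition, a negative set (default up to 1,000 genes) is
sampled from the non-disease pool — resampled each repetition by default,
with a fixed-once mode behind a flag since either reading of the protocol
is defensible — folds are stratified by class, and each fold trains from
scratch with fold-specific seeds derived deterministically from the CV
seed. AUROC is the rank statistic P(score⁺ > score⁻) + ½P(tie); AUPRC is
average precision with step interpolation (trapezoidal interpolation of
precision–recall is optimistic and is not used). Genome-wide output is
the gene list sorted by risk score, ties broken lexicographically,
with known positives excluded.

## Validation statistics

* **Decile enrichment.** The ranking is cut into 10 near-equal contiguous
  bins (remainders go to the earlier bins). Per term: per-bin member
  fractions, the hypergeometric upper tail P(X ≥ overlap) for the first
  bin (universe = ranking length, draws = first-bin size), and BH FDR
  across terms. Terms with no member in the ranking are skipped with a
  warning rather than failing the batch.
* **Network association.** Statistic: number of network edges joining the
  candidate set to the known disease-gene set (duplicate/self edges are
  dropped; candidates absent from the network are excluded and reported).
  Null: size-matched gene sets drawn uniformly from the network genes
  excluding the known set; `p = (1 + #{null ≥ obs}) / (1 + n_perm)`, so p
  is never zero and never below `1/(n_perm+1)`. The default
  `n_perm = 10,000` resolves p-values to 1e-4. The null does not preserve
  the degree sequence; with strongly heterogeneous degree distributions a
  degree-aware null would be more conservative — this is a known
  limitation of the uniform construction.
* **Monotone expression trend.** Per gene, Kendall tau-b against the
  ordinal stage vector, with tie corrections on both margins and the
  normal-approximation p-value (appropriate at cohort-scale n; exact
  enumeration is only used by the test oracles at tiny n). Genes constant
  across samples have undefined tau and are recorded as tau = NaN, p = 1,
  direction `none`. Missing expression values are dropped pairwise per
  gene. BH across genes; a gene is called trending when FDR < 0.05 and
  its direction is the sign of tau.
* **Multiple testing** is Benjamini–Hochberg throughout (the procedure
  is exposed directly and configurable at the call sites).

## Synthetic benchmarks

The generators produce the smallest data that still exercises every code
path with realistic structure:

* **Planted-module hypergraph** (default 300 genes, 30 disease genes, 40
  relevant + 120 background hyperedges, sizes 5–25): each member of a
  relevant hyperedge is a disease gene with probability 0.8, otherwise
  uniform; background hyperedges are uniform. Half the disease genes are
  exposed as training positives; 100 negatives are sampled from
  non-disease genes, keeping roughly the 1:7 positive:negative ratio of a
  curated-disease setting. These defaults train in under two seconds on
  one CPU.
* **Staged expression** (default 500 genes, 50 trend genes, stage groups
  174/100/104): trend genes have their group mean shifted by ±0.5 per
  stage step (sign random per gene and recorded, so up- and
  down-regulated trends are both represented), noise is iid N(0, 1).
  A ±0.5σ shift per stage is a moderate proteomic effect — strong enough
  that the trend test should find nearly all planted genes at this cohort
  size, so the benchmark measures FDR control as much as power.
* **Toy network**: planted candidate–known edges over an Erdős–Rényi
  background.

What the generators do *not* emulate: overlapping/nested real gene-set
hierarchies (GO term redundancy), scale-free degree distributions,
batch effects or heteroscedastic noise in expression, and correlated
genes. Passing benchmarks therefore demonstrate correctness of the
machinery and sensible behaviour under clean planted signal, not expected
performance on real cohorts.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the planted benchmark at
its default scale (300 genes × 160 hyperedges), with 5 seeds for
held-out recovery, 10 seeds × 3-fold CV for the weighting ablation,
200 simulated datasets for permutation-p calibration, and 3 seeds of the
174/100/104 expression cohort for the trend test — sizes chosen so a full
from-scratch reproduction completes in a few minutes on a single CPU
while keeping every statistic's sampling error well inside its decision
margin.

## Known limitations

* Gene symbols are matched verbatim; there is no alias/namespace mapping,
  so inputs must share one nomenclature.
* The model is transductive: scoring new genes requires rebuilding the
  hypergraph and retraining.
* Hyperedge weights are a fixed function of the training positives, not
  learned jointly; a learned attention over hyperedges is a natural
  extension.
* The permutation null ignores network degree structure (see above).
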