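# hyperad

A hypergraph neural network for prioritizing disease risk genes from
annotated gene-set collections.

Complex polygenic diseases are driven by the collective action of gene
modules, not isolated pairwise interactions. Conventional network-based
prioritization ("guilt-by-association" on a PPI or functional gene network)
models only binary edges and discards the higher-order structure that
curated gene sets — pathways, ontology terms, regulatory-target sets —
encode directly. `hyperad` keeps that structure intact: genes are nodes,
each annotated gene set is one **hyperedge** connecting all of its members,
and a two-stage message-passing network learns gene embeddings on the
resulting hypergraph and scores every gene's disease association.

The package is aimed at computational biologists who have (a) gene-set
collections in GMT format (e.g. MSigDB), (b) a curated list of known
disease genes and a pool of presumed non-disease genes, and who want a
genome-wide risk ranking plus the statistics to validate it.

## Model

With N genes, M gene sets, incidence matrix `H ∈ {0,1}^{N×M}`
(`H[v,e] = 1` iff gene v belongs to set e), node degree
`d(v) = Σ_e w(e) H(v,e)` and hyperedge degree `δ(e) = Σ_v H(v,e)`:

**Disease-specific hyperedge weights.** Not every pathway is relevant to
one disease; each hyperedge is weighted by the fraction of its members
that are known disease genes `V_d`:

    w(e) = |N(e) ∩ V_d| / δ(e)        ∈ [0, 1]

**Two-stage message passing.** One-hot gene inputs pass through an
embedding layer, then L blocks of

    y_e  = σ( Σ_{v∈N(e)}  x_v / d(v) · Θ_{v→e} )               (gene → set)
    x_v' = σ( Σ_{e∈E(v)}  w(e) · y_e · Θ_{e→v}  +  x_v )       (set → gene, residual)

followed by a softmax head `Z = softmax(x Θ₁ + b₁)`, giving a two-class
probability per gene; column 1 is the risk score. Training is
transductive: the whole hypergraph participates in every forward pass
while the cross-entropy loss touches only labeled training genes, and
`w(e)` is always computed from the training-fold positives alone.
Optimization is Adam; the implementation is pure numpy with analytic
gradients and is bit-for-bit reproducible under a fixed seed.

The classic hypergraph convolution
`σ(D_v^{-1/2} H W D_e^{-1} H^T D_v^{-1/2} X Θ)` and the normalized
hypergraph Laplacian `Δ = I − D_v^{-1/2} H W D_e^{-1} H^T D_v^{-1/2}`
are provided for baseline comparisons and spectral sanity checks.

Around the model the package supplies the full evaluation protocol
(repeated stratified cross-validation with AUROC/AUPRC), three downstream
validation statistics (first-decile hypergeometric enrichment of a ranked
list, permutation tests of candidate-to-known network connectivity,
per-gene Kendall tau-b monotone-trend tests across ordered disease stages
with BH FDR), and seeded synthetic-data generators so the entire pipeline
runs without external downloads.

## Worked example

`examples/02_train_and_rank.py` builds a 300-gene benchmark in which 30
genes form a planted disease module co-occurring in "relevant" hyperedges,
trains on 15 of them plus 100 negatives, and ranks the rest:

```
benchmark: 299 genes, 160 gene sets, 30 disease genes (15 exposed as positives)
cross-entropy loss: 0.727 -> 0.0837 over 200 epochs

top 20 novel genes contain 15/15 held-out disease genes:
   1. G108 <- held-out disease gene
   2. G120 <- held-out disease gene
   ...
held-out disease-gene AUROC: 1.000
```

Every held-out disease gene lands in the top of the ranking, and the
AUROC of 1.0 says each of them outscores every unlabeled non-disease
gene — the network has propagated the disease signal through the shared
hyperedges, not memorized the training labels. The other example scripts
cover hypergraph construction (`01`), the cross-validated weighting
ablation (`03`), and the three validation statistics (`04`).

A thin CLI wraps the same functions:

```bash
hyperad simulate bench/ --seed 1            # write a synthetic benchmark
hyperad build bench/gene_sets.gmt --out-prefix out/hg
hyperad train bench/gene_sets.gmt --positives bench/positives.txt \
       --negatives bench/negatives.txt --seed 1 --out scores.tsv
hyperad cv bench/gene_sets.gmt --positives bench/positives.txt \
       --negative-pool bench/negatives.txt --reps 10 --folds 5 --seed 1
hyperad validate trend bench/expression.tsv --stages bench/stages.tsv
```

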