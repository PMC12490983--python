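"""Cross-validated evaluation and the hyperedge-weighting ablation.

Runs stratified cross-validation of the model on the planted benchmark
twice — once with disease-specific hyperedge weights w(e) (the fraction of
a gene set's members that are training positives) and once with uniform
weights — and compares AUROC/AUPRC.
"""

from hyperad import (
    CVConfig,
    ModelConfig,
    PlantedHypergraphSpec,
    cross_validate,
    generate_planted_hypergraph,
)

hg, _, disease = generate_planted_hypergraph(PlantedHypergraphSpec(seed=7))
positives = sorted(set(disease) & set(hg.genes))
pool = [g for g in hg.genes if g not in disease]
cv_cfg = CVConfig(n_repetitions=2, n_folds=3, seed=7, negative_pool_size=100)

print(f"{len(positives)} positives, negative pool of {len(pool)}, "
      f"{cv_cfg.n_repetitions} x {cv_cfg.n_folds}-fold CV\n")
for mode in ("ad_weighted", "unweighted"):
    res = cross_validate(hg, positives, pool, ModelConfig(seed=7, weight_mode=mode), cv_cfg)
    print(f"{mode:12s}  AUROC {res.auroc_mean:.3f} +/- {res.auroc_std:.3f}   "
          f"AUPRC {res.auprc_mean:.3f} +/- {res.auprc_std:.3f}")

print("\nWeighting the hyperedge-to-node messages by disease relevance "
      "concentrates the signal\nin the planted module's gene sets, so the "
      "weighted model should match or beat the unweighted one.")
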