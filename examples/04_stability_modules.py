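"""Differential stability and canonical-module association.

DS is the mean Pearson correlation of a gene's regional profile between
donor pairs: genes that follow a planted module are reproducible (DS near 1)
while per-subject random genes center on 0.  Module scores map genes, then
diseases, onto the module eigengenes via Fisher-z averaged correlations.
"""

import numpy as np

import braintx as bt

cfg = bt.SynthConfig(
    n_subjects=3, n_structures=30, n_regions=5, n_modules=6,
    genes_per_module=60, n_unstable_genes=30, n_diseases=12,
    n_disease_groups=3, genes_per_disease=(8, 12),
    subject_noise_sd=0.2, seed=7,
)
expr, eigengenes, truth = bt.synth_subject_expression(cfg)
sets = bt.filter_associations(bt.synth_gda(cfg, truth), min_curated=0, min_genes=5)

ds = bt.differential_stability_all(expr)
stable = [g for g in expr.genes if truth[g] is not None]
unstable = [g for g in expr.genes if truth[g] is None]
print(f"DS of module genes:   mean {ds.loc[stable, 'ds'].mean():.3f}")
print(f"DS of unstable genes: mean {ds.loc[unstable, 'ds'].mean():.3f}")

high, low, thr = bt.ds_partition(ds, quantile=len(unstable) / cfg.n_genes)
print(f"top-DS partition threshold: {thr:.3f}; {len(high)} genes above")

scores = bt.module_scores(expr, eigengenes)
hits = np.mean([scores.values.loc[g].idxmax() == truth[g] for g in stable])
print(f"gene -> module argmax recovery: {100 * hits:.1f}%")

dm = bt.disease_module_matrix(scores, sets)
print("\ndisease -> strongest module (planted group in parentheses):")
groups = bt.planted_group_labels(cfg)
for d in dm.values.index[:6]:
    print(f"  {d}: {dm.values.loc[d].idxmax()}  (group {groups[d]}, planted M{groups[d] + 1})")
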