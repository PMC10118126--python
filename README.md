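# braintx

Anatomic and cell-type transcriptome signatures of brain-disease gene sets.

Brain diseases are usually classified by phenotype, but the genes conferring
risk for a disease have characteristic *expression* signatures in the
neurotypical brain: a regional signature over a brain-structure ontology, and
a cell-type signature in cortex.  `braintx` builds both kinds of signature
from a gene–disease association table and expression matrices, compares and
clusters diseases by them, and quantifies how reproducible and specific the
signatures are.  It is a library for computational neurogenomics analyses of
disease gene sets, with a seeded synthetic-data generator so that every stage
can be exercised and validated without access to donor data.

## What it computes

* **Disease gene sets** — DisGeNET-style filtering (≥ 1 curated source,
  ≥ 10 genes per disease), evidence weighting via the GDA score
  `C + M + I + L` (curated-source tier 0/0.3/0.5/0.6, animal-model 0.2,
  inferred 0.1, literature 0.01·N capped at 0.1), Jaccard overlap and
  class-level shared-gene permutation tests.
* **Anatomic profiles** — disease × structure z-scored mean expression;
  Ward clustering (ward.D2) on `1 − ρ` distance into Anatomic Disease
  Groups; per-structure ANOVA and pairwise *t* tests with Benjamini–Hochberg
  correction; cross-subject identifiability (nearest-signature assignment
  between donors); rank-order signature codes via prime factorization
  `2^r1·3^r2·5^r3·7^r4·11^r5`; gene-subsampling cluster stability.
* **Differential stability** — `DS(g)` = mean Pearson correlation of gene
  *g*'s regional profile over all donor pairs on structures observed in
  both; quantile partition into high/low-DS corpora.
* **Module association** — per-subject correlation with module eigengenes,
  Fisher r-to-z, averaged across subjects, standardized per module
  (μ = 0, σ = 1); disease rows as means over member genes.
* **Cell types** — specificity `τ = Σ(1 − x_i/max x)/(N − 1)`;
  disease × cell-type matrices and Cell Type Groups; expression-weighted
  cell-type enrichment (EWCE) with permutation p-values
  `(1 + #{perm ≥ obs})/(n_perm + 1)`; |cosine| covariation maps thresholded
  at mean + 1.5σ; consensus correlation matrices, 2-D embedding and a
  within/between-class distance ratio.
* **Cross species** — alignment of disease signatures through a homologous
  consensus cell-type map, joint co-clustering, the fraction of diseases
  whose nearest cross-species signature is themselves, and two-sample K-S
  comparison of EWCE distributions.

## Worked example

Scripts in `examples/` each build a small synthetic input, run one
capability, and print what it computes.  For instance:

```bash
$ python examples/04_stability_modules.py
DS of module genes:   mean 0.964
DS of unstable genes: mean -0.014
top-DS partition threshold: 0.884; 360 genes above
gene -> module argmax recovery: 100.0%

disease -> strongest module (planted group in parentheses):
  D001: M1  (group 0, planted M1)
  ...
```

Genes planted in a co-expression module keep their regional pattern in every
synthetic donor, so their differential stability is near 1 while per-donor
random genes center on 0; every module gene's strongest eigengene correlation
recovers its planted module, and each disease's module profile peaks at the
module its gene set was drawn from.

The full pipeline (synthetic inputs → filtering → profiles/ADG → DS/modules
→ cell types/EWCE → cross-species) runs from a YAML config and writes every
artifact with a checksum into a run manifest:

```bash
braintx run --config config.yaml      # or: braintx synth / gda-filter / cluster / ewce ...
```

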