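# Methods

This note records the models and procedures `braintx` implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely open.

## Disease gene sets and evidence weighting

A gene–disease association (GDA) table is a long-format record set
(disease, GBD phenotypic class, gene, evidence counts N1–N4).  Filtering
keeps records with at least `min_curated` curated sources (default 1) and
diseases with at least `min_genes` surviving genes (default 10); gene
symbols are uppercased and stripped, and symbols absent from the expression
matrix in use are dropped with a logged warning rather than an error — how
unmeasured symbols should be treated is not otherwise specified, and
silently zero-filling them would bias profile means.

The evidence weight of one association is

```
GDA = C(N1) + M(N2) + I(N3) + L(N4)
C = 0, 0.3, 0.5, 0.6   for N1 = 0, 1, 2, >2      (curated sources)
M = 0.2·[N2 > 0]                                  (animal models)
I = 0.1·[N3 > 0]                                  (inferred sources)
L = 0.01·N4 if N4 ≤ 9 else 0.1                    (publications)
```

so the maximum weight 1.0 requires ≥ 3 curated sources, an animal model, an
inferred source and ≥ 10 publications.

Class-level overlap is reported as the mean pairwise shared-gene percentage
among the diseases of a class.  Because "percent shared" does not pin a
normalization, both mean pairwise Jaccard ×100 (default) and
|∩|/min(|A|,|B|) ×100 are available; the permutation test (shuffling the
disease → class assignment, preserving class sizes) applies to whichever is
selected.  All permutation p-values use the pseudocount form
`p = (1 + k)/(n_perm + 1)` so p is never 0.  Note that when gene sets are
largely disjoint the overlap statistic has an atom at zero and permutation
p-values become conservative (super-uniform); the uniformity property holds
for effectively continuous statistics.

## Anatomic profiles and Anatomic Disease Groups

Per subject, a disease's profile is the (optionally GDA-weighted) mean of
its measured genes' expression at each structure.  Subject profiles are
averaged structure-wise first and the pooled row is z-scored across
structures last (averaging before normalizing matches the construction of a
single representative expression matrix from multiple donors); per-subject
profiles kept for holdout analyses are z-scored within subject.  A structure
masked in a subject (absent tissue) is NaN throughout and drops out of that
subject's average; it is never zero-filled.

Clustering uses the distance `1 − ρ` (Pearson between profile rows) with
Ward linkage under the ward.D2 convention — scipy's `linkage(..., "ward")`
on a condensed distance matrix applies the squared-distance Lance–Williams
update, matching R `hclust`'s `ward.D2` — cut to `k` clusters (ADG k = 5,
CTG k = 4 by default).  Cluster ids are renumbered in order of first
appearance, and scipy's deterministic merge order breaks ties by input
order.  Constant (zero-variance) rows have undefined correlation and raise
an error naming the offending disease.

Structure-wise tests are one-way ANOVA across groups on disease-level
z-scores at each structure (disease rows are the displayed observations;
subject×disease observations would inflate n), followed by all pairwise
two-sided unpaired t tests; BH correction is applied across structures for
the ANOVA family and across structure × group-pair for the t family.
Degenerate inputs (all observations equal) are reported as F = 0, p = 1
rather than NaN.

Cross-subject identifiability: for each subject s and disease d, the most
similar profile among all diseases in every other subject is found (Pearson
similarity, or mean-squared Euclidean distance over jointly observed
structures); ties break to the lowest disease index.  Exact-disease,
same-ADG and same-GBD hit frequencies are tallied over the
n·(n−1) subject-ordered comparisons, with an option to exclude the disease's
own profile from candidacy.  The rank order of 5 group means at a structure
is encoded by unique prime factorization `2^r1·3^r2·5^r3·7^r4·11^r5`
(ranks 1–5 ascending), which is injective over the 120 orderings; exact
ties raise by default or rank by input position under `stable-order`.

## Differential stability and module association

`DS(g)` is the unweighted mean over all subject pairs of the Pearson
correlation of g's profile across the structures observed in both members
of the pair (pairwise-present structures, not the global intersection);
pairs sharing fewer than 3 structures are skipped with a warning, and DS is
an error only if every pair is skipped.  The high/low partition takes genes
strictly above a configurable DS quantile (default the median); the source
atlas' fixed numeric threshold is a corpus median, so a quantile rather
than a constant is the portable definition.

Module scores correlate each gene with each module eigengene within each
subject over the eigengene's structures, clip r to ±(1 − 1e−6) (atanh
diverges at ±1), Fisher-transform, and average z across subjects.  Each
module column is then standardized (μ = 0, σ = 1) over **all** genes scored
in the run, not only disease genes — the corpus-wide reading of the
standardization.  Disease rows are exact arithmetic means of their member
genes' standardized rows.

## Cell-type analyses

CPM normalization scales each cell-type row to 1e6; a zero row is an error
naming the cell type.  Specificity is `τ = Σ_i (1 − x_i/max x)/(N − 1)`;
τ is scale-invariant, 0 for uniform and 1 for one-hot expression, and
undefined (error) for an all-zero vector.

Disease × cell-type matrices average `log1p(CPM)` of the disease's genes
per cell type (the displayed quantity is CPM and the transform is not
specified; `log1p` tames heavy-tailed abundances and `linear` is available),
z-score rows, and cluster as above.  Pooled per-group τ significance uses
same-size random gene sets from the measured corpus.

EWCE scores a gene set by its summed per-gene specificity fractions
`s(g,c) = expr(g,c)/Σ_c expr(g,c)` per cell type — the specificity-
normalized form, which cancels any per-gene scaling; raw-CPM scoring is an
option.  The null draws `n_perm` same-size sets from the background (all
measured genes excluding the target set) without replacement within each
set; `p(c) = (1 + #{perm ≥ obs})/(n_perm + 1)`, fold = observed/null mean,
BH across cell types per disease.  The production default is
`n_perm = 100,000`; tests and the acceptance script use 2,000, which bounds
the Monte-Carlo error of a 0.05-level decision at about ±0.005 while keeping
desk-scale runtimes.  Permutation draws are chunked so the
celltypes × chunk × set-size gather stays near 40 MB.

Covariation maps compare cell types as vectors over a disease's *unique*
(single-disease) genes, per-gene max-normalized by default so
high-magnitude genes do not dominate (raw vectors available); entry (i, j)
is |cosine|.  "1.5σ" thresholding is read as mean + 1.5·sd of that
disease's own off-diagonal entries (per-matrix, not pooled — each disease's
gene set induces its own covariation scale); both the multiplier and the
normalization are configurable.  Cell types with all-zero expression over
the gene set get zeroed pairs with a warning.

The consensus matrix is the elementwise mean of the structural and
cell-type disease correlation matrices.  The 2-D embedding is pluggable:
classical metric scaling of `1 − r` (deterministic eigendecomposition) is
the default, with umap-learn as the optional nonlinear embedder — all
quantitative results are computed on the matrices feeding the embedding,
never on a particular embedder's coordinates.  The class-cohesion ratio of
a disease is its mean embedded distance to same-GBD diseases divided by its
mean distance to different-GBD diseases (NaN without a same-class partner).

## Cross-species comparison

A homology map sends each species' cell types to consensus types (each type
to at most one consensus); consensus types missing measured columns on
either side are dropped, not zero-filled.  Aligned disease × consensus EWCE
matrices are stacked with species tags and co-clustered; the headline
statistic is the fraction of species-tagged rows whose most correlated row
in the other species is the same disease (Pearson on signature vectors;
Euclidean available).  Distribution-level comparison uses the asymptotic
two-sample Kolmogorov–Smirnov test.

## Synthetic-data generator

The generator plants exactly the structure the statistics assume:

* **Subjects** (default 6 donors × 104 structures in 15 parent regions):
  each of 32 module eigengenes is a standardized random pattern over
  structures; a module gene's profile is `pattern + N(0, σ)` independently
  per subject with σ = `subject_noise_sd` (default 0.3, i.e. 30% of the
  unit pattern sd); unstable genes get a fresh random pattern per subject.
  Defaults give 271 genes per module (8,672 module genes) plus 8,676
  unstable genes — a 17,348-gene corpus whose top-DS half is the module
  corpus, mirroring the scale of the source atlas.  Values are log-scale
  expression units; a per-subject structure-dropout probability (default 0)
  exercises the masked-structure contracts.
* **Cell types** (default 20 types in 3 classes, subclasses pairing
  adjacent types): each gene concentrates `marker_specificity` (default
  0.8) of its expression in one marker type — module genes map to types by
  module index so planted disease groups align with disjoint marker pools —
  with the remainder uniform; gene abundances are log-normal; rows are CPM.
  The mouse matrix perturbs the human one by a per-entry log-normal species
  effect (sd 0.1) on homologous types, giving conserved signatures with
  species-specific expression.
* **Diseases** (default 40 in 5 groups): group g draws its diseases'
  gene sets disjointly from module M(g+1)'s pool, then swaps in an
  `overlap_rate` fraction (default 0.1) of a same-group neighbour's genes,
  so within-group overlap is exactly controlled (empty at rate 0).  Set
  sizes are uniform in `genes_per_disease` (default 15–35, sized so a
  group's disjoint draws cannot exhaust a 271-gene pool).  Evidence counts
  N1–N4 are Poisson with means (2.0, 0.5, 0.5, 3.0), so the default
  curated-evidence filter removes a realistic minority of records.

Each generator draws from an RNG stream keyed by `(seed, generator-id)`, so
identical configs are bit-reproducible and adding one generator call never
perturbs another's output.

What the generator does **not** emulate: read counts or UMI sampling,
probe-level microarray noise, correlated module eigengenes, region-size
imbalance, gene–gene co-expression beyond module membership, and diseases
spanning several modules.  Passing recovery tests therefore demonstrates
correctness of the statistics under the planted model, not performance on
donor data — in real data modules correlate, gene sets straddle patterns,
and class boundaries are far softer.

A consequence of the planted design worth stating: diseases in the same
group share one eigengene, and per-subject noise is independent across
subjects, so *exact-disease* identifiability within a group is at chance by
construction.  Identifiability conditions (exact-match frequency,
assignment-diagonal dominance, cross-species self-pairing) are therefore
exercised on configurations with one module per disease — distinct planted
signatures — while group-recovery conditions (ARI, module argmax, DS
separation) use the 5-group configuration.

## Problem sizes and determinism

The test suite runs small cohorts (3 subjects, 30 structures, 6 modules,
12 diseases) for unit checks and the full study scale (6 × 104 × 32 × 40)
for recovery checks; ADG recovery is asserted over 20 seeds, EWCE
calibration over 1,000 null sets at 2,000 permutations, and the
permutation-uniformity property over 170 replicates of 99 label shuffles.
`scripts/acceptance.py` recomputes everything from scratch at study scale
in about a minute; every stochastic stage takes an explicit seed, and the
pipeline manifest records a sha256 checksum per artifact so reruns are
verifiable.

## Known limitations

* The ANOVA observation unit is the disease row; donor-level variance is
  not propagated into the structure tests.
* Permutation p-values are conservative when the statistic is heavily tied
  (disjoint gene sets, zero overlaps).
* The Euclidean identifiability metric uses mean squared difference over
  jointly observed structures, which differs from true Euclidean distance
  when subjects mask different structure subsets.
* Cross-species homology is consumed, not inferred; one-sided consensus
  types are dropped rather than imputed.
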