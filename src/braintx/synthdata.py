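"""Seeded generators for synthetic study inputs.

The generators emulate the statistical structure of the study's four inputs:

* per-subject structure × gene expression matrices built from planted module
  eigengenes plus independent per-subject noise (log-scale units, as for
  microarray log-intensities), with a structure ontology mapping each of the
  structures to a parent region;
* cell-type × gene mean-expression matrices (CPM) for two species, with a
  planted marker structure (each gene concentrates a configurable fraction of
  its expression in one cell type) and a cell-type homology map;
* a DisGeNET-style gene–disease association table whose diseases are grouped,
  each group drawing its genes from one planted module, with controlled
  within-group overlap and Poisson evidence counts.

Each generator draws from its own RNG stream derived from ``(seed, k)`` with a
fixed per-generator ``k``, so adding or reordering generator calls does not
perturb the output of the others.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SynthConfig",
    "SubjectExpressionSet",
    "ModuleEigengenes",
    "synth_subject_expression",
    "synth_cell_expression",
    "synth_gda",
]

# Fixed stream indices so the three generators are mutually independent.
_STREAM_SUBJECT = 1
_STREAM_CELL = 2
_STREAM_GDA = 3

# GBD phenotypic classes used to label planted disease groups.
GBD_CLASSES = (
    "psychiatric",
    "neurodegenerative",
    "substance_abuse",
    "tumor",
    "developmental",
    "movement",
    "other",
)


class ConfigurationError(ValueError):
    """Raised when a SynthConfig (or derived request) is not satisfiable."""


@dataclass(frozen=True)
class SynthConfig:
    """Dimensions and noise levels of the synthetic cohort.

    Defaults mirror the study's scale: 6 donor brains, 104 brain structures in
    15 parent regions, 32 co-expression modules, 40 diseases in 5 planted
    groups, and a 20-type cell taxonomy (the subclass level at which the
    cross-species comparison operates).
    """

    n_subjects: int = 6
    n_structures: int = 104
    n_regions: int = 15
    n_modules: int = 32
    genes_per_module: int = 271
    n_unstable_genes: int = 8676
    subject_noise_sd: float = 0.3
    structure_dropout: float = 0.0
    n_celltypes: int = 20
    n_classes: int = 3
    marker_specificity: float = 0.8
    species_effect_sd: float = 0.1
    n_diseases: int = 40
    n_disease_groups: int = 5
    genes_per_disease: tuple[int, int] = (15, 35)
    overlap_rate: float = 0.1
    evidence_rates: tuple[float, float, float, float] = (2.0, 0.5, 0.5, 3.0)
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_subjects": self.n_subjects,
            "n_structures": self.n_structures,
            "n_regions": self.n_regions,
            "n_modules": self.n_modules,
            "genes_per_module": self.genes_per_module,
            "n_celltypes": self.n_celltypes,
            "n_classes": self.n_classes,
            "n_diseases": self.n_diseases,
            "n_disease_groups": self.n_disease_groups,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise ConfigurationError(f"{name} must be a positive integer, got {value!r}")
        if self.n_unstable_genes < 0:
            raise ConfigurationError("n_unstable_genes must be >= 0")
        if self.subject_noise_sd < 0:
            raise ConfigurationError("subject_noise_sd must be >= 0")
        if not 0.0 <= self.structure_dropout < 1.0:
            raise ConfigurationError("structure_dropout must be in [0, 1)")
        if not 0.0 <= self.marker_specificity <= 1.0:
            raise ConfigurationError("marker_specificity must be in [0, 1]")
        if not 0.0 <= self.overlap_rate <= 1.0:
            raise ConfigurationError("overlap_rate must be in [0, 1]")
        lo, hi = self.genes_per_disease
        if lo < 1 or hi < lo:
            raise ConfigurationError("genes_per_disease must be a (low, high) range with 1 <= low <= high")
        if len(self.evidence_rates) != 4 or any(r < 0 for r in self.evidence_rates):
            raise ConfigurationError("evidence_rates must be 4 non-negative means")
        if self.n_regions > self.n_structures:
            raise ConfigurationError("n_regions cannot exceed n_structures")
        if self.n_classes > self.n_celltypes:
            raise ConfigurationError("n_classes cannot exceed n_celltypes")
        if self.n_disease_groups > min(self.n_diseases, self.n_modules):
            raise ConfigurationError("n_disease_groups cannot exceed n_diseases or n_modules")

    @property
    def n_genes(self) -> int:
        return self.n_modules * self.genes_per_module + self.n_unstable_genes

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["genes_per_disease"] = list(self.genes_per_disease)
        d["evidence_rates"] = list(self.evidence_rates)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        d = dict(d)
        if "genes_per_disease" in d:
            d["genes_per_disease"] = tuple(d["genes_per_disease"])
        if "evidence_rates" in d:
            d["evidence_rates"] = tuple(d["evidence_rates"])
        return cls(**d)


@dataclass
class SubjectExpressionSet:
    """Per-subject structure × gene matrices on shared axes.

    ``matrices[s]`` is a structures × genes DataFrame for subject
    ``subjects[s]``; a structure absent in a subject is a row of NaN (masked,
    never zero-filled).  ``ontology`` maps each structure to its parent region.
    """

    subjects: list[str]
    matrices: list[pd.DataFrame]
    structures: list[str]
    ontology: dict[str, str]
    genes: list[str]

    def __post_init__(self) -> None:
        for m in self.matrices:
            if list(m.index) != list(self.structures) or list(m.columns) != list(self.genes):
                raise ValueError("all subject matrices must share the structure and gene axes")


@dataclass
class ModuleEigengenes:
    """Module × structure characteristic expression patterns.

    Each pattern is standardized (mean 0, sd 1) across structures.
    """

    modules: list[str]
    patterns: pd.DataFrame  # modules × structures
    celltype_order: list[str] | None = None


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    x = x - x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _gene_names(config: SynthConfig) -> tuple[list[str], dict[str, str | None]]:
    genes: list[str] = []
    truth: dict[str, str | None] = {}
    for m in range(config.n_modules):
        for j in range(config.genes_per_module):
            g = f"G{m * config.genes_per_module + j + 1:05d}"
            genes.append(g)
            truth[g] = f"M{m + 1}"
    base = config.n_modules * config.genes_per_module
    for j in range(config.n_unstable_genes):
        g = f"G{base + j + 1:05d}"
        genes.append(g)
        truth[g] = None
    return genes, truth


def synth_subject_expression(
    config: SynthConfig,
) -> tuple[SubjectExpressionSet, ModuleEigengenes, dict[str, str | None]]:
    """Generate per-subject expression from planted module eigengenes.

    A gene in module m has profile ``pattern_m + N(0, subject_noise_sd)``
    independently in each subject; an unstable gene gets a fresh standardized
    random pattern per subject.  Returns the expression set, the eigengene
    patterns, and the gene → module truth map (None for unstable genes).
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, _STREAM_SUBJECT)))
    structures = [f"S{i + 1:03d}" for i in range(config.n_structures)]
    # contiguous partition of structures into parent regions
    bounds = np.linspace(0, config.n_structures, config.n_regions + 1).astype(int)
    ontology: dict[str, str] = {}
    for r in range(config.n_regions):
        for i in range(bounds[r], bounds[r + 1]):
            ontology[structures[i]] = f"R{r + 1:02d}"

    modules = [f"M{m + 1}" for m in range(config.n_modules)]
    patterns = _standardize_rows(rng.standard_normal((config.n_modules, config.n_structures)))
    eigengenes = ModuleEigengenes(
        modules=modules,
        patterns=pd.DataFrame(patterns, index=modules, columns=structures),
    )

    genes, truth = _gene_names(config)
    module_idx = np.array(
        [int(truth[g][1:]) - 1 if truth[g] is not None else -1 for g in genes]
    )
    stable = module_idx >= 0

    subjects = [f"B{s + 1}" for s in range(config.n_subjects)]
    matrices: list[pd.DataFrame] = []
    for _ in subjects:
        x = np.empty((config.n_structures, len(genes)))
        # module genes: shared eigengene pattern + independent noise
        x[:, stable] = patterns[module_idx[stable]].T
        if config.subject_noise_sd > 0:
            x[:, stable] += rng.normal(
                0.0, config.subject_noise_sd, size=(config.n_structures, int(stable.sum()))
            )
        # unstable genes: a fresh random standardized pattern in every subject
        n_unstable = int((~stable).sum())
        if n_unstable:
            x[:, ~stable] = _standardize_rows(
                rng.standard_normal((n_unstable, config.n_structures))
            ).T
        if config.structure_dropout > 0:
            drop = rng.random(config.n_structures) < config.structure_dropout
            x[drop, :] = np.nan
        matrices.append(pd.DataFrame(x, index=structures, columns=genes))

    expr = SubjectExpressionSet(
        subjects=subjects,
        matrices=matrices,
        structures=structures,
        ontology=ontology,
        genes=genes,
    )
    return expr, eigengenes, truth


def _marker_assignment(config: SynthConfig, genes: list[str], truth: dict[str, str | None]) -> np.ndarray:
    """Assign each gene a marker cell type; module genes map by module so that
    planted disease groups (one module each) align with disjoint marker pools."""
    idx = np.empty(len(genes), dtype=int)
    for i, g in enumerate(genes):
        module = truth[g]
        if module is not None:
            idx[i] = (int(module[1:]) - 1) % config.n_celltypes
        else:
            idx[i] = i % config.n_celltypes
    return idx


def _taxonomy(config: SynthConfig, celltypes: list[str]) -> pd.DataFrame:
    n = config.n_celltypes
    cls = [f"class{(i * config.n_classes) // n + 1}" for i in range(n)]
    sub = [f"sub{i // 2 + 1}" for i in range(n)]
    return pd.DataFrame({"celltype": celltypes, "cls": cls, "subclass": sub}).set_index("celltype")


def synth_cell_expression(config: SynthConfig, truth: dict[str, str | None] | None = None):
    """Generate human and mouse cell-type × gene CPM matrices plus a homology map.

    Each gene concentrates a ``marker_specificity`` fraction of its expression
    in one marker cell type, spreading the remainder uniformly; homologous
    types share marker identity, with a per-entry log-normal species effect of
    sd ``species_effect_sd`` perturbing the mouse matrix.  Rows are CPM
    (sum 1e6 across genes).
    """
    from .celltype import CellTypeExpressionMatrix, cpm_normalize

    if config.n_celltypes < 2:
        raise ConfigurationError("synth_cell_expression requires n_celltypes >= 2")
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, _STREAM_CELL)))
    genes, truth_map = _gene_names(config)
    if truth is None:
        truth = truth_map
    celltypes_h = [f"HT{i + 1:02d}" for i in range(config.n_celltypes)]
    celltypes_m = [f"MT{i + 1:02d}" for i in range(config.n_celltypes)]

    marker = _marker_assignment(config, genes, truth)
    abundance = rng.lognormal(mean=0.0, sigma=0.5, size=len(genes))
    spec = config.marker_specificity
    base = np.full((config.n_celltypes, len(genes)), (1.0 - spec) / config.n_celltypes)
    base[marker, np.arange(len(genes))] += spec
    raw_h = base * abundance[None, :]

    if config.species_effect_sd > 0:
        raw_m = raw_h * rng.lognormal(0.0, config.species_effect_sd, size=raw_h.shape)
    else:
        raw_m = raw_h.copy()

    tax_h = _taxonomy(config, celltypes_h)
    tax_m = _taxonomy(config, celltypes_m)
    human = cpm_normalize(
        pd.DataFrame(raw_h, index=celltypes_h, columns=genes), taxonomy=tax_h, species="human"
    )
    mouse = cpm_normalize(
        pd.DataFrame(raw_m, index=celltypes_m, columns=genes), taxonomy=tax_m, species="mouse"
    )
    homology = {
        f"CT{i + 1:02d}": ([celltypes_h[i]], [celltypes_m[i]]) for i in range(config.n_celltypes)
    }
    return human, mouse, homology


def _group_of_disease(config: SynthConfig, i: int) -> int:
    # contiguous blocks of near-equal size
    return (i * config.n_disease_groups) // config.n_diseases


def synth_gda(config: SynthConfig, truth: dict[str, str | None]) -> pd.DataFrame:
    """Generate a DisGeNET-style gene–disease table from the planted truth.

    Diseases in planted group g draw genes (without replacement) from module
    M(g+1)'s gene pool; a fraction ``overlap_rate`` of each set after the
    group's first disease is replaced by genes of a random earlier disease in
    the same group.  Evidence counts N1..N4 are Poisson with means
    ``evidence_rates``.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, _STREAM_GDA)))
    remaining: dict[int, list[str]] = {}
    for g in range(config.n_disease_groups):
        module = f"M{g + 1}"
        remaining[g] = sorted(gene for gene, m in truth.items() if m == module)

    lo, hi = config.genes_per_disease
    if hi > min(len(p) for p in remaining.values()):
        raise ConfigurationError(
            f"genes_per_disease upper bound {hi} exceeds the planted module pool size "
            f"{min(len(p) for p in remaining.values())}"
        )

    records = []
    group_sets: dict[int, list[tuple[str, list[str]]]] = {g: [] for g in range(config.n_disease_groups)}
    for i in range(config.n_diseases):
        g = _group_of_disease(config, i)
        disease_id = f"D{i + 1:03d}"
        size = int(rng.integers(lo, hi + 1))
        if len(remaining[g]) < size:
            raise ConfigurationError(
                f"module pool for planted group {g} exhausted: need {size} genes, "
                f"{len(remaining[g])} left (increase genes_per_module or shrink sets)"
            )
        # within-group sets are disjoint by construction; overlap is injected below
        gene_set = list(rng.choice(remaining[g], size=size, replace=False))
        remaining[g] = [x for x in remaining[g] if x not in set(gene_set)]
        prior = group_sets[g]
        n_shared = int(np.floor(config.overlap_rate * size))
        if prior and n_shared > 0:
            _, donor_genes = prior[int(rng.integers(len(prior)))]
            shared = list(rng.choice(donor_genes, size=min(n_shared, len(donor_genes)), replace=False))
            returned = gene_set[: len(shared)]  # swap out own genes, keep the size
            gene_set = gene_set[len(shared):] + shared
            remaining[g] = sorted(set(remaining[g]) | set(returned))
        group_sets[g].append((disease_id, gene_set))
        gbd = GBD_CLASSES[g % len(GBD_CLASSES)]
        for gene in gene_set:
            n1, n2, n3, n4 = (int(rng.poisson(r)) for r in config.evidence_rates)
            records.append(
                {
                    "disease_id": disease_id,
                    "disease_name": f"synthetic disease {i + 1}",
                    "gbd_class": gbd,
                    "gene": gene,
                    "n_curated": n1,
                    "n_animal": n2,
                    "n_inferred": n3,
                    "n_literature": n4,
                }
            )
    table = pd.DataFrame.from_records(records)
    dup = table.duplicated(["disease_id", "gene"])
    return table.loc[~dup].reset_index(drop=True)


def planted_group_labels(config: SynthConfig) -> dict[str, int]:
    """Ground-truth disease → planted-group map (for recovery tests)."""
    return {f"D{i + 1:03d}": _group_of_disease(config, i) for i in range(config.n_diseases)}
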