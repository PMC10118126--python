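"""Loading, filtering, weighting and comparing gene–disease association sets.

The evidence-based GDA weight combines four literature components:
``C`` from the number of confirmed curated sources (0 / 0.3 / 0.5 / 0.6 for
N1 = 0 / 1 / 2 / >2), ``M = 0.2`` if any animal-model source reports the
association, ``I = 0.1`` if any inferred source does, and ``L = 0.01·N4``
capped at 0.1 for ten or more supporting publications.  The maximum score is
1.0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthdata import GBD_CLASSES

logger = logging.getLogger(__name__)

__all__ = [
    "DiseaseGeneSets",
    "OverlapResult",
    "NoDiseasesSurviveError",
    "filter_associations",
    "gda_score",
    "overlap_stats",
]


class NoDiseasesSurviveError(ValueError):
    """No disease passes the evidence and set-size filters."""


@dataclass
class DiseaseGeneSets:
    """Filtered disease gene sets with class labels and optional GDA weights."""

    sets: dict[str, set[str]]
    gbd: dict[str, str]
    weights: dict[str, dict[str, float]] | None = None
    names: dict[str, str] = field(default_factory=dict)

    @property
    def diseases(self) -> list[str]:
        return list(self.sets)

    def union(self) -> set[str]:
        out: set[str] = set()
        for s in self.sets.values():
            out |= s
        return out

    def class_union(self, gbd_class: str) -> set[str]:
        out: set[str] = set()
        for d, s in self.sets.items():
            if self.gbd[d] == gbd_class:
                out |= s
        return out

    def unique_sets(self) -> dict[str, set[str]]:
        """Genes belonging to exactly one disease (non-overlapping genes)."""
        counts: dict[str, int] = {}
        for s in self.sets.values():
            for g in s:
                counts[g] = counts.get(g, 0) + 1
        return {d: {g for g in s if counts[g] == 1} for d, s in self.sets.items()}


@dataclass
class OverlapResult:
    jaccard: pd.DataFrame
    unique_fraction: pd.Series
    class_union_sizes: pd.Series
    class_intersections: pd.DataFrame
    class_shared_pct: pd.Series
    perm_p: pd.Series
    shared_metric: str


def gda_score(n_curated: int, n_animal: int, n_inferred: int, n_literature: int) -> float:
    """Evidence weight of one gene–disease association, in [0, 1]."""
    for name, v in (
        ("n_curated", n_curated),
        ("n_animal", n_animal),
        ("n_inferred", n_inferred),
        ("n_literature", n_literature),
    ):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    if n_curated == 0:
        c = 0.0
    elif n_curated == 1:
        c = 0.3
    elif n_curated == 2:
        c = 0.5
    else:
        c = 0.6
    m = 0.2 if n_animal > 0 else 0.0
    i = 0.1 if n_inferred > 0 else 0.0
    l = 0.01 * n_literature if n_literature <= 9 else 0.1
    return c + m + i + l


def _normalize_symbol(g: str) -> str:
    return str(g).strip().upper()


def filter_associations(
    table: pd.DataFrame,
    min_curated: int = 1,
    min_genes: int = 10,
    measured_genes: set[str] | None = None,
    label_set: tuple[str, ...] = GBD_CLASSES,
) -> DiseaseGeneSets:
    """Filter a gene–disease table to well-supported, large-enough sets.

    Drops records with fewer than ``min_curated`` curated sources, then drops
    diseases whose surviving set has fewer than ``min_genes`` genes.  If
    ``measured_genes`` is given, symbols absent from it are dropped with a
    logged warning before the size filter.  Raises
    :class:`NoDiseasesSurviveError` when nothing survives.
    """
    if table.empty:
        raise ValueError("gene–disease table is empty")
    df = table.copy()
    df["gene"] = df["gene"].map(_normalize_symbol)
    unknown = set(df["gbd_class"]) - set(label_set)
    if unknown:
        raise ValueError(f"unknown GBD class labels: {sorted(unknown)}")
    if df.duplicated(["disease_id", "gene"]).any():
        raise ValueError("(disease_id, gene) pairs must be unique")

    n0 = len(df)
    df = df[df["n_curated"] >= min_curated]
    logger.info("evidence filter (min_curated=%d): %d -> %d records", min_curated, n0, len(df))

    if measured_genes is not None:
        measured = {_normalize_symbol(g) for g in measured_genes}
        n1 = len(df)
        df = df[df["gene"].isin(measured)]
        if len(df) < n1:
            logger.warning("dropped %d records whose gene is not measured", n1 - len(df))

    sizes = df.groupby("disease_id")["gene"].nunique()
    keep = sizes[sizes >= min_genes].index
    dropped = sorted(set(df["disease_id"]) - set(keep))
    if dropped:
        logger.info("size filter (min_genes=%d): dropped diseases %s", min_genes, dropped)
    df = df[df["disease_id"].isin(keep)]
    if df.empty:
        raise NoDiseasesSurviveError(
            f"no diseases survive filters (min_curated={min_curated}, min_genes={min_genes})"
        )

    sets: dict[str, set[str]] = {}
    gbd: dict[str, str] = {}
    names: dict[str, str] = {}
    weights: dict[str, dict[str, float]] = {}
    for disease_id, grp in df.groupby("disease_id", sort=True):
        sets[disease_id] = set(grp["gene"])
        gbd[disease_id] = grp["gbd_class"].iloc[0]
        if "disease_name" in grp:
            names[disease_id] = str(grp["disease_name"].iloc[0])
        weights[disease_id] = {
            row.gene: gda_score(row.n_curated, row.n_animal, row.n_inferred, row.n_literature)
            for row in grp.itertuples()
        }
    logger.info("retained %d diseases, %d unique genes", len(sets), len(set().union(*sets.values())))
    return DiseaseGeneSets(sets=sets, gbd=gbd, weights=weights, names=names)


def _pairwise_shared(sets: list[set[str]], metric: str) -> np.ndarray:
    """Pairwise shared-gene fraction matrix under the selected normalization."""
    n = len(sets)
    out = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            inter = len(sets[i] & sets[j])
            if metric == "jaccard":
                denom = len(sets[i] | sets[j])
            elif metric == "min":
                denom = min(len(sets[i]), len(sets[j]))
            else:
                raise ValueError(f"unknown shared metric {metric!r}")
            out[i, j] = out[j, i] = inter / denom if denom else 0.0
    return out


def _class_mean_shared(shared: np.ndarray, labels: np.ndarray, cls: str) -> float:
    idx = np.flatnonzero(labels == cls)
    if len(idx) < 2:
        return np.nan
    sub = shared[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    return float(sub[iu].mean())


def overlap_stats(
    sets: DiseaseGeneSets,
    n_perm: int = 1000,
    seed: int = 0,
    shared_metric: str = "jaccard",
    label_set: tuple[str, ...] = GBD_CLASSES,
) -> OverlapResult:
    """Pairwise Jaccard, per-disease uniqueness, and class-level overlap.

    The class-level statistic is the mean pairwise shared-gene percentage
    among the diseases of a GBD class; its significance is a permutation test
    shuffling the disease → class assignment while preserving class sizes
    (corrected for class size), with p = (1 + #{perm >= obs}) / (n_perm + 1).
    """
    diseases = sets.diseases
    if len(diseases) < 2:
        raise ValueError("overlap_stats requires at least 2 diseases")
    unknown = set(sets.gbd.values()) - set(label_set)
    if unknown:
        raise ValueError(f"unknown GBD class labels: {sorted(unknown)}")

    gene_sets = [sets.sets[d] for d in diseases]
    jaccard = pd.DataFrame(
        _pairwise_shared(gene_sets, "jaccard"), index=diseases, columns=diseases
    )
    shared = (
        jaccard.to_numpy()
        if shared_metric == "jaccard"
        else _pairwise_shared(gene_sets, shared_metric)
    )

    counts: dict[str, int] = {}
    for s in gene_sets:
        for g in s:
            counts[g] = counts.get(g, 0) + 1
    unique_fraction = pd.Series(
        {d: np.mean([counts[g] == 1 for g in sets.sets[d]]) for d in diseases},
        name="unique_fraction",
    )

    labels = np.array([sets.gbd[d] for d in diseases])
    classes = [c for c in label_set if c in set(labels)]
    class_union_sizes = pd.Series(
        {c: len(sets.class_union(c)) for c in classes}, name="class_union_size"
    )
    inter = pd.DataFrame(0, index=classes, columns=classes)
    for a in classes:
        ua = sets.class_union(a)
        for b in classes:
            inter.loc[a, b] = len(ua & sets.class_union(b))

    observed = pd.Series(
        {c: 100.0 * _class_mean_shared(shared, labels, c) for c in classes},
        name="class_shared_pct",
    )

    rng = np.random.default_rng(seed)
    exceed = {c: 0 for c in classes}
    valid = {c: 0 for c in classes}
    for _ in range(n_perm):
        perm = labels[rng.permutation(len(labels))]
        for c in classes:
            if np.isnan(observed[c]):
                continue
            stat = 100.0 * _class_mean_shared(shared, perm, c)
            valid[c] += 1
            if stat >= observed[c]:
                exceed[c] += 1
    perm_p = pd.Series(
        {
            c: (1 + exceed[c]) / (valid[c] + 1) if valid[c] else np.nan
            for c in classes
        },
        name="perm_p",
    )
    return OverlapResult(
        jaccard=jaccard,
        unique_fraction=unique_fraction,
        class_union_sizes=class_union_sizes,
        class_intersections=inter,
        class_shared_pct=observed,
        perm_p=perm_p,
        shared_metric=shared_metric,
    )
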