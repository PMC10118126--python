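"""Differential stability and canonical-module association.

Differential stability (DS) of a gene is the mean Pearson correlation of its
regional expression profile between all pairs of donor brains, computed over
the structures observed in both members of each pair.  Module association
correlates each gene's regional profile with the module eigengenes within each
subject, Fisher r-to-z transforms the correlations, averages z across
subjects, and standardizes each module column (mean 0, sd 1) over all scored
genes; disease-level scores are the mean of the member genes' rows.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gda import DiseaseGeneSets
from .synthdata import ModuleEigengenes, SubjectExpressionSet

logger = logging.getLogger(__name__)

__all__ = [
    "StabilityRecord",
    "ModuleScoreMatrix",
    "differential_stability",
    "differential_stability_all",
    "ds_partition",
    "module_scores",
    "disease_module_matrix",
]

_CLIP = 1.0 - 1e-6  # Fisher z diverges at |rho| = 1
_MIN_SHARED = 3  # a subject pair contributes only with >= 3 shared structures


@dataclass
class StabilityRecord:
    gene: str
    ds: float
    n_pairs: int
    n_structures_used: list[int]


@dataclass
class ModuleScoreMatrix:
    """Gene- or disease-level module association scores (z units)."""

    values: pd.DataFrame  # rows × modules, standardized
    raw: pd.DataFrame  # pre-standardization mean Fisher-z
    level: str  # "gene" | "disease"


def _pair_correlations(
    xa: np.ndarray, xb: np.ndarray
) -> tuple[np.ndarray, int]:
    """Column-wise Pearson r between two structures × genes matrices over the
    structures finite in both.  Masking is structure-level (whole rows NaN)."""
    mask = np.isfinite(xa).all(axis=1) & np.isfinite(xb).all(axis=1)
    n_shared = int(mask.sum())
    if n_shared < _MIN_SHARED:
        return np.full(xa.shape[1], np.nan), n_shared
    a, b = xa[mask], xb[mask]
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    denom = np.sqrt((a**2).sum(axis=0) * (b**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a * b).sum(axis=0) / denom
    return r, n_shared


def differential_stability_all(
    expr: SubjectExpressionSet, genes: list[str] | None = None
) -> pd.DataFrame:
    """DS for every requested gene: mean pairwise Pearson r across subjects.

    Returns a DataFrame indexed by gene with columns ``ds`` and ``n_pairs``.
    Subject pairs sharing fewer than 3 structures are skipped with a warning;
    a gene with no usable pair gets NaN.
    """
    if len(expr.subjects) < 2:
        raise ValueError("differential stability requires >= 2 subjects")
    cols = list(expr.genes) if genes is None else [g for g in genes if g in set(expr.genes)]
    mats = [m[cols].to_numpy(dtype=float) for m in expr.matrices]
    per_pair = []
    for ia, ib in itertools.combinations(range(len(mats)), 2):
        r, n_shared = _pair_correlations(mats[ia], mats[ib])
        if n_shared < _MIN_SHARED:
            logger.warning(
                "subject pair (%s, %s) shares only %d structures; skipped",
                expr.subjects[ia], expr.subjects[ib], n_shared,
            )
            continue
        per_pair.append(r)
    if not per_pair:
        raise ValueError("undefined DS: no subject pair shares >= 3 structures")
    stacked = np.vstack(per_pair)
    ds = np.nanmean(stacked, axis=0)
    n_pairs = np.isfinite(stacked).sum(axis=0)
    return pd.DataFrame({"ds": ds, "n_pairs": n_pairs}, index=cols)


def differential_stability(expr: SubjectExpressionSet, gene: str) -> StabilityRecord:
    """DS of a single gene (see :func:`differential_stability_all`)."""
    if gene not in set(expr.genes):
        raise KeyError(f"gene {gene!r} not measured")
    mats = [m[[gene]].to_numpy(dtype=float) for m in expr.matrices]
    rs, ns = [], []
    for ia, ib in itertools.combinations(range(len(mats)), 2):
        r, n_shared = _pair_correlations(mats[ia], mats[ib])
        if n_shared < _MIN_SHARED:
            logger.warning(
                "subject pair (%s, %s) shares only %d structures; skipped",
                expr.subjects[ia], expr.subjects[ib], n_shared,
            )
            continue
        if np.isfinite(r[0]):
            rs.append(float(r[0]))
            ns.append(n_shared)
    if not rs:
        raise ValueError(f"undefined DS for {gene!r}: all subject pairs skipped")
    return StabilityRecord(gene=gene, ds=float(np.mean(rs)), n_pairs=len(rs), n_structures_used=ns)


def ds_partition(
    records: pd.DataFrame, quantile: float = 0.5
) -> tuple[set[str], set[str], float]:
    """Split genes at a DS quantile: strictly above → high set.

    Returns ``(high, low, threshold)``.  With ``quantile=0.5`` this is the
    top-half / bottom-half split used to define the reproducible-module gene
    corpus.
    """
    if len(records) < 2:
        raise ValueError("ds_partition requires >= 2 records")
    ds = records["ds"].to_numpy(dtype=float)
    threshold = float(np.nanquantile(ds, quantile))
    high = set(records.index[ds > threshold])
    low = set(records.index) - high
    return high, low, threshold


def module_scores(
    expr: SubjectExpressionSet,
    eigengenes: ModuleEigengenes,
    genes: list[str] | None = None,
) -> ModuleScoreMatrix:
    """Gene × module association scores.

    Within each subject, every gene's profile is correlated with each module
    eigengene over the structures observed in that subject; r is clipped to
    ±(1 − 1e-6), Fisher-z transformed, and z is averaged across subjects.
    Each module column is then standardized over all scored genes.
    """
    eg_structs = list(eigengenes.patterns.columns)
    if not set(eg_structs) <= set(expr.structures):
        raise ValueError("eigengene structures must be a subset of expression structures")
    measured = set(expr.genes)
    cols = list(expr.genes) if genes is None else [g for g in genes if g in measured]
    skipped = [] if genes is None else [g for g in genes if g not in measured]
    if skipped:
        logger.warning("skipping %d genes absent from expression: %s...", len(skipped), skipped[:5])
    if not cols:
        raise ValueError("no requested gene is measured")

    P = eigengenes.patterns[eg_structs].to_numpy(dtype=float)  # modules × structures
    z_sum = np.zeros((len(cols), len(eigengenes.modules)))
    z_cnt = np.zeros_like(z_sum)
    for m in expr.matrices:
        X = m.loc[eg_structs, cols].to_numpy(dtype=float)  # structures × genes
        mask = np.isfinite(X).all(axis=1)
        if mask.sum() < _MIN_SHARED:
            continue
        Xo, Po = X[mask], P[:, mask]
        Xc = Xo - Xo.mean(axis=0)
        Pc = Po - Po.mean(axis=1, keepdims=True)
        denom = np.sqrt((Xc**2).sum(axis=0)[:, None] * (Pc**2).sum(axis=1)[None, :])
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Xc.T @ Pc.T) / denom  # genes × modules
        r = np.clip(r, -_CLIP, _CLIP)
        finite = np.isfinite(r)
        z = np.where(finite, np.arctanh(np.where(finite, r, 0.0)), 0.0)
        z_sum += z
        z_cnt += finite
    with np.errstate(invalid="ignore"):
        raw = z_sum / z_cnt
    raw_df = pd.DataFrame(raw, index=cols, columns=eigengenes.modules)
    mu = raw_df.mean(axis=0)
    sd = raw_df.std(axis=0, ddof=0)
    values = (raw_df - mu) / sd
    return ModuleScoreMatrix(values=values, raw=raw_df, level="gene")


def disease_module_matrix(
    gene_scores: ModuleScoreMatrix, sets: DiseaseGeneSets
) -> ModuleScoreMatrix:
    """Disease-level module matrix: mean of member genes' standardized rows."""
    if gene_scores.level != "gene":
        raise ValueError("disease_module_matrix expects gene-level scores")
    scored = set(gene_scores.values.index)
    rows, raw_rows, index = [], [], []
    for d in sets.diseases:
        genes = sorted(sets.sets[d] & scored)
        if not genes:
            logger.warning("disease %s has no scored genes; dropped", d)
            continue
        rows.append(gene_scores.values.loc[genes].mean(axis=0))
        raw_rows.append(gene_scores.raw.loc[genes].mean(axis=0))
        index.append(d)
    if not rows:
        raise ValueError("no disease has scored genes")
    return ModuleScoreMatrix(
        values=pd.DataFrame(rows, index=index),
        raw=pd.DataFrame(raw_rows, index=index),
        level="disease",
    )
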