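"""Cell-type specificity, disease × cell-type profiling, EWCE enrichment,
covariation interaction maps and consensus matrices.

The specificity index tau of a gene over N cell types is
``τ = Σ_i (1 − x_i / max(x)) / (N − 1)``: 0 for uniform expression, 1 for
expression exclusive to one type.  Expression-weighted cell-type enrichment
(EWCE) sums per-gene specificity fractions over a gene set and compares the
per-type sums to same-size random background sets by permutation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gda import DiseaseGeneSets

logger = logging.getLogger(__name__)

__all__ = [
    "CellTypeExpressionMatrix",
    "EnrichmentResult",
    "CovariationMap",
    "DiseaseCellTypeResult",
    "cpm_normalize",
    "tau_specificity",
    "tau_all",
    "disease_celltype_matrix",
    "ewce",
    "covariation_map",
    "consensus_matrix",
    "embed_2d",
    "gbd_ratio",
]


@dataclass
class CellTypeExpressionMatrix:
    """Cell-type × gene mean expression in CPM with a class/subclass taxonomy."""

    values: pd.DataFrame  # celltypes × genes, non-negative, rows sum to 1e6
    taxonomy: pd.DataFrame  # index celltype, columns cls, subclass
    species: str = ""
    counts_total: pd.Series | None = None

    def __post_init__(self) -> None:
        missing = set(self.values.index) - set(self.taxonomy.index)
        if missing:
            raise ValueError(f"taxonomy does not cover cell types: {sorted(missing)[:5]}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def celltypes(self) -> list[str]:
        return list(self.values.index)

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)

    def aggregate(self, level: str) -> "CellTypeExpressionMatrix":
        """Average cell types into class- or subclass-level units."""
        if level == "type":
            return self
        if level not in ("cls", "subclass"):
            raise ValueError(f"unknown aggregation level {level!r}")
        grouper = self.taxonomy.loc[self.values.index, level]
        agg = self.values.groupby(grouper, sort=False).mean()
        tax = pd.DataFrame(
            {"cls": agg.index if level == "cls" else
             self.taxonomy.groupby(grouper, sort=False)["cls"].first(),
             "subclass": agg.index},
            index=agg.index,
        )
        return CellTypeExpressionMatrix(values=agg, taxonomy=tax, species=self.species)


@dataclass
class EnrichmentResult:
    """Per cell-type EWCE statistics for one gene set."""

    table: pd.DataFrame  # celltype, observed, fold, p, q
    n_perm: int
    seed: int
    level: str
    set_size: int


@dataclass
class CovariationMap:
    per_disease: dict[str, pd.DataFrame]
    thresholds: dict[str, float]
    combined: dict[tuple[str, str], set[str]] = field(default_factory=dict)


@dataclass
class DiseaseCellTypeResult:
    matrix: pd.DataFrame  # disease × celltype, z-scored rows
    clusters: "object"  # anatomic.ClusterResult (CTG labels)
    disease_tau: pd.Series
    group_tau: pd.DataFrame  # group, pooled_tau, perm_p
    transform: str


def cpm_normalize(
    counts: pd.DataFrame,
    taxonomy: pd.DataFrame | None = None,
    species: str = "",
    counts_total: pd.Series | None = None,
) -> CellTypeExpressionMatrix:
    """Scale each cell-type row to sum to one million (CPM)."""
    sums = counts.sum(axis=1)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValueError(f"cell type(s) with zero total expression: {list(zero.index)}")
    values = counts.div(sums, axis=0) * 1e6
    if taxonomy is None:
        taxonomy = pd.DataFrame(
            {"cls": "all", "subclass": counts.index}, index=counts.index
        )
    return CellTypeExpressionMatrix(
        values=values, taxonomy=taxonomy, species=species, counts_total=counts_total
    )


def tau_specificity(x) -> float:
    """Specificity index τ of one gene's expression across N cell types."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("tau requires expression in >= 2 cell types")
    if (x < 0).any():
        raise ValueError("tau requires non-negative expression")
    mx = x.max()
    if mx <= 0:
        raise ValueError("undefined tau: all-zero expression vector")
    return float(np.sum(1.0 - x / mx) / (x.size - 1))


def tau_all(expr: CellTypeExpressionMatrix) -> pd.Series:
    """τ for every gene with any expression (all-zero genes are NaN)."""
    x = expr.values.to_numpy(dtype=float)
    mx = x.max(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tau = (1.0 - x / mx).sum(axis=0) / (x.shape[0] - 1)
    tau[mx <= 0] = np.nan
    return pd.Series(tau, index=expr.genes, name="tau")


def _transform_values(values: pd.DataFrame, transform: str) -> pd.DataFrame:
    if transform == "linear":
        return values
    if transform == "log1p":
        return np.log1p(values)
    raise ValueError(f"unknown transform {transform!r}")


def disease_celltype_matrix(
    sets: DiseaseGeneSets,
    expr: CellTypeExpressionMatrix,
    transform: str = "log1p",
    k: int = 4,
    n_perm: int = 1000,
    seed: int = 0,
) -> DiseaseCellTypeResult:
    """Disease × cell-type mean expression matrix with CTG clustering and τ.

    Each disease row is the mean (transformed) CPM of its measured genes per
    cell type, z-scored across cell types, then clustered (1 − Pearson, Ward)
    into ``k`` cell-type groups.  Per-disease mean τ and per-CTG pooled τ are
    reported, the latter with a permutation p against same-size random gene
    sets (corrected for group gene count).
    """
    from .anatomic import _zscore_rows, cluster_profiles

    values = _transform_values(expr.values, transform)
    measured = set(expr.genes)
    tau = tau_all(expr)
    rows, index, disease_genes = [], [], {}
    for d in sets.diseases:
        genes = sorted(sets.sets[d] & measured)
        if not genes:
            logger.warning("disease %s has no measured genes; dropped", d)
            continue
        rows.append(values[genes].mean(axis=1))
        index.append(d)
        disease_genes[d] = genes
    if len(index) < k:
        raise ValueError(f"only {len(index)} diseases have measured genes; need >= k={k}")
    matrix = _zscore_rows(pd.DataFrame(rows, index=index))
    clusters = cluster_profiles(matrix, k=k)

    disease_tau = pd.Series(
        {d: float(tau[disease_genes[d]].mean()) for d in index}, name="mean_tau"
    )

    rng = np.random.default_rng(seed)
    tau_arr = tau.dropna()
    pool = tau_arr.to_numpy()
    group_rows = []
    for g in sorted(set(clusters.labels.values())):
        members = [d for d in index if clusters.labels[d] == g]
        genes = sorted({x for d in members for x in disease_genes[d] if x in tau_arr.index})
        obs = float(tau_arr[genes].mean())
        null = np.array(
            [pool[rng.choice(len(pool), size=len(genes), replace=False)].mean() for _ in range(n_perm)]
        )
        p = (1 + np.sum(null >= obs)) / (n_perm + 1)
        group_rows.append({"group": g, "n_genes": len(genes), "pooled_tau": obs, "perm_p": p})
    return DiseaseCellTypeResult(
        matrix=matrix,
        clusters=clusters,
        disease_tau=disease_tau,
        group_tau=pd.DataFrame(group_rows),
        transform=transform,
    )


def specificity_matrix(expr: CellTypeExpressionMatrix) -> pd.DataFrame:
    """Per-gene specificity fractions s(g, c) = expr(g, c) / Σ_c expr(g, c).

    Genes with zero total expression are dropped.  The normalization cancels
    any per-row (library size) rescaling of the CPM matrix.
    """
    totals = expr.values.sum(axis=0)
    keep = totals[totals > 0].index
    if len(keep) < len(totals):
        logger.warning("dropping %d genes with zero total expression", len(totals) - len(keep))
    return expr.values[keep].div(totals[keep], axis=1)


def ewce(
    gene_set,
    expr: CellTypeExpressionMatrix,
    n_perm: int = 100_000,
    seed: int = 0,
    level: str = "type",
) -> EnrichmentResult:
    """Expression-weighted cell-type enrichment of a gene set.

    ``observed(c)`` sums the specificity fractions of the set's genes in cell
    type c; ``n_perm`` same-size random sets drawn from the background (all
    measured genes excluding the target set) give
    ``p(c) = (1 + #{perm ≥ observed}) / (n_perm + 1)`` and
    ``fold = observed / null mean``.  BH correction is applied across cell
    types.  ``level`` aggregates the expression matrix to class ("cls") or
    subclass means before scoring.
    """
    agg = expr.aggregate("cls" if level == "class" else level)
    spec = specificity_matrix(agg)
    measured = [g for g in spec.columns]
    upper = {str(g).strip().upper(): g for g in measured}
    wanted = {str(g).strip().upper() for g in gene_set}
    target = sorted(upper[u] for u in wanted & set(upper))
    if not target:
        raise ValueError("no target gene is measured")
    background = [g for g in measured if g not in set(target)]
    if len(target) > len(background):
        raise ValueError("target set larger than background")

    S = spec.to_numpy(dtype=float)  # celltypes × genes
    col = {g: i for i, g in enumerate(measured)}
    obs = S[:, [col[g] for g in target]].sum(axis=1)

    rng = np.random.default_rng(seed)
    bg_idx = np.array([col[g] for g in background])
    n_types = S.shape[0]
    ge = np.zeros(n_types)
    null_sum = np.zeros(n_types)
    # bound the celltypes × chunk × set_size gather to ~40 MB
    chunk = max(1, min(n_perm, int(5e6 // (n_types * len(target) + 1))))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        # without replacement within each permuted set
        picks = np.empty((m, len(target)), dtype=np.int64)
        for r in range(m):
            picks[r] = rng.choice(bg_idx, size=len(target), replace=False)
        sums = S[:, picks].sum(axis=2)  # celltypes × m
        ge += (sums >= obs[:, None]).sum(axis=1)
        null_sum += sums.sum(axis=1)
        done += m
    p = (1.0 + ge) / (n_perm + 1.0)
    null_mean = null_sum / n_perm
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(null_mean > 0, obs / null_mean, np.nan)

    from statsmodels.stats.multitest import multipletests

    q = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {"celltype": list(spec.index), "observed": obs, "fold": fold, "p": p, "q": q}
    ).set_index("celltype")
    return EnrichmentResult(table=table, n_perm=n_perm, seed=seed, level=level, set_size=len(target))


def disease_ewce_matrix(
    sets: DiseaseGeneSets,
    expr: CellTypeExpressionMatrix,
    n_perm: int = 10_000,
    seed: int = 0,
    level: str = "subclass",
    statistic: str = "fold",
) -> pd.DataFrame:
    """Disease × cell-type matrix of EWCE values (fold by default)."""
    rows = {}
    for i, d in enumerate(sets.diseases):
        try:
            res = ewce(sets.sets[d], expr, n_perm=n_perm, seed=seed + i, level=level)
        except ValueError as err:
            logger.warning("EWCE skipped for %s: %s", d, err)
            continue
        rows[d] = res.table[statistic]
    return pd.DataFrame(rows).T


def covariation_map(
    unique_sets: dict[str, set[str]],
    expr: CellTypeExpressionMatrix,
    sigma_mult: float = 1.5,
    normalize: str = "max",
) -> CovariationMap:
    """Per-disease cell-type × cell-type |cosine| covariation with thresholds.

    For each disease, cell types are compared as vectors over the disease's
    unique (non-overlapping) genes — per-gene max-normalized by default so
    high-magnitude genes do not dominate — and entry (i, j) is the absolute
    cosine similarity.  Each disease's threshold is mean + ``sigma_mult``·sd
    of its own off-diagonal entries; ``combined`` maps each pair to the
    diseases exceeding their threshold.
    """
    per_disease: dict[str, pd.DataFrame] = {}
    thresholds: dict[str, float] = {}
    celltypes = expr.celltypes
    for d, genes in unique_sets.items():
        cols = sorted(set(genes) & set(expr.genes))
        if len(cols) < 2:
            raise ValueError(f"disease {d} has fewer than 2 unique measured genes")
        A = expr.values[cols].to_numpy(dtype=float)
        if normalize == "max":
            mx = A.max(axis=0)
            keep = mx > 0
            if not keep.all():
                logger.warning("disease %s: %d all-zero genes ignored", d, int((~keep).sum()))
            A = A[:, keep] / mx[keep]
        elif normalize != "raw":
            raise ValueError(f"unknown normalize {normalize!r}")
        norms = np.linalg.norm(A, axis=1)
        zero_rows = norms == 0
        if zero_rows.any():
            logger.warning(
                "disease %s: cell types with all-zero expression: %s",
                d, [celltypes[i] for i in np.flatnonzero(zero_rows)],
            )
        safe = np.where(zero_rows, 1.0, norms)
        M = np.abs((A @ A.T) / np.outer(safe, safe))
        M[zero_rows, :] = 0.0
        M[:, zero_rows] = 0.0
        np.fill_diagonal(M, np.where(zero_rows, 0.0, 1.0))
        df = pd.DataFrame(M, index=celltypes, columns=celltypes)
        iu = np.triu_indices(len(celltypes), k=1)
        off = M[iu]
        thresholds[d] = float(off.mean() + sigma_mult * off.std())
        per_disease[d] = df
    combined: dict[tuple[str, str], set[str]] = {}
    for i, a in enumerate(celltypes):
        for b in celltypes[i + 1:]:
            passed = {
                d for d, m in per_disease.items() if m.loc[a, b] > thresholds[d]
            }
            if passed:
                combined[(a, b)] = passed
    return CovariationMap(per_disease=per_disease, thresholds=thresholds, combined=combined)


def consensus_matrix(corr_struct: pd.DataFrame, corr_cell: pd.DataFrame) -> pd.DataFrame:
    """Elementwise mean of the structural and cell-type correlation matrices."""
    if list(corr_struct.index) != list(corr_cell.index) or list(
        corr_struct.columns
    ) != list(corr_cell.columns):
        raise ValueError("matrices must share the disease universe and ordering")
    return (corr_struct + corr_cell) / 2.0


def embed_2d(corr: pd.DataFrame, method: str = "mds", seed: int = 0) -> pd.DataFrame:
    """2-D embedding of a disease correlation matrix.

    ``method="mds"`` is classical metric scaling of the 1 − r distance
    (deterministic); ``method="umap"`` delegates to umap-learn if installed.
    """
    dist = 1.0 - corr.to_numpy(dtype=float)
    np.fill_diagonal(dist, 0.0)
    if method == "umap":
        import umap

        emb = umap.UMAP(n_components=2, random_state=seed, metric="precomputed").fit_transform(dist)
    elif method == "mds":
        n = dist.shape[0]
        d2 = dist**2
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ d2 @ J
        w, v = np.linalg.eigh(B)
        order = np.argsort(w)[::-1][:2]
        emb = v[:, order] * np.sqrt(np.clip(w[order], 0.0, None))
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    return pd.DataFrame(emb, index=corr.index, columns=["x", "y"])


def gbd_ratio(coords: pd.DataFrame, gbd: dict[str, str]) -> pd.Series:
    """Per-disease ratio of mean within-class to mean between-class distance.

    Values below 1 indicate a disease sitting closer to its own GBD class in
    the embedding; a disease with no same-class partner is NaN.
    """
    diseases = list(coords.index)
    X = coords.to_numpy(dtype=float)
    labels = np.array([gbd[str(d)] for d in diseases])
    d2 = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))
    out = {}
    for i, d in enumerate(diseases):
        same = (labels == labels[i]) & (np.arange(len(diseases)) != i)
        diff = labels != labels[i]
        if not same.any() or not diff.any():
            out[d] = np.nan
            continue
        out[d] = float(d2[i, same].mean() / d2[i, diff].mean())
    return pd.Series(out, name="gbd_ratio")
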