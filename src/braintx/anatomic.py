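"""Anatomic disease profiles, ADG clustering, structure-wise tests and
cross-subject identifiability.

A disease's anatomic profile is the (optionally GDA-weighted) mean expression
of its genes at each brain structure, averaged across subjects and z-scored
across structures.  Diseases are clustered on the 1 − Pearson distance between
profiles with Ward linkage (the ward.D2 squared-distance update, as in R
``hclust``), giving Anatomic Disease Groups (ADGs).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats as sps
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .gda import DiseaseGeneSets
from .synthdata import SubjectExpressionSet

logger = logging.getLogger(__name__)

__all__ = [
    "DiseaseProfileMatrix",
    "ClusterResult",
    "IdentityResult",
    "StructureTestResult",
    "disease_profile",
    "cluster_profiles",
    "structure_tests",
    "crosssubject_identity",
    "signature_code",
    "decode_signature",
    "subsample_stability",
    "clustering_agreement",
]

_PRIMES = (2, 3, 5, 7, 11)


@dataclass
class DiseaseProfileMatrix:
    """Disease × structure z-scored mean expression, with per-subject variants."""

    values: pd.DataFrame  # diseases × structures, each row mean 0 sd 1
    per_subject: list[pd.DataFrame] | None = None
    subjects: list[str] | None = None
    weights_used: bool = False
    dropped: list[str] = field(default_factory=list)

    @property
    def diseases(self) -> list[str]:
        return list(self.values.index)

    @property
    def structures(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ClusterResult:
    labels: dict[str, int]
    linkage: np.ndarray
    k: int

    def label_array(self, order: list[str]) -> np.ndarray:
        return np.array([self.labels[d] for d in order])


@dataclass
class IdentityResult:
    exact_freq: pd.Series
    adg_freq: pd.Series
    gbd_freq: pd.Series
    assignment_counts: pd.DataFrame
    metric: str
    exclude_self: bool


@dataclass
class StructureTestResult:
    anova: pd.DataFrame  # structure, F, p, q
    pairwise: pd.DataFrame  # structure, group_a, group_b, t, p, q


def _zscore_rows(df: pd.DataFrame) -> pd.DataFrame:
    x = df.to_numpy(dtype=float)
    mu = np.nanmean(x, axis=1, keepdims=True)
    sd = np.nanstd(x, axis=1, keepdims=True)
    if np.any(sd == 0):
        bad = [df.index[i] for i in np.flatnonzero(sd[:, 0] == 0)]
        raise ValueError(f"constant profile (zero variance) for: {bad}")
    return pd.DataFrame((x - mu) / sd, index=df.index, columns=df.columns)


def disease_profile(
    expr: SubjectExpressionSet,
    sets: DiseaseGeneSets,
    weights: dict[str, dict[str, float]] | None = None,
) -> DiseaseProfileMatrix:
    """Build the disease × structure profile matrix.

    Per subject, each disease's profile is the (weighted) mean over its
    measured genes at each structure; subject profiles are averaged
    structure-wise (a structure masked in a subject is excluded from that
    average) and each disease row is z-scored across structures.  Per-subject
    profiles, z-scored within subject, are retained for holdout analyses.
    """
    measured = set(expr.genes)
    gene_pos = {g: i for i, g in enumerate(expr.genes)}
    diseases, dropped = [], []
    w_cols = []
    for d in sets.diseases:
        genes = [g for g in sorted(sets.sets[d]) if g in measured]
        if not genes:
            dropped.append(d)
            logger.warning("disease %s has no measured genes; dropped", d)
            continue
        w = np.zeros(len(expr.genes))
        if weights is not None:
            dw = weights.get(d, {})
            for g in genes:
                w[gene_pos[g]] = dw.get(g, 0.0)
            if w.sum() == 0:  # all-zero weights degrade to the unweighted mean
                for g in genes:
                    w[gene_pos[g]] = 1.0
        else:
            for g in genes:
                w[gene_pos[g]] = 1.0
        w_cols.append(w / w.sum())
        diseases.append(d)
    if not diseases:
        raise ValueError("no disease has any measured gene")
    W = np.column_stack(w_cols)  # genes × diseases

    per_subject_raw = []
    for m in expr.matrices:
        per_subject_raw.append(m.to_numpy(dtype=float) @ W)  # structures × diseases
    stack = np.stack(per_subject_raw)  # subjects × structures × diseases
    mean = np.nanmean(stack, axis=0)

    values = _zscore_rows(
        pd.DataFrame(mean.T, index=diseases, columns=expr.structures)
    )
    per_subject = []
    for s, x in enumerate(per_subject_raw):
        df = pd.DataFrame(x.T, index=diseases, columns=expr.structures)
        mu = np.nanmean(df.to_numpy(), axis=1, keepdims=True)
        sd = np.nanstd(df.to_numpy(), axis=1, keepdims=True)
        sd[sd == 0] = np.nan
        per_subject.append(
            pd.DataFrame((df.to_numpy() - mu) / sd, index=diseases, columns=expr.structures)
        )
    return DiseaseProfileMatrix(
        values=values,
        per_subject=per_subject,
        subjects=list(expr.subjects),
        weights_used=weights is not None,
        dropped=dropped,
    )


def _correlation_distance(rows: pd.DataFrame) -> np.ndarray:
    x = rows.to_numpy(dtype=float)
    sd = x.std(axis=1)
    if np.any(sd == 0):
        bad = [rows.index[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"correlation undefined for constant profile(s): {bad}")
    dist = 1.0 - np.corrcoef(x)
    np.fill_diagonal(dist, 0.0)
    return np.clip(dist, 0.0, None)


def cluster_profiles(profiles: DiseaseProfileMatrix | pd.DataFrame, k: int) -> ClusterResult:
    """Ward (ward.D2) clustering of profile rows on 1 − Pearson distance.

    Cluster ids are renumbered 1..k in order of first appearance in the input,
    making the labeling deterministic.
    """
    rows = profiles.values if isinstance(profiles, DiseaseProfileMatrix) else profiles
    if len(rows) < k:
        raise ValueError(f"need at least k={k} profiles, got {len(rows)}")
    dist = _correlation_distance(rows)
    Z = sch.linkage(squareform(dist, checks=False), method="ward")
    raw = sch.fcluster(Z, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    labels: dict[str, int] = {}
    for name, c in zip(rows.index, raw):
        if c not in relabel:
            relabel[c] = len(relabel) + 1
        labels[str(name)] = relabel[c]
    return ClusterResult(labels=labels, linkage=Z, k=len(set(raw)))


def structure_tests(
    profiles: DiseaseProfileMatrix | pd.DataFrame, labels: dict[str, int | str]
) -> StructureTestResult:
    """Per-structure one-way ANOVA across groups plus all pairwise t tests.

    BH correction is applied across structures for the ANOVA family and across
    structure × group-pair for the t-test family.  Groups with a single member
    are excluded from pairwise tests with a warning.
    """
    rows = profiles.values if isinstance(profiles, DiseaseProfileMatrix) else profiles
    groups: dict[object, list[str]] = {}
    for d in rows.index:
        groups.setdefault(labels[str(d)], []).append(d)
    multi = {g: ds for g, ds in groups.items() if len(ds) >= 2}
    if len(multi) < 2:
        raise ValueError("need at least 2 groups with >= 2 members")
    singletons = sorted(set(groups) - set(multi), key=str)
    if singletons:
        logger.warning("groups %s have a single member; excluded from pairwise tests", singletons)

    anova_rows = []
    for s in rows.columns:
        samples = [rows.loc[ds, s].to_numpy() for ds in multi.values()]
        pooled = np.concatenate(samples)
        if np.allclose(pooled, pooled[0]):
            f, p = 0.0, 1.0
        else:
            f, p = sps.f_oneway(*samples)
            if not np.isfinite(p):
                f, p = 0.0, 1.0
        anova_rows.append({"structure": s, "F": f, "p": p})
    anova = pd.DataFrame(anova_rows)
    anova["q"] = multipletests(anova["p"], method="fdr_bh")[1]

    pair_rows = []
    for a, b in itertools.combinations(sorted(multi, key=str), 2):
        xa, xb = rows.loc[multi[a]], rows.loc[multi[b]]
        for s in rows.columns:
            va, vb = xa[s].to_numpy(), xb[s].to_numpy()
            both = np.concatenate([va, vb])
            if np.allclose(both, both[0]):
                t, p = 0.0, 1.0
            else:
                t, p = sps.ttest_ind(va, vb)
            pair_rows.append(
                {"structure": s, "group_a": a, "group_b": b, "t": t, "p": p}
            )
    pairwise = pd.DataFrame(pair_rows)
    pairwise["q"] = multipletests(pairwise["p"], method="fdr_bh")[1]
    return StructureTestResult(anova=anova, pairwise=pairwise)


def _nan_pearson(a: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson r between vector a and each row of B, over jointly observed entries."""
    out = np.full(B.shape[0], -np.inf)
    for i in range(B.shape[0]):
        mask = np.isfinite(a) & np.isfinite(B[i])
        if mask.sum() < 3:
            continue
        x, y = a[mask], B[i][mask]
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            continue
        out[i] = float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))
    return out


def _nan_euclidean(a: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Mean squared difference over jointly observed entries (lower = closer)."""
    out = np.full(B.shape[0], np.inf)
    for i in range(B.shape[0]):
        mask = np.isfinite(a) & np.isfinite(B[i])
        if mask.sum() < 3:
            continue
        out[i] = float(np.mean((a[mask] - B[i][mask]) ** 2))
    return out


def crosssubject_identity(
    profiles: DiseaseProfileMatrix,
    adg: dict[str, int | str],
    gbd: dict[str, str],
    metric: str = "pearson",
    exclude_self: bool = False,
) -> IdentityResult:
    """Nearest-disease assignment of each subject's profiles in every other subject.

    For subject s and disease d, the most similar profile among all diseases
    in each other subject s' is found (Pearson similarity, or Euclidean
    distance); ties break toward the lowest disease index.  ``exact_freq`` is
    the fraction of the n_subjects·(n_subjects−1) comparisons hitting d
    itself; ``adg_freq``/``gbd_freq`` the fraction landing in the same group.
    With ``exclude_self`` the disease's own profile is not a candidate (the
    closest disease other than the given one).
    """
    if metric not in ("pearson", "euclidean"):
        raise ValueError(f"unknown metric {metric!r}")
    if not profiles.per_subject or len(profiles.per_subject) < 2:
        raise ValueError("crosssubject_identity requires per-subject profiles (>= 2 subjects)")
    diseases = profiles.diseases
    n = len(diseases)
    mats = [m.to_numpy(dtype=float) for m in profiles.per_subject]
    counts = np.zeros((n, n), dtype=int)
    hits_exact = np.zeros(n)
    hits_adg = np.zeros(n)
    hits_gbd = np.zeros(n)
    n_comp = 0
    n_subj = len(mats)
    for s in range(n_subj):
        for t in range(n_subj):
            if s == t:
                continue
            n_comp += 1
            for i in range(n):
                score = (
                    _nan_pearson(mats[s][i], mats[t])
                    if metric == "pearson"
                    else -_nan_euclidean(mats[s][i], mats[t])
                )
                if exclude_self:
                    score[i] = -np.inf
                j = int(np.argmax(score))  # argmax takes the first (lowest index) on ties
                counts[i, j] += 1
                hits_exact[i] += j == i
                hits_adg[i] += adg[diseases[j]] == adg[diseases[i]]
                hits_gbd[i] += gbd[diseases[j]] == gbd[diseases[i]]
    denom = float(n_comp)
    return IdentityResult(
        exact_freq=pd.Series(hits_exact / denom, index=diseases, name="exact_freq"),
        adg_freq=pd.Series(hits_adg / denom, index=diseases, name="adg_freq"),
        gbd_freq=pd.Series(hits_gbd / denom, index=diseases, name="gbd_freq"),
        assignment_counts=pd.DataFrame(counts, index=diseases, columns=diseases),
        metric=metric,
        exclude_self=exclude_self,
    )


def signature_code(group_means, tie_policy: str = "error") -> int:
    """Encode the ascending rank order of 5 group means as a single integer.

    Values are ranked 1..5 from lowest to highest and the pattern is encoded
    by unique prime factorization as ``2^r1 · 3^r2 · 5^r3 · 7^r4 · 11^r5``
    (ri = rank of the i-th input), so distinct orderings map to distinct
    integers.  Exact ties raise unless ``tie_policy="stable-order"``, which
    ranks tied values by input position.
    """
    x = np.asarray(group_means, dtype=float)
    if x.shape != (5,):
        raise ValueError("signature_code expects exactly 5 values")
    if tie_policy not in ("error", "stable-order"):
        raise ValueError(f"unknown tie_policy {tie_policy!r}")
    if tie_policy == "error" and len(np.unique(x)) != 5:
        raise ValueError("tied group means; signature rank order is ambiguous")
    order = np.argsort(x, kind="stable")
    ranks = np.empty(5, dtype=int)
    ranks[order] = np.arange(1, 6)
    n = 1
    for p, r in zip(_PRIMES, ranks):
        n *= p ** int(r)
    return n


def decode_signature(n: int) -> tuple[int, ...]:
    """Invert :func:`signature_code`, recovering the 5 ranks."""
    ranks = []
    for p in _PRIMES:
        r = 0
        while n % p == 0:
            n //= p
            r += 1
        ranks.append(r)
    if n != 1 or sorted(ranks) != [1, 2, 3, 4, 5]:
        raise ValueError("not a valid signature code")
    return tuple(ranks)


def subsample_stability(
    sets: DiseaseGeneSets,
    expr: SubjectExpressionSet,
    max_genes: int = 200,
    reps: int = 1000,
    k: int = 5,
    seed: int = 0,
    weights: dict[str, dict[str, float]] | None = None,
) -> pd.DataFrame:
    """Co-clustering frequency under downsampling of oversized gene sets.

    Each repetition samples ``max_genes`` genes without replacement from any
    disease with more than that many genes, rebuilds profiles and reclusters
    with ``k``; the returned matrix is the fraction of repetitions in which
    each disease pair lands in the same cluster.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    diseases = sets.diseases
    co = np.zeros((len(diseases), len(diseases)))
    for _ in range(reps):
        sub = {}
        for d in diseases:
            genes = sorted(sets.sets[d])
            if len(genes) > max_genes:
                genes = list(rng.choice(genes, size=max_genes, replace=False))
            sub[d] = set(genes)
        sub_sets = DiseaseGeneSets(sets=sub, gbd=dict(sets.gbd), weights=sets.weights)
        prof = disease_profile(expr, sub_sets, weights=weights)
        res = cluster_profiles(prof, k=k)
        lab = np.array([res.labels[d] for d in diseases])
        co += lab[:, None] == lab[None, :]
    return pd.DataFrame(co / reps, index=diseases, columns=diseases)


def clustering_agreement(labels_a: dict[str, object], labels_b: dict[str, object]) -> float:
    """Fraction of unordered pairs whose co-membership agrees between labelings."""
    if set(labels_a) != set(labels_b):
        raise ValueError("labelings cover different disease universes")
    items = sorted(labels_a, key=str)
    if len(items) < 2:
        raise ValueError("need at least 2 items")
    a = np.array([hash(labels_a[i]) for i in items])
    b = np.array([hash(labels_b[i]) for i in items])
    iu = np.triu_indices(len(items), k=1)
    same_a = (a[:, None] == a[None, :])[iu]
    same_b = (b[:, None] == b[None, :])[iu]
    return float(np.mean(same_a == same_b))
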