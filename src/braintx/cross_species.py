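"""Cross-species comparison of disease cell-type signatures.

Human and mouse disease × cell-type matrices are aligned through a homologous
consensus cell-type map (each species' types averaged into their consensus
type), co-clustered, and scored by the fraction of diseases whose nearest
cross-species signature (Pearson) is the same disease.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "HomologyMap",
    "align_signatures",
    "species_coclustering",
    "ks_compare",
]


@dataclass
class HomologyMap:
    """Consensus cell type → (human types, mouse types)."""

    mapping: dict[str, tuple[list[str], list[str]]]
    level: str = "subclass"

    def __post_init__(self) -> None:
        if not self.mapping:
            raise ValueError("empty consensus set")
        for species_idx, species in ((0, "human"), (1, "mouse")):
            seen: set[str] = set()
            for consensus, pair in self.mapping.items():
                for t in pair[species_idx]:
                    if t in seen:
                        raise ValueError(
                            f"{species} type {t!r} maps to more than one consensus type"
                        )
                    seen.add(t)

    def one_sided(self) -> list[str]:
        """Consensus types with an empty side in either species (flagged)."""
        return [c for c, (h, m) in self.mapping.items() if not h or not m]

    @classmethod
    def from_frame(cls, df: pd.DataFrame, level: str = "subclass") -> "HomologyMap":
        """Build from a long table with columns consensus_id, species, celltype_id."""
        mapping: dict[str, tuple[list[str], list[str]]] = {}
        for cid, grp in df.groupby("consensus_id", sort=True):
            h = sorted(grp.loc[grp["species"] == "human", "celltype_id"])
            m = sorted(grp.loc[grp["species"] == "mouse", "celltype_id"])
            mapping[str(cid)] = (h, m)
        return cls(mapping=mapping, level=level)


def align_signatures(
    human: pd.DataFrame, mouse: pd.DataFrame, homology: HomologyMap
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Average each species' columns into consensus cell types.

    Consensus types missing measured columns on either side are dropped with
    a log message.  Both outputs share the disease index and consensus column
    order.
    """
    if list(human.index) != list(mouse.index):
        raise ValueError("human and mouse matrices must share the disease universe")
    h_cols, m_cols, kept = {}, {}, []
    for consensus, (h_types, m_types) in homology.mapping.items():
        h_present = [t for t in h_types if t in human.columns]
        m_present = [t for t in m_types if t in mouse.columns]
        if not h_present or not m_present:
            logger.info("consensus type %s missing on one side; dropped", consensus)
            continue
        h_cols[consensus] = human[h_present].mean(axis=1)
        m_cols[consensus] = mouse[m_present].mean(axis=1)
        kept.append(consensus)
    if not kept:
        raise ValueError("no consensus type is present in both species")
    return pd.DataFrame(h_cols)[kept], pd.DataFrame(m_cols)[kept]


def species_coclustering(
    ewce_h: pd.DataFrame, ewce_m: pd.DataFrame, k: int | None = None
):
    """Joint clustering of species-tagged signatures and cross-species NN score.

    Rows of both aligned matrices are stacked with species tags and clustered
    (1 − Pearson, Ward).  ``nn_same_disease_fraction`` is the fraction of the
    2·D species-tagged rows whose most correlated row in the other species is
    the same disease.  Returns ``(ClusterResult, fraction)``.
    """
    from .anatomic import cluster_profiles

    if list(ewce_h.columns) != list(ewce_m.columns) or list(ewce_h.index) != list(ewce_m.index):
        raise ValueError("aligned matrices must share disease and consensus axes")
    diseases = list(ewce_h.index)
    H = ewce_h.to_numpy(dtype=float)
    M = ewce_m.to_numpy(dtype=float)
    for name, X in (("human", H), ("mouse", M)):
        sd = X.std(axis=1)
        if np.any(sd == 0):
            bad = [diseases[i] for i in np.flatnonzero(sd == 0)]
            raise ValueError(f"constant {name} signature for disease(s): {bad}")

    stacked = pd.concat(
        [
            ewce_h.set_index(pd.Index([f"human:{d}" for d in diseases])),
            ewce_m.set_index(pd.Index([f"mouse:{d}" for d in diseases])),
        ]
    )
    if k is None:
        k = len(diseases)
    clusters = cluster_profiles(stacked, k=min(k, len(stacked)))

    Hc = (H - H.mean(axis=1, keepdims=True)) / H.std(axis=1, keepdims=True)
    Mc = (M - M.mean(axis=1, keepdims=True)) / M.std(axis=1, keepdims=True)
    corr = Hc @ Mc.T / H.shape[1]  # human i vs mouse j
    hits = (np.argmax(corr, axis=1) == np.arange(len(diseases))).sum()
    hits += (np.argmax(corr, axis=0) == np.arange(len(diseases))).sum()
    fraction = hits / (2.0 * len(diseases))
    return clusters, float(fraction)


def ks_compare(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test: (D, asymptotic p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)
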