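"""End-to-end pipeline: synthetic (or file-based) inputs through every stage.

``run_pipeline`` executes gda → anatomic → stability/modules → celltype →
cross-species, writing each artifact as TSV/JSON with a sha256 checksum into a
run manifest.  Deterministic stages reproduce identical checksums under the
same configuration and seeds.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import anatomic, celltype, cross_species, gda, io, stability, synthdata

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Validated pipeline configuration; round-trips through YAML unchanged."""

    out_dir: str
    synth: dict = field(default_factory=dict)  # SynthConfig overrides
    gda_table: str | None = None  # optional TSV path; synthetic when None
    min_curated: int = 1
    min_genes: int = 10
    adg_k: int = 5
    ctg_k: int = 4
    metric: str = "pearson"
    n_perm_overlap: int = 200
    n_perm_ewce: int = 2000
    ewce_level: str = "subclass"
    seed: int = 0

    def validate(self) -> "synthdata.SynthConfig":
        if self.metric not in ("pearson", "euclidean"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.gda_table is not None and not Path(self.gda_table).exists():
            raise FileNotFoundError(f"gda_table not found: {self.gda_table}")
        synth = dict(self.synth)
        synth.setdefault("seed", self.seed)
        return synthdata.SynthConfig.from_dict(synth)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**io.read_yaml(path))

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


def _write(df: pd.DataFrame, path: Path, artifacts: dict) -> None:
    io.write_matrix_tsv(df, path)
    artifacts[path.name] = io.file_checksum(path)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the manifest (also written to out_dir)."""
    synth_cfg = config.validate()  # fail fast before any stage runs
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}}

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            artifacts: dict = {}
            try:
                info = fn(artifacts) or {}
            except Exception as err:
                raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err
            manifest["stages"][name] = {
                "artifacts": artifacts,
                "seconds": round(time.perf_counter() - t0, 3),
                **info,
            }

        return wrap

    # --- synthetic inputs -------------------------------------------------
    expr = eigengenes = truth = human = mouse = homology = None

    @stage("synthdata")
    def _(artifacts):
        nonlocal expr, eigengenes, truth, human, mouse, homology
        expr, eigengenes, truth = synthdata.synth_subject_expression(synth_cfg)
        human, mouse, homology = synthdata.synth_cell_expression(synth_cfg, truth)
        io.write_yaml(synth_cfg.to_dict(), out / "synth_config.yaml")
        artifacts["synth_config.yaml"] = io.file_checksum(out / "synth_config.yaml")
        io.write_json({g: m for g, m in truth.items()}, out / "truth_gene_module.json")
        artifacts["truth_gene_module.json"] = io.file_checksum(out / "truth_gene_module.json")
        _write(eigengenes.patterns, out / "eigengenes.tsv", artifacts)
        _write(expr.matrices[0], out / "expression_subject1.tsv", artifacts)
        return {"n_subjects": len(expr.subjects), "n_genes": len(expr.genes)}

    # --- gda --------------------------------------------------------------
    sets = None

    @stage("gda")
    def _(artifacts):
        nonlocal sets
        if config.gda_table is not None:
            table = io.read_gene_disease_tsv(config.gda_table)
        else:
            table = synthdata.synth_gda(synth_cfg, truth)
            io.write_gene_disease_tsv(table, out / "gda_table.tsv")
            artifacts["gda_table.tsv"] = io.file_checksum(out / "gda_table.tsv")
        sets = gda.filter_associations(
            table, min_curated=config.min_curated, min_genes=config.min_genes
        )
        io.write_gmt(sets.sets, out / "disease_sets.gmt", descriptions=sets.gbd)
        artifacts["disease_sets.gmt"] = io.file_checksum(out / "disease_sets.gmt")
        overlap = gda.overlap_stats(sets, n_perm=config.n_perm_overlap, seed=config.seed)
        _write(overlap.jaccard, out / "jaccard.tsv", artifacts)
        io.write_json(
            {
                "class_union_sizes": overlap.class_union_sizes.to_dict(),
                "class_shared_pct": overlap.class_shared_pct.to_dict(),
                "perm_p": overlap.perm_p.to_dict(),
                "n_records": int(len(table)),
            },
            out / "overlap_summary.json",
        )
        artifacts["overlap_summary.json"] = io.file_checksum(out / "overlap_summary.json")
        return {"n_diseases": len(sets.diseases), "n_unique_genes": len(sets.union())}

    # --- anatomic ---------------------------------------------------------
    profiles = adg = None

    @stage("anatomic")
    def _(artifacts):
        nonlocal profiles, adg
        profiles = anatomic.disease_profile(expr, sets)
        adg = anatomic.cluster_profiles(profiles, k=config.adg_k)
        _write(profiles.values, out / "disease_profiles.tsv", artifacts)
        _write(
            pd.DataFrame(adg.linkage, columns=["a", "b", "height", "count"]),
            out / "adg_linkage.tsv",
            artifacts,
        )
        io.write_json(adg.labels, out / "adg_labels.json")
        artifacts["adg_labels.json"] = io.file_checksum(out / "adg_labels.json")
        tests = anatomic.structure_tests(profiles, adg.labels)
        _write(tests.anova.set_index("structure"), out / "anova.tsv", artifacts)
        ident = anatomic.crosssubject_identity(
            profiles, adg.labels, sets.gbd, metric=config.metric
        )
        _write(ident.assignment_counts, out / "identity_counts.tsv", artifacts)
        return {
            "n_profiled": len(profiles.diseases),
            "mean_exact_freq": float(ident.exact_freq.mean()),
        }

    # --- stability & modules ---------------------------------------------
    @stage("stability_modules")
    def _(artifacts):
        ds = stability.differential_stability_all(expr)
        _write(ds, out / "differential_stability.tsv", artifacts)
        scores = stability.module_scores(expr, eigengenes)
        _write(scores.values, out / "gene_module_scores.tsv", artifacts)
        dm = stability.disease_module_matrix(scores, sets)
        _write(dm.values, out / "disease_module_scores.tsv", artifacts)
        return {"median_ds": float(ds["ds"].median())}

    # --- celltype ---------------------------------------------------------
    ct_result = ewce_h = ewce_m = None

    @stage("celltype")
    def _(artifacts):
        nonlocal ct_result, ewce_h, ewce_m
        ct_result = celltype.disease_celltype_matrix(
            sets, human, k=config.ctg_k, seed=config.seed
        )
        _write(ct_result.matrix, out / "disease_celltype.tsv", artifacts)
        io.write_json(ct_result.clusters.labels, out / "ctg_labels.json")
        artifacts["ctg_labels.json"] = io.file_checksum(out / "ctg_labels.json")
        ewce_h = celltype.disease_ewce_matrix(
            sets, human, n_perm=config.n_perm_ewce, seed=config.seed, level=config.ewce_level
        )
        ewce_m = celltype.disease_ewce_matrix(
            sets, mouse, n_perm=config.n_perm_ewce, seed=config.seed, level=config.ewce_level
        )
        _write(ewce_h, out / "ewce_human.tsv", artifacts)
        _write(ewce_m, out / "ewce_mouse.tsv", artifacts)
        corr_struct = profiles.values.T.corr()
        corr_cell = ct_result.matrix.loc[profiles.diseases].T.corr()
        consensus = celltype.consensus_matrix(corr_struct, corr_cell)
        _write(consensus, out / "consensus.tsv", artifacts)
        coords = celltype.embed_2d(consensus, method="mds", seed=config.seed)
        _write(coords, out / "embedding.tsv", artifacts)
        ratios = celltype.gbd_ratio(coords, sets.gbd)
        _write(ratios.to_frame(), out / "gbd_ratio.tsv", artifacts)
        return {"mean_gbd_ratio": float(np.nanmean(ratios.to_numpy()))}

    # --- cross-species ----------------------------------------------------
    @stage("cross_species")
    def _(artifacts):
        # subclass-level EWCE columns are already shared labels when both
        # taxonomies are generated by synthdata; build the homology map at
        # the matching level
        hmap = cross_species.HomologyMap(
            mapping={c: ([c], [c]) for c in ewce_h.columns}, level=config.ewce_level
        )
        h_al, m_al = cross_species.align_signatures(ewce_h, ewce_m, hmap)
        clusters, fraction = cross_species.species_coclustering(h_al, m_al)
        io.write_json(clusters.labels, out / "xspecies_labels.json")
        artifacts["xspecies_labels.json"] = io.file_checksum(out / "xspecies_labels.json")
        d, p = cross_species.ks_compare(
            h_al.to_numpy().ravel(), m_al.to_numpy().ravel()
        )
        io.write_json(
            {"nn_same_disease_fraction": fraction, "ks_D": d, "ks_p": p},
            out / "xspecies_summary.json",
        )
        artifacts["xspecies_summary.json"] = io.file_checksum(out / "xspecies_summary.json")
        return {"nn_same_disease_fraction": fraction}

    io.write_json(manifest, out / "manifest.json")
    return manifest
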