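"""Shared fixtures: small seeded synthetic cohorts reused across test modules."""

import pytest

import braintx as bt


@pytest.fixture(scope="session")
def small_cfg() -> bt.SynthConfig:
    """Desk-scale cohort: 3 subjects, 30 structures, 6 modules, 12 diseases."""
    return bt.SynthConfig(
        n_subjects=3,
        n_structures=30,
        n_regions=5,
        n_modules=6,
        genes_per_module=60,
        n_unstable_genes=30,
        subject_noise_sd=0.2,
        n_celltypes=8,
        n_classes=2,
        n_diseases=12,
        n_disease_groups=3,
        genes_per_disease=(8, 12),
        overlap_rate=0.1,
        seed=7,
    )


@pytest.fixture(scope="session")
def cohort(small_cfg):
    return bt.synth_subject_expression(small_cfg)


@pytest.fixture(scope="session")
def cells(small_cfg, cohort):
    _, _, truth = cohort
    return bt.synth_cell_expression(small_cfg, truth)


@pytest.fixture(scope="session")
def gda_table(small_cfg, cohort):
    _, _, truth = cohort
    return bt.synth_gda(small_cfg, truth)


@pytest.fixture(scope="session")
def disease_sets(small_cfg, gda_table):
    return bt.filter_associations(gda_table, min_curated=0, min_genes=5)


@pytest.fixture(scope="session")
def profiles(cohort, disease_sets):
    expr, _, _ = cohort
    return bt.disease_profile(expr, disease_sets)
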