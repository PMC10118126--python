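"""Anatomic profiles, ADG clustering, structure tests, identifiability,
signature codes and clustering agreement."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import braintx as bt
from braintx.anatomic import decode_signature


class TestDiseaseProfile:
    def test_rows_are_zscored(self, profiles):
        x = profiles.values.to_numpy()
        assert np.allclose(x.mean(axis=1), 0, atol=1e-9)
        assert np.allclose(x.std(axis=1), 1, atol=1e-9)
        for ps in profiles.per_subject:
            y = ps.to_numpy()
            assert np.allclose(np.nanmean(y, axis=1), 0, atol=1e-9)
            assert np.allclose(np.nanstd(y, axis=1), 1, atol=1e-9)

    def test_single_gene_disease_equals_gene_profile(self, cohort):
        expr, _, _ = cohort
        g = expr.genes[0]
        sets = bt.DiseaseGeneSets(sets={"d": {g}}, gbd={"d": "other"})
        prof = bt.disease_profile(expr, sets)
        mean = np.mean([m[g].to_numpy() for m in expr.matrices], axis=0)
        z = (mean - mean.mean()) / mean.std()
        assert np.allclose(prof.values.loc["d"].to_numpy(), z)

    def test_equal_weights_match_unweighted(self, cohort, disease_sets):
        expr, _, _ = cohort
        w = {d: {g: 0.7 for g in s} for d, s in disease_sets.sets.items()}
        a = bt.disease_profile(expr, disease_sets)
        b = bt.disease_profile(expr, disease_sets, weights=w)
        pd.testing.assert_frame_equal(a.values, b.values)
        assert b.weights_used

    def test_disease_without_measured_genes_recorded(self, cohort):
        expr, _, _ = cohort
        sets = bt.DiseaseGeneSets(
            sets={"good": {expr.genes[0], expr.genes[1]}, "ghost": {"NOPE"}},
            gbd={"good": "other", "ghost": "other"},
        )
        prof = bt.disease_profile(expr, sets)
        assert prof.dropped == ["ghost"]
        assert prof.diseases == ["good"]


class TestClusterProfiles:
    def test_planted_groups_recovered(self, profiles, small_cfg):
        res = bt.cluster_profiles(profiles, k=small_cfg.n_disease_groups)
        truth = bt.planted_group_labels(small_cfg)
        ari = adjusted_rand_score(
            [truth[d] for d in profiles.diseases],
            [res.labels[d] for d in profiles.diseases],
        )
        assert ari == 1.0

    def test_degenerate_cut_every_disease_own_cluster(self, profiles):
        res = bt.cluster_profiles(profiles, k=len(profiles.diseases))
        assert len(set(res.labels.values())) == len(profiles.diseases)

    def test_duplicates_merge_first_at_zero_height(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal((3, 10))
        rows = pd.DataFrame(
            np.vstack([base, base[0]]), index=["a", "b", "c", "a2"]
        )
        res = bt.cluster_profiles(rows, k=3)
        assert res.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert res.labels["a"] == res.labels["a2"]

    def test_row_scaling_invariance(self, profiles):
        scaled = profiles.values * 3.7
        a = bt.cluster_profiles(profiles.values, k=3)
        b = bt.cluster_profiles(scaled, k=3)
        assert a.labels == b.labels

    def test_constant_row_named_in_error(self):
        rows = pd.DataFrame([[1.0, 1.0, 1.0], [1, 2, 3]], index=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            bt.cluster_profiles(rows, k=2)


class TestStructureTests:
    def test_identical_rows_give_null_statistics(self):
        row = np.arange(6, dtype=float)
        rows = pd.DataFrame([row] * 4, index=list("abcd"))
        labels = {"a": 1, "b": 1, "c": 2, "d": 2}
        res = bt.structure_tests(rows, labels)
        assert (res.anova["F"] == 0).all()
        assert (res.anova["p"] == 1).all()
        assert (res.anova["q"] >= res.anova["p"]).all()

    def test_bh_hand_example(self):
        # step-up on (0.01, 0.02, 0.03, 0.04) gives q = 0.04 everywhere
        from statsmodels.stats.multitest import multipletests

        q = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        assert np.allclose(q, 0.04)

    def test_bh_matches_literal_step_up(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        p = rng.random(37)
        q = multipletests(p, method="fdr_bh")[1]
        # literal step-up re-implementation
        m = len(p)
        order = np.argsort(p)
        adj = p[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(adj[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(adj, 1.0)
        assert np.allclose(q, expected)

    def test_planted_shift_detected_only_at_shifted_structure(self):
        rng = np.random.default_rng(2)
        n, s = 8, 12
        rows = rng.standard_normal((2 * n, s))
        rows[:n, 4] += 3.0  # group 1 shifted at structure index 4
        rows = (rows - rows.mean(axis=1, keepdims=True)) / rows.std(axis=1, keepdims=True)
        df = pd.DataFrame(rows, index=[f"d{i}" for i in range(2 * n)],
                          columns=[f"s{j}" for j in range(s)])
        labels = {f"d{i}": int(i < n) for i in range(2 * n)}
        res = bt.structure_tests(df, labels)
        hit = res.anova.set_index("structure").loc["s4"]
        assert hit["q"] < 0.05
        others = res.anova[res.anova["structure"] != "s4"]
        assert (others["q"] > 0.05).mean() > 0.8

    def test_singleton_group_excluded_from_pairwise(self, profiles):
        labels = {d: i for i, d in enumerate(profiles.diseases)}
        # all singletons -> cannot test at all
        with pytest.raises(ValueError):
            bt.structure_tests(profiles, labels)


class TestIdentity:
    def test_identical_subjects_give_perfect_exact_freq(self, profiles, disease_sets):
        clone = bt.DiseaseProfileMatrix(
            values=profiles.values,
            per_subject=[profiles.values.copy() for _ in range(3)],
            subjects=["a", "b", "c"],
        )
        adg = {d: 1 for d in profiles.diseases}
        res = bt.crosssubject_identity(clone, adg, disease_sets.gbd)
        assert (res.exact_freq == 1.0).all()
        assert np.all(np.diag(res.assignment_counts.to_numpy()) == 6)

    def test_randomized_rows_hit_near_chance(self, profiles, disease_sets):
        rng = np.random.default_rng(11)
        n, s = profiles.values.shape
        rand = [
            pd.DataFrame(
                rng.standard_normal((n, s)),
                index=profiles.values.index,
                columns=profiles.values.columns,
            )
            for _ in range(4)
        ]
        noisy = bt.DiseaseProfileMatrix(
            values=profiles.values, per_subject=rand, subjects=list("abcd")
        )
        adg = {d: 1 for d in profiles.diseases}
        res = bt.crosssubject_identity(noisy, adg, disease_sets.gbd)
        # expectation 1/n with 12 comparisons per disease; loose 3x band
        assert res.exact_freq.mean() < 3.0 / n

    def test_metric_validation_and_affine_invariance(self, profiles, disease_sets):
        adg = {d: 1 for d in profiles.diseases}
        with pytest.raises(ValueError):
            bt.crosssubject_identity(profiles, adg, disease_sets.gbd, metric="cosine")
        res = bt.crosssubject_identity(profiles, adg, disease_sets.gbd, metric="pearson")
        rescaled = bt.DiseaseProfileMatrix(
            values=profiles.values,
            per_subject=[2.5 * m + 1.0 for m in profiles.per_subject],
            subjects=profiles.subjects,
        )
        res2 = bt.crosssubject_identity(rescaled, adg, disease_sets.gbd, metric="pearson")
        pd.testing.assert_frame_equal(res.assignment_counts, res2.assignment_counts)

    def test_exclude_self_never_assigns_self(self, profiles, disease_sets):
        adg = {d: 1 for d in profiles.diseases}
        res = bt.crosssubject_identity(
            profiles, adg, disease_sets.gbd, exclude_self=True
        )
        assert np.all(np.diag(res.assignment_counts.to_numpy()) == 0)
        assert (res.exact_freq == 0).all()


class TestSignatureCode:
    def test_roundtrip_all_120_permutations(self):
        codes = set()
        for perm in itertools.permutations([1, 2, 3, 4, 5]):
            values = [p * 10.0 for p in perm]
            code = bt.signature_code(values)
            ranks = decode_signature(code)
            assert list(ranks) == list(perm)
            codes.add(code)
        assert len(codes) == 120  # injective

    def test_ties(self):
        with pytest.raises(ValueError, match="tie"):
            bt.signature_code([1, 1, 2, 3, 4])
        code = bt.signature_code([1, 1, 2, 3, 4], tie_policy="stable-order")
        assert decode_signature(code) == (1, 2, 3, 4, 5)

    def test_wrong_arity(self):
        with pytest.raises(ValueError):
            bt.signature_code([1, 2, 3])


class TestSubsampleStability:
    def test_determinism_and_noop_downsample(self, cohort, disease_sets):
        expr, _, _ = cohort
        a = bt.subsample_stability(disease_sets, expr, max_genes=200, reps=3, k=3, seed=4)
        b = bt.subsample_stability(disease_sets, expr, max_genes=200, reps=3, k=3, seed=4)
        pd.testing.assert_frame_equal(a, b)
        # max_genes above every set size -> every rep identical -> frequencies 0/1
        assert set(np.unique(a.to_numpy())) <= {0.0, 1.0}

    def test_well_separated_groups_costable(self, cohort, disease_sets, small_cfg):
        expr, _, _ = cohort
        freq = bt.subsample_stability(disease_sets, expr, max_genes=6, reps=20, k=3, seed=4)
        truth = bt.planted_group_labels(small_cfg)
        for a in freq.index:
            for b in freq.columns:
                if truth[a] == truth[b]:
                    assert freq.loc[a, b] >= 0.95


class TestClusteringAgreement:
    def test_hand_case_and_identity(self):
        a = {"1": "x", "2": "x", "3": "y", "4": "y"}
        b = {"1": "x", "2": "y", "3": "x", "4": "y"}
        assert bt.clustering_agreement(a, b) == pytest.approx(1 / 3)
        assert bt.clustering_agreement(a, a) == 1.0
        singles = {k: k for k in "1234"}
        assert bt.clustering_agreement(singles, singles) == 1.0

    def test_mismatched_universe_rejected(self):
        with pytest.raises(ValueError):
            bt.clustering_agreement({"a": 1}, {"b": 1})
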