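"""CPM normalization, tau specificity, disease cell-type profiles, EWCE,
covariation maps and consensus representation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import braintx as bt
from braintx.celltype import specificity_matrix


def make_ct(values, celltypes=None, genes=None, species="human"):
    values = np.asarray(values, dtype=float)
    celltypes = celltypes or [f"c{i}" for i in range(values.shape[0])]
    genes = genes or [f"g{i}" for i in range(values.shape[1])]
    df = pd.DataFrame(values, index=celltypes, columns=genes)
    return bt.cpm_normalize(df, species=species)


class TestCpmNormalize:
    def test_hand_scaling(self):
        out = bt.cpm_normalize(pd.DataFrame([[1.0, 1.0, 2.0]], index=["c"]))
        assert np.allclose(out.values.to_numpy(), [[250000, 250000, 500000]])

    def test_idempotence_and_row_sums(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.random((4, 9)), index=list("abcd"))
        once = bt.cpm_normalize(df)
        twice = bt.cpm_normalize(once.values)
        pd.testing.assert_frame_equal(once.values, twice.values)
        assert np.allclose(once.values.sum(axis=1), 1e6, atol=1e-6)

    def test_zero_row_names_cell_type(self):
        df = pd.DataFrame([[1.0, 2.0], [0.0, 0.0]], index=["ok", "empty"])
        with pytest.raises(ValueError, match="empty"):
            bt.cpm_normalize(df)


class TestTau:
    def test_hand_cases(self):
        assert bt.tau_specificity([1, 1, 1, 1]) == pytest.approx(0.0)
        assert bt.tau_specificity([0, 5, 0]) == pytest.approx(1.0)
        assert bt.tau_specificity([1.0, 0.5, 0.0]) == pytest.approx(0.75)

    def test_all_zero_undefined(self):
        with pytest.raises(ValueError):
            bt.tau_specificity([0.0, 0.0])

    @settings(max_examples=150, deadline=None)
    @given(
        st.lists(st.floats(0, 100), min_size=2, max_size=12).filter(lambda x: max(x) > 0),
        st.floats(0.01, 50),
    )
    def test_scale_invariant_and_bounded(self, x, scale):
        t = bt.tau_specificity(x)
        assert 0.0 <= t <= 1.0
        assert bt.tau_specificity([scale * v for v in x]) == pytest.approx(t, abs=1e-9)

    def test_monotone_under_mass_transfer_to_max(self):
        x = np.array([5.0, 3.0, 2.0])
        before = bt.tau_specificity(x)
        x2 = np.array([6.0, 3.0, 1.0])  # move mass from non-maximal to maximal
        assert bt.tau_specificity(x2) > before

    def test_tau_all_matches_scalar(self, cells):
        human, _, _ = cells
        taus = bt.tau_all(human)
        for g in human.genes[:5]:
            assert taus[g] == pytest.approx(bt.tau_specificity(human.values[g]))


class TestDiseaseCellTypeMatrix:
    def test_single_gene_disease_row(self, cells):
        human, _, _ = cells
        g0, g1 = human.genes[0], human.genes[25]
        sets = bt.DiseaseGeneSets(
            sets={"a": {g0}, "b": {g1}, "c": {g0, g1}, "d": {human.genes[50]}},
            gbd={k: "other" for k in "abcd"},
        )
        res = bt.disease_celltype_matrix(sets, human, k=2, n_perm=50, seed=0)
        x = np.log1p(human.values[g0].to_numpy())
        z = (x - x.mean()) / x.std()
        assert np.allclose(res.matrix.loc["a"].to_numpy(), z)

    def test_planted_groups_recover_ctg(self, cells, disease_sets, small_cfg):
        human, _, _ = cells
        res = bt.disease_celltype_matrix(
            disease_sets, human, k=small_cfg.n_disease_groups, n_perm=50, seed=0
        )
        from sklearn.metrics import adjusted_rand_score

        truth = bt.planted_group_labels(small_cfg)
        diseases = list(res.matrix.index)
        ari = adjusted_rand_score(
            [truth[d] for d in diseases], [res.clusters.labels[d] for d in diseases]
        )
        assert ari == 1.0

    def test_random_sets_pooled_tau_near_corpus_mean(self, cells):
        human, _, _ = cells
        rng = np.random.default_rng(8)
        taus = bt.tau_all(human)
        genes = list(human.genes)
        sets = {
            f"r{i}": set(rng.choice(genes, size=15, replace=False)) for i in range(6)
        }
        dsets = bt.DiseaseGeneSets(sets=sets, gbd={k: "other" for k in sets})
        res = bt.disease_celltype_matrix(dsets, human, k=2, n_perm=400, seed=1)
        pooled = res.group_tau["pooled_tau"]
        se = taus.std() / np.sqrt(15)
        assert (np.abs(pooled - taus.mean()) < 4 * se).all()
        # and permutation p should not be extreme for random sets
        assert (res.group_tau["perm_p"] > 0.01).all()


class TestEwce:
    def test_exclusive_markers_hit_p_floor(self, cells):
        human, _, _ = cells
        spec = specificity_matrix(human)
        target_type = human.celltypes[0]
        markers = [g for g in human.genes if spec[g].idxmax() == target_type][:10]
        res = bt.ewce(markers, human, n_perm=200, seed=3)
        assert res.table.loc[target_type, "p"] == pytest.approx(1 / 201)
        assert res.table["p"].between(1 / 201, 1).all()
        assert (res.table["q"] >= res.table["p"]).all()

    def test_uniform_specificity_fold_near_one(self):
        rng = np.random.default_rng(5)
        expr = make_ct(np.ones((6, 300)) * rng.random(300))
        res = bt.ewce(expr.genes[:30], expr, n_perm=500, seed=0)
        assert np.allclose(res.table["fold"], 1.0, atol=1e-9)

    def test_fold_invariant_to_per_gene_rescaling(self, cells):
        # per-gene specificity normalization cancels any per-gene scale
        human, _, _ = cells
        rng = np.random.default_rng(7)
        scales = rng.uniform(0.1, 10.0, size=len(human.genes))
        rescaled = bt.CellTypeExpressionMatrix(
            values=human.values.mul(scales, axis=1),
            taxonomy=human.taxonomy,
            species="human",
        )
        a = bt.ewce(human.genes[:12], human, n_perm=100, seed=2)
        b = bt.ewce(human.genes[:12], rescaled, n_perm=100, seed=2)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_aggregation_levels(self, cells):
        human, _, _ = cells
        res_sub = bt.ewce(human.genes[:12], human, n_perm=50, seed=0, level="subclass")
        assert list(res_sub.table.index) == list(human.taxonomy["subclass"].unique())
        res_cls = bt.ewce(human.genes[:12], human, n_perm=50, seed=0, level="class")
        assert list(res_cls.table.index) == list(human.taxonomy["cls"].unique())

    def test_target_validation(self, cells):
        human, _, _ = cells
        with pytest.raises(ValueError, match="measured"):
            bt.ewce(["GHOST"], human, n_perm=10, seed=0)


class TestCovariation:
    def test_hand_cosine_cases(self):
        # two cell types over two genes: (1,0) vs (1,1) -> 1/sqrt(2)
        expr = make_ct(np.array([[1.0, 0.0], [1.0, 1.0]]))
        cov = bt.covariation_map({"d": {"g0", "g1"}}, expr, normalize="raw")
        m = cov.per_disease["d"]
        assert m.loc["c0", "c1"] == pytest.approx(1 / np.sqrt(2))
        assert m.loc["c0", "c0"] == 1.0

    def test_orthogonal_types(self):
        expr = make_ct(np.array([[1.0, 0.0], [0.0, 1.0]]))
        cov = bt.covariation_map({"d": {"g0", "g1"}}, expr, normalize="raw")
        assert cov.per_disease["d"].loc["c0", "c1"] == pytest.approx(0.0)

    def test_threshold_and_combined(self, cells, disease_sets):
        human, _, _ = cells
        unique = disease_sets.unique_sets()
        unique = {d: g for d, g in unique.items() if len(g) >= 2}
        cov = bt.covariation_map(unique, human)
        for d, m in cov.per_disease.items():
            x = m.to_numpy()
            assert np.allclose(x, x.T)
            iu = np.triu_indices(len(x), k=1)
            expected = x[iu].mean() + 1.5 * x[iu].std()
            assert cov.thresholds[d] == pytest.approx(expected)
        for (a, b), ds in cov.combined.items():
            for d in ds:
                assert cov.per_disease[d].loc[a, b] > cov.thresholds[d]

    def test_too_few_unique_genes_rejected(self, cells):
        human, _, _ = cells
        with pytest.raises(ValueError, match="fewer than 2"):
            bt.covariation_map({"d": {human.genes[0]}}, human)


class TestConsensus:
    def test_idempotent_mean(self, profiles):
        corr = profiles.values.T.corr()
        out = bt.consensus_matrix(corr, corr)
        pd.testing.assert_frame_equal(out, corr)
        assert np.allclose(out.to_numpy(), out.to_numpy().T)
        assert np.allclose(np.diag(out.to_numpy()), 1.0)

    def test_mismatched_universe_rejected(self, profiles):
        corr = profiles.values.T.corr()
        with pytest.raises(ValueError):
            bt.consensus_matrix(corr, corr.iloc[::-1])

    def test_gbd_ratio_zero_for_coincident_groups(self):
        coords = pd.DataFrame(
            {"x": [0.0, 0.0, 10.0, 10.0], "y": [0.0, 0.0, 0.0, 0.0]},
            index=list("abcd"),
        )
        gbd = {"a": "g1", "b": "g1", "c": "g2", "d": "g2"}
        ratios = bt.gbd_ratio(coords, gbd)
        assert np.allclose(ratios.to_numpy(), 0.0)

    def test_gbd_ratio_permuted_labels_near_one(self):
        rng = np.random.default_rng(9)
        coords = pd.DataFrame(
            rng.standard_normal((20, 2)), columns=["x", "y"],
            index=[f"d{i}" for i in range(20)],
        )
        means = []
        for _ in range(200):
            labels = dict(zip(coords.index, rng.permutation(["a"] * 10 + ["b"] * 10)))
            means.append(np.nanmean(bt.gbd_ratio(coords, labels)))
        assert abs(np.mean(means) - 1.0) < 0.05

    def test_gbd_ratio_missing_partner_is_nan(self):
        coords = pd.DataFrame(
            {"x": [0.0, 1.0, 2.0], "y": [0.0, 0.0, 0.0]}, index=list("abc")
        )
        ratios = bt.gbd_ratio(coords, {"a": "solo", "b": "g", "c": "g"})
        assert np.isnan(ratios["a"])

    def test_mds_embedding_deterministic(self, profiles):
        corr = profiles.values.T.corr()
        a = bt.embed_2d(corr, method="mds")
        b = bt.embed_2d(corr, method="mds")
        pd.testing.assert_frame_equal(a, b)
        with pytest.raises(ValueError):
            bt.embed_2d(corr, method="nope")
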