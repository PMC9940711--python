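"""Structure inference: PCA, BIC, admixture EM, distances, AMOVA, Fst."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from sklearn.metrics import silhouette_score

from yammerit import simulate, structure
from yammerit.containers import GenotypeMatrix, MarkerPanel
from yammerit.simulate import SimulationConfig


def _clustered_geno(fst, n=60, m=800, K=2, seed=0, admix=0.0):
    cfg = SimulationConfig(
        n_landraces=n, n_elite=0, n_markers=m, K_true=K, fst_target=fst,
        admix_fraction=admix, missing_rate=0.0, simulate_depth=False, seed=seed,
    )
    panel = simulate.generate_marker_panel(cfg)
    geno, model = simulate.generate_structured_genotypes(panel, cfg)
    return geno, model


def _matrix(dosage, ids=None):
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    panel = MarkerPanel(
        marker_id=np.array([f"chr1_{j + 1}" for j in range(m)]),
        chromosome=np.ones(m, dtype=int), position=np.arange(1, m + 1),
        ref_allele=np.full(m, "A"), alt_allele=np.full(m, "C"),
    )
    ids = np.array([f"s{i}" for i in range(n)]) if ids is None else np.asarray(ids)
    return GenotypeMatrix(sample_ids=ids, panel=panel, dosage=dosage)


class TestPca:
    def test_separates_diverged_clusters(self):
        geno, model = _clustered_geno(fst=0.3, seed=1)
        scores, _, _ = structure.pca_genotypes(geno, n_components=2)
        labels = model.Q_true.argmax(axis=1)
        assert silhouette_score(scores[:, :1], labels) > 0.8

    def test_constant_marker_zero_loading(self):
        x = np.array([[0, 2], [0, 0], [0, 2], [0, 0]])
        _, loadings, _ = structure.pca_genotypes(x, n_components=1)
        assert loadings[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_explained_variance_nonincreasing_and_bounded(self, imputed_small):
        x = imputed_small.dosage.astype(float)
        _, _, ev = structure.pca_genotypes(imputed_small, n_components=10)
        assert np.all(np.diff(ev) <= 1e-9)
        total_var = ((x - x.mean(0)) ** 2).sum() / (x.shape[0] - 1)
        assert ev.sum() <= total_var + 1e-8

    def test_too_many_components_rejected(self, imputed_small):
        with pytest.raises(ValueError):
            structure.pca_genotypes(imputed_small, n_components=10_000)


class TestSelectK:
    def test_recovers_three_clusters(self):
        hits = 0
        for seed in range(5):
            geno, _ = _clustered_geno(fst=0.2, n=90, m=1000, K=3, seed=seed)
            scores, _, _ = structure.pca_genotypes(geno, n_components=40)
            _, k_opt = structure.select_k_bic(scores, seed=seed)
            hits += k_opt == 3
        assert hits >= 4

    def test_single_cluster_curve_increases(self):
        rises = 0
        for seed in range(5):
            geno, _ = _clustered_geno(fst=0.0, n=60, m=500, K=1, seed=100 + seed)
            scores, _, _ = structure.pca_genotypes(geno, n_components=40)
            bic, _ = structure.select_k_bic(scores, k_range=range(1, 7), seed=seed)
            vals = [bic[k] for k in sorted(bic)]
            rises += all(np.diff(vals) > 0)
        assert rises >= 4

    def test_deterministic_under_seed(self, imputed_small):
        scores, _, _ = structure.pca_genotypes(imputed_small, n_components=5)
        a = structure.select_k_bic(scores, seed=7)
        b = structure.select_k_bic(scores, seed=7)
        assert a == b


class TestAdmixtureEM:
    def test_k1_closed_form(self):
        geno, _ = _clustered_geno(fst=0.0, n=30, m=200, K=1, seed=2)
        res = structure.admixture_em(geno, K=1)
        assert np.all(res.Q == 1.0)
        p = geno.dosage.mean(axis=0) / 2.0
        expect = np.clip(p, structure.F_EPS, 1 - structure.F_EPS)
        assert np.allclose(res.F[0], expect)
        x = geno.dosage.astype(float)
        ll = np.sum(x * np.log(expect) + (2 - x) * np.log1p(-expect))
        assert res.loglik == pytest.approx(ll)

    def test_two_cluster_recovery_and_monotone_loglik(self):
        geno, model = _clustered_geno(fst=0.25, n=60, m=800, K=2, seed=3)
        res = structure.admixture_em(geno, K=2, seed=3)
        assert np.all(np.diff(res.loglik_trace) >= -1e-8)
        assert res.Q.max(axis=1).mean() > 0.9
        assert np.allclose(res.Q.sum(axis=1), 1.0, atol=1e-8)
        assert res.F.min() >= structure.F_EPS and res.F.max() <= 1 - structure.F_EPS

    def test_restart_stability_up_to_label_permutation(self):
        from itertools import permutations

        geno, _ = _clustered_geno(fst=0.3, n=40, m=500, K=2, seed=4)
        base = structure.admixture_em(geno, K=2, seed=0)
        for seed in range(1, 5):
            alt = structure.admixture_em(geno, K=2, seed=seed)
            best = min(
                np.abs(alt.Q[:, list(perm)] - base.Q).max()
                for perm in permutations(range(2))
            )
            assert best < 0.05


class TestMembership:
    @pytest.mark.parametrize(
        "row, expected",
        [((0.8, 0.1, 0.1), "1"), ((0.5, 0.3, 0.2), "admixed"), ((0.7, 0.2, 0.1), "1")],
    )
    def test_threshold_rule(self, row, expected):
        assert structure.assign_membership(np.array([row]))[0] == expected

    @settings(max_examples=50, derandomize=True)
    @given(hnp.arrays(np.float64, (4, 3), elements=st.floats(0.01, 1.0)))
    def test_assignment_is_argmax_or_admixed_property(self, raw):
        """Every label is either the argmax cluster (top share >= 0.7) or admixed."""
        Q = raw / raw.sum(axis=1, keepdims=True)
        labels = structure.assign_membership(Q, threshold=0.70)
        for i, lab in enumerate(labels):
            if Q[i].max() >= 0.70:
                assert lab == str(Q[i].argmax() + 1)
            else:
                assert lab == "admixed"


class TestDistances:
    def test_identical_samples_zero(self):
        geno = _matrix([[0, 1, 2], [0, 1, 2]])
        for method in ("one_minus_ibs", "jaccard"):
            d = structure.distance_matrix(geno, method)
            assert d.values[0, 1] == pytest.approx(0.0)

    def test_opposite_homozygotes_maximal_ibs(self):
        geno = _matrix([[0, 2], [2, 0]])
        d = structure.distance_matrix(geno, "one_minus_ibs")
        assert d.values[0, 1] == pytest.approx(1.0)

    def test_jaccard_matches_hand_sets(self):
        # hand-computed set Jaccard: d(0,1)=0.75, d(0,2)=0.75, d(1,2)=1.0
        geno = _matrix([[0, 1, 2, 0, 1], [1, 0, 2, 0, 0], [0, 0, 0, 1, 2]])
        d = structure.distance_matrix(geno, "jaccard")
        assert d.values[0, 1] == pytest.approx(0.75)
        assert d.values[0, 2] == pytest.approx(0.75)
        assert d.values[1, 2] == pytest.approx(1.0)

    def test_symmetry_zero_diagonal(self, imputed_small):
        for method in ("one_minus_ibs", "jaccard"):
            d = structure.distance_matrix(imputed_small, method)
            assert np.allclose(d.values, d.values.T)
            assert np.allclose(np.diag(d.values), 0.0)


class TestWardTree:
    def _toy_dist(self):
        # two tight pairs (a,b) and (c,d), far apart
        ids = np.array(["a", "b", "c", "d"])
        vals = np.array(
            [[0.0, 0.1, 1.0, 1.1], [0.1, 0.0, 1.05, 1.0], [1.0, 1.05, 0.0, 0.12], [1.1, 1.0, 0.12, 0.0]]
        )
        return structure.DistanceMatrix(sample_ids=ids, values=vals, method="one_minus_ibs")

    def test_first_merges_are_the_pairs(self):
        tree = structure.ward_tree(self._toy_dist())
        Z = tree.linkage_matrix
        first_two = {frozenset(map(int, Z[0, :2])), frozenset(map(int, Z[1, :2]))}
        ids = list(tree.sample_ids)
        assert frozenset((ids.index("a"), ids.index("b"))) in first_two
        assert frozenset((ids.index("c"), ids.index("d"))) in first_two
        labels = tree.cut_at(2)
        by_id = dict(zip(tree.sample_ids, labels))
        assert by_id["a"] == by_id["b"] != by_id["c"] == by_id["d"]

    def test_cut_at_n_gives_singletons(self):
        tree = structure.ward_tree(self._toy_dist())
        assert len(set(tree.cut_at(4))) == 4

    def test_newick_round_trip_leaves(self):
        import dendropy

        tree = structure.ward_tree(self._toy_dist())
        t = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        leaves = sorted(l.taxon.label for l in t.leaf_node_iter())
        assert leaves == ["a", "b", "c", "d"]

    def test_single_sample_rejected(self):
        d = structure.DistanceMatrix(np.array(["a"]), np.zeros((1, 1)), "jaccard")
        with pytest.raises(ValueError):
            structure.ward_tree(d)


class TestAmova:
    def test_hand_computed_two_groups(self):
        # 2 groups of 3; within-group d=0, between-group d=1
        vals = np.ones((6, 6)) - np.eye(6)
        vals[:3, :3] = 0.0
        vals[3:, 3:] = 0.0
        d = structure.DistanceMatrix(np.array(list("abcdef")), vals, "one_minus_ibs")
        table = structure.amova(d, np.array([1, 1, 1, 2, 2, 2]))
        assert table.loc["total", "SS"] == pytest.approx(1.5)
        assert table.loc["among", "SS"] == pytest.approx(1.5)
        assert table.loc["within", "SS"] == pytest.approx(0.0)
        assert table.loc["among", "est_var"] == pytest.approx(0.5)
        assert table.loc["among", "pct_variation"] == pytest.approx(100.0)

    def test_degenerate_all_identical(self):
        d = structure.DistanceMatrix(np.array(list("abcd")), np.zeros((4, 4)), "jaccard")
        table = structure.amova(d, np.array([1, 1, 2, 2]))
        assert table.attrs["degenerate"]
        assert table.loc["among", "pct_variation"] == 0.0

    def test_additivity_on_real_distances(self, imputed_small):
        d = structure.distance_matrix(imputed_small, "one_minus_ibs")
        groups = np.repeat([1, 2, 3], [15, 15, 15])
        table = structure.amova(d, groups)
        assert table.loc["among", "SS"] + table.loc["within", "SS"] == pytest.approx(
            table.loc["total", "SS"], abs=1e-9
        )
        assert table.loc["among", "df"] + table.loc["within", "df"] == table.loc["total", "df"]
        assert table.loc["among", "pct_variation"] + table.loc["within", "pct_variation"] == pytest.approx(100.0, abs=0.5)

    def test_all_singletons_rejected(self):
        d = structure.DistanceMatrix(np.array(list("abc")), np.ones((3, 3)) - np.eye(3), "jaccard")
        with pytest.raises(ValueError):
            structure.amova(d, np.array([1, 2, 3]))


class TestFst:
    def test_textbook_toy_exact(self):
        # frozen from an independent scalar evaluation of the a,b,c components
        geno = _matrix(np.array([[0], [1], [1], [2], [0], [2], [2], [1], [2], [2]]))
        mask1 = np.arange(10) < 5
        theta, per_locus = structure.wc_fst(geno, mask1, ~mask1)
        assert theta == pytest.approx(0.35344827586206906, abs=1e-10)
        assert per_locus[0] == pytest.approx(theta, abs=1e-10)

    def test_fixed_difference_is_one(self):
        geno = _matrix(np.vstack([np.zeros((10, 5)), np.full((10, 5), 2)]))
        mask = np.arange(20) < 10
        theta, _ = structure.wc_fst(geno, mask, ~mask)
        assert theta == pytest.approx(1.0)

    def test_null_split_near_zero(self):
        geno, _ = _clustered_geno(fst=0.0, n=100, m=1000, K=1, seed=8)
        thetas = []
        for seed in range(5):
            split = np.random.default_rng(seed).permutation(100) < 50
            theta, _ = structure.wc_fst(geno, split, ~split)
            thetas.append(theta)
        assert abs(np.mean(thetas)) < 0.01

    def test_pairwise_table_symmetric(self, imputed_small):
        groups = np.repeat([1, 2, 3], [15, 15, 15])
        fst = structure.pairwise_fst(imputed_small, groups)
        assert np.allclose(fst.to_numpy(), fst.to_numpy().T)
        assert np.allclose(np.diag(fst.to_numpy()), 0.0)
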