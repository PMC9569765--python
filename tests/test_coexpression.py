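import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from cernaffl import coexpression as cx
from cernaffl.data_io import DataValidationError
from cernaffl.diffexpr import log_normalize
from cernaffl.synthetic_data import SimulationConfig, simulate_counts
from conftest import make_matrix


def factor_matrix(rng, blocks, n_noise, n_samples, loading=0.8):
    """Direct factor-model expression: each block shares a latent factor."""
    rows, labels = [], []
    for b, size in enumerate(blocks, start=1):
        f = rng.normal(size=n_samples)
        for _ in range(size):
            rows.append(loading * f + np.sqrt(1 - loading ** 2) * rng.normal(size=n_samples))
            labels.append(b)
    for _ in range(n_noise):
        rows.append(rng.normal(size=n_samples))
        labels.append(0)
    return make_matrix(np.array(rows)), np.array(labels)


class TestMadFilter:
    def test_keeps_75_percent_of_1000(self, rng):
        mat = make_matrix(rng.normal(size=(1000, 10)))
        assert cx.mad_filter(mat).values.shape[0] == 750

    def test_constant_gene_dropped_first(self, rng):
        vals = rng.normal(size=(5, 8))
        vals[2] = 7.0  # MAD 0
        kept = cx.mad_filter(make_matrix(vals), keep_fraction=0.8)
        assert "F002" not in kept.feature_ids

    def test_ceiling_of_fraction(self, rng):
        mat = make_matrix(rng.normal(size=(4, 6)))
        assert cx.mad_filter(mat, 0.75).values.shape[0] == 3

    def test_bad_fraction_error(self, rng):
        with pytest.raises(DataValidationError):
            cx.mad_filter(make_matrix(rng.normal(size=(5, 4))), 1.5)


class TestSoftThreshold:
    def test_power_one_adjacency_is_absolute_correlation(self, rng):
        vals = rng.normal(size=(6, 20))
        adj = cx._adjacency(vals, 1)
        cor = np.abs(np.corrcoef(vals))
        np.fill_diagonal(cor, 0.0)
        assert np.allclose(adj, cor)

    def test_mean_connectivity_decreases_with_power(self, rng):
        mat = make_matrix(rng.normal(size=(30, 20)))
        _, diag = cx.pick_soft_threshold(mat, powers=[1, 2, 4, 8])
        assert np.all(np.diff(diag["mean_k"]) < 0)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_scale_free_data_reaches_target_fit(self, seed):
        # Gaussian Markov field on a preferential-attachment tree:
        # cor(i, j) = c^distance exactly, so connectivity follows the
        # scale-free degree distribution of the tree
        import networkx as nx
        c, n_nodes, n_samples = 0.55, 2000, 150
        rr = np.random.default_rng(seed)
        g = nx.barabasi_albert_graph(n_nodes, 1, seed=seed)
        x = np.zeros((n_nodes, n_samples))
        parent = {v: u for u, v in nx.bfs_edges(g, 0)}
        x[0] = rr.normal(size=n_samples)
        for v in list(nx.bfs_tree(g, 0))[1:]:
            x[v] = c * x[parent[v]] + np.sqrt(1 - c ** 2) * rr.normal(size=n_samples)
        beta, diag = cx.pick_soft_threshold(make_matrix(x), powers=[1, 2, 3, 4])
        assert float(diag.loc[diag["power"] == beta, "r2"].iloc[0]) >= 0.8
        assert beta == int(diag[diag["r2"] >= 0.8]["power"].iloc[0])

    def test_degenerate_matrix_error(self):
        with pytest.raises(DataValidationError):
            cx.pick_soft_threshold(make_matrix(np.ones((25, 10))))


class TestTom:
    def test_hand_computed_three_nodes(self):
        adj = np.array([[0, 0.5, 0.5], [0.5, 0, 0], [0.5, 0, 0]])
        tom = cx.tom_from_adjacency(adj)
        # TOM_23 = (0.5*0.5 + 0) / (min(0.5, 0.5) + 1 - 0) = 1/6
        assert tom[1, 2] == pytest.approx(1 / 6)

    def test_perfect_triangle_saturates(self):
        adj = np.ones((3, 3)) - np.eye(3)
        tom = cx.tom_from_adjacency(adj)
        assert np.allclose(tom, 1.0)

    def test_isolated_gene_row_near_zero(self, rng):
        vals = rng.normal(size=(6, 200))
        vals[0] = rng.normal(size=200)  # independent of the rest
        tom = cx.tom_similarity(make_matrix(vals), beta=6)
        assert tom.iloc[0, 1:].max() < 0.1

    def test_symmetry_unit_diagonal_and_range(self, rng):
        for _ in range(10):
            adj = rng.random((8, 8))
            adj = (adj + adj.T) / 2
            np.fill_diagonal(adj, 0.0)
            tom = cx.tom_from_adjacency(adj)
            assert np.allclose(tom, tom.T)
            assert np.allclose(np.diag(tom), 1.0)
            assert tom.min() >= 0.0 and tom.max() <= 1.0


class TestDetectModules:
    def test_planted_blocks_recovered_exactly(self, rng):
        mat, truth = factor_matrix(rng, [50, 50], 0, 40, loading=0.9)
        tom = cx.tom_similarity(mat, beta=6)
        labels = cx.detect_modules(tom, min_module_size=10)
        assert adjusted_rand_score(truth, labels.to_numpy()) == 1.0

    def test_identical_rows_single_module(self):
        tom = pd.DataFrame(np.ones((40, 40)), index=[f"g{i}" for i in range(40)],
                           columns=[f"g{i}" for i in range(40)])
        labels = cx.detect_modules(tom, min_module_size=10)
        assert set(labels) == {1}

    def test_min_size_filter_unassigns_all(self, rng):
        mat, _ = factor_matrix(rng, [10], 0, 30)
        tom = cx.tom_similarity(mat, beta=4)
        labels = cx.detect_modules(tom, min_module_size=30)
        assert set(labels) == {0}

    def test_gene_permutation_preserves_partition(self, rng):
        mat, _ = factor_matrix(rng, [30, 30], 5, 40)
        tom = cx.tom_similarity(mat, beta=6)
        labels = cx.detect_modules(tom, min_module_size=10)
        perm = rng.permutation(tom.shape[0])
        tom_p = tom.iloc[perm, perm]
        labels_p = cx.detect_modules(tom_p, min_module_size=10)
        aligned = labels_p.loc[labels.index]
        assert adjusted_rand_score(labels.to_numpy(), aligned.to_numpy()) == 1.0


class TestEigengenes:
    def test_identical_genes_recover_profile(self, rng):
        profile = rng.normal(size=20)
        vals = np.tile(profile, (5, 1))
        mat = make_matrix(vals)
        labels = pd.Series([1] * 5, index=mat.feature_ids)
        me = cx.module_eigengenes(mat, labels)
        r = np.corrcoef(me.loc[1], profile)[0, 1]
        assert r == pytest.approx(1.0)

    def test_sign_flip_of_module_leaves_me_correlated(self, rng):
        mat, _ = factor_matrix(rng, [10], 0, 30)
        labels = pd.Series([1] * 10, index=mat.feature_ids)
        me_a = cx.module_eigengenes(mat, labels)
        flipped = make_matrix(-mat.values.to_numpy())
        me_b = cx.module_eigengenes(flipped, pd.Series([1] * 10, index=flipped.feature_ids))
        # orientation rule picks the direction agreeing with the module genes
        r = np.corrcoef(me_a.loc[1], me_b.loc[1])[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-9)

    def test_planted_factor_recovered(self, rng):
        n_samples = 50
        f = rng.normal(size=n_samples)
        rows = [0.85 * f + 0.4 * rng.normal(size=n_samples) for _ in range(20)]
        mat = make_matrix(np.array(rows))
        labels = pd.Series([1] * 20, index=mat.feature_ids)
        me = cx.module_eigengenes(mat, labels)
        assert abs(np.corrcoef(me.loc[1], f)[0, 1]) >= 0.95

    def test_single_gene_module_error(self, rng):
        mat = make_matrix(rng.normal(size=(2, 10)))
        labels = pd.Series([1, 2], index=mat.feature_ids)
        with pytest.raises(DataValidationError):
            cx.module_eigengenes(mat, labels)


class TestMergeModules:
    def _two_module_matrix(self, rng, shared=True):
        n = 40
        f1 = rng.normal(size=n)
        f2 = 0.95 * f1 + np.sqrt(1 - 0.95 ** 2) * rng.normal(size=n) if shared \
            else rng.normal(size=n)
        rows = [0.9 * f1 + 0.3 * rng.normal(size=n) for _ in range(12)]
        rows += [0.9 * f2 + 0.3 * rng.normal(size=n) for _ in range(12)]
        mat = make_matrix(np.array(rows))
        labels = pd.Series([1] * 12 + [2] * 12, index=mat.feature_ids)
        return mat, labels

    def test_highly_correlated_modules_merge(self, rng):
        mat, labels = self._two_module_matrix(rng, shared=True)
        merged, _ = cx.merge_modules(mat, labels, merge_r=0.75)
        assert merged.nunique() == 1

    def test_uncorrelated_modules_unchanged(self, rng):
        mat, labels = self._two_module_matrix(rng, shared=False)
        merged, _ = cx.merge_modules(mat, labels, merge_r=0.75)
        assert merged.nunique() == 2

    def test_three_mutually_correlated_merge_to_one(self, rng):
        n = 40
        f = rng.normal(size=n)
        rows = [0.95 * f + 0.2 * rng.normal(size=n) for _ in range(18)]
        mat = make_matrix(np.array(rows))
        labels = pd.Series([1] * 6 + [2] * 6 + [3] * 6, index=mat.feature_ids)
        merged, _ = cx.merge_modules(mat, labels, merge_r=0.75)
        assert merged.nunique() == 1


class TestTraitCorrelation:
    def test_me_equal_to_trait(self):
        trait = pd.Series([0.0, 0, 0, 1, 1, 1], index=[f"s{i}" for i in range(6)])
        me = pd.DataFrame([trait.to_numpy()], index=[1], columns=trait.index)
        r, p, selected = cx.module_trait_correlation(me, trait)
        assert r[1] == pytest.approx(1.0)
        assert selected == 1

    def test_anti_trait_me(self):
        trait = pd.Series([0.0, 0, 0, 1, 1, 1], index=[f"s{i}" for i in range(6)])
        me = pd.DataFrame([-trait.to_numpy()], index=[1], columns=trait.index)
        r, _, selected = cx.module_trait_correlation(me, trait)
        assert r[1] == pytest.approx(-1.0)
        assert selected == 1

    def test_null_false_selection_rate(self, rng):
        trait = pd.Series([0.0] * 25 + [1.0] * 25, index=[f"s{i}" for i in range(50)])
        hits = 0
        for _ in range(100):
            me = pd.DataFrame([rng.normal(size=50)], index=[1], columns=trait.index)
            _, p, _ = cx.module_trait_correlation(me, trait)
            hits += p[1] < 0.05
        assert hits <= 12  # ~5% nominal

    def test_constant_trait_error(self):
        trait = pd.Series([1.0] * 6, index=[f"s{i}" for i in range(6)])
        me = pd.DataFrame([np.arange(6.0)], index=[1], columns=trait.index)
        with pytest.raises(DataValidationError):
            cx.module_trait_correlation(me, trait)


class TestPlantedRecoveryFromCounts:
    def test_planted_modules_recovered_from_count_data(self):
        """Full path: counts -> log normalize -> TOM -> clusters, ARI >= 0.9."""
        aris = []
        for seed in range(5):
            genes = [f"G{i:04d}" for i in range(120)]
            cfg = SimulationConfig(
                n_genes=120, n_mirnas=0, n_lncrnas=0, n_tfs=0, n_pairs=25,
                planted_modules=[(tuple(genes[:30]), 0.9, 0),
                                 (tuple(genes[30:60]), 0.9, 0)],
                seed=seed)
            mats, gt = simulate_counts(cfg)
            expr = log_normalize(mats["mRNA"])
            beta, _ = cx.pick_soft_threshold(expr)
            tom = cx.tom_similarity(expr, beta)
            labels = cx.detect_modules(tom, min_module_size=10)
            truth = np.array([gt.true_module_labels.get(g, 0) for g in expr.feature_ids])
            aris.append(adjusted_rand_score(truth, labels.to_numpy()))
        assert np.mean(aris) >= 0.9
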