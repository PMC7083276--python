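import networkx as nx
import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from sigscale import (
    AssociationTable,
    GeneScoreTable,
    auc_score,
    combine_scores,
    cross_validate,
    mss_scores,
    rwr_scores,
    synthetic_ppi,
)


@pytest.fixture(scope="module")
def small_ppi():
    graph, assoc, truth, designated = synthetic_ppi(
        module_sizes=(40,) * 8, n_disease_genes=30, n_disease_modules=2, seed=5
    )
    return graph, assoc["synthetic_disease"], truth, designated


class TestMSSScores:
    def test_module_proportion_hand_example(self):
        g = nx.path_graph(10)
        part = {i: 0 for i in range(10)}
        table = mss_scores(g, [part], train_genes={0, 1, 2})
        assert all(v == pytest.approx(0.3) for v in table.scores.values())

    def test_gene_without_train_module_scores_zero(self):
        g = nx.Graph([(0, 1), (2, 3)])
        part = {0: 0, 1: 0, 2: 1, 3: 1}
        table = mss_scores(g, [part], train_genes={0})
        assert table.scores[2] == 0.0 and table.scores[3] == 0.0

    def test_mean_over_partitions(self):
        g = nx.Graph([(0, 1), (1, 2), (2, 3)])
        p1 = {0: 0, 1: 0, 2: 1, 3: 1}  # gene 1 in module with train gene 0 -> 0.5
        p2 = {0: 0, 1: 1, 2: 1, 3: 1}  # gene 1 in train-free module -> 0
        table = mss_scores(g, [p1, p2], train_genes={0})
        assert table.scores[1] == pytest.approx(0.25)
        table_max = mss_scores(g, [p1, p2], train_genes={0}, combine="max")
        assert table_max.scores[1] == pytest.approx(0.5)

    def test_empty_train_rejected(self):
        g = nx.path_graph(4)
        with pytest.raises(ValueError):
            mss_scores(g, [{i: 0 for i in g}], train_genes=set())


class TestRWRScores:
    def test_restart_one_returns_seed_distribution(self):
        g = nx.path_graph(5)
        table = rwr_scores(g, {1, 3}, restart=1.0)
        assert table.scores[1] == pytest.approx(0.5)
        assert table.scores[0] == 0.0

    def test_scores_sum_to_one(self):
        g = nx.gnp_random_graph(60, 0.1, seed=2)
        table = rwr_scores(g, {0, 1, 2}, restart=0.7)
        assert sum(table.scores.values()) == pytest.approx(1.0, abs=1e-9)

    def test_path_center_matches_linear_solve(self):
        g = nx.path_graph(5)
        c = 0.7
        table = rwr_scores(g, {2}, restart=c)
        adj = nx.to_numpy_array(g)
        w = adj / adj.sum(axis=0, keepdims=True)
        e = np.zeros(5)
        e[2] = 1.0
        x = np.linalg.solve(np.eye(5) - (1 - c) * w, c * e)
        for i in range(5):
            assert table.scores[i] == pytest.approx(x[i], abs=1e-8)

    def test_disjoint_seeds_rejected(self):
        g = nx.path_graph(3)
        with pytest.raises(ValueError):
            rwr_scores(g, {"absent"})


class TestCombineScores:
    def _tables(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(30)]
        a = GeneScoreTable({g: float(rng.random()) for g in genes}, "a")
        b = GeneScoreTable({g: float(rng.random()) for g in genes}, "b")
        return genes, a, b

    def test_weight_endpoints_preserve_ranking(self):
        genes, a, b = self._tables()
        for w, src in ((1.0, a), (0.0, b)):
            combined = combine_scores(a, b, weight=w)
            order = sorted(genes, key=lambda g: combined.scores[g])
            assert order == sorted(genes, key=lambda g: src.scores[g])

    def test_constant_vector_defers_to_other(self):
        genes, _, b = self._tables()
        const = GeneScoreTable({g: 0.7 for g in genes}, "const")
        combined = combine_scores(const, b, weight=0.5)
        order = sorted(genes, key=lambda g: combined.scores[g])
        assert order == sorted(genes, key=lambda g: b.scores[g])

    def test_universe_mismatch_rejected(self):
        genes, a, b = self._tables()
        del b.scores[genes[0]]
        with pytest.raises(ValueError):
            combine_scores(a, b)


class TestAUC:
    def test_agrees_with_mann_whitney(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            pos = rng.normal(0.5, 1, size=rng.integers(3, 20))
            neg = rng.normal(0.0, 1, size=rng.integers(3, 40))
            u = mannwhitneyu(pos, neg, alternative="two-sided").statistic
            assert auc_score(pos, neg) == pytest.approx(u / (len(pos) * len(neg)))

    def test_ties_mid_ranked(self):
        # pos-neg pairs: two clear wins, one tie counted half -> 3/4
        assert auc_score([1.0, 1.0], [1.0, 0.0]) == pytest.approx(0.75)


class TestCrossValidate:
    def test_perfect_oracle_gives_auc_one(self, small_ppi):
        graph, genes, _, _ = small_ppi
        oracle = lambda train: {g: (1.0 if g in genes else 0.0) for g in graph}
        cv = cross_validate(graph, genes, oracle, seed=0)
        assert cv.fold_aucs == [1.0] * 5

    def test_random_scores_near_half(self, small_ppi):
        graph, genes, _, _ = small_ppi
        aucs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            scorer = lambda train: {g: float(rng.random()) for g in graph}
            aucs.append(cross_validate(graph, genes, scorer, seed=seed).mean_auc)
        # null AUC has SE ~ sqrt((np+nn+1)/(12*np*nn)) per fold
        assert abs(np.mean(aucs) - 0.5) < 3 * 0.13 / np.sqrt(len(aucs) * 5)

    def test_folds_partition_gene_set(self, small_ppi):
        graph, genes, _, _ = small_ppi
        oracle = lambda train: {g: 0.0 for g in graph}
        cv = cross_validate(graph, genes, oracle, seed=3)
        pooled = [g for fold in cv.folds for g in fold]
        assert sorted(pooled, key=str) == sorted(set(genes) & set(graph), key=str)
        sizes = sorted(len(f) for f in cv.folds)
        assert sizes[-1] - sizes[0] <= 1

    def test_too_few_genes_rejected(self):
        g = nx.path_graph(10)
        with pytest.raises(ValueError):
            cross_validate(g, {0, 1, 2}, "rwr", k=5)


class TestSyntheticPPI:
    def test_association_inclusion_criterion(self, small_ppi):
        _, genes, _, _ = small_ppi
        assert len(genes) >= 20
        with pytest.raises(ValueError):
            synthetic_ppi(module_sizes=(30,) * 4, n_disease_genes=10, seed=0)

    def test_full_concentration_zero_pout_confines_disease_genes(self):
        graph, assoc, truth, designated = synthetic_ppi(
            module_sizes=(30,) * 6,
            p_out=0.0,
            concentration=1.0,
            n_disease_genes=20,
            n_disease_modules=2,
            seed=7,
        )
        for gene in assoc["synthetic_disease"]:
            assert truth[gene] in designated

    def test_edge_count_expectation(self):
        """Total edges within 3 SE of the planted-partition expectation."""
        sizes = (20,) * 5
        p_in, p_out = 0.3, 0.02
        pairs_in = 5 * 20 * 19 / 2
        pairs_out = (100 * 99 / 2) - pairs_in
        mean_m = pairs_in * p_in + pairs_out * p_out
        var_m = pairs_in * p_in * (1 - p_in) + pairs_out * p_out * (1 - p_out)
        ms = []
        for seed in range(50):
            g, _, _, _ = synthetic_ppi(
                module_sizes=sizes, p_in=p_in, p_out=p_out, n_disease_genes=20, seed=seed
            )
            ms.append(g.number_of_edges())
        assert abs(np.mean(ms) - mean_m) < 3 * np.sqrt(var_m / 50)

    def test_association_table_validation(self):
        table = AssociationTable({"d": set(f"g{i}" for i in range(5))})
        with pytest.raises(ValueError):
            table.validate()
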