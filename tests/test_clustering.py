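import itertools

import numpy as np
import pytest

from phenolink.clustering import (
    ClusterAssignment,
    TermGraph,
    cluster_cross_ontology_similarity,
    normalized_cut_value,
    project_term_graph,
    recursive_split,
    spectral_ncut,
)
from phenolink.ontology import OntologyDAG, compute_ic, propagate


def exhaustive_min_ncut(graph: TermGraph, k: int = 2) -> float:
    """Minimum normalized cut over all k-partitions (tiny graphs only)."""
    n = graph.n_nodes
    best = np.inf
    for labels in itertools.product(range(k), repeat=n):
        if len(set(labels)) != k:
            continue
        best = min(best, normalized_cut_value(graph, np.array(labels)))
    return best


def planted_two_block(n=8, within=1.0, between=0.05, seed=0):
    rng = np.random.default_rng(seed)
    w = np.full((n, n), between)
    half = n // 2
    w[:half, :half] = within
    w[half:, half:] = within
    w += rng.uniform(0, 0.01, size=(n, n))  # break symmetry-induced ties
    w = np.clip((w + w.T) / 2, 0, 1)
    np.fill_diagonal(w, 0)
    return TermGraph(nodes=[f"t{i}" for i in range(n)], weights=w)


class TestTermGraph:
    def test_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            TermGraph(["a", "b"], np.array([[0, 1], [0.5, 0]]))
        with pytest.raises(ValueError, match="self-loops"):
            TermGraph(["a"], np.array([[1.0]]))

    def test_components(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 1.0
        g = TermGraph(["a", "b", "c", "d"], w)
        comps = g.components()
        assert sorted(tuple(c) for c in comps) == [(0, 1), (2, 3)]


class TestProjection:
    @pytest.fixture
    def flat_dag(self):
        terms = {"root", "t1", "t2", "t3"}
        return OntologyDAG(
            terms=terms,
            parents={"root": set(), "t1": {"root"}, "t2": {"root"}, "t3": {"root"}},
            root="root",
        )

    def test_jaccard_weight(self, flat_dag):
        corpus = propagate({"g1": {"t1"}, "g2": {"t1", "t2"}, "g3": {"t2"}}, flat_dag)
        graph = project_term_graph(corpus, term_set={"t1", "t2"})
        i, j = graph.nodes.index("t1"), graph.nodes.index("t2")
        assert graph.weights[i, j] == pytest.approx(1 / 3)

    def test_disjoint_gene_sets_no_edge(self, flat_dag):
        corpus = propagate({"g1": {"t1"}, "g2": {"t2"}}, flat_dag)
        graph = project_term_graph(corpus, term_set={"t1", "t2"})
        assert graph.weights[0, 1] == 0.0

    def test_identical_gene_sets_weight_one(self, flat_dag):
        corpus = propagate({"g1": {"t1", "t2"}, "g2": {"t1", "t2"}}, flat_dag)
        graph = project_term_graph(corpus, term_set={"t1", "t2"})
        assert graph.weights[0, 1] == pytest.approx(1.0)

    def test_weights_match_set_oracle(self, toy50_dag):
        rng = np.random.default_rng(17)
        terms = sorted(toy50_dag.terms)
        direct = {
            f"g{i}": set(rng.choice(terms, size=rng.integers(1, 4), replace=False))
            for i in range(30)
        }
        corpus = propagate(direct, toy50_dag)
        graph = project_term_graph(corpus)
        gene_sets = {
            t: {g for g in corpus.universe if t in corpus.propagated[g]} for t in graph.nodes
        }
        for i, t1 in enumerate(graph.nodes):
            for j in range(i + 1, len(graph.nodes)):
                t2 = graph.nodes[j]
                inter = gene_sets[t1] & gene_sets[t2]
                expected = len(inter) / len(gene_sets[t1] | gene_sets[t2]) if inter else 0.0
                assert graph.weights[i, j] == pytest.approx(expected)

    def test_zero_gene_terms_dropped(self, flat_dag, caplog):
        corpus = propagate({"g1": {"t1"}}, flat_dag)
        with caplog.at_level("WARNING"):
            graph = project_term_graph(corpus, term_set={"t1", "t2"})
        assert "t2" not in graph.nodes


class TestSpectralNcut:
    def test_two_disconnected_cliques(self):
        w = np.zeros((6, 6))
        w[:3, :3] = 1.0
        w[3:, 3:] = 1.0
        np.fill_diagonal(w, 0)
        graph = TermGraph([f"t{i}" for i in range(6)], w)
        assign = spectral_ncut(graph, k=2, seed=0)
        groups = {}
        for t, c in assign.assignment.items():
            groups.setdefault(c, set()).add(t)
        assert set(map(frozenset, groups.values())) == {
            frozenset({"t0", "t1", "t2"}),
            frozenset({"t3", "t4", "t5"}),
        }
        assert assign.objective == pytest.approx(0.0)

    def test_k_one(self):
        graph = planted_two_block()
        assign = spectral_ncut(graph, k=1, seed=0)
        assert set(assign.assignment.values()) == {0}
        assert assign.objective == pytest.approx(0.0)

    def test_k_too_large(self):
        graph = planted_two_block()
        with pytest.raises(ValueError):
            spectral_ncut(graph, k=9, seed=0)

    def test_exhaustive_oracle_on_planted_blocks(self):
        for seed in range(20):
            graph = planted_two_block(n=8, seed=seed)
            assign = spectral_ncut(graph, k=2, seed=seed)
            best = exhaustive_min_ncut(graph, k=2)
            assert assign.objective == pytest.approx(best, abs=1e-8)

    def test_beats_random_partitions(self):
        graph = planted_two_block(n=10, seed=3)
        assign = spectral_ncut(graph, k=3, seed=0)
        rng = np.random.default_rng(0)
        done = 0
        while done < 100:
            labels = rng.integers(0, 3, size=10)
            if len(set(labels.tolist())) != 3:
                continue
            done += 1
            assert assign.objective <= normalized_cut_value(graph, labels) + 1e-9

    def test_contiguous_cluster_ids(self):
        graph = planted_two_block(n=10, seed=1)
        assign = spectral_ncut(graph, k=4, seed=0)
        assert set(assign.assignment.values()) == set(range(assign.k))


class TestRecursiveSplit:
    def test_empty_splits_identical(self):
        graph = planted_two_block(n=10, seed=2)
        a = spectral_ncut(graph, k=2, seed=5)
        b = recursive_split(graph, base_k=2, splits=[], seed=5)
        assert a.assignment == b.assignment

    def test_cluster_count_identity(self):
        graph = planted_two_block(n=12, seed=4)
        assign = recursive_split(graph, base_k=2, splits=[(1, 3), (2, 2)], seed=0)
        assert assign.k == 2 - 2 + 3 + 2

    def test_locality_of_split(self):
        graph = planted_two_block(n=12, seed=6)
        base = spectral_ncut(graph, k=2, seed=1)
        split = recursive_split(graph, base_k=2, splits=[(1, 2)], seed=1)
        sizes = sorted(base.sizes().items(), key=lambda kv: (-kv[1], kv[0]))
        untouched_cluster = sizes[1][0]
        untouched = {t for t, c in base.assignment.items() if c == untouched_cluster}
        split_labels = {split.assignment[t] for t in untouched}
        assert len(split_labels) == 1  # still together
        rest_labels = {c for t, c in split.assignment.items() if t not in untouched}
        assert len(rest_labels) == 2

    def test_split_too_small_rejected(self):
        graph = planted_two_block(n=8, seed=0)
        with pytest.raises(ValueError):
            recursive_split(graph, base_k=2, splits=[(1, 40)], seed=0)


class TestCrossOntologyCoherence:
    @pytest.fixture
    def setup(self, small_planted):
        cfg, go_dag, cmpo_dag, ds = small_planted
        ic_cmpo = compute_ic(ds.cmpo_corpus, cmpo_dag)
        graph = project_term_graph(ds.go_corpus)
        assign = spectral_ncut(graph, k=cfg.n_modules, seed=0)
        return ds, cmpo_dag, ic_cmpo, assign

    def test_null_preserves_cluster_sizes(self, setup):
        # indirectly: the shuffled assignment is a permutation of labels, so
        # scored cluster nulls are always computable for same-size clusters
        ds, cmpo_dag, ic_cmpo, assign = setup
        results = cluster_cross_ontology_similarity(
            assign, ds.go_corpus, ds.cmpo_corpus, cmpo_dag, ic_cmpo, n_rand=20, seed=0
        )
        assert sum(r.size for r in results) == len(assign.assignment)
        for r in results:
            if not r.excluded:
                assert len(r.null) == 20
                assert 0 < r.p <= 1

    def test_cluster_without_linked_terms_excluded(self, diamond_dag):
        # corpus B annotates no gene of cluster 1's terms
        dag_a = OntologyDAG(
            terms={"root", "x", "y"},
            parents={"root": set(), "x": {"root"}, "y": {"root"}},
            root="root",
        )
        corpus_a = propagate({"g1": {"x"}, "g2": {"y"}}, dag_a)
        corpus_b = propagate({"g1": {"c"}, "g1b": {"d"}}, diamond_dag)
        ic_b = compute_ic(corpus_b, diamond_dag)
        assign = ClusterAssignment(
            assignment={"x": 0, "y": 1, "root": 0}, k=2, objective=0.0
        )
        results = cluster_cross_ontology_similarity(
            assign, corpus_a, corpus_b, diamond_dag, ic_b, n_rand=10, seed=0
        )
        by_cluster = {r.cluster: r for r in results}
        assert by_cluster[1].excluded  # g2 has no B annotation

    def test_identical_annotations_p_one(self, diamond_dag):
        dag_a = OntologyDAG(
            terms={"root", "x", "y"},
            parents={"root": set(), "x": {"root"}, "y": {"root"}},
            root="root",
        )
        corpus_a = propagate({"g1": {"x"}, "g2": {"y"}}, dag_a)
        # both genes carry the identical 2-term B annotation set
        corpus_b = propagate({"g1": {"c", "d"}, "g2": {"c", "d"}}, diamond_dag)
        ic_b = compute_ic(corpus_b, diamond_dag)
        assign = ClusterAssignment(assignment={"x": 0, "y": 1}, k=2, objective=0.0)
        results = cluster_cross_ontology_similarity(
            assign, corpus_a, corpus_b, diamond_dag, ic_b, n_rand=30, seed=0
        )
        for r in results:
            if not r.excluded:
                assert r.p == pytest.approx(1.0)

    def test_planted_clusters_significant(self, setup):
        ds, cmpo_dag, ic_cmpo, assign = setup
        results = cluster_cross_ontology_similarity(
            assign, ds.go_corpus, ds.cmpo_corpus, cmpo_dag, ic_cmpo, n_rand=200, seed=1
        )
        scored = [r for r in results if not r.excluded]
        assert scored
        sens = np.mean([r.significant for r in scored])
        assert sens >= 0.75
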