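"""Annotation-driven term graphs and their normalized-cut spectral clustering.

Gene-term annotations are projected onto a weighted term-term graph (edge
weight = Jaccard index of the two terms' propagated gene sets, edges only
between terms sharing at least one gene). The graph is partitioned by
normalized spectral embedding plus seeded k-means, optionally with recursive
splitting of chosen clusters, and clusters are scored for cross-ontology
coherence against randomized term-to-cluster assignments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import eigh
from sklearn.cluster import KMeans

from .ontology import AnnotationCorpus, OntologyDAG, TermIC
from .semantic import TermSimilarityCache
from .stats import bh_adjust, empirical_pvalue

logger = logging.getLogger(__name__)

__all__ = [
    "TermGraph",
    "ClusterAssignment",
    "ClusterSimilarityResult",
    "project_term_graph",
    "spectral_ncut",
    "recursive_split",
    "normalized_cut_value",
    "cluster_cross_ontology_similarity",
]


@dataclass
class TermGraph:
    """Weighted undirected term-term graph; weights in (0, 1], no self-loops."""

    nodes: list[str]
    weights: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.nodes)
        if self.weights.shape != (n, n):
            raise ValueError("weight matrix shape does not match node list")
        if not np.allclose(self.weights, self.weights.T):
            raise ValueError("weight matrix must be symmetric")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("self-loops are not allowed")
        if np.any(self.weights < 0) or np.any(self.weights > 1):
            raise ValueError("weights must lie in [0, 1]")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def edges(self) -> list[tuple[str, str, float]]:
        out = []
        for i in range(self.n_nodes):
            for j in range(i + 1, self.n_nodes):
                w = self.weights[i, j]
                if w > 0:
                    out.append((self.nodes[i], self.nodes[j], float(w)))
        return out

    def subgraph(self, indices: np.ndarray) -> "TermGraph":
        return TermGraph(
            nodes=[self.nodes[i] for i in indices],
            weights=self.weights[np.ix_(indices, indices)],
        )

    def components(self) -> list[np.ndarray]:
        """Connected components as index arrays, largest first."""
        n = self.n_nodes
        seen = np.zeros(n, dtype=bool)
        comps: list[np.ndarray] = []
        for start in range(n):
            if seen[start]:
                continue
            stack, members = [start], []
            seen[start] = True
            while stack:
                u = stack.pop()
                members.append(u)
                for v in np.flatnonzero(self.weights[u] > 0):
                    if not seen[v]:
                        seen[v] = True
                        stack.append(int(v))
            comps.append(np.array(sorted(members)))
        comps.sort(key=lambda c: (-len(c), int(c[0])))
        return comps

    def to_edge_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as handle:
            handle.write("#term1\tterm2\tweight\n")
            for t1, t2, w in self.edges():
                handle.write(f"{t1}\t{t2}\t{w:.10g}\n")


@dataclass
class ClusterAssignment:
    """Term -> cluster partition with its normalized-cut objective."""

    assignment: dict[str, int]
    k: int
    objective: float
    seed: int = 0

    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for term, c in self.assignment.items():
            out.setdefault(c, []).append(term)
        return {c: sorted(ts) for c, ts in out.items()}

    def sizes(self) -> dict[int, int]:
        return {c: len(ts) for c, ts in self.clusters().items()}

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as handle:
            handle.write("#term\tcluster\n")
            for term in sorted(self.assignment):
                handle.write(f"{term}\t{self.assignment[term]}\n")


def project_term_graph(corpus: AnnotationCorpus, term_set=None) -> TermGraph:
    """Bipartite projection of gene-term annotations onto a term graph.

    Two terms are linked iff they share at least one gene (propagated
    annotations, restricted to the corpus universe); the edge weight is the
    Jaccard index of their gene sets, which compensates for the inherited-gene
    degree bias of high-level terms.
    """
    gene_sets: dict[str, set[str]] = {}
    for gene in corpus.universe:
        for term in corpus.propagated[gene]:
            gene_sets.setdefault(term, set()).add(gene)
    if term_set is not None:
        requested = set(term_set)
        zero = requested - set(gene_sets)
        if zero:
            logger.warning("dropping %d terms with no annotated genes", len(zero))
        gene_sets = {t: s for t, s in gene_sets.items() if t in requested}
    nodes = sorted(gene_sets)
    n = len(nodes)
    weights = np.zeros((n, n))
    sets = [gene_sets[t] for t in nodes]
    for i in range(n):
        for j in range(i + 1, n):
            inter = len(sets[i] & sets[j])
            if inter:
                w = inter / len(sets[i] | sets[j])
                weights[i, j] = weights[j, i] = w
    return TermGraph(nodes=nodes, weights=weights)


def normalized_cut_value(graph: TermGraph, labels: np.ndarray) -> float:
    """Ncut(P) = sum over clusters of cut(A, V-A) / vol(A); vol-0 clusters add 0."""
    labels = np.asarray(labels)
    total = 0.0
    degrees = graph.weights.sum(axis=1)
    for c in np.unique(labels):
        mask = labels == c
        vol = degrees[mask].sum()
        if vol == 0:
            continue
        cut = graph.weights[np.ix_(mask, ~mask)].sum()
        total += cut / vol
    return float(total)


def _spectral_partition(weights: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Normalized spectral embedding + k-means on one connected graph.

    Several seeded k-means restarts are scored by the ncut objective itself
    and the best partition is kept.
    """
    n = weights.shape[0]
    if k >= n:
        return np.arange(n)
    degrees = weights.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(np.maximum(degrees, 1e-12))
    sym = weights * inv_sqrt[:, None] * inv_sqrt[None, :]
    # leading k eigenvectors of D^-1/2 W D^-1/2 == bottom of L_sym
    eigvals, eigvecs = eigh(sym)
    embed = eigvecs[:, np.argsort(eigvals)[::-1][:k]]
    norms = np.sqrt((embed * embed).sum(axis=1))
    embed = embed / np.maximum(norms, 1e-12)[:, None]
    graph = TermGraph(nodes=[str(i) for i in range(n)], weights=weights)
    best_labels, best_obj = None, np.inf
    for restart in range(5):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed + restart)
        labels = km.fit_predict(embed)
        if len(set(labels.tolist())) < k:
            continue
        obj = normalized_cut_value(graph, labels)
        if obj < best_obj:
            best_labels, best_obj = labels, obj
    if best_labels is None:  # degenerate embedding; fall back to size-k split
        best_labels = np.arange(n) % k
    return best_labels


def _relabel_contiguous(labels: np.ndarray) -> np.ndarray:
    mapping = {c: i for i, c in enumerate(dict.fromkeys(labels.tolist()))}
    return np.array([mapping[c] for c in labels.tolist()])


def spectral_ncut(graph: TermGraph, k: int, seed: int = 0) -> ClusterAssignment:
    """Partition the term graph into k clusters by normalized-cut spectral clustering.

    Disconnected graphs are handled before eigen-decomposition: components are
    either used directly as clusters (when there are at least k of them, the
    smallest are lumped) or allocated sub-cluster budgets proportional to
    their size and clustered independently, which keeps all zero-weight cuts
    free.
    """
    n = graph.n_nodes
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of nodes ({n})")
    if k == 1:
        labels = np.zeros(n, dtype=int)
        return ClusterAssignment(
            assignment=dict(zip(graph.nodes, labels.tolist())),
            k=1,
            objective=normalized_cut_value(graph, labels),
            seed=seed,
        )

    comps = graph.components()
    labels = np.empty(n, dtype=int)
    if len(comps) >= k:
        # k-1 largest components become clusters; the remainder share one
        for c, comp in enumerate(comps):
            labels[comp] = min(c, k - 1)
    else:
        # allocate k among components proportionally to size (each >= 1)
        sizes = np.array([len(c) for c in comps], dtype=float)
        alloc = np.maximum(1, np.floor(k * sizes / sizes.sum()).astype(int))
        alloc = np.minimum(alloc, sizes.astype(int))
        while alloc.sum() < k:
            room = np.flatnonzero(alloc < sizes)
            alloc[room[np.argmax(sizes[room] / alloc[room])]] += 1
        while alloc.sum() > k:
            shrink = np.flatnonzero(alloc > 1)
            alloc[shrink[np.argmin(sizes[shrink] / alloc[shrink])]] -= 1
        offset = 0
        for comp, k_c in zip(comps, alloc):
            sub = _spectral_partition(graph.weights[np.ix_(comp, comp)], int(k_c), seed)
            labels[comp] = sub + offset
            offset += int(k_c)
    labels = _relabel_contiguous(labels)
    return ClusterAssignment(
        assignment=dict(zip(graph.nodes, labels.tolist())),
        k=int(labels.max()) + 1,
        objective=normalized_cut_value(graph, labels),
        seed=seed,
    )


def recursive_split(
    graph: TermGraph,
    base_k: int,
    splits: list[tuple[int, int]],
    seed: int = 0,
) -> ClusterAssignment:
    """Cluster into base_k, then re-cluster chosen clusters' induced subgraphs.

    ``splits`` is a list of (cluster rank by descending size, 1-based; sub_k).
    The final number of clusters is base_k - len(splits) + sum(sub_k).
    """
    base = spectral_ncut(graph, base_k, seed=seed)
    if not splits:
        return base
    node_index = {t: i for i, t in enumerate(graph.nodes)}
    labels = np.array([base.assignment[t] for t in graph.nodes])
    by_size = sorted(base.sizes().items(), key=lambda kv: (-kv[1], kv[0]))
    next_label = int(labels.max()) + 1
    targeted: set[int] = set()
    for rank, sub_k in splits:
        if not 1 <= rank <= len(by_size):
            raise ValueError(f"no cluster at size rank {rank}")
        cluster_id = by_size[rank - 1][0]
        if cluster_id in targeted:
            raise ValueError(f"cluster at rank {rank} targeted twice")
        targeted.add(cluster_id)
        members = np.flatnonzero(labels == cluster_id)
        if len(members) < sub_k:
            raise ValueError(
                f"cluster at rank {rank} has {len(members)} nodes, cannot split into {sub_k}"
            )
        sub_assign = spectral_ncut(graph.subgraph(members), sub_k, seed=seed)
        for term, sub_label in sub_assign.assignment.items():
            labels[node_index[term]] = next_label + sub_label
        next_label += sub_assign.k
    labels = _relabel_contiguous(labels)
    return ClusterAssignment(
        assignment=dict(zip(graph.nodes, labels.tolist())),
        k=int(labels.max()) + 1,
        objective=normalized_cut_value(graph, labels),
        seed=seed,
    )


@dataclass
class ClusterSimilarityResult:
    cluster: int
    size: int
    linked_terms: list[str] = field(default_factory=list)
    observed: float = float("nan")
    null: np.ndarray = field(default_factory=lambda: np.array([]))
    p: float = float("nan")
    q: float = float("nan")
    significant: bool = False
    excluded: bool = False
    reason: str = ""


def _cluster_statistic(
    cluster_terms: list[str],
    term_genes: dict[str, set[str]],
    gene_terms_b: dict[str, set[str]],
    sim_cache: TermSimilarityCache,
    weighting: str = "genes",
) -> tuple[float, list[str]]:
    """Mean cross-ontology similarity of the B-terms linked to a cluster.

    ``weighting='genes'`` weights each B-term pair by the product of the
    numbers of cluster genes carrying the terms, so rare spurious annotations
    do not drown the signal; ``'uniform'`` is the plain mean over distinct
    B-term pairs.
    """
    genes: set[str] = set()
    for t in cluster_terms:
        genes |= term_genes.get(t, set())
    counts: dict[str, int] = {}
    for g in genes:
        for t in gene_terms_b.get(g, ()):
            counts[t] = counts.get(t, 0) + 1
    terms_b = sorted(counts)
    if len(terms_b) < 2:
        return float("nan"), terms_b
    total, denom = 0.0, 0.0
    for i, t1 in enumerate(terms_b):
        for t2 in terms_b[i + 1 :]:
            w = counts[t1] * counts[t2] if weighting == "genes" else 1.0
            total += w * sim_cache(t1, t2)
            denom += w
    return total / denom, terms_b


def cluster_cross_ontology_similarity(
    assign: ClusterAssignment,
    corpus_a: AnnotationCorpus,
    corpus_b: AnnotationCorpus,
    dag_b: OntologyDAG,
    ic_b: TermIC,
    n_rand: int = 100,
    seed: int = 0,
    method: str = "resnik",
    alpha: float = 0.01,
    weighting: str = "genes",
) -> list[ClusterSimilarityResult]:
    """Score each cluster's cross-ontology coherence against a shuffle null.

    Per cluster: genes annotated (propagated) to any cluster term are
    collected, their direct ontology-B terms pooled, and the observed
    statistic is the mean term-pair semantic similarity over distinct B-term
    pairs (gene-frequency weighted by default, see ``_cluster_statistic``).
    The null shuffles the term-to-cluster assignment preserving cluster sizes
    and recomputes the statistic. Clusters linked to fewer than two B-terms
    are excluded, not scored.
    """
    rng = np.random.default_rng(seed)
    sim_cache = TermSimilarityCache(method, dag_b, ic_b)
    term_genes: dict[str, set[str]] = {}
    for gene in corpus_a.universe:
        for term in corpus_a.propagated[gene]:
            term_genes.setdefault(term, set()).add(gene)
    gene_terms_b = {
        g: {t for t in ts if t in ic_b and t in dag_b.terms}
        for g, ts in corpus_b.direct.items()
    }

    clusters = assign.clusters()
    terms_in_order = sorted(assign.assignment)
    cluster_labels = np.array([assign.assignment[t] for t in terms_in_order])

    results: dict[int, ClusterSimilarityResult] = {}
    scored: list[int] = []
    for cid, terms in sorted(clusters.items()):
        obs, linked = _cluster_statistic(terms, term_genes, gene_terms_b, sim_cache, weighting)
        res = ClusterSimilarityResult(cluster=cid, size=len(terms), linked_terms=linked)
        if len(linked) < 2:
            res.excluded = True
            res.reason = "no linked terms" if not linked else "fewer than 2 linked terms"
        else:
            res.observed = obs
            scored.append(cid)
        results[cid] = res

    if scored:
        nulls: dict[int, list[float]] = {cid: [] for cid in scored}
        for _ in range(n_rand):
            shuffled = cluster_labels[rng.permutation(len(cluster_labels))]
            null_clusters: dict[int, list[str]] = {}
            for term, c in zip(terms_in_order, shuffled.tolist()):
                null_clusters.setdefault(c, []).append(term)
            for cid in scored:
                stat, _ = _cluster_statistic(
                    null_clusters.get(cid, []), term_genes, gene_terms_b, sim_cache, weighting
                )
                nulls[cid].append(stat if not np.isnan(stat) else -np.inf)
        for cid in scored:
            res = results[cid]
            res.null = np.array(nulls[cid])
            res.p = empirical_pvalue(res.null, res.observed)
        qvals = bh_adjust([results[cid].p for cid in scored])
        for cid, q in zip(scored, qvals):
            results[cid].q = float(q)
            results[cid].significant = bool(q <= alpha)
    return [results[cid] for cid in sorted(results)]
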