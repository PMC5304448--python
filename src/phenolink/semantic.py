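"""Ontology semantic similarity between terms and between annotated genes.

Five term-level measures (resnik, lin, schlicker, jiang, pesquita/simGIC) and
three term-set aggregations to gene pairs (max, average, best-match-average).
Term similarities are computed on direct annotation sets; ancestor closure
enters only through common-ancestor search and information content.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .ontology import AnnotationCorpus, OntologyDAG, TermIC, mica
from .profiles import SimilarityMatrix

logger = logging.getLogger(__name__)

SEMANTIC_METHODS = ("resnik", "lin", "schlicker", "jiang", "pesquita")
AGGREGATIONS = ("max", "average", "bma")

__all__ = [
    "SEMANTIC_METHODS",
    "AGGREGATIONS",
    "GenePairSemanticScore",
    "term_similarity",
    "aggregate",
    "gene_similarity",
    "gene_similarity_matrix",
    "gene_similarity_pairs",
    "PairScoreTable",
    "TermSimilarityCache",
]


@dataclass
class GenePairSemanticScore:
    gene1: str
    gene2: str
    method: str
    aggregation: str
    value: float


def term_similarity(t1: str, t2: str, method: str, dag: OntologyDAG, ic: TermIC) -> float:
    """Semantic similarity between two ontology terms.

    resnik = IC(MICA); lin = 2 IC(MICA) / (IC(t1) + IC(t2));
    schlicker = lin * (1 - p(MICA));
    jiang = 1 - min(1, IC(t1) + IC(t2) - 2 IC(MICA));
    pesquita = sum of IC over common ancestors-or-self / sum over the union of
    ancestors-or-self (simGIC).
    """
    if method not in SEMANTIC_METHODS:
        raise ValueError(f"unknown semantic similarity method: {method!r}")
    if method == "pesquita":
        a1 = {t for t in dag.ancestors(t1) if t in ic}
        a2 = {t for t in dag.ancestors(t2) if t in ic}
        denom = sum(ic.ic[t] for t in a1 | a2)
        if denom == 0.0:
            logger.warning("simGIC denominator 0 for (%s, %s); scored 0", t1, t2)
            return 0.0
        return sum(ic.ic[t] for t in a1 & a2) / denom

    _, ic_mica = mica(t1, t2, dag, ic)
    if method == "resnik":
        return ic_mica
    ic1, ic2 = ic.ic[t1], ic.ic[t2]
    if method == "jiang":
        return 1.0 - min(1.0, ic1 + ic2 - 2.0 * ic_mica)
    if ic1 + ic2 == 0.0:
        logger.warning("lin-type similarity undefined for two zero-IC terms; scored 0")
        return 0.0
    lin = 2.0 * ic_mica / (ic1 + ic2)
    if method == "lin":
        return lin
    # schlicker: damp by the MICA's annotation probability
    mica_term, _ = mica(t1, t2, dag, ic)
    return lin * (1.0 - ic.p[mica_term])


class TermSimilarityCache:
    """Memoized term-pair similarity for one (method, dag, ic) context."""

    def __init__(self, method: str, dag: OntologyDAG, ic: TermIC):
        if method not in SEMANTIC_METHODS:
            raise ValueError(f"unknown semantic similarity method: {method!r}")
        self.method = method
        self.dag = dag
        self.ic = ic
        self._cache: dict[tuple[str, str], float] = {}

    def __call__(self, t1: str, t2: str) -> float:
        key = (t1, t2) if t1 <= t2 else (t2, t1)
        value = self._cache.get(key)
        if value is None:
            value = term_similarity(key[0], key[1], self.method, self.dag, self.ic)
            self._cache[key] = value
        return value

    def block(self, terms1: list[str], terms2: list[str]) -> np.ndarray:
        return np.array([[self(a, b) for b in terms2] for a in terms1])


def aggregate(block: np.ndarray, aggregation: str) -> float:
    """Collapse a |T1| x |T2| term-pair similarity block to one score."""
    if aggregation == "max":
        return float(block.max())
    if aggregation == "average":
        return float(block.mean())
    if aggregation == "bma":
        return float((block.max(axis=1).mean() + block.max(axis=0).mean()) / 2.0)
    raise ValueError(f"unknown aggregation: {aggregation!r}")


def gene_similarity(
    g1: str,
    g2: str,
    corpus: AnnotationCorpus,
    method: str,
    aggregation: str,
    dag: OntologyDAG,
    ic: TermIC,
) -> GenePairSemanticScore:
    """Aggregate term-level similarity over the two genes' direct annotation sets."""
    cache = TermSimilarityCache(method, dag, ic)
    t1 = sorted(t for t in corpus.direct.get(g1, ()) if t in ic and t in dag.terms)
    t2 = sorted(t for t in corpus.direct.get(g2, ()) if t in ic and t in dag.terms)
    if not t1 or not t2:
        raise ValueError(f"gene without scoreable annotations: {g1 if not t1 else g2}")
    value = aggregate(cache.block(t1, t2), aggregation)
    return GenePairSemanticScore(gene1=g1, gene2=g2, method=method, aggregation=aggregation, value=value)


def gene_similarity_matrix(
    corpus: AnnotationCorpus,
    method: str,
    aggregation: str,
    dag: OntologyDAG,
    ic: TermIC,
    genes: list[str] | None = None,
) -> SimilarityMatrix:
    """All-pairs gene semantic similarity as a :class:`SimilarityMatrix`.

    Genes without any annotation to an IC-scored DAG term are excluded with a
    logged count. Term-pair similarities are cached across gene pairs.
    """
    cache = TermSimilarityCache(method, dag, ic)
    if genes is None:
        genes = sorted(corpus.universe)
    kept: list[str] = []
    term_lists: list[list[str]] = []
    for g in genes:
        terms = sorted(t for t in corpus.direct.get(g, ()) if t in ic and t in dag.terms)
        if terms:
            kept.append(g)
            term_lists.append(terms)
    n_dropped = len(genes) - len(kept)
    if n_dropped:
        logger.info("excluded %d genes without scoreable annotations", n_dropped)

    n = len(kept)
    values = np.zeros((n, n))
    for i in range(n):
        values[i, i] = aggregate(cache.block(term_lists[i], term_lists[i]), aggregation)
        for j in range(i + 1, n):
            s = aggregate(cache.block(term_lists[i], term_lists[j]), aggregation)
            values[i, j] = values[j, i] = s
    return SimilarityMatrix(
        labels=kept,
        values=values,
        measure=f"{method}",
        metadata={"space": "semantic", "aggregation": aggregation},
    )


class PairScoreTable:
    """Sparse gene-pair score lookup quacking like :class:`SimilarityMatrix`."""

    def __init__(self, scores: dict[tuple[str, str], float], measure: str):
        self._scores = {(min(a, b), max(a, b)): v for (a, b), v in scores.items()}
        self.measure = measure

    def score(self, g1: str, g2: str) -> float:
        return self._scores[(min(g1, g2), max(g1, g2))]

    def has(self, g1: str, g2: str) -> bool:
        return (min(g1, g2), max(g1, g2)) in self._scores


def gene_similarity_pairs(
    corpus: AnnotationCorpus,
    pairs,
    method: str,
    aggregation: str,
    dag: OntologyDAG,
    ic: TermIC,
) -> PairScoreTable:
    """Semantic similarity for an explicit set of gene pairs only.

    Much cheaper than the all-pairs matrix when only benchmark pairs are
    needed. Pairs with an unannotatable gene are silently omitted (the caller
    can check with :meth:`PairScoreTable.has`).
    """
    cache = TermSimilarityCache(method, dag, ic)
    term_lists: dict[str, list[str]] = {}

    def terms_of(g: str) -> list[str]:
        if g not in term_lists:
            term_lists[g] = sorted(
                t for t in corpus.direct.get(g, ()) if t in ic and t in dag.terms
            )
        return term_lists[g]

    scores: dict[tuple[str, str], float] = {}
    for g1, g2 in pairs:
        t1, t2 = terms_of(g1), terms_of(g2)
        if not t1 or not t2:
            continue
        scores[(g1, g2)] = aggregate(cache.block(t1, t2), aggregation)
    return PairScoreTable(scores, measure=method)
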