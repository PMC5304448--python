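"""Benchmarking similarity measures against protein-interaction evidence.

Ranks measures by (i) pairwise AUC between positive and negative interaction
pairs (Mann-Whitney identity, ties count 1/2), (ii) the number of genes whose
nearest phenotypic neighbour is a known interaction partner, with
hypergeometric significance, and (iii) summarizes inter-measure agreement as
an average-linkage dendrogram on 1 - Pearson correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.cluster import hierarchy
from scipy.stats import rankdata

from .profiles import SimilarityMatrix
from .stats import hypergeometric_pvalue

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionSet",
    "BenchmarkResult",
    "auc_interactions",
    "nearest_neighbor_score",
    "hypergeometric_pvalue",
    "measure_correlation_dendrogram",
]


def _canonical(pair) -> tuple[str, str]:
    a, b = pair
    if a == b:
        raise ValueError(f"self-pair not allowed: {a}")
    return (a, b) if a <= b else (b, a)


@dataclass
class InteractionSet:
    """Labelled positive/negative unordered gene pairs over a gene universe."""

    positives: set[tuple[str, str]]
    negatives: set[tuple[str, str]]
    universe: set[str]

    def __post_init__(self) -> None:
        self.positives = {_canonical(p) for p in self.positives}
        self.negatives = {_canonical(p) for p in self.negatives}
        overlap = self.positives & self.negatives
        if overlap:
            raise ValueError(f"{len(overlap)} pairs labelled both positive and negative")
        for pair in self.positives | self.negatives:
            if pair[0] not in self.universe or pair[1] not in self.universe:
                raise ValueError(f"pair {pair} outside the gene universe")

    def restrict_to(self, genes) -> "InteractionSet":
        genes = set(genes)
        return InteractionSet(
            positives={p for p in self.positives if p[0] in genes and p[1] in genes},
            negatives={p for p in self.negatives if p[0] in genes and p[1] in genes},
            universe=self.universe & genes,
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "InteractionSet":
        """Read ``gene1<TAB>gene2<TAB>label(pos|neg)[<TAB>source]`` rows."""
        positives: set[tuple[str, str]] = set()
        negatives: set[tuple[str, str]] = set()
        universe: set[str] = set()
        with Path(path).open() as handle:
            for raw in handle:
                line = raw.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                cols = line.split("\t")
                g1, g2, label = cols[0], cols[1], cols[2]
                universe.update((g1, g2))
                if label == "pos":
                    positives.add(_canonical((g1, g2)))
                elif label == "neg":
                    negatives.add(_canonical((g1, g2)))
                else:
                    raise ValueError(f"unknown interaction label: {label!r}")
        return cls(positives=positives, negatives=negatives, universe=universe)

    def to_tsv(self, path: str | Path, source: str = "synthetic") -> None:
        with Path(path).open("w") as handle:
            handle.write("#gene1\tgene2\tlabel\tsource\n")
            for g1, g2 in sorted(self.positives):
                handle.write(f"{g1}\t{g2}\tpos\t{source}\n")
            for g1, g2 in sorted(self.negatives):
                handle.write(f"{g1}\t{g2}\tneg\t{source}\n")


@dataclass
class BenchmarkResult:
    measure: str
    auc: float
    nn_hits: int
    nn_pvalue: float
    parameters: dict = field(default_factory=dict)


def auc_interactions(sim: SimilarityMatrix, iset: InteractionSet) -> float:
    """P(score(pos) > score(neg)) + P(tie)/2 via the rank-sum identity."""
    if not iset.positives or not iset.negatives:
        raise ValueError("need at least one positive and one negative pair")
    pos = np.array([sim.score(*p) for p in sorted(iset.positives)])
    neg = np.array([sim.score(*p) for p in sorted(iset.negatives)])
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def nearest_neighbor_score(
    sim: SimilarityMatrix, known_pairs: set[tuple[str, str]], seed: int = 0
) -> tuple[int, dict[str, str]]:
    """Count genes whose most similar partner forms a known pair.

    For each gene the argmax-similarity partner is taken; exact ties are
    broken uniformly at random with the given seed. Returns the hit count and
    the chosen partner per gene.
    """
    rng = np.random.default_rng(seed)
    known = {_canonical(p) for p in known_pairs}
    values = sim.values
    n = len(sim.labels)
    if n < 2:
        raise ValueError("similarity matrix must cover at least two genes")
    hits = 0
    partners: dict[str, str] = {}
    for i, gene in enumerate(sim.labels):
        row = values[i].copy()
        row[i] = -np.inf
        best = row.max()
        candidates = np.flatnonzero(row == best)
        j = int(candidates[rng.integers(len(candidates))])
        partner = sim.labels[j]
        partners[gene] = partner
        if _canonical((gene, partner)) in known:
            hits += 1
    return hits, partners


def measure_correlation_dendrogram(
    sims: list[SimilarityMatrix],
) -> tuple[np.ndarray, list[str]]:
    """Average-linkage tree over measures, distance 1 - Pearson correlation.

    Correlation is computed between the vectorized upper-triangle scores of
    each measure; measures with constant score vectors are dropped with a
    warning. Returns a scipy linkage matrix and the retained measure labels.
    """
    if len(sims) < 2:
        raise ValueError("need at least two measures")
    ref = sims[0].labels
    for s in sims[1:]:
        if s.labels != ref:
            raise ValueError("all similarity matrices must cover the same gene set")
    vectors, labels = [], []
    for s in sims:
        v = s.pair_vector()
        if np.std(v) == 0:
            logger.warning("measure %s has constant scores; dropped from dendrogram", s.measure)
            continue
        vectors.append(v)
        labels.append(s.measure)
    if len(vectors) < 2:
        raise ValueError("fewer than two non-constant measures")
    corr = np.corrcoef(np.vstack(vectors))
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    condensed = dist[np.triu_indices(len(labels), k=1)]
    linkage = hierarchy.linkage(condensed, method="average")
    return linkage, labels
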