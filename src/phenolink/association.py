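"""Do phenotypes indicate function?

Per-phenotype mean functional similarity with permutation nulls (column sums
preserved), BH-corrected significance, cross-similarity binned distributions,
the high-similarity randomization check and information-content profile
comparison between a gene subset and the full corpus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .ontology import AnnotationCorpus, TermIC
from .profiles import PhenotypeMatrix, SimilarityMatrix
from .stats import bh_adjust, empirical_pvalue

logger = logging.getLogger(__name__)

__all__ = [
    "PhenotypePermutationResult",
    "per_phenotype_mean_go_similarity",
    "permutation_test",
    "cross_similarity_bins",
    "high_similarity_randomization",
    "ic_profile_comparison",
]


@dataclass
class PhenotypePermutationResult:
    phenotype: str
    n_genes: int
    observed: float
    null: np.ndarray
    p: float
    q: float = float("nan")
    significant: bool = False
    ic_cmpo: float = float("nan")


def _pair_mean(values: np.ndarray, idx: np.ndarray) -> float:
    """Mean similarity over unordered distinct pairs of the indexed genes."""
    k = len(idx)
    sub = values[np.ix_(idx, idx)]
    return float((sub.sum() - np.trace(sub)) / (k * (k - 1)))


def per_phenotype_mean_go_similarity(
    matrix: PhenotypeMatrix, go_sim: SimilarityMatrix
) -> tuple[dict[str, tuple[float, int]], list[str]]:
    """Mean functional similarity over all gene pairs sharing each phenotype.

    Genes without functional annotation (absent from ``go_sim``) are excluded.
    Returns ({phenotype: (mean, n annotated genes)}, excluded phenotypes with
    fewer than two annotated genes).
    """
    sim_index = {g: i for i, g in enumerate(go_sim.labels)}
    results: dict[str, tuple[float, int]] = {}
    excluded: list[str] = []
    for j, phenotype in enumerate(matrix.phenotypes):
        genes = [g for g, v in zip(matrix.genes, matrix.values[:, j]) if v and g in sim_index]
        if len(genes) < 2:
            excluded.append(phenotype)
            continue
        idx = np.array([sim_index[g] for g in genes])
        results[phenotype] = (_pair_mean(go_sim.values, idx), len(genes))
    if excluded:
        logger.info("%d phenotypes excluded (<2 functionally annotated genes)", len(excluded))
    return results, excluded


def permutation_test(
    matrix: PhenotypeMatrix,
    go_sim: SimilarityMatrix,
    n_perm: int = 100,
    seed: int = 0,
    ic_cmpo: TermIC | None = None,
    alpha: float = 0.01,
) -> list[PhenotypePermutationResult]:
    """Permutation test of per-phenotype functional coherence.

    Each permutation reassigns every phenotype's gene links to a uniformly
    random gene subset of the same size (column sums preserved exactly).
    Empirical p uses the +1/(n+1) correction; q-values are BH over the tested
    phenotypes; the significance flag is q <= ``alpha``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    sim_index = {g: i for i, g in enumerate(go_sim.labels)}
    annotated = [g for g in matrix.genes if g in sim_index]
    annotated_idx = np.array([sim_index[g] for g in annotated])
    gene_in_sim = np.array([g in sim_index for g in matrix.genes])

    observed, _ = per_phenotype_mean_go_similarity(matrix, go_sim)

    tested = [p for p in matrix.phenotypes if p in observed]
    # per-phenotype column sizes drawn over ALL matrix genes, then filtered to
    # annotated ones, mirroring the observed-statistic pipeline
    col_sizes = {
        p: int(matrix.values[:, matrix.phenotypes.index(p)].sum()) for p in tested
    }
    n_genes = matrix.n_genes

    nulls: dict[str, list[float]] = {p: [] for p in tested}
    for _ in range(n_perm):
        for p in tested:
            chosen = rng.choice(n_genes, size=col_sizes[p], replace=False)
            chosen = chosen[gene_in_sim[chosen]]
            if len(chosen) < 2:
                nulls[p].append(-np.inf)
                continue
            idx = np.array([sim_index[matrix.genes[i]] for i in chosen])
            nulls[p].append(_pair_mean(go_sim.values, idx))

    results: list[PhenotypePermutationResult] = []
    for p in tested:
        null = np.array(nulls[p])
        obs, n_ann = observed[p]
        pval = empirical_pvalue(null, obs)
        results.append(
            PhenotypePermutationResult(
                phenotype=p,
                n_genes=n_ann,
                observed=obs,
                null=null,
                p=pval,
                ic_cmpo=(ic_cmpo.ic.get(p, float("nan")) if ic_cmpo is not None else float("nan")),
            )
        )
    qvals = bh_adjust([r.p for r in results])
    for r, q in zip(results, qvals):
        r.q = float(q)
        r.significant = bool(q <= alpha)
    return results


def permute_matrix_columns(matrix: PhenotypeMatrix, seed: int) -> PhenotypeMatrix:
    """One column-sum-preserving shuffle of gene-phenotype links."""
    rng = np.random.default_rng(seed)
    values = np.zeros_like(matrix.values)
    for j in range(matrix.n_phenotypes):
        k = int(matrix.values[:, j].sum())
        chosen = rng.choice(matrix.n_genes, size=k, replace=False)
        values[chosen, j] = 1
    return PhenotypeMatrix(genes=list(matrix.genes), phenotypes=list(matrix.phenotypes), values=values)


@dataclass
class BinSummary:
    low: float
    high: float
    n: int
    median: float = float("nan")
    q1: float = float("nan")
    q3: float = float("nan")


def cross_similarity_bins(
    sim_a: np.ndarray, sim_b: np.ndarray, bins: np.ndarray | int = 10
) -> list[BinSummary]:
    """Quartile summary of ``sim_b`` within bins of ``sim_a`` over the same pairs.

    ``bins`` is either explicit break points or a count of quantile bins of
    ``sim_a`` (default deciles). Empty bins are reported with n=0.
    """
    sim_a = np.asarray(sim_a, dtype=float)
    sim_b = np.asarray(sim_b, dtype=float)
    if sim_a.shape != sim_b.shape:
        raise ValueError("score vectors must cover the same pair universe")
    if np.isscalar(bins) or isinstance(bins, int):
        breaks = np.unique(np.quantile(sim_a, np.linspace(0, 1, int(bins) + 1)))
    else:
        breaks = np.asarray(bins, dtype=float)
    out: list[BinSummary] = []
    for lo, hi in zip(breaks[:-1], breaks[1:]):
        last = hi == breaks[-1]
        mask = (sim_a >= lo) & ((sim_a <= hi) if last else (sim_a < hi))
        vals = sim_b[mask]
        if vals.size == 0:
            out.append(BinSummary(low=float(lo), high=float(hi), n=0))
        else:
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            out.append(
                BinSummary(low=float(lo), high=float(hi), n=int(vals.size), median=float(med), q1=float(q1), q3=float(q3))
            )
    return out


def high_similarity_randomization(
    sim_a: np.ndarray,
    sim_b: np.ndarray,
    threshold: float,
    n_rand: int = 100,
    seed: int = 0,
) -> tuple[float, np.ndarray, float]:
    """Is mean sim_b among high-sim_a pairs larger than for random pair sets?

    The null draws the same number of ``sim_b`` values uniformly without
    replacement from all pairs. Returns (observed mean, null means, empirical p).
    """
    sim_a = np.asarray(sim_a, dtype=float)
    sim_b = np.asarray(sim_b, dtype=float)
    if sim_a.shape != sim_b.shape:
        raise ValueError("score vectors must cover the same pair universe")
    if threshold > sim_a.max():
        raise ValueError("threshold exceeds the maximum similarity")
    mask = sim_a >= threshold
    k = int(mask.sum())
    observed = float(sim_b[mask].mean())
    rng = np.random.default_rng(seed)
    null = np.array([sim_b[rng.choice(sim_b.size, size=k, replace=False)].mean() for _ in range(n_rand)])
    return observed, null, empirical_pvalue(null, observed)


def ic_profile_comparison(
    corpus: AnnotationCorpus,
    subset: set[str],
    ic: TermIC,
    bins: np.ndarray | int = 10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binned IC proportions of direct gene-term annotations: subset vs all genes.

    Returns (bin edges, subset proportions, all-gene proportions); each
    proportion vector sums to 1.
    """
    if not subset:
        raise ValueError("gene subset is empty")
    if not subset <= corpus.universe:
        raise ValueError("subset must be contained in the corpus universe")

    def ic_values(genes) -> np.ndarray:
        return np.array(
            [ic.ic[t] for g in genes for t in corpus.direct[g] if t in ic], dtype=float
        )

    all_vals = ic_values(sorted(corpus.universe))
    sub_vals = ic_values(sorted(subset))
    if sub_vals.size == 0:
        raise ValueError("subset has no IC-scored annotations")
    if np.isscalar(bins) or isinstance(bins, int):
        edges = np.linspace(0.0, float(all_vals.max()) + 1e-12, int(bins) + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    sub_hist, _ = np.histogram(sub_vals, bins=edges)
    all_hist, _ = np.histogram(all_vals, bins=edges)
    return edges, sub_hist / sub_hist.sum(), all_hist / all_hist.sum()
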