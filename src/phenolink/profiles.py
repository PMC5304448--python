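"""Similarity measures on binary phenotype profiles.

Seven measures operate directly on the binary gene x phenotype matrix
(euclidean, correlation, cosine, hamming, jaccard, kappa, tfidf); three more
are the euclidean/correlation/cosine variants computed in a logistic-PCA
reduced space. A seeded sparsity perturbation flips a chosen proportion of
1-entries to 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

PROFILE_METHODS = ("euclidean", "correlation", "cosine", "hamming", "jaccard", "kappa", "tfidf")
EMBEDDING_METHODS = ("euclidean", "correlation", "cosine")

__all__ = [
    "PhenotypeMatrix",
    "SimilarityMatrix",
    "profile_similarity",
    "embedding_similarity",
    "logistic_pca_embed",
    "perturb_sparsity",
    "PROFILE_METHODS",
    "EMBEDDING_METHODS",
]


@dataclass
class PhenotypeMatrix:
    """Binary genes x phenotypes matrix with row/column labels."""

    genes: list[str]
    phenotypes: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.genes), len(self.phenotypes)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.phenotypes)} phenotypes"
            )
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("phenotype matrix entries must be 0 or 1")
        self.values = self.values.astype(np.int8)
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene labels")
        if len(set(self.phenotypes)) != len(self.phenotypes):
            raise ValueError("duplicate phenotype labels")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_phenotypes(self) -> int:
        return len(self.phenotypes)

    def drop_empty_rows(self) -> "PhenotypeMatrix":
        """Remove genes showing no phenotype (required before similarity computation)."""
        keep = self.values.sum(axis=1) > 0
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info("dropping %d genes with all-zero phenotype profiles", n_dropped)
        return PhenotypeMatrix(
            genes=[g for g, k in zip(self.genes, keep) if k],
            phenotypes=list(self.phenotypes),
            values=self.values[keep],
        )

    def to_annotations(self) -> dict[str, set[str]]:
        """Gene -> set of phenotype term ids with value 1."""
        return {
            gene: {p for p, v in zip(self.phenotypes, row) if v}
            for gene, row in zip(self.genes, self.values)
            if row.any()
        }

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PhenotypeMatrix":
        """Read the TSV dialect: header of phenotype ids, first column gene id, 0/1 cells."""
        genes: list[str] = []
        rows: list[list[int]] = []
        with Path(path).open() as handle:
            lines = [l.rstrip("\n") for l in handle if l.strip() and not l.startswith("#")]
        header = lines[0].split("\t")
        phenotypes = header[1:]
        for line in lines[1:]:
            cols = line.split("\t")
            genes.append(cols[0])
            rows.append([int(c) for c in cols[1:]])
        return cls(genes=genes, phenotypes=phenotypes, values=np.array(rows, dtype=np.int8))

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as handle:
            handle.write("gene\t" + "\t".join(self.phenotypes) + "\n")
            for gene, row in zip(self.genes, self.values):
                handle.write(gene + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise gene similarity with provenance metadata."""

    labels: list[str]
    values: np.ndarray
    measure: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix shape does not match labels")
        self._index = {g: i for i, g in enumerate(self.labels)}

    def score(self, g1: str, g2: str) -> float:
        return float(self.values[self._index[g1], self._index[g2]])

    def has(self, g1: str, g2: str) -> bool:
        return g1 in self._index and g2 in self._index

    def pair_vector(self) -> np.ndarray:
        """Upper-triangle scores in row-major pair order (i < j)."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def to_square_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as handle:
            handle.write("gene\t" + "\t".join(self.labels) + "\n")
            for gene, row in zip(self.labels, self.values):
                handle.write(gene + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")

    def to_long_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as handle:
            handle.write("gene1\tgene2\tscore\n")
            for i, g1 in enumerate(self.labels):
                for j in range(i + 1, len(self.labels)):
                    handle.write(f"{g1}\t{self.labels[j]}\t{self.values[i, j]:.10g}\n")


def _real_similarity(x: np.ndarray, method: str) -> np.ndarray:
    """euclidean/correlation/cosine similarity on real-valued row vectors."""
    n = x.shape[0]
    if method == "euclidean":
        sq = (x * x).sum(axis=1)
        d2 = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
        np.maximum(d2, 0.0, out=d2)
        return 1.0 / (1.0 + d2)
    if method == "cosine":
        norms = np.sqrt((x * x).sum(axis=1))
        zero = norms == 0
        if zero.any():
            logger.warning("%d all-zero profiles in cosine similarity scored 0", int(zero.sum()))
        safe = np.where(zero, 1.0, norms)
        sim = (x @ x.T) / np.outer(safe, safe)
        sim[zero, :] = 0.0
        sim[:, zero] = 0.0
        return sim
    if method == "correlation":
        centered = x - x.mean(axis=1, keepdims=True)
        sd = np.sqrt((centered * centered).sum(axis=1))
        zero = sd == 0
        if zero.any():
            logger.warning(
                "%d zero-variance profiles in correlation similarity scored 0", int(zero.sum())
            )
        safe = np.where(zero, 1.0, sd)
        sim = (centered @ centered.T) / np.outer(safe, safe)
        sim[zero, :] = 0.0
        sim[:, zero] = 0.0
        np.clip(sim, -1.0, 1.0, out=sim)
        return sim
    raise ValueError(f"unknown real-vector method: {method}")


def profile_similarity(matrix: PhenotypeMatrix, method: str) -> SimilarityMatrix:
    """Pairwise gene similarity on binary profiles.

    Formulas (x1, x2 binary over n_P phenotype positions):

    - euclidean: 1 / (1 + squared euclidean distance)
    - correlation: Pearson over positions
    - cosine: dot / (|x1| |x2|)
    - hamming: matching positions / n_P
    - jaccard: |1s intersection| / |1s union|
    - kappa: (p0 - pc) / (1 - pc), p0 the matching fraction and
      pc = q1*q2 + (1-q1)(1-q2) from the marginal 1-frequencies
    - tfidf: max over shared phenotypes p of IDF(p) = log(n_G / (1 + column sum)),
      0 when no phenotype is shared

    Degenerate pairs (zero vectors, zero variance, pc = 1) score 0 with a
    logged warning instead of NaN.
    """
    if method not in PROFILE_METHODS:
        raise ValueError(f"unknown profile similarity method: {method!r}")
    x = matrix.values.astype(float)
    n_genes, n_p = x.shape
    if method == "correlation" and n_p < 2:
        raise ValueError("correlation requires at least 2 phenotypes")

    if method in ("euclidean", "correlation", "cosine"):
        sim = _real_similarity(x, method)
    elif method == "hamming":
        mismatches = (x[:, None, :] != x[None, :, :]).sum(axis=2) if n_genes <= 512 else None
        if mismatches is None:
            # matching = n - |x1| - |x2| + 2 x1.x2  on binary vectors
            ones = x.sum(axis=1)
            dot = x @ x.T
            mismatches = ones[:, None] + ones[None, :] - 2 * dot
        sim = (n_p - mismatches) / n_p
    elif method == "jaccard":
        inter = x @ x.T
        ones = x.sum(axis=1)
        union = ones[:, None] + ones[None, :] - inter
        zero = union == 0
        if zero.any():
            logger.warning("gene pairs with empty union in jaccard scored 0")
        sim = np.where(zero, 0.0, inter / np.where(zero, 1.0, union))
    elif method == "kappa":
        dot = x @ x.T
        ones = x.sum(axis=1)
        matching = n_p - (ones[:, None] + ones[None, :] - 2 * dot)
        p0 = matching / n_p
        q = ones / n_p
        pc = q[:, None] * q[None, :] + (1 - q[:, None]) * (1 - q[None, :])
        degenerate = np.isclose(pc, 1.0)
        if degenerate.any():
            logger.warning("kappa pairs with chance agreement 1 scored 0")
        sim = np.where(degenerate, 0.0, (p0 - pc) / np.where(degenerate, 1.0, 1.0 - pc))
    elif method == "tfidf":
        idf = np.log(n_genes / (1.0 + x.sum(axis=0)))
        sim = np.zeros((n_genes, n_genes))
        for i in range(n_genes):
            shared = (x[i] > 0) & (x > 0)  # n_genes x n_p
            weighted = np.where(shared, idf[None, :], -np.inf)
            best = weighted.max(axis=1)
            sim[i] = np.where(np.isneginf(best), 0.0, best)
        sim = np.maximum(sim, sim.T)  # guard symmetry against fp quirks

    sim = (sim + sim.T) / 2.0
    return SimilarityMatrix(
        labels=list(matrix.genes), values=sim, measure=method, metadata={"space": "profile"}
    )


def embedding_similarity(
    embedding: np.ndarray, labels: Sequence[str], method: str, metadata: dict | None = None
) -> SimilarityMatrix:
    """euclidean/correlation/cosine similarity in a real-valued embedding space."""
    if method not in EMBEDDING_METHODS:
        raise ValueError(f"unknown embedding similarity method: {method!r}")
    sim = _real_similarity(np.asarray(embedding, dtype=float), method)
    sim = (sim + sim.T) / 2.0
    meta = {"space": "embedding"}
    meta.update(metadata or {})
    return SimilarityMatrix(labels=list(labels), values=sim, measure=method, metadata=meta)


def logistic_pca_embed(
    matrix: PhenotypeMatrix,
    k: int = 10,
    seed: int = 0,
    m: float = 4.0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> np.ndarray:
    """Logistic (Bernoulli-likelihood) PCA embedding of a binary matrix.

    Majorization-minimization on the projection formulation: natural
    parameters are approximated by ``m * (2X - 1)`` and projected onto a rank-k
    subspace; each iteration solves a symmetric eigenproblem, so the fit is
    deterministic for a fixed input (``seed`` is recorded for provenance and
    sign conventions are fixed). Returns the n_genes x k score matrix.
    """
    x = matrix.values.astype(float)
    n, d = x.shape
    if k > d:
        raise ValueError(f"k={k} exceeds the number of phenotypes ({d})")
    q = 2.0 * x - 1.0
    theta_tilde = m * q
    mu = theta_tilde.mean(axis=0)
    tc = theta_tilde - mu  # centered natural parameters

    def sigmoid(t: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-np.clip(t, -30, 30)))

    def neg_loglik(theta: np.ndarray) -> float:
        t = np.clip(theta, -30, 30)
        return float(np.sum(np.log1p(np.exp(t)) - x * t))

    # init: ordinary PCA directions of the centered natural parameters
    _, _, vt = np.linalg.svd(tc, full_matrices=False)
    u = vt[:k].T

    last = np.inf
    converged = False
    for _ in range(max_iter):
        theta = mu + tc @ u @ u.T
        z = theta + 4.0 * (x - sigmoid(theta))
        zc = z - mu
        # minimizing ||Zc - Tc U U'||_F^2 over orthonormal U: top-k eigenvectors
        sym = tc.T @ zc
        eigvals, eigvecs = np.linalg.eigh(sym + sym.T - tc.T @ tc)
        u = eigvecs[:, np.argsort(eigvals)[::-1][:k]]
        loss = neg_loglik(mu + tc @ u @ u.T)
        if abs(last - loss) <= tol * (abs(last) + 1.0):
            converged = True
            break
        last = loss
    if not converged:
        logger.warning("logistic PCA did not converge in %d iterations; using best iterate", max_iter)

    # fix the eigenvector sign ambiguity deterministically
    for j in range(u.shape[1]):
        pivot = np.argmax(np.abs(u[:, j]))
        if u[pivot, j] < 0:
            u[:, j] = -u[:, j]
    return tc @ u


def perturb_sparsity(matrix: PhenotypeMatrix, fraction: float, seed: int) -> PhenotypeMatrix:
    """Flip round(fraction * #ones) uniformly chosen 1-entries to 0 (seeded).

    Zero entries are never modified.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie strictly between 0 and 1")
    ones_idx = np.argwhere(matrix.values == 1)
    if len(ones_idx) == 0:
        raise ValueError("matrix contains no 1-entries to perturb")
    n_flip = int(round(fraction * len(ones_idx)))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(ones_idx), size=n_flip, replace=False)
    values = matrix.values.copy()
    for i in chosen:
        r, c = ones_idx[i]
        values[r, c] = 0
    return PhenotypeMatrix(genes=list(matrix.genes), phenotypes=list(matrix.phenotypes), values=values)
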