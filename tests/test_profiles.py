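import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenolink.profiles import (
    EMBEDDING_METHODS,
    PROFILE_METHODS,
    PhenotypeMatrix,
    embedding_similarity,
    logistic_pca_embed,
    perturb_sparsity,
    profile_similarity,
)


def oracle_pair_score(x1, x2, method, n_genes, column_sums):
    """Direct-from-formula scalar oracle for one gene pair."""
    x1, x2 = np.asarray(x1, float), np.asarray(x2, float)
    n = len(x1)
    if method == "euclidean":
        return 1.0 / (1.0 + ((x1 - x2) ** 2).sum())
    if method == "cosine":
        if x1.sum() == 0 or x2.sum() == 0:
            return 0.0
        return float(x1 @ x2 / (math.sqrt(x1 @ x1) * math.sqrt(x2 @ x2)))
    if method == "correlation":
        c1, c2 = x1 - x1.mean(), x2 - x2.mean()
        if (c1 @ c1) == 0 or (c2 @ c2) == 0:
            return 0.0
        return float(c1 @ c2 / math.sqrt((c1 @ c1) * (c2 @ c2)))
    if method == "hamming":
        return float((x1 == x2).sum() / n)
    if method == "jaccard":
        union = np.logical_or(x1, x2).sum()
        if union == 0:
            return 0.0
        return float(np.logical_and(x1, x2).sum() / union)
    if method == "kappa":
        p0 = (x1 == x2).sum() / n
        q1, q2 = x1.mean(), x2.mean()
        pc = q1 * q2 + (1 - q1) * (1 - q2)
        if math.isclose(pc, 1.0):
            return 0.0
        return float((p0 - pc) / (1 - pc))
    if method == "tfidf":
        shared = np.flatnonzero((x1 > 0) & (x2 > 0))
        if len(shared) == 0:
            return 0.0
        return float(max(math.log(n_genes / (1 + column_sums[p])) for p in shared))
    raise ValueError(method)


class TestMatrixValidation:
    def test_rejects_non_binary(self):
        with pytest.raises(ValueError, match="0 or 1"):
            PhenotypeMatrix(["g1"], ["p1", "p2"], np.array([[1, 2]]))

    def test_rejects_duplicate_labels(self):
        with pytest.raises(ValueError, match="duplicate"):
            PhenotypeMatrix(["g1", "g1"], ["p1"], np.array([[1], [0]]))

    def test_drop_empty_rows(self):
        m = PhenotypeMatrix(["g1", "g2"], ["p1"], np.array([[1], [0]]))
        assert m.drop_empty_rows().genes == ["g1"]

    def test_tsv_roundtrip(self, tmp_path, small_matrix):
        path = tmp_path / "m.tsv"
        small_matrix.to_tsv(path)
        back = PhenotypeMatrix.from_tsv(path)
        assert back.genes == small_matrix.genes
        assert back.phenotypes == small_matrix.phenotypes
        np.testing.assert_array_equal(back.values, small_matrix.values)


class TestProfileSimilarityExamples:
    def test_forced_formulas(self):
        m = PhenotypeMatrix(["g1", "g2"], ["a", "b", "c"], np.array([[1, 0, 1], [1, 1, 1]]))
        assert profile_similarity(m, "hamming").score("g1", "g2") == pytest.approx(2 / 3)
        assert profile_similarity(m, "jaccard").score("g1", "g2") == pytest.approx(2 / 3)
        assert profile_similarity(m, "euclidean").score("g1", "g2") == pytest.approx(0.5)

    def test_identical_profiles(self):
        m = PhenotypeMatrix(["g1", "g2"], ["a", "b", "c"], np.array([[1, 0, 1], [1, 0, 1]]))
        for method in ("correlation", "cosine", "kappa"):
            assert profile_similarity(m, method).score("g1", "g2") == pytest.approx(1.0)

    def test_tfidf_shared_rare_phenotype(self):
        # phenotype 'a' present in exactly g1 and g2 among 4 genes: IDF = log(4/3)
        m = PhenotypeMatrix(
            ["g1", "g2", "g3", "g4"],
            ["a", "b"],
            np.array([[1, 0], [1, 0], [0, 1], [0, 1]]),
        )
        assert profile_similarity(m, "tfidf").score("g1", "g2") >= math.log(4 / 3) - 1e-12
        assert profile_similarity(m, "tfidf").score("g1", "g2") == pytest.approx(math.log(4 / 3))

    def test_kappa_hand_example(self):
        m = PhenotypeMatrix(["g1", "g2"], list("abcd"), np.array([[1, 1, 0, 0], [1, 0, 1, 0]]))
        assert profile_similarity(m, "kappa").score("g1", "g2") == pytest.approx(0.0)

    def test_unknown_method(self, small_matrix):
        with pytest.raises(ValueError, match="unknown"):
            profile_similarity(small_matrix, "manhattan")


class TestProfileSimilarityOracle:
    @pytest.mark.parametrize("method", PROFILE_METHODS)
    def test_100_random_instances(self, method):
        rng = np.random.default_rng(42)
        for trial in range(100):
            values = (rng.random((10, 8)) < 0.4).astype(int)
            values[values.sum(axis=1) == 0, 0] = 1  # no all-zero rows
            m = PhenotypeMatrix([f"g{i}" for i in range(10)], [f"p{j}" for j in range(8)], values)
            sim = profile_similarity(m, method)
            column_sums = values.sum(axis=0)
            for i in range(10):
                for j in range(i, 10):
                    expected = oracle_pair_score(values[i], values[j], method, 10, column_sums)
                    assert sim.values[i, j] == pytest.approx(expected, abs=1e-10), (
                        method, trial, i, j)


class TestProfileSimilarityProperties:
    @pytest.mark.parametrize("method", PROFILE_METHODS)
    def test_symmetry_and_ranges(self, method):
        rng = np.random.default_rng(7)
        values = (rng.random((15, 9)) < 0.5).astype(int)
        values[values.sum(axis=1) == 0, 0] = 1
        m = PhenotypeMatrix([f"g{i}" for i in range(15)], [f"p{j}" for j in range(9)], values)
        sim = profile_similarity(m, method).values
        np.testing.assert_allclose(sim, sim.T, atol=1e-12)
        off = sim[np.triu_indices(15, k=1)]
        if method in ("hamming", "jaccard", "cosine"):
            assert ((off >= -1e-12) & (off <= 1 + 1e-12)).all()
        elif method in ("correlation", "kappa"):
            assert ((off >= -1 - 1e-12) & (off <= 1 + 1e-12)).all()
        elif method == "euclidean":
            assert ((off > 0) & (off <= 1 + 1e-12)).all()
        else:
            assert (off >= 0).all()  # tfidf with no column fuller than n_G/ e

    @given(st.integers(0, 9))
    @settings(max_examples=10, deadline=None)
    def test_euclidean_decreasing_in_mismatch(self, mismatches):
        x1 = np.ones(10, dtype=int)
        x2 = x1.copy()
        x2[:mismatches] = 0
        m = PhenotypeMatrix(["g1", "g2"], [f"p{j}" for j in range(10)], np.vstack([x1, x2]))
        s = profile_similarity(m, "euclidean").score("g1", "g2")
        assert s == pytest.approx(1.0 / (1.0 + mismatches))

    def test_tfidf_idf_antimonotone_in_frequency(self):
        # pair sharing only the commonest phenotype scores <= pair sharing only the rarest
        values = np.array(
            [
                [1, 0],  # g1, g2 share only 'common'
                [1, 0],
                [1, 1],  # g3, g4 share only 'rare'... both columns set for contrast
                [1, 1],
                [1, 0],
                [1, 0],
            ]
        )
        m = PhenotypeMatrix([f"g{i}" for i in range(6)], ["common", "rare"], values)
        sim = profile_similarity(m, "tfidf")
        assert sim.score("g1", "g2") <= sim.score("g3", "g4") + 1e-12


class TestLogisticPCA:
    def test_shape_contract(self, small_matrix):
        emb = logistic_pca_embed(small_matrix, k=2, seed=0)
        assert emb.shape == (4, 2)

    def test_determinism(self, small_matrix):
        e1 = logistic_pca_embed(small_matrix, k=2, seed=3)
        e2 = logistic_pca_embed(small_matrix, k=2, seed=3)
        np.testing.assert_array_equal(e1, e2)

    def test_k_too_large(self, small_matrix):
        with pytest.raises(ValueError):
            logistic_pca_embed(small_matrix, k=5, seed=0)

    def test_two_block_structure_recovered(self):
        rng = np.random.default_rng(0)
        block = np.zeros((40, 12), dtype=int)
        block[:20, :6] = (rng.random((20, 6)) < 0.9).astype(int)
        block[20:, 6:] = (rng.random((20, 6)) < 0.9).astype(int)
        block[block.sum(axis=1) == 0, 0] = 1
        m = PhenotypeMatrix([f"g{i}" for i in range(40)], [f"p{j}" for j in range(12)], block)
        emb = logistic_pca_embed(m, k=3, seed=1)
        sim = embedding_similarity(emb, m.genes, "cosine").values
        within = np.concatenate([sim[:20, :20][np.triu_indices(20, 1)],
                                 sim[20:, 20:][np.triu_indices(20, 1)]])
        between = sim[:20, 20:].ravel()
        assert within.mean() > between.mean()

    @pytest.mark.parametrize("method", EMBEDDING_METHODS)
    def test_embedding_similarity_symmetric(self, small_matrix, method):
        emb = logistic_pca_embed(small_matrix, k=2, seed=0)
        sim = embedding_similarity(emb, small_matrix.genes, method).values
        np.testing.assert_allclose(sim, sim.T, atol=1e-12)


class TestPerturbSparsity:
    def test_exact_count(self):
        values = np.zeros((5, 4), dtype=int)
        values[np.unravel_index(range(10), values.shape)] = 1
        m = PhenotypeMatrix([f"g{i}" for i in range(5)], [f"p{j}" for j in range(4)], values)
        out = perturb_sparsity(m, 0.5, seed=0)
        assert out.values.sum() == 5

    def test_determinism(self, small_matrix):
        a = perturb_sparsity(small_matrix, 0.3, seed=9)
        b = perturb_sparsity(small_matrix, 0.3, seed=9)
        np.testing.assert_array_equal(a.values, b.values)

    def test_zeros_never_modified(self, small_matrix):
        out = perturb_sparsity(small_matrix, 0.3, seed=2)
        assert ((small_matrix.values == 0) <= (out.values == 0)).all()

    def test_fraction_bounds(self, small_matrix):
        with pytest.raises(ValueError):
            perturb_sparsity(small_matrix, 1.5, seed=0)

    def test_no_ones_rejected(self):
        m = PhenotypeMatrix(["g1"], ["p1"], np.array([[0]]))
        with pytest.raises(ValueError):
            perturb_sparsity(m, 0.1, seed=0)
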