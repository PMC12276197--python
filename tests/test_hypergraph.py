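import numpy as np
import pytest
from scipy import stats

from hypercoex import (
    Hypergraph,
    binarize_incidence,
    build_hypergraph,
    compare_topology,
    connectivity,
    correlation_matrix,
    detect_clusters,
    hypergraph_entropy,
    peripheral_genes,
    permute_incidence,
    reduced_adjacency,
)

from conftest import make_expression


def make_hypergraph(M, g=None, gc=None):
    M = np.asarray(M, dtype=np.int8)
    g = g or [f"t{i}" for i in range(M.shape[0])]
    gc = gc or [f"b{j}" for j in range(M.shape[1])]
    return Hypergraph(g, gc, M, reduced_adjacency(M), 0.0, 1.0)


class TestCorrelationMatrix:
    def test_toy_vectors_match_hand_pearson(self):
        x, y = [1.0, 2, 3, 4], [1.0, 3, 2, 4]
        X = make_expression([x, y], ages=[5, 5, 10, 10])
        R = correlation_matrix(X, ["g0"], ["g1"])
        xm, ym = np.mean(x), np.mean(y)
        oracle = np.sum((np.array(x) - xm) * (np.array(y) - ym)) / (
            np.sqrt(np.sum((np.array(x) - xm) ** 2))
            * np.sqrt(np.sum((np.array(y) - ym) ** 2))
        )
        assert R.loc["g0", "g1"] == pytest.approx(oracle)

    def test_copy_and_negation(self):
        base = [1.0, 4, 2, 8, 5]
        X = make_expression([base, base, [-v for v in base]], ages=[5] * 5)
        R = correlation_matrix(X, ["g0"], ["g1", "g2"])
        assert R.loc["g0", "g1"] == pytest.approx(1.0)
        assert R.loc["g0", "g2"] == pytest.approx(-1.0)

    def test_rest_excludes_targets(self, tiny_expr):
        R = correlation_matrix(tiny_expr, ["g0", "g1"], "rest")
        assert list(R.index) == ["g0", "g1"]
        assert set(R.columns) == {"g2", "g3"}

    def test_zero_variance_target_is_error(self):
        X = make_expression([[1.0, 1, 1, 1], [1.0, 2, 3, 4]], ages=[5, 5, 10, 10])
        with pytest.raises(ValueError, match="g0"):
            correlation_matrix(X, ["g0"], ["g1"])

    def test_too_few_samples_is_error(self):
        X = make_expression([[1.0, 2], [3.0, 4]], ages=[5, 10])
        with pytest.raises(ValueError, match="3 samples"):
            correlation_matrix(X, ["g0"], ["g1"])


class TestBinarize:
    def test_single_row_hand_computation(self):
        R = np.array([[0.9, 0.1, -0.8, 0.0, 0.05]])
        M, r_mean, r_sd = binarize_incidence(R)
        assert r_mean == pytest.approx(0.05)
        assert r_sd == pytest.approx(np.std(R, ddof=1))
        assert r_sd == pytest.approx(0.602, abs=1e-3)
        assert M.tolist() == [[1, 0, 1, 0, 0]]

    def test_constant_matrix_all_zero_with_warning(self):
        with pytest.warns(UserWarning, match="zero pooled sd"):
            M, _, r_sd = binarize_incidence(np.full((2, 3), 0.4))
        assert M.sum() == 0 and r_sd == 0

    def test_two_sided_symmetry_about_zero_mean(self):
        rng = np.random.default_rng(0)
        R = rng.uniform(-1, 1, (6, 9))
        R = R - R.mean()  # exactly zero-mean
        M_pos, _, _ = binarize_incidence(R)
        M_neg, _, _ = binarize_incidence(-R)
        assert np.array_equal(M_pos, M_neg)


class TestReducedAdjacency:
    @pytest.mark.parametrize(
        "M,expected",
        [
            ([[1, 0, 1], [1, 1, 0]], [[2, 1], [1, 2]]),
            ([[0, 0], [0, 0]], [[0, 0], [0, 0]]),
            ([[1, 1], [1, 1]], [[2, 2], [2, 2]]),
        ],
    )
    def test_hand_products(self, M, expected):
        assert reduced_adjacency(np.array(M)).tolist() == expected

    def test_matches_shared_column_count_oracle(self):
        """A[i][j] equals a brute-force count of columns where both rows are 1."""
        rng = np.random.default_rng(7)
        for _ in range(1000):
            n = rng.integers(2, 9)
            m = rng.integers(2, 13)
            M = (rng.random((n, m)) < rng.uniform(0.2, 0.8)).astype(np.int8)
            A = reduced_adjacency(M)
            for i in range(n):
                for j in range(n):
                    brute = sum(
                        1 for c in range(m) if M[i, c] == 1 and M[j, c] == 1
                    )
                    assert A[i, j] == brute

    def test_all_ones_column_increments_every_entry(self):
        rng = np.random.default_rng(8)
        M = (rng.random((5, 9)) < 0.5).astype(np.int8)
        A = reduced_adjacency(M)
        A_plus = reduced_adjacency(np.hstack([M, np.ones((5, 1), dtype=np.int8)]))
        assert np.array_equal(A_plus, A + 1)


class TestConnectivity:
    def test_hand_row_sums(self):
        H = make_hypergraph([[1, 0, 1], [1, 1, 0]])
        assert connectivity(H, "incidence").tolist() == [2, 2]
        assert connectivity(H, "adjacency").tolist() == [3, 3]

    def test_all_zero(self):
        H = make_hypergraph(np.zeros((3, 4), dtype=int))
        assert connectivity(H, "incidence").tolist() == [0, 0, 0]
        assert connectivity(H, "adjacency").tolist() == [0, 0, 0]

    def test_gene_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        M = (rng.random((6, 10)) < 0.4).astype(np.int8)
        H = make_hypergraph(M)
        perm = rng.permutation(6)
        Hp = make_hypergraph(M[perm])
        for kind in ("incidence", "adjacency"):
            assert connectivity(Hp, kind).tolist() == connectivity(H, kind)[perm].tolist()


class TestEntropy:
    def test_uniform_is_one(self):
        assert hypergraph_entropy([3.0, 3, 3, 3]) == pytest.approx(1.0)

    def test_degenerate_is_zero(self):
        assert hypergraph_entropy([0.0, 5.0, 0.0]) == pytest.approx(0.0)

    def test_hand_shannon_value(self):
        # p = [1/2, 1/4, 1/4]: H = 1.5 bits, max = log2(3) -> 0.9464
        assert hypergraph_entropy([2.0, 1.0, 1.0]) == pytest.approx(0.9464, abs=1e-4)

    def test_all_zero_is_error(self):
        with pytest.raises(ValueError, match="empty distribution"):
            hypergraph_entropy([0.0, 0.0])

    def test_short_vector_is_error(self):
        with pytest.raises(ValueError):
            hypergraph_entropy([1.0])

    def test_range_on_random_vectors(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            v = rng.gamma(1.0, 1.0, rng.integers(2, 30))
            assert 0.0 <= hypergraph_entropy(v) <= 1.0


class TestDetectClusters:
    def block_hypergraph(self):
        # two blocks of targets sharing disjoint background sets
        M = np.zeros((6, 12), dtype=np.int8)
        M[:3, :6] = 1
        M[3:, 6:] = 1
        return make_hypergraph(M)

    def test_two_blocks_recovered(self):
        H = self.block_hypergraph()
        assignment, _ = detect_clusters(H, k=2)
        labels = [assignment[g] for g in H.g]
        assert labels[0] == labels[1] == labels[2]
        assert labels[3] == labels[4] == labels[5]
        assert labels[0] != labels[3]

    def test_k_equal_n_gives_singletons(self):
        H = self.block_hypergraph()
        assignment, _ = detect_clusters(H, k=6)
        assert len(set(assignment.values())) == 6

    def test_zero_adjacency_is_error(self):
        H = make_hypergraph(np.zeros((3, 5), dtype=int))
        with pytest.raises(ValueError, match="disconnected"):
            detect_clusters(H)

    def test_auto_k_on_planted_hypergraph(self, synth_default):
        from sklearn.metrics import adjusted_rand_score

        sc, _, truth = synth_default
        targets = truth[truth["role"] == "cluster"]["gene"].tolist()
        H = build_hypergraph(sc, targets)
        assignment, _ = detect_clusters(H, k="auto")
        true_labels = truth.set_index("gene").loc[targets, "cluster"].tolist()
        pred = [assignment[g] for g in targets]
        assert adjusted_rand_score(true_labels, pred) >= 0.8


class TestPeripheral:
    def test_hand_column_scan(self):
        H = make_hypergraph([[1, 0, 1], [1, 1, 1]], gc=["c1", "c2", "c3"])
        assert peripheral_genes(H, H.g) == ["c1", "c3"]

    def test_all_zero_row_gives_empty_set(self):
        H = make_hypergraph([[0, 0, 0], [1, 1, 1]])
        assert peripheral_genes(H, H.g) == []

    def test_single_gene_cluster_base_case(self):
        H = make_hypergraph([[1, 0, 1], [0, 1, 1]], gc=["c1", "c2", "c3"])
        assert peripheral_genes(H, [H.g[0]]) == ["c1", "c3"]

    def test_matches_brute_force_subset_criterion(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            M = (rng.random((5, 10)) < 0.5).astype(np.int8)
            H = make_hypergraph(M)
            size = rng.integers(1, 5)
            cluster = list(rng.choice(H.g, size=size, replace=False))
            got = set(peripheral_genes(H, cluster))
            idx = {g: i for i, g in enumerate(H.g)}
            expected = {
                H.gc[j]
                for j in range(M.shape[1])
                if all(M[idx[g], j] == 1 for g in cluster)
            }
            assert got == expected


class TestPermutation:
    def test_row_sums_conserved(self):
        rng = np.random.default_rng(4)
        M = (rng.random((6, 15)) < 0.4).astype(np.int8)
        H = make_hypergraph(M)
        null = permute_incidence(H, n_perm=50, seed=0)
        expected = M.sum(axis=1)
        assert (null.incidence == expected[None, :]).all()

    def test_identical_seed_identical_stream(self):
        rng = np.random.default_rng(5)
        M = (rng.random((4, 10)) < 0.5).astype(np.int8)
        H = make_hypergraph(M)
        a = permute_incidence(H, n_perm=20, seed=11)
        b = permute_incidence(H, n_perm=20, seed=11)
        assert np.array_equal(a.adjacency, b.adjacency)

    def test_permuted_adjacency_mean_matches_exact_expectation(self):
        """Independent within-row shuffles: E[A'[i][j]] = k_i * k_j / m."""
        M = np.array([[1, 1, 0, 0, 0], [1, 1, 1, 0, 0], [1, 0, 0, 0, 1]], dtype=np.int8)
        H = make_hypergraph(M)
        null = permute_incidence(H, n_perm=1000, seed=6)
        m = M.shape[1]
        # adjacency row sum i = sum_j A'[i][j]; exact expectation by linearity
        k = M.sum(axis=1)
        for i in range(3):
            exact = sum(k[i] * k[j] / m if j != i else k[i] for j in range(3))
            emp = null.adjacency[:, i].astype(float)
            se = emp.std(ddof=1) / np.sqrt(len(emp))
            assert abs(emp.mean() - exact) < 3 * max(se, 1e-9)


class TestCompareTopology:
    def test_identical_vectors(self):
        p, fold = compare_topology([1.0, 2, 3], [1.0, 2, 3])
        assert p == pytest.approx(1.0)
        assert fold == pytest.approx(1.0)

    def test_large_shift_separates(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, 100)
        p, _ = compare_topology(a + 100, a)
        assert p < 1e-10

    def test_small_sample_matches_exhaustive_enumeration(self):
        from itertools import combinations

        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        p, _ = compare_topology(a, b)
        # enumerate all C(6,3) assignments of ranks to group a
        pooled_ranks = stats.rankdata(a + b)
        obs = pooled_ranks[:3].sum()
        sums = [sum(c) for c in combinations(pooled_ranks, 3)]
        center = np.mean(sums)
        extreme = sum(1 for s in sums if abs(s - center) >= abs(obs - center) - 1e-9)
        assert p == pytest.approx(extreme / len(sums))

    def test_zero_mean_denominator_fold_missing(self):
        p, fold = compare_topology([1.0, 2.0], [0.0, 0.0])
        assert np.isnan(fold)
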