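import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emtnet.grn import (
    PIDCNetwork,
    confidence_network,
    discretize_matrix,
    mutual_information,
    puc_matrix,
    redundancy_imin,
    state_grn,
    unique_information,
)

# exhaustive 4-sample tables over binary (x, z)
X4 = np.array([0, 0, 1, 1])
Z4 = np.array([0, 1, 0, 1])
XOR4 = X4 ^ Z4


def brute_force_mi(x, y):
    """Independent plug-in estimate via explicit dictionary counting."""
    n = len(x)
    joint, px, py = {}, {}, {}
    for a, b in zip(x, y):
        joint[(a, b)] = joint.get((a, b), 0) + 1
        px[a] = px.get(a, 0) + 1
        py[b] = py.get(b, 0) + 1
    total = 0.0
    for (a, b), c in joint.items():
        p = c / n
        total += p * np.log2(p / ((px[a] / n) * (py[b] / n)))
    return total


class TestDiscretize:
    def test_constant_gene_single_bin(self):
        D = discretize_matrix(np.full((10, 1), 3.0))
        assert D.n_bins == [1]
        assert np.all(D.codes == 0)

    def test_two_bins_split_at_midpoint(self):
        D = discretize_matrix(np.array([[0.0], [1.0], [2.0], [3.0]]), n_bins=2)
        assert list(D.codes[:, 0]) == [0, 0, 1, 1]

    def test_sturges_auto_bins(self):
        D = discretize_matrix(np.arange(8.0).reshape(8, 1))
        assert D.n_bins == [4]


class TestInformationMeasures:
    def test_perfect_copy_is_one_bit(self):
        x = np.array([0, 1, 0, 1, 0, 1])
        assert mutual_information(x, x) == pytest.approx(1.0)

    def test_constant_has_zero_information(self):
        x = np.zeros(6, dtype=int)
        y = np.array([0, 1, 0, 1, 0, 1])
        assert mutual_information(x, y) == 0.0

    def test_hand_computed_joint(self):
        # p(0,0)=p(1,1)=3/8, p(0,1)=p(1,0)=1/8 as an 8-sample dataset
        x = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        y = np.array([0, 0, 0, 1, 1, 1, 1, 0])
        expected = 1.0 - (-(0.25 * np.log2(0.25) + 0.75 * np.log2(0.75)))
        assert mutual_information(x, y) == pytest.approx(expected, abs=1e-12)
        assert mutual_information(x, y) == pytest.approx(0.18872, abs=1e-5)

    def test_symmetry_and_brute_force_agreement(self, rng):
        for _ in range(20):
            x = rng.integers(0, 3, 30)
            y = rng.integers(0, 4, 30)
            mi = mutual_information(x, y)
            assert abs(mi - mutual_information(y, x)) < 1e-12
            assert abs(mi - brute_force_mi(x, y)) < 1e-12

    def test_redundancy_of_perfect_copies(self):
        y = np.array([0, 1, 0, 1])
        assert redundancy_imin(y, y, y) == pytest.approx(1.0)

    def test_xor_has_no_redundancy(self):
        assert redundancy_imin(XOR4, X4, Z4) == pytest.approx(0.0)
        assert mutual_information(X4, XOR4) == pytest.approx(0.0)

    def test_constant_source_zeroes_redundancy(self):
        y = np.array([0, 1, 0, 1])
        z = np.zeros(4, dtype=int)
        assert redundancy_imin(y, y, z) == pytest.approx(0.0)

    def test_unique_information_cases(self):
        y = X4.copy()
        assert unique_information(X4, y, Z4) == pytest.approx(1.0)  # Z independent
        assert unique_information(X4, y, X4) == pytest.approx(0.0)  # Z redundant
        assert unique_information(X4, XOR4, Z4) == pytest.approx(0.0)  # synergy only

    @settings(max_examples=60, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(0, 1), st.integers(0, 1), st.integers(0, 1)),
            min_size=4,
            max_size=16,
        )
    )
    def test_pid_inequalities_on_binary_triples(self, samples):
        x, y, z = (np.array(v) for v in zip(*samples))
        imin = redundancy_imin(y, x, z)
        assert imin >= -1e-12
        assert imin <= min(mutual_information(x, y), mutual_information(z, y)) + 1e-12
        assert unique_information(x, y, z) >= 0


class TestPUC:
    def test_three_identical_genes_have_no_unique_information(self):
        col = np.array([0, 1, 0, 1, 0, 1])
        U = puc_matrix(discretize_matrix(np.column_stack([col, col, col]).astype(float)))
        assert np.allclose(U, 0.0, atol=1e-12)

    def test_copied_pair_with_independent_third(self):
        x = np.array([0, 0, 1, 1], dtype=float)
        z = np.array([0, 1, 0, 1], dtype=float)
        U = puc_matrix(discretize_matrix(np.column_stack([x, x, z])))
        assert U[0, 1] == pytest.approx(2.0)

    def test_symmetric_zero_diagonal(self, rng):
        U = puc_matrix(discretize_matrix(rng.random((25, 5))))
        assert np.allclose(U, U.T)
        assert np.all(np.diag(U) == 0)
        assert np.all(U >= 0)

    def test_matches_pairwise_definition(self, rng):
        """Vectorized accumulation equals the naive sum over third genes."""
        values = rng.integers(0, 2, (16, 4)).astype(float)
        D = discretize_matrix(values, n_bins=2)
        U = puc_matrix(D)
        codes = D.codes
        for a in range(4):
            for b in range(a + 1, 4):
                mi = mutual_information(codes[:, a], codes[:, b])
                if mi == 0:
                    expected = 0.0
                else:
                    expected = sum(
                        unique_information(codes[:, a], codes[:, b], codes[:, c])
                        + unique_information(codes[:, b], codes[:, a], codes[:, c])
                        for c in range(4)
                        if c not in (a, b)
                    ) / mi
                assert U[a, b] == pytest.approx(expected, abs=1e-10)

    def test_too_few_genes_rejected(self, rng):
        with pytest.raises(ValueError):
            puc_matrix(discretize_matrix(rng.random((10, 2))))


class TestConfidence:
    def test_worked_example(self):
        U = np.array([[0.0, 2.0, 1.0], [2.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        C = confidence_network(U)
        assert C[0, 1] == pytest.approx(2.0)
        assert C[0, 2] == pytest.approx(1.5)
        assert C[1, 2] == pytest.approx(1.0)

    def test_uniform_scores_saturate(self):
        U = np.full((4, 4), 0.7)
        np.fill_diagonal(U, 0)
        C = confidence_network(U)
        off = ~np.eye(4, dtype=bool)
        assert np.allclose(C[off], 2.0)

    def test_symmetric_bounded(self, rng):
        A = rng.random((6, 6))
        U = (A + A.T) / 2
        np.fill_diagonal(U, 0)
        C = confidence_network(U)
        assert np.allclose(C, C.T)
        off = ~np.eye(6, dtype=bool)
        assert np.all(C[off] > 0) and np.all(C[off] <= 2)

    def test_invariant_under_monotone_transform(self, rng):
        A = rng.random((5, 5))
        U = (A + A.T) / 2
        np.fill_diagonal(U, 0)
        transformed = np.exp(3 * U) - 1  # strictly monotone, preserves 0
        np.fill_diagonal(transformed, 0)
        assert np.allclose(confidence_network(U), confidence_network(transformed))


class TestStateGRN:
    def test_ceiling_prune_and_rescale(self, rng):
        # 5 genes -> 10 candidate edges; keep 30% -> ceil(3) = 3 edges
        values = rng.random((12, 5))
        labels = np.zeros(12, dtype=int)
        out = state_grn(pd.DataFrame(values, columns=list("abcde")), labels, 0,
                        list("abcde"), keep_fraction=0.3, max_weight_norm=2.0)
        assert len(out.edges) == 3
        assert out.edges[0][2] == pytest.approx(2.0)
        weights = [w for *_, w in out.edges]
        assert weights == sorted(weights, reverse=True)

    def test_planted_coexpressed_pair_ranks_first(self, rng):
        base = rng.integers(0, 5, 40).astype(float)
        twin = base + rng.normal(0, 0.05, 40)
        noise = rng.random((40, 3)) * 4
        X = pd.DataFrame(
            np.column_stack([base, twin, noise]), columns=["a", "b", "c", "d", "e"]
        )
        out = state_grn(X, np.zeros(40, dtype=int), 0, list("abcde"),
                        keep_fraction=0.2)
        assert {out.edges[0][0], out.edges[0][1]} == {"a", "b"}

    def test_too_few_cells_names_state(self, rng):
        X = pd.DataFrame(rng.random((6, 3)), columns=list("abc"))
        with pytest.raises(ValueError, match="state 1"):
            state_grn(X, np.array([0, 0, 0, 0, 0, 1]), 1, list("abc"))

    def test_estimator_edge_table_sorted(self, rng):
        X = pd.DataFrame(rng.random((20, 4)), columns=list("abcd"))
        net = PIDCNetwork().fit(X)
        table = net.edge_table()
        assert list(table.columns) == ["gene_x", "gene_y", "puc", "confidence"]
        assert table["confidence"].is_monotonic_decreasing
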