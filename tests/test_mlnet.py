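import numpy as np
import pandas as pd
import pytest

from emtnet.grn import StateGRN
from emtnet.mlnet import (
    assemble_multilayer,
    compute_centralities,
    node_closeness,
    node_pagerank,
    node_strength,
    target_expression_links,
    target_marker_links,
)


def floyd_warshall(cost):
    """Independent all-pairs shortest-path oracle."""
    K = cost.shape[0]
    D = cost.copy()
    np.fill_diagonal(D, 0.0)
    for m in range(K):
        for i in range(K):
            for j in range(K):
                if D[i, m] + D[m, j] < D[i, j]:
                    D[i, j] = D[i, m] + D[m, j]
    return D


def closeness_oracle(P, mode):
    cost = np.where(P > 0, P, np.inf)
    D = floyd_warshall(cost)
    if mode == "in":
        D = D.T
    K = P.shape[0]
    out = np.zeros(K)
    for v in range(K):
        d = np.delete(D[v], v)
        fin = np.isfinite(d)
        r = fin.sum()
        if r and d[fin].sum() > 0:
            out[v] = (r / d[fin].sum()) * (r / (K - 1))
    return out


def google_matrix_oracle(P, damping=0.85):
    K = P.shape[0]
    out = P.sum(axis=1)
    T = np.divide(P, out[:, None], out=np.zeros_like(P), where=out[:, None] > 0)
    T[out == 0] = 1.0 / K
    G = damping * T + (1 - damping) / K
    vals, vecs = np.linalg.eig(G.T)
    v = np.real(vecs[:, np.argmax(np.real(vals))])
    v = np.abs(v)
    return v / v.sum()


def _grn(state, edges):
    genes = sorted({g for e in edges for g in e[:2]})
    return StateGRN(state=state, gene_ids=genes, edges=edges,
                    keep_fraction=0.3, max_weight_norm=2.0)


class TestInterLayerLinks:
    def test_state_exclusive_target_zero_elsewhere(self):
        X = pd.DataFrame({"t": [3.0, 3.0, 0.0, 0.0], "o": [1.0] * 4})
        labels = np.array([0, 0, 1, 1])
        links = target_expression_links(X, labels, ["t"], keep_fraction=1.0)
        weights = {k: w for k, _, w in links}
        assert weights[0] == pytest.approx(3.0)
        assert weights[1] == 0.0

    def test_keep_fraction_ceiling(self, rng):
        X = pd.DataFrame(rng.random((10, 5)), columns=list("abcde"))
        labels = np.repeat([0, 1], 5)
        links = target_expression_links(X, labels, list("abcde"), keep_fraction=0.2)
        assert len(links) == 2  # ceil(0.2 * 2 * 5)

    def test_hand_computed_means(self):
        X = pd.DataFrame({"t": [1.0, 3.0, 5.0, 7.0]})
        labels = np.array([0, 0, 1, 1])
        links = dict(
            ((k, t), w)
            for k, t, w in target_expression_links(X, labels, ["t"], keep_fraction=1.0)
        )
        assert links[(0, "t")] == pytest.approx(2.0)
        assert links[(1, "t")] == pytest.approx(6.0)

    def test_cross_links_full_keep_covers_all_pairs(self, rng):
        X = pd.DataFrame(rng.random((20, 4)), columns=["t1", "t2", "m1", "m2"])
        labels = np.repeat([0, 1], 10)
        links = target_marker_links(
            X, labels, ["t1", "t2"], ["m1", "m2"], keep_fraction=1.0
        )
        assert len(links) == 2 * 2 * 2  # states x targets x markers
        assert all(t.startswith("t") and m.startswith("m") for _, t, m, _ in links)


class TestAssembly:
    def _components(self, P):
        K = P.shape[0]
        tg = {k: _grn(k, [("t1", "t2", 2.0)]) for k in range(K)}
        mg = {k: _grn(k, [("m1", "m2", 1.0)]) for k in range(K)}
        return tg, mg

    def test_threshold_rule_on_layer1(self):
        P = np.array([[0.0, 0.6], [0.4, 0.0]])
        tg, mg = self._components(P)
        net = assemble_multilayer(P, tg, mg, [], [], signaling_threshold=0.5)
        assert net.edge_count("intra1") == 1

    def test_empty_target_grns_still_valid(self):
        P = np.array([[0.0, 0.6], [0.4, 0.0]])
        tg = {k: _grn(k, []) for k in range(2)}
        _, mg = self._components(P)
        net = assemble_multilayer(P, tg, mg, [], [])
        assert net.edge_count("intra2") == 0
        assert net.edge_count("intra3") == 2

    def test_node_tuple_count(self):
        P = np.zeros((3, 3))
        tg, mg = self._components(P)
        net = assemble_multilayer(P, tg, mg, [], [])
        assert len(net.nodes) == 3 * (1 + 2 + 2)

    def test_state_set_mismatch_rejected(self):
        P = np.zeros((3, 3))
        tg, mg = self._components(P)
        del tg[2]
        with pytest.raises(ValueError, match="states"):
            assemble_multilayer(P, tg, mg, [], [])

    def test_unknown_edge_endpoint_rejected(self):
        P = np.zeros((2, 2))
        tg, mg = self._components(P)
        with pytest.raises(ValueError, match="unknown"):
            assemble_multilayer(P, tg, mg, [(0, "absent_gene", 1.0)], [])

    def test_raising_threshold_never_adds_edges(self, rng):
        P = rng.random((4, 4))
        tg, mg = self._components(P)
        counts = [
            assemble_multilayer(P, tg, mg, [], [], signaling_threshold=t).edge_count(
                "intra1"
            )
            for t in (0.1, 0.5, 0.9)
        ]
        assert counts == sorted(counts, reverse=True)


class TestStrength:
    def test_single_edge(self):
        P = np.zeros((2, 2))
        P[0, 1] = 0.3
        assert list(node_strength(P, "in")) == [0.0, 0.3]
        assert list(node_strength(P, "out")) == [0.3, 0.0]

    def test_conservation(self, rng):
        P = rng.random((5, 5))
        assert node_strength(P, "in").sum() == pytest.approx(
            node_strength(P, "out").sum()
        )

    def test_hand_summed_matrix(self):
        P = np.array([[0.0, 0.2, 0.1], [0.0, 0.0, 0.4], [0.3, 0.0, 0.0]])
        assert np.allclose(node_strength(P, "out"), [0.3, 0.4, 0.3])
        assert np.allclose(node_strength(P, "in"), [0.3, 0.2, 0.5])


class TestCloseness:
    def test_two_node_single_edge(self):
        P = np.zeros((2, 2))
        P[0, 1] = 0.5
        out = node_closeness(P, "out")
        assert out[0] == pytest.approx(2.0)
        assert out[1] == 0.0
        inn = node_closeness(P, "in")
        assert inn[0] == 0.0
        assert inn[1] == pytest.approx(2.0)

    def test_complete_unit_graph_all_equal_one(self):
        P = np.ones((4, 4)) - np.eye(4)
        assert np.allclose(node_closeness(P, "in"), 1.0)
        assert np.allclose(node_closeness(P, "out"), 1.0)

    def test_matches_shortest_path_oracle(self, rng):
        for _ in range(20):
            K = int(rng.integers(5, 7))
            P = rng.random((K, K)) * (rng.random((K, K)) > 0.4)
            np.fill_diagonal(P, 0)
            for mode in ("in", "out"):
                assert np.allclose(
                    node_closeness(P, mode), closeness_oracle(P, mode), atol=1e-9
                )


class TestPagerank:
    def test_symmetric_two_cycle(self):
        P = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert np.allclose(node_pagerank(P), [0.5, 0.5])

    def test_sums_to_one(self, rng):
        P = rng.random((6, 6)) * (rng.random((6, 6)) > 0.5)
        assert node_pagerank(P).sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_google_matrix_eigenvector(self, rng):
        for _ in range(20):
            K = 5
            P = rng.random((K, K)) * (rng.random((K, K)) > 0.4)
            np.fill_diagonal(P, 0)
            assert np.allclose(
                node_pagerank(P), google_matrix_oracle(P), atol=1e-9
            )


class TestReceiverSignature:
    def test_pure_receiver_has_max_in_strength_min_in_closeness(self):
        # node 3 receives heavy edges from everyone, sends nothing;
        # senders are cheaply interconnected
        K = 4
        P = np.full((K, K), 0.1)
        np.fill_diagonal(P, 0)
        P[:, 3] = 0.8
        P[3, :] = 0.0
        s_in = node_strength(P, "in")
        assert s_in.argmax() == 3
        c_in = node_closeness(P, "in")
        assert all(c_in[3] < c_in[v] for v in range(3))

    def test_receiver_is_pagerank_hub(self):
        P = np.zeros((3, 3))
        P[0, 2] = P[1, 2] = 0.9
        P[0, 1] = 0.1
        pr = node_pagerank(P)
        assert pr.argmax() == 2


def test_centrality_table_shape(rng):
    P = rng.random((4, 4))
    table = compute_centralities(P)
    assert list(table.columns) == [
        "in_strength", "out_strength", "in_closeness", "out_closeness", "pagerank",
    ]
    assert len(table) == 4
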