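"""Multilayer network assembly and signaling-network centralities.

The hierarchical multilayer network has two aspects: a hierarchy aspect with
three layers (cell-cell communication, target genes, marker genes) and a
cell-state aspect with one layer per cluster, ordered by trajectory
position. Layer 1 holds one node per state and the thresholded directed
cluster-cluster signaling edges; layers 2 and 3 hold, per state, the pruned
gene networks among pathway target genes and among cluster marker genes.
Inter-layer edges link a state to its highly expressed targets (layer 1 ->
2) and targets to markers with strong state-specific interactions (layer 2
-> 3).

Centralities of the directed, weighted signaling network follow the usual
graph-library conventions: in-/out-strength are weighted degree sums;
closeness treats edge weights as path costs and is normalized by the
reachable fraction of the network, so a state that receives only heavy
(high-probability) edges shows high in-strength but low in-closeness — the
receiver signature; pagerank uses the weight-proportional random walk with
uniform teleport and uniform redistribution of dangling mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import dijkstra

from .comm import ClusterSignaling
from .grn import StateGRN

__all__ = [
    "MultilayerNetwork",
    "assemble_multilayer",
    "target_expression_links",
    "target_marker_links",
    "node_strength",
    "node_closeness",
    "node_pagerank",
    "compute_centralities",
]

DEFAULT_SIGNALING_THRESHOLD = 0.5
DEFAULT_EXPR_KEEP = 0.20
DEFAULT_CROSS_KEEP = 0.015


@dataclass
class MultilayerNetwork:
    """Validated node-layer tuples and edges of the assembled network.

    Nodes are (node id, hierarchy layer in {1,2,3}, state layer); edges carry
    a weight and a kind tag (intra1|intra2|intra3|inter12|inter23).
    """

    states: list[int]
    targets: list[str]
    markers: list[str]
    state_order: list[int]  # trajectory order of the state layers
    nodes: list[tuple[str, int, int]]
    edges: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for e in self.edges:
            if e["src"] not in node_set or e["dst"] not in node_set:
                raise ValueError(f"edge references unknown node-layer tuple: {e}")

    def edge_count(self, kind: str | None = None) -> int:
        if kind is None:
            return len(self.edges)
        return sum(e["kind"] == kind for e in self.edges)

    def to_dict(self) -> dict:
        return {
            "states": self.states,
            "targets": self.targets,
            "markers": self.markers,
            "state_order": self.state_order,
            "nodes": [
                {"id": nid, "hierarchy_layer": h, "state_layer": s}
                for nid, h, s in self.nodes
            ],
            "edges": [
                {
                    "src": list(e["src"]),
                    "dst": list(e["dst"]),
                    "weight": e["weight"],
                    "kind": e["kind"],
                }
                for e in self.edges
            ],
        }


def target_expression_links(
    X,
    labels: np.ndarray,
    targets: list[str],
    keep_fraction: float = DEFAULT_EXPR_KEEP,
) -> list[tuple[int, str, float]]:
    """State -> target links weighted by mean target expression in the state.

    Keeps the global top ceil(keep_fraction * N_states * |targets|) links by
    weight (ties by state then target id). Empty states contribute weight 0.
    """
    if not targets:
        raise ValueError("targets must be nonempty")
    df = X.to_frame() if hasattr(X, "to_frame") and not isinstance(X, pd.DataFrame) else (
        X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
    )
    labels = np.asarray(labels, dtype=int)
    states = sorted(set(int(s) for s in labels))
    links = []
    for k in states:
        mask = labels == k
        for t in targets:
            w = float(df.loc[np.asarray(df.index)[mask], t].mean()) if mask.any() else 0.0
            links.append((k, t, w))
    links.sort(key=lambda e: (-e[2], e[0], e[1]))
    n_keep = int(np.ceil(keep_fraction * len(states) * len(targets)))
    return links[:n_keep]


def target_marker_links(
    X,
    labels: np.ndarray,
    targets: list[str],
    markers: list[str],
    keep_fraction: float = DEFAULT_CROSS_KEEP,
    n_bins: int | None = None,
    min_cells: int = 5,
) -> list[tuple[int, str, str, float]]:
    """Target -> marker links from state-specific confidence networks.

    Runs the PUC/confidence pipeline on targets + markers within each state,
    keeps only target-marker cross pairs, then the global top
    ceil(keep_fraction * N_states * |targets| * |markers|) by confidence.
    """
    from .grn import confidence_network, discretize_matrix, puc_matrix

    genes = list(dict.fromkeys(list(targets) + list(markers)))
    if len(genes) < 3:
        raise ValueError("need at least 3 genes across targets and markers")
    df = X.to_frame() if hasattr(X, "to_frame") and not isinstance(X, pd.DataFrame) else (
        X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
    )
    labels = np.asarray(labels, dtype=int)
    states = sorted(set(int(s) for s in labels))
    target_set, marker_set = set(targets), set(markers)
    links = []
    for k in states:
        mask = labels == k
        if mask.sum() < min_cells:
            raise ValueError(
                f"state {k}: only {int(mask.sum())} cells for cross-layer inference"
            )
        sub = df.loc[np.asarray(df.index)[mask], genes]
        C = confidence_network(puc_matrix(discretize_matrix(sub.to_numpy(float), n_bins)))
        for a in range(len(genes)):
            for b in range(a + 1, len(genes)):
                ga, gb = genes[a], genes[b]
                if ga in target_set and gb in marker_set:
                    links.append((k, ga, gb, float(C[a, b])))
                elif ga in marker_set and gb in target_set:
                    links.append((k, gb, ga, float(C[a, b])))
    links.sort(key=lambda e: (-e[3], e[0], e[1], e[2]))
    n_keep = int(np.ceil(keep_fraction * len(states) * len(targets) * len(markers)))
    return links[:n_keep]


def assemble_multilayer(
    Pc: ClusterSignaling | np.ndarray,
    target_grns: dict[int, StateGRN],
    marker_grns: dict[int, StateGRN],
    expr_links: list[tuple[int, str, float]],
    cross_links: list[tuple[int, str, str, float]],
    signaling_threshold: float = DEFAULT_SIGNALING_THRESHOLD,
    state_order: list[int] | None = None,
) -> MultilayerNetwork:
    """Assemble the hierarchy x cell-state multilayer network.

    Layer-1 intra edges are the cluster-signaling entries strictly above
    ``signaling_threshold``; layer-2/3 intra edges come from the per-state
    GRNs; inter-layer edges are attached as supplied.
    """
    P = Pc.probabilities if isinstance(Pc, ClusterSignaling) else np.asarray(Pc, float)
    K = P.shape[0]
    states = list(range(K))
    if state_order is None:
        state_order = states
    if sorted(state_order) != states:
        raise ValueError("state_order must be a permutation of the states")
    if set(target_grns) != set(states) or set(marker_grns) != set(states):
        raise ValueError("per-state GRNs must cover exactly the signaling states")

    targets = sorted({g for grn in target_grns.values() for g in grn.gene_ids})
    markers = sorted({g for grn in marker_grns.values() for g in grn.gene_ids})

    nodes: list[tuple[str, int, int]] = []
    for k in states:
        nodes.append((f"S{k}", 1, k))
        nodes.extend((t, 2, k) for t in targets)
        nodes.extend((m, 3, k) for m in markers)

    edges: list[dict] = []
    for u in range(K):
        for v in range(K):
            if u != v and P[u, v] > signaling_threshold:
                edges.append(
                    {"src": (f"S{u}", 1, u), "dst": (f"S{v}", 1, v),
                     "weight": float(P[u, v]), "kind": "intra1"}
                )
    for k, grn_obj in target_grns.items():
        for gx, gy, w in grn_obj.edges:
            edges.append(
                {"src": (gx, 2, k), "dst": (gy, 2, k), "weight": float(w),
                 "kind": "intra2"}
            )
    for k, grn_obj in marker_grns.items():
        for gx, gy, w in grn_obj.edges:
            edges.append(
                {"src": (gx, 3, k), "dst": (gy, 3, k), "weight": float(w),
                 "kind": "intra3"}
            )
    for k, t, w in expr_links:
        edges.append(
            {"src": (f"S{k}", 1, k), "dst": (t, 2, k), "weight": float(w),
             "kind": "inter12"}
        )
    for k, t, m, w in cross_links:
        edges.append(
            {"src": (t, 2, k), "dst": (m, 3, k), "weight": float(w),
             "kind": "inter23"}
        )
    return MultilayerNetwork(
        states=states,
        targets=targets,
        markers=markers,
        state_order=list(state_order),
        nodes=nodes,
        edges=edges,
    )


def _as_matrix(Pc) -> np.ndarray:
    P = Pc.probabilities if isinstance(Pc, ClusterSignaling) else np.asarray(Pc, float)
    return np.asarray(P, dtype=float)


def node_strength(Pc, mode: str = "in") -> np.ndarray:
    """Weighted degree: sum of incoming (``in``) or outgoing (``out``) weights."""
    P = _as_matrix(Pc)
    if mode == "in":
        return P.sum(axis=0)
    if mode == "out":
        return P.sum(axis=1)
    raise ValueError(f"mode must be 'in' or 'out', got {mode!r}")


def node_closeness(Pc, mode: str = "in", weights_as: str = "cost") -> np.ndarray:
    """Normalized closeness with edge weights as shortest-path costs.

    closeness(v) = (r_v / sum of distances) * (r_v / (K - 1)) where r_v is
    the number of nodes reachable from/to v; unreachable nodes give 0.
    ``weights_as='affinity'`` uses cost = 1/weight instead.
    """
    P = _as_matrix(Pc)
    K = P.shape[0]
    if K < 2:
        raise ValueError("closeness needs at least 2 nodes")
    if weights_as == "cost":
        cost = np.where(P > 0, P, np.inf)
    elif weights_as == "affinity":
        with np.errstate(divide="ignore"):
            cost = np.where(P > 0, 1.0 / np.where(P > 0, P, 1.0), np.inf)
    else:
        raise ValueError("weights_as must be 'cost' or 'affinity'")
    np.fill_diagonal(cost, 0.0)
    D = dijkstra(cost, directed=True)  # D[i, j] = dist from i to j
    if mode == "in":
        D = D.T  # D[v, u] = dist from u to v
    elif mode != "out":
        raise ValueError(f"mode must be 'in' or 'out', got {mode!r}")
    out = np.zeros(K)
    for v in range(K):
        d = np.delete(D[v], v)
        finite = np.isfinite(d)
        r = int(finite.sum())
        if r == 0:
            continue
        total = float(d[finite].sum())
        if total <= 0:
            continue
        out[v] = (r / total) * (r / (K - 1))
    return out


def node_pagerank(
    Pc, damping: float = 0.85, tol: float = 1e-12, max_iter: int = 10000
) -> np.ndarray:
    """Weighted pagerank by power iteration; entries sum to 1.

    Transition probabilities are proportional to out-edge weights; dangling
    nodes redistribute uniformly; teleport is uniform with probability
    1 - damping.
    """
    P = _as_matrix(Pc)
    K = P.shape[0]
    if not 0 < damping < 1:
        raise ValueError("damping must lie in (0, 1)")
    out = P.sum(axis=1)
    T = np.divide(P, out[:, None], out=np.zeros_like(P), where=out[:, None] > 0)
    dangling = out <= 0
    x = np.full(K, 1.0 / K)
    for _ in range(max_iter):
        new = damping * (x @ T + x[dangling].sum() / K) + (1 - damping) / K
        if np.abs(new - x).sum() < tol:
            return new / new.sum()
        x = new
    raise RuntimeError(f"pagerank did not converge within {max_iter} iterations")


def compute_centralities(
    Pc,
    damping: float = 0.85,
    weights_as: str = "cost",
) -> pd.DataFrame:
    """All signaling-network centralities per state, as a DataFrame."""
    P = _as_matrix(Pc)
    return pd.DataFrame(
        {
            "in_strength": node_strength(P, "in"),
            "out_strength": node_strength(P, "out"),
            "in_closeness": node_closeness(P, "in", weights_as),
            "out_closeness": node_closeness(P, "out", weights_as),
            "pagerank": node_pagerank(P, damping=damping),
        },
        index=pd.RangeIndex(P.shape[0], name="state"),
    )
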