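"""Transition cells, cluster graph, trajectory, pseudotime and marker genes.

Transition cells (TCs) are the cells with the highest Cell Plasticity Index;
each is attributed to the unordered pair of clusters carrying its two largest
memberships. The fraction of TCs between each cluster pair (relative to all
cells) forms a weighted cluster graph; the clusters with the least TC
involvement are the terminal (E/M) candidates, and the transition trajectory
is the maximum-weight Hamiltonian path through the cluster graph starting at
the chosen terminal state. Pseudotime is the membership-weighted position of
each cell along that path, scaled to [0, 1].

Marker genes are scored by nonnegative least squares: each gene's expression
is decomposed over the soft membership columns, and the per-cluster share of
its NNLS coefficients measures how uniquely the gene marks that cluster.
Transition genes between two adjacent clusters are ranked by the magnitude
of the Spearman correlation between expression and pseudotime over the cells
attributed to that pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import spearmanr

from .cluster import compute_cpi

__all__ = [
    "TransitionCellSet",
    "MarkerTable",
    "identify_transition_cells",
    "cluster_transition_weights",
    "select_terminal_states",
    "infer_trajectory",
    "compute_pseudotime",
    "infer_marker_genes",
    "infer_transition_genes",
]

DEFAULT_TC_TOP_FRACTION = 0.2
MAX_EXHAUSTIVE_K = 10


@dataclass
class TransitionCellSet:
    """Indices of transition cells with their attributed cluster pairs."""

    indices: list[int]
    pairs: list[tuple[int, int]]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for a, b in self.pairs:
            if a == b:
                raise ValueError("a transition-cell pair must name two clusters")

    def __len__(self) -> int:
        return len(self.indices)


def _top2_pair(row: np.ndarray) -> tuple[int, int]:
    order = np.argsort(-row, kind="stable")  # ties -> smaller cluster index
    a, b = int(order[0]), int(order[1])
    return (a, b) if a < b else (b, a)


def identify_transition_cells(
    H: np.ndarray,
    cpi_threshold: float | None = None,
    top_fraction: float | None = None,
) -> TransitionCellSet:
    """Select TCs either by a CPI cutoff or as the top CPI fraction of cells.

    Exactly one of ``cpi_threshold`` / ``top_fraction`` must be given. In
    fraction mode the ceil(top_fraction * n) highest-CPI cells are taken,
    ties resolved by cell index.
    """
    if (cpi_threshold is None) == (top_fraction is None):
        raise ValueError("supply exactly one of cpi_threshold / top_fraction")
    H = np.asarray(H, dtype=float)
    n = H.shape[0]
    cpi = compute_cpi(H)
    if cpi_threshold is not None:
        idx = np.flatnonzero(cpi > cpi_threshold)
        params = {"cpi_threshold": cpi_threshold}
    else:
        if not 0 <= top_fraction <= 1:
            raise ValueError("top_fraction must lie in [0, 1]")
        m = int(np.ceil(top_fraction * n))
        order = np.argsort(-cpi, kind="stable")
        idx = np.sort(order[:m])
        params = {"top_fraction": top_fraction}
    return TransitionCellSet(
        indices=[int(i) for i in idx],
        pairs=[_top2_pair(H[i]) for i in idx],
        params=params,
    )


def cluster_transition_weights(
    tcs: TransitionCellSet, n_total: int, K: int
) -> np.ndarray:
    """Symmetric K x K matrix of TC fractions relative to all cells."""
    if n_total < len(tcs):
        raise ValueError("n_total smaller than the number of transition cells")
    W = np.zeros((K, K))
    for a, b in tcs.pairs:
        W[a, b] += 1.0
        W[b, a] += 1.0
    return W / n_total


def select_terminal_states(W: np.ndarray) -> list[int]:
    """Rank clusters by total TC involvement, least-involved first.

    The two lowest-ranked clusters are the terminal (E/M) candidates; which
    one is epithelial is decided by the caller from marker expression.
    """
    W = np.asarray(W, dtype=float)
    involvement = W.sum(axis=1)
    return [int(k) for k in np.argsort(involvement, kind="stable")]


def infer_trajectory(W: np.ndarray, start: int) -> list[int]:
    """Maximum-weight Hamiltonian path through the cluster graph from ``start``.

    Exhaustive over all (K-1)! orderings (K <= 10 enforced); ties resolved in
    favor of the lexicographically smallest path.
    """
    W = np.asarray(W, dtype=float)
    K = W.shape[0]
    if not 0 <= start < K:
        raise ValueError(f"start cluster {start} out of range")
    if K > MAX_EXHAUSTIVE_K:
        raise ValueError(f"exhaustive trajectory search supports K <= {MAX_EXHAUSTIVE_K}")
    rest = [k for k in range(K) if k != start]
    best_path, best_score = None, -np.inf
    for perm in permutations(rest):  # lexicographic order -> first max wins ties
        path = (start, *perm)
        score = sum(W[path[i], path[i + 1]] for i in range(K - 1))
        if score > best_score + 1e-15:
            best_path, best_score = path, score
    return [int(c) for c in best_path]


def compute_pseudotime(H: np.ndarray, path: list[int]) -> np.ndarray:
    """Membership-weighted trajectory position of each cell, in [0, 1]."""
    H = np.asarray(H, dtype=float)
    K = H.shape[1]
    if sorted(path) != list(range(K)):
        raise ValueError("path must be a permutation of all clusters")
    pos = np.empty(K)
    for i, c in enumerate(path):
        pos[c] = i
    return (H @ pos) / max(K - 1, 1)


@dataclass
class MarkerTable:
    """Per-gene, per-cluster marker scores and ranked top markers."""

    scores: pd.DataFrame  # genes x clusters, rows sum to 1 (or 0)
    top_markers: dict[int, list[str]]


def infer_marker_genes(X, H: np.ndarray, top_m: int = 5) -> MarkerTable:
    """Score how uniquely each gene marks each cluster via NNLS decomposition.

    Solves x_g ~ H @ c_g with c_g >= 0 per gene; the marker score of gene g
    for cluster k is c_g[k] / sum(c_g). ``X`` may be an ExpressionMatrix or a
    cells x genes DataFrame.
    """
    df = X.to_frame() if hasattr(X, "to_frame") and not isinstance(X, pd.DataFrame) else (
        X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
    )
    H = np.asarray(H, dtype=float)
    if df.shape[0] != H.shape[0]:
        raise ValueError("expression and membership matrices disagree on cell count")
    K = H.shape[1]
    coefs = np.zeros((df.shape[1], K))
    values = df.to_numpy(dtype=float)
    for j in range(df.shape[1]):
        coefs[j], _ = nnls(H, values[:, j])
    totals = coefs.sum(axis=1, keepdims=True)
    scores = np.divide(coefs, totals, out=np.zeros_like(coefs), where=totals > 0)
    table = pd.DataFrame(scores, index=df.columns, columns=range(K))
    top = {
        k: list(
            table[k].sort_index().sort_values(ascending=False, kind="stable").index[:top_m]
        )
        for k in range(K)
    }
    return MarkerTable(scores=table, top_markers=top)


def infer_transition_genes(
    X,
    H: np.ndarray,
    pseudotime: np.ndarray,
    pair: tuple[int, int],
    top_m: int | None = None,
) -> pd.DataFrame:
    """Rank genes by |Spearman rho| with pseudotime across one transition.

    Restricts to cells whose two largest memberships are exactly ``pair``
    (which includes that pair's transition cells). Genes with undefined
    correlation (constant expression) score 0 and rank last. Returns a
    DataFrame with columns ``rho`` and ``abs_rho`` sorted by descending
    ``abs_rho``, ties by gene id.
    """
    df = X.to_frame() if hasattr(X, "to_frame") and not isinstance(X, pd.DataFrame) else (
        X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
    )
    H = np.asarray(H, dtype=float)
    pair = tuple(sorted(int(p) for p in pair))
    mask = np.array([_top2_pair(H[i]) == pair for i in range(H.shape[0])])
    if mask.sum() < 3:
        raise ValueError(
            f"only {int(mask.sum())} cells attributed to pair {pair}; need >= 3"
        )
    sub = df.iloc[np.flatnonzero(mask)]
    pt = np.asarray(pseudotime, dtype=float)[mask]
    rhos = []
    for g in sub.columns:
        x = sub[g].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(pt) == 0:
            rhos.append(0.0)
            continue
        rho = spearmanr(x, pt).statistic
        rhos.append(0.0 if np.isnan(rho) else float(rho))
    out = pd.DataFrame({"rho": rhos}, index=sub.columns)
    out["abs_rho"] = out["rho"].abs()
    out = out.sort_index().sort_values("abs_rho", ascending=False, kind="stable")
    return out if top_m is None else out.head(top_m)
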