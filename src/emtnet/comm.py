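"""Ligand-receptor cell-cell signaling probabilities.

For a ligand-receptor pair, the probability that cell i signals to cell j
combines three saturating factors computed from (log1p) expression:

    alpha_ij = exp(-1 / (l_i * r_j))      ligand in sender, receptor in receiver
    beta_j   = exp(-1 / ubar_j)           mean up-target activity in receiver
    gamma_j  = exp(-dbar_j)               mean down-target activity (suppression)

with alpha = 0 when l_i * r_j = 0, beta = 0 when up-targets are listed but
silent, and beta (gamma) = 1 when no up- (down-) targets are given. Each
sender row is normalized over receivers, so P[i, :] sums to 1 (or is all
zero when cell i expresses no ligand). Multiple pairs of a pathway are
averaged into a consensus matrix. Cluster-level signaling from cluster u to
cluster v is the mean of P[i, j] over all (i in u, j in v) cell pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import ExpressionMatrix, PathwaySpec

__all__ = [
    "ClusterSignaling",
    "lr_signaling_probability",
    "consensus_signaling",
    "cluster_signaling",
    "LigandReceptorSignaling",
]


def _to_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    if isinstance(X, ExpressionMatrix):
        return X.to_frame()
    raise TypeError("expected an ExpressionMatrix or a cells x genes DataFrame")


def _gene(df: pd.DataFrame, gene: str) -> np.ndarray:
    if gene not in df.columns:
        raise KeyError(f"gene {gene!r} not present in expression matrix")
    return df[gene].to_numpy(dtype=float)


def lr_signaling_probability(
    X,
    pair: dict,
    targets_up: list[str] | None = None,
    targets_down: list[str] | None = None,
) -> np.ndarray:
    """Cell-to-cell signaling probability matrix for one ligand-receptor pair.

    Rows (senders) sum to 1, or are all zero when the sender expresses no
    ligand or no receiver passes the target-activity filters.
    """
    df = _to_frame(X)
    lig = _gene(df, pair["ligand"])
    rec = _gene(df, pair["receptor"])
    lr = np.outer(lig, rec)
    with np.errstate(divide="ignore"):
        alpha = np.where(lr > 0, np.exp(-1.0 / np.maximum(lr, 1e-300)), 0.0)

    n = df.shape[0]
    beta = np.ones(n)
    if targets_up:
        ubar = np.mean([_gene(df, t) for t in targets_up], axis=0)
        beta = np.where(ubar > 0, np.exp(-1.0 / np.maximum(ubar, 1e-300)), 0.0)
    gamma = np.ones(n)
    if targets_down:
        dbar = np.mean([_gene(df, t) for t in targets_down], axis=0)
        gamma = np.exp(-dbar)

    P = alpha * (beta * gamma)[None, :]
    rowsum = P.sum(axis=1, keepdims=True)
    return np.divide(P, rowsum, out=np.zeros_like(P), where=rowsum > 0)


def consensus_signaling(matrices: list[np.ndarray]) -> np.ndarray:
    """Elementwise mean over per-pair signaling matrices (order-invariant)."""
    if not matrices:
        raise ValueError("need at least one signaling matrix")
    shapes = {m.shape for m in matrices}
    if len(shapes) != 1:
        raise ValueError(f"signaling matrices have mismatched shapes: {shapes}")
    return np.mean(matrices, axis=0)


@dataclass
class ClusterSignaling:
    """Directed K x K cluster-level signaling probabilities.

    ``support_counts[u, v]`` is the number of (sender, receiver) cell pairs
    with strictly positive probability, reported alongside the mean.
    """

    probabilities: np.ndarray
    support_counts: np.ndarray

    @property
    def n_clusters(self) -> int:
        return self.probabilities.shape[0]


def cluster_signaling(P: np.ndarray, labels: np.ndarray, K: int) -> ClusterSignaling:
    """Average cell-cell probabilities into cluster-cluster signaling.

    Pc[u, v] = sum_{i in C_u, j in C_v} P[i, j] / (|C_u| |C_v|); entries with
    an empty sender or receiver cluster are 0.
    """
    P = np.asarray(P, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if labels.min(initial=0) < 0 or labels.max(initial=0) >= K:
        raise ValueError("cluster labels out of range")
    n = P.shape[0]
    Z = np.zeros((n, K))
    Z[np.arange(n), labels] = 1.0
    sizes = Z.sum(axis=0)
    totals = Z.T @ P @ Z
    denom = np.outer(sizes, sizes)
    Pc = np.divide(totals, denom, out=np.zeros_like(totals), where=denom > 0)
    support = (Z.T @ (P > 0) @ Z).astype(int)
    return ClusterSignaling(probabilities=Pc, support_counts=support)


class LigandReceptorSignaling(BaseEstimator):
    """Pathway-level signaling inference in sklearn style.

    ``fit`` computes per-pair and consensus cell-cell probability matrices
    from a cells x genes expression table (log1p values recommended);
    ``cluster_matrix`` aggregates the consensus to cluster level.

    Attributes
    ----------
    pair_probabilities_ : dict mapping "ligand->receptor" to (n, n) arrays.
    cell_probabilities_ : (n, n) consensus matrix.
    """

    def __init__(self, pathway: PathwaySpec):
        self.pathway = pathway

    def fit(self, X, y=None):
        df = _to_frame(X)
        self.n_features_in_ = df.shape[1]
        self.pair_probabilities_ = {
            f"{p['ligand']}->{p['receptor']}": lr_signaling_probability(
                df, p, self.pathway.targets_up, self.pathway.targets_down
            )
            for p in self.pathway.pairs
        }
        self.cell_probabilities_ = consensus_signaling(
            list(self.pair_probabilities_.values())
        )
        return self

    def cluster_matrix(self, labels: np.ndarray, K: int) -> ClusterSignaling:
        return cluster_signaling(self.cell_probabilities_, labels, K)
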