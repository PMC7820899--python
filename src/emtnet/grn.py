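"""Gene-regulatory-network inference by partial information decomposition.

For every gene pair (X, Y) and every third gene Z, the mutual information
I(X;Y) is decomposed with the Williams-Beer redundancy measure

    I_min(Y; {X, Z}) = sum_y p(y) * min_A I_spec(Y=y; A),  A in {X, Z},

where the specific information I_spec(Y=y; A) = D_KL(p(a|y) || p(a)) is the
information source A carries about the particular outcome y. The unique
information of X about Y with respect to Z is U_Z(X->Y) = I(X;Y) - I_min.
The proportional unique contribution (PUC) of a pair accumulates both
directions over all third genes, normalized by the pair's mutual
information:

    U[X,Y] = sum_{Z not in {X,Y}} (U_Z(X->Y) + U_Z(Y->X)) / I(X;Y).

Edge confidence rescales PUC against each gene's own score distribution:
c = F_X(U[X,Y]) + F_Y(U[X,Y]) with F_X the empirical CDF of all PUC scores
involving X, so an edge is confident when it is extreme for *both* genes.
Per-cell-state networks keep the top fraction of edges by confidence and
rescale weights to a fixed maximum, making networks comparable across
states and datasets.

Expression is discretized gene-by-gene into uniform-width bins (Sturges
count by default); information is measured in bits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "DiscreteMatrix",
    "StateGRN",
    "discretize_matrix",
    "mutual_information",
    "redundancy_imin",
    "unique_information",
    "puc_matrix",
    "confidence_network",
    "state_grn",
    "PIDCNetwork",
]

DEFAULT_KEEP_FRACTION = 0.30
DEFAULT_MAX_WEIGHT = 2.0


@dataclass
class DiscreteMatrix:
    """Per-gene integer codes with bin counts and edges."""

    codes: np.ndarray  # cells x genes, int
    n_bins: list[int]
    bin_edges: list[np.ndarray]


def _sturges(n: int) -> int:
    return max(2, int(np.ceil(np.log2(n) + 1)))


def discretize_matrix(X, n_bins: int | None = None) -> DiscreteMatrix:
    """Uniform-width discretization per gene; constant genes get one bin.

    ``n_bins=None`` uses the Sturges count max(2, ceil(log2 n + 1)). The top
    bin is right-closed so the maximum maps into the last bin.
    """
    values = np.asarray(getattr(X, "values", X), dtype=float)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 cells")
    n, g = values.shape
    b_default = _sturges(n) if n_bins is None else int(n_bins)
    codes = np.zeros((n, g), dtype=np.int64)
    counts, edges_list = [], []
    for j in range(g):
        x = values[:, j]
        lo, hi = float(x.min()), float(x.max())
        if hi == lo:
            counts.append(1)
            edges_list.append(np.array([lo, hi]))
            continue
        b = b_default
        codes[:, j] = np.minimum(((x - lo) / (hi - lo) * b).astype(np.int64), b - 1)
        counts.append(b)
        edges_list.append(np.linspace(lo, hi, b + 1))
    return DiscreteMatrix(codes=codes, n_bins=counts, bin_edges=edges_list)


def _joint(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Joint probability table of two discrete vectors (plug-in MLE)."""
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("vectors must share a length >= 2")
    bx, by = x.max() + 1, y.max() + 1
    table = np.bincount(x * by + y, minlength=bx * by).reshape(bx, by)
    return table / x.size


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information I(X;Y) in bits; symmetric, >= 0."""
    pxy = _joint(x, y)
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    mask = pxy > 0
    ratio = pxy[mask] / (px @ py)[mask]
    return float(np.sum(pxy[mask] * np.log2(ratio)))


def _specific_information(y: np.ndarray, a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """I_spec(Y=y; A) for each outcome y, with the marginal p(y).

    I_spec(Y=y; A) = D_KL(p(a|y) || p(a)) >= 0; its p(y)-weighted mean is
    I(A;Y).
    """
    pay = _joint(a, y)  # rows a, cols y
    pa = pay.sum(axis=1, keepdims=True)
    py = pay.sum(axis=0)
    spec = np.zeros(pay.shape[1])
    for yi in range(pay.shape[1]):
        if py[yi] == 0:
            continue
        cond = pay[:, yi] / py[yi]  # p(a|y)
        m = cond > 0
        spec[yi] = float(np.sum(cond[m] * np.log2(cond[m] / pa[m, 0])))
    return spec, py


def redundancy_imin(y: np.ndarray, x: np.ndarray, z: np.ndarray) -> float:
    """Williams-Beer redundancy of sources X, Z about target Y (bits)."""
    sx, py = _specific_information(y, x)
    sz, _ = _specific_information(y, z)
    return float(np.sum(py * np.minimum(sx, sz)))


def unique_information(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> float:
    """Unique information of X about Y beyond Z: I(X;Y) - I_min(Y;{X,Z})."""
    return max(mutual_information(x, y) - redundancy_imin(y, x, z), 0.0)


def puc_matrix(D: DiscreteMatrix) -> np.ndarray:
    """Symmetric proportional-unique-contribution matrix over all gene pairs.

    Accumulates, for each pair (X, Y), the unique information in both
    directions over every third gene Z, normalized by I(X;Y); pairs with
    I(X;Y) = 0 score 0.
    """
    codes = D.codes
    g = codes.shape[1]
    if g < 3:
        raise ValueError("PUC needs at least 3 genes")
    mi = np.zeros((g, g))
    for a in range(g):
        for b in range(a + 1, g):
            mi[a, b] = mi[b, a] = mutual_information(codes[:, a], codes[:, b])

    # directional unique sums: S[x, y] = sum_{z not in {x,y}} U_z(x -> y)
    S = np.zeros((g, g))
    for y_idx in range(g):
        b_y = D.n_bins[y_idx]
        spec = np.zeros((g, b_y))
        py = None
        for a in range(g):
            if a == y_idx:
                continue  # row stays 0: never a source for its own target
            spec[a], py = _specific_information(codes[:, y_idx], codes[:, a])
        # imin_all[x, z] = I_min(Y; {X, Z})
        imin_all = np.einsum(
            "xzb,b->xz", np.minimum(spec[:, None, :], spec[None, :, :]), py
        )
        for x_idx in range(g):
            if x_idx == y_idx:
                continue
            # exclude z = x (equals I(X;Y)) and z = y (stored as 0)
            total = imin_all[x_idx].sum() - imin_all[x_idx, x_idx]
            S[x_idx, y_idx] = max((g - 2) * mi[x_idx, y_idx] - total, 0.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        U = np.where(mi > 0, (S + S.T) / np.where(mi > 0, mi, 1.0), 0.0)
    np.fill_diagonal(U, 0.0)
    return U


def confidence_network(U: np.ndarray) -> np.ndarray:
    """Edge confidence c = F_X(U[X,Y]) + F_Y(U[X,Y]) from per-gene ECDFs.

    F_X is the right-continuous empirical CDF of the PUC scores involving
    gene X; confidences lie in (0, 2].
    """
    U = np.asarray(U, dtype=float)
    g = U.shape[0]
    if g < 3:
        raise ValueError("confidence network needs at least 3 genes")
    off = ~np.eye(g, dtype=bool)
    F = np.zeros((g, g))  # F[x, y] = F_x(U[x, y])
    for x in range(g):
        row = U[x, off[x]]
        F[x] = (row[None, :] <= U[x][:, None]).mean(axis=1)
    C = F + F.T
    np.fill_diagonal(C, 0.0)
    return C


@dataclass
class StateGRN:
    """Pruned, rescaled gene network for one cell state."""

    state: int
    gene_ids: list[str]
    edges: list[tuple[str, str, float]]  # (gene_x, gene_y, weight), desc weight
    keep_fraction: float
    max_weight_norm: float


def _prune_and_rescale(
    C: np.ndarray,
    gene_ids: list[str],
    keep_fraction: float,
    max_weight_norm: float,
) -> list[tuple[str, str, float]]:
    g = len(gene_ids)
    pairs = [
        (C[a, b], tuple(sorted((gene_ids[a], gene_ids[b]))))
        for a in range(g)
        for b in range(a + 1, g)
    ]
    pairs.sort(key=lambda t: (-t[0], t[1]))
    n_keep = int(np.ceil(keep_fraction * g * (g - 1) / 2))
    kept = pairs[:n_keep]
    if not kept:
        return []
    top = kept[0][0]
    scale = max_weight_norm / top if top > 0 else 0.0
    return [(gx, gy, w * scale) for w, (gx, gy) in kept]


def state_grn(
    X,
    labels: np.ndarray,
    state: int,
    genes: list[str],
    keep_fraction: float = DEFAULT_KEEP_FRACTION,
    max_weight_norm: float = DEFAULT_MAX_WEIGHT,
    n_bins: int | None = None,
) -> StateGRN:
    """Infer the pruned confidence network among ``genes`` within one state.

    Subsets the cells of ``state``, discretizes, computes PUC and edge
    confidences, keeps the top ``keep_fraction`` of edges (ties by gene-id
    pair) and linearly rescales so the strongest kept edge has weight
    ``max_weight_norm``.
    """
    df = X.to_frame() if hasattr(X, "to_frame") and not isinstance(X, pd.DataFrame) else (
        X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
    )
    labels = np.asarray(labels, dtype=int)
    missing = [g for g in genes if g not in df.columns]
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing[:5]}")
    if len(genes) < 3:
        raise ValueError(f"state {state}: need >= 3 genes, got {len(genes)}")
    mask = labels == state
    if mask.sum() < 5:
        raise ValueError(
            f"state {state}: only {int(mask.sum())} cells; need >= 5 for inference"
        )
    sub = df.loc[np.asarray(df.index)[mask], list(genes)]
    D = discretize_matrix(sub.to_numpy(dtype=float), n_bins=n_bins)
    C = confidence_network(puc_matrix(D))
    edges = _prune_and_rescale(C, list(genes), keep_fraction, max_weight_norm)
    return StateGRN(
        state=int(state),
        gene_ids=list(genes),
        edges=edges,
        keep_fraction=keep_fraction,
        max_weight_norm=max_weight_norm,
    )


class PIDCNetwork(BaseEstimator):
    """Partial-information-decomposition network inference, sklearn style.

    ``fit`` takes a cells x genes table, discretizes it, and computes the
    PUC matrix and edge-confidence matrix.

    Attributes
    ----------
    gene_ids_ : list of str
    puc_ : ndarray (g, g), symmetric proportional unique contributions.
    confidence_ : ndarray (g, g), symmetric edge confidences in (0, 2].
    """

    def __init__(self, n_bins: int | None = None):
        self.n_bins = n_bins

    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            self.gene_ids_ = [str(c) for c in X.columns]
            values = X.to_numpy(dtype=float)
        else:
            values = np.asarray(getattr(X, "values", X), dtype=float)
            self.gene_ids_ = [f"g{j}" for j in range(values.shape[1])]
        self.n_features_in_ = values.shape[1]
        self.discrete_ = discretize_matrix(values, n_bins=self.n_bins)
        self.puc_ = puc_matrix(self.discrete_)
        self.confidence_ = confidence_network(self.puc_)
        return self

    def edge_table(self) -> pd.DataFrame:
        """All gene pairs with PUC and confidence, sorted by confidence."""
        check_is_fitted(self)
        g = len(self.gene_ids_)
        rows = [
            (self.gene_ids_[a], self.gene_ids_[b], self.puc_[a, b], self.confidence_[a, b])
            for a in range(g)
            for b in range(a + 1, g)
        ]
        df = pd.DataFrame(rows, columns=["gene_x", "gene_y", "puc", "confidence"])
        return df.sort_values(
            ["confidence", "gene_x", "gene_y"], ascending=[False, True, True], kind="stable"
        ).reset_index(drop=True)
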