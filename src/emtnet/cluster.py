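"""Consensus similarity, eigen-gap model selection and symmetric-NMF soft
clustering.

The cell-cell similarity is a co-clustering frequency: cells are projected
onto the top-d principal components and k-means is run over a grid of
(k, d, seed) settings; S[i, j] is the fraction of runs in which cells i and j
land in the same cluster. The number of clusters is chosen by the largest
eigenvalue gap of the symmetric normalized graph Laplacian of S, searching
from K = 3 upward (an E state, an M state and at least one intermediate
state). Soft memberships come from symmetric nonnegative matrix
factorization, min ||S - H H^T||_F^2 over H >= 0, via the damped
multiplicative update

    H <- H * (1/2 + 1/2 * (S H) / (H H^T H)),

after which rows are normalized onto the probability simplex. The Cell
Plasticity Index (CPI) is the entropy of a cell's membership row normalized
by log K; cells with CPI near 1 sit between clusters.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
from scipy.linalg import eigh
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.utils.validation import validate_data

__all__ = [
    "consensus_similarity",
    "estimate_num_clusters",
    "sym_nmf",
    "soft_cluster",
    "compute_cpi",
    "ConsensusSoftCluster",
]

DEFAULT_K_VALUES = (3, 4, 5, 6, 7, 8)
DEFAULT_D_VALUES = (4, 6, 8, 10)


def _as_values(X) -> np.ndarray:
    values = getattr(X, "values", X)
    return np.asarray(values, dtype=float)


def consensus_similarity(
    X,
    k_values: Sequence[int] = DEFAULT_K_VALUES,
    d_values: Sequence[int] = DEFAULT_D_VALUES,
    n_seeds: int = 10,
    seed: int = 0,
    subsample_fraction: float = 0.8,
) -> np.ndarray:
    """Co-clustering similarity over a resampled (k, d, seed) k-means grid.

    Each run clusters a random ``subsample_fraction`` of the cells (the
    resampling of consensus clustering: without it k-means settles into the
    same partition every run and the similarity degenerates to 0/1);
    S[i, j] is the fraction of runs containing both cells in which they
    share a cluster. Returns a symmetric n x n matrix with unit diagonal
    and entries in [0, 1]. Deterministic given ``seed``.
    """
    values = _as_values(X)
    n, p = values.shape
    k_values = sorted(set(int(k) for k in k_values))
    if k_values[0] < 2:
        raise ValueError("k_values must all be >= 2")
    if k_values[-1] > n:
        raise ValueError(f"k={k_values[-1]} exceeds the number of cells ({n})")
    if not 0 < subsample_fraction <= 1:
        raise ValueError("subsample_fraction must lie in (0, 1]")
    d_values = sorted(set(min(int(d), n, p) for d in d_values))

    d_max = max(d_values)
    scores = PCA(n_components=d_max, random_state=seed).fit_transform(values)

    rng = np.random.default_rng(seed)
    n_sub = max(int(subsample_fraction * n), max(k_values))
    co = np.zeros((n, n))
    both = np.zeros((n, n))
    for d in d_values:
        Z = scores[:, :d]
        for k in k_values:
            for _ in range(n_seeds):
                if n_sub < n:
                    idx = rng.choice(n, size=n_sub, replace=False)
                else:
                    idx = np.arange(n)
                rs = int(rng.integers(0, 2**31 - 1))
                labels = KMeans(n_clusters=k, n_init=1, random_state=rs).fit_predict(Z[idx])
                full = np.full(n, -1, dtype=int)
                full[idx] = labels
                sampled = full >= 0
                pair_sampled = np.outer(sampled, sampled)
                both += pair_sampled
                co += (full[:, None] == full[None, :]) & pair_sampled
    S = np.divide(co, both, out=np.zeros_like(co), where=both > 0)
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    return S


def estimate_num_clusters(S: np.ndarray, k_min: int = 3, k_max: int = 8) -> int:
    """Choose K by the largest gap in the sorted Laplacian eigenvalues.

    Uses L_sym = I - D^{-1/2} S D^{-1/2}; with eigenvalues in ascending order
    lambda_1 <= lambda_2 <= ..., returns the k in [k_min, k_max] maximizing
    lambda_{k+1} - lambda_k (ties -> smallest k). The search starts at 3
    because the transition model assumes at least an E state, an M state and
    one intermediate state.
    """
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    if not 3 <= k_min <= k_max:
        raise ValueError("need 3 <= k_min <= k_max")
    k_max = min(k_max, n - 1)
    d = S.sum(axis=1)
    if np.any(d <= 0):
        raise ValueError("degenerate similarity: zero row sum")
    inv_sqrt = 1.0 / np.sqrt(d)
    L = np.eye(n) - inv_sqrt[:, None] * S * inv_sqrt[None, :]
    lam = np.sort(eigh(L, eigvals_only=True))
    gaps = lam[k_min : k_max + 1] - lam[k_min - 1 : k_max]  # gap after lambda_k
    return int(k_min + np.argmax(gaps))


def sym_nmf(
    S: np.ndarray,
    K: int,
    max_iter: int = 500,
    tol: float = 1e-8,
    seed: int = 0,
    return_history: bool = False,
):
    """Symmetric NMF S ~ H H^T by damped multiplicative updates.

    Initialized from the absolute top-K eigenvectors of S plus a small seeded
    jitter. The objective ||S - H H^T||_F^2 is non-increasing across
    iterations. Returns (H, converged) or (H, converged, objectives).
    """
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    if K < 2:
        raise ValueError("K must be >= 2")
    rng = np.random.default_rng(seed)
    lam, V = eigh(S)
    top = np.argsort(lam)[::-1][:K]
    # scale columns by sqrt(eigenvalue) so H H^T starts on the scale of S
    H = np.abs(V[:, top] * np.sqrt(np.maximum(lam[top], 0.0))) + 0.01 * rng.random((n, K))

    def objective(H):
        R = S - H @ H.T
        return float(np.sum(R * R))

    obj = objective(H)
    history = [obj]
    converged = False
    for _ in range(max_iter):
        numer = S @ H
        denom = np.maximum(H @ (H.T @ H), 1e-12)
        H = H * (0.5 + 0.5 * numer / denom)
        new_obj = objective(H)
        history.append(new_obj)
        if 0 <= obj - new_obj < tol * max(obj, 1e-300):
            converged = True
            break
        obj = new_obj
    if not converged:
        warnings.warn(
            f"symmetric NMF did not converge in {max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    if return_history:
        return H, converged, history
    return H, converged


def soft_cluster(
    S: np.ndarray, K: int, max_iter: int = 500, tol: float = 1e-8, seed: int = 0
) -> np.ndarray:
    """Soft cell-to-cluster memberships: symmetric NMF rows on the simplex."""
    H, _ = sym_nmf(S, K, max_iter=max_iter, tol=tol, seed=seed)
    rows = H.sum(axis=1, keepdims=True)
    H = np.where(rows > 0, H / np.maximum(rows, 1e-300), 1.0 / K)
    return H


def compute_cpi(H: np.ndarray) -> np.ndarray:
    """Cell Plasticity Index: membership-row entropy normalized by log K.

    1 for a uniform row (maximal plasticity), 0 for a one-hot row.
    """
    H = np.asarray(H, dtype=float)
    K = H.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(H > 0, H * np.log(H), 0.0)
    return -terms.sum(axis=1) / np.log(K)


class ConsensusSoftCluster(ClusterMixin, BaseEstimator):
    """Soft clustering of cells by consensus similarity + symmetric NMF.

    Parameters
    ----------
    n_clusters : int or None
        Number of clusters; None selects it by the Laplacian eigen-gap
        searched over [k_min, k_max].
    k_values, d_values, n_seeds
        Grid of the consensus k-means runs (cluster counts, PCA dimensions,
        seeds per setting).
    nmf_max_iter, nmf_tol
        Stopping rule of the symmetric NMF.
    random_state : int
        Seed for the consensus runs and NMF jitter.

    Attributes
    ----------
    similarity_ : ndarray (n, n)
        Consensus co-clustering similarity.
    n_clusters_ : int
        Number of clusters used.
    memberships_ : ndarray (n, n_clusters_)
        Soft assignment, rows on the simplex.
    labels_ : ndarray (n,)
        Argmax cluster per cell (ties -> smallest index).
    cpi_ : ndarray (n,)
        Cell Plasticity Index per cell.
    """

    def __init__(
        self,
        n_clusters: int | None = None,
        k_values: Iterable[int] = DEFAULT_K_VALUES,
        d_values: Iterable[int] = DEFAULT_D_VALUES,
        n_seeds: int = 10,
        subsample_fraction: float = 0.8,
        k_min: int = 3,
        k_max: int = 8,
        nmf_max_iter: int = 500,
        nmf_tol: float = 1e-8,
        random_state: int = 0,
    ):
        self.n_clusters = n_clusters
        self.k_values = k_values
        self.d_values = d_values
        self.n_seeds = n_seeds
        self.subsample_fraction = subsample_fraction
        self.k_min = k_min
        self.k_max = k_max
        self.nmf_max_iter = nmf_max_iter
        self.nmf_tol = nmf_tol
        self.random_state = random_state

    def fit(self, X, y=None):
        X = validate_data(self, X, ensure_min_samples=4)
        self.similarity_ = consensus_similarity(
            X,
            k_values=tuple(self.k_values),
            d_values=tuple(self.d_values),
            n_seeds=self.n_seeds,
            seed=self.random_state,
            subsample_fraction=self.subsample_fraction,
        )
        if self.n_clusters is None:
            self.n_clusters_ = estimate_num_clusters(
                self.similarity_, k_min=self.k_min, k_max=self.k_max
            )
        else:
            self.n_clusters_ = int(self.n_clusters)
        self.memberships_ = soft_cluster(
            self.similarity_,
            self.n_clusters_,
            max_iter=self.nmf_max_iter,
            tol=self.nmf_tol,
            seed=self.random_state,
        )
        self.labels_ = np.argmax(self.memberships_, axis=1)
        self.cpi_ = compute_cpi(self.memberships_)
        return self
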