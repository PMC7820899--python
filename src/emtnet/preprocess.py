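"""Cell quality filtering and bimodality-based informative-gene selection.

Low-quality cells are removed by requiring that a cell expresses at least a
given fraction (default 95%) of all *detected* genes (genes seen in at least
one cell). Informative genes are then ranked by a bimodality index computed
from a two-component equal-variance Gaussian mixture fit to the log1p values:

    BI = |mu_1 - mu_2| / sigma * sqrt(p (1 - p))

where p is the mixing weight of the first component. Genes whose expression
splits into a clear on/off pattern across cells score high; unimodal genes
score near zero. The mixture is fit by EM with a deterministic initialization
from the two extreme deciles, so scores are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .containers import ExpressionMatrix

__all__ = [
    "GeneSelection",
    "filter_cells",
    "bimodality_score",
    "select_genes",
    "BimodalGeneFilter",
]

DEFAULT_MIN_DETECTED_FRACTION = 0.95
DEFAULT_N_TOP_GENES = 3000


def filter_cells(
    X: ExpressionMatrix,
    min_detected_fraction: float = DEFAULT_MIN_DETECTED_FRACTION,
) -> ExpressionMatrix:
    """Remove cells expressing fewer than a fraction of the detected genes.

    A gene is *detected* if it is nonzero in at least one cell; a cell is kept
    if its nonzero fraction among detected genes is >= ``min_detected_fraction``.
    Cell order is preserved. Idempotent: filtering twice equals filtering once.
    """
    if not 0 <= min_detected_fraction <= 1:
        raise ValueError("min_detected_fraction must lie in [0, 1]")
    if X.n_cells == 0:
        raise ValueError("expression matrix has no cells")
    detected = (X.values > 0).any(axis=0)
    n_detected = int(detected.sum())
    if n_detected == 0:
        raise ValueError("all cells filtered: no detected genes in the matrix")
    frac = (X.values[:, detected] > 0).sum(axis=1) / n_detected
    keep = np.flatnonzero(frac >= min_detected_fraction)
    if keep.size == 0:
        raise ValueError(
            f"all cells filtered at min_detected_fraction={min_detected_fraction}"
        )
    return X.subset_cells(keep)


def _fit_two_gaussian_em(
    x: np.ndarray, max_iter: int = 200, tol: float = 1e-10
) -> tuple[float, float, float, float]:
    """Equal-variance two-component 1-D Gaussian mixture via EM.

    Initialized from the 10%/90% quantiles (deterministic). Returns
    (mu1, mu2, sigma2, p) with p the weight of component 1.
    """
    mu = np.array([np.quantile(x, 0.1), np.quantile(x, 0.9)])
    var = max(float(np.var(x)), 1e-12)
    sigma2 = var
    p = 0.5
    for _ in range(max_iter):
        # E step: responsibilities of component 1
        d1 = (x - mu[0]) ** 2
        d2 = (x - mu[1]) ** 2
        log_r1 = np.log(p + 1e-300) - d1 / (2 * sigma2)
        log_r2 = np.log(1 - p + 1e-300) - d2 / (2 * sigma2)
        m = np.maximum(log_r1, log_r2)
        r1 = np.exp(log_r1 - m)
        r1 /= r1 + np.exp(log_r2 - m)
        # M step
        w1 = r1.sum()
        w2 = len(x) - w1
        new_mu = np.array(
            [
                (r1 * x).sum() / max(w1, 1e-300),
                ((1 - r1) * x).sum() / max(w2, 1e-300),
            ]
        )
        new_sigma2 = float((r1 * (x - new_mu[0]) ** 2).sum()
                           + ((1 - r1) * (x - new_mu[1]) ** 2).sum()) / len(x)
        # Floor at the count-granularity scale: on log1p counts, within-mode
        # spread below ~half a unit count is discreteness, not biology, and
        # an unfloored sigma lets near-two-spike sparse genes score
        # arbitrarily high.
        new_sigma2 = max(new_sigma2, 0.1)
        new_p = w1 / len(x)
        shift = abs(new_mu - mu).max() + abs(new_sigma2 - sigma2) + abs(new_p - p)
        mu, sigma2, p = new_mu, new_sigma2, new_p
        if shift < tol:
            break
    return float(mu[0]), float(mu[1]), float(sigma2), float(p)


def bimodality_score(x: np.ndarray) -> float:
    """Bimodality index of one gene's expression across cells.

    Operates on log1p values. Constant genes score exactly 0; the score is
    invariant to permutation of cells.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("bimodality_score needs at least 4 cells")
    x = np.log1p(x)
    if np.ptp(x) == 0:
        return 0.0
    mu1, mu2, sigma2, p = _fit_two_gaussian_em(x)
    return abs(mu1 - mu2) / np.sqrt(sigma2) * np.sqrt(max(p * (1 - p), 0.0))


@dataclass
class GeneSelection:
    """Genes ranked by bimodality, scores non-increasing."""

    gene_ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("scores must be sorted non-increasing")


def _rank_genes(values: np.ndarray, gene_ids: list[str]) -> tuple[list[int], np.ndarray]:
    scores = np.array([bimodality_score(values[:, j]) for j in range(values.shape[1])])
    # descending score, ties by lexicographic gene id
    order = sorted(range(len(gene_ids)), key=lambda j: (-scores[j], gene_ids[j]))
    return order, scores


def select_genes(X: ExpressionMatrix, n_top: int | None = None) -> GeneSelection:
    """Rank genes by bimodality and keep the top ``n_top``.

    ``n_top=None`` keeps min(3000, n_genes). Ties are broken by gene id so the
    selection is deterministic.
    """
    if n_top is None:
        n_top = min(DEFAULT_N_TOP_GENES, X.n_genes)
    if not 1 <= n_top <= X.n_genes:
        raise ValueError(f"n_top={n_top} out of range [1, {X.n_genes}]")
    order, scores = _rank_genes(X.values, X.gene_ids)
    top = order[:n_top]
    return GeneSelection(
        gene_ids=[X.gene_ids[j] for j in top], scores=scores[top]
    )


class BimodalGeneFilter(SelectorMixin, BaseEstimator):
    """Feature selector keeping the most bimodal genes.

    sklearn-style transformer: ``fit`` scores every column with the
    bimodality index, ``transform`` keeps the top ``n_top`` columns.

    Attributes
    ----------
    scores_ : ndarray of shape (n_features,)
        Bimodality index per input column.
    """

    def __init__(self, n_top: int | None = None):
        self.n_top = n_top

    def fit(self, X, y=None):
        X = validate_data(self, X, ensure_min_samples=4)
        g = X.shape[1]
        n_top = min(DEFAULT_N_TOP_GENES, g) if self.n_top is None else self.n_top
        if not 1 <= n_top <= g:
            raise ValueError(f"n_top={n_top} out of range [1, {g}]")
        self.scores_ = np.array([bimodality_score(X[:, j]) for j in range(g)])
        order = np.argsort(-self.scores_, kind="stable")
        self._support = np.zeros(g, dtype=bool)
        self._support[order[:n_top]] = True
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self._support
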