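"""Synthetic single-cell EMT data with planted ground truth.

Emulates the structure of an induced epithelial-to-mesenchymal transition
time series: ``K`` cell states arranged on a linear trajectory, a fraction of
transition cells with mixed membership in two trajectory-adjacent states,
per-state bimodal marker genes, collection-time labels whose relation to
trajectory position is either tight (synchronous induction) or nearly flat
(asynchronous), and a planted sender -> receiver ligand-receptor signal with
activated up-targets and suppressed down-targets in the receiver state.

Counts are negative-binomial (mean/overdispersion parameterization) with
Bernoulli dropout; downstream stages consume ``log1p`` of these counts.
Every quantity a downstream stage infers (memberships, labels, trajectory,
time labels, signaling pairs) is returned as ground truth, so recovery can
be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import ExpressionMatrix, PathwaySpec

__all__ = [
    "SynthConfig",
    "SynthDataset",
    "generate_pathway_spec",
    "generate_emt_dataset",
    "expected_cluster_signaling",
]


@dataclass
class SynthConfig:
    """Parameters of the synthetic EMT generator.

    Defaults describe the emulated study design: four states (E, two
    intermediate states, M) of 50 cells each, 10% transition cells, five
    collection time points, markers with a strong on/off contrast and
    moderate count noise.
    """

    n_clusters: int = 4
    cells_per_cluster: int = 50
    tc_fraction: float = 0.1
    n_genes: int = 150
    markers_per_cluster: int = 10
    n_timepoints: int = 5
    sync_mode: str = "synchronous"
    mean_high: float = 8.0
    mean_low: float = 0.2
    dispersion: float = 0.3
    dropout_rate: float = 0.1
    seed: int = 0
    # planted (sender, receiver) cluster pairs; None -> (path start, path end)
    signaling_pairs: tuple | None = None
    # spread of time labels around trajectory position, in trajectory units
    sync_jitter: float = 0.05
    async_drift: float = 0.15

    def validate(self, pathway: PathwaySpec | None = None) -> None:
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if self.cells_per_cluster < 1:
            raise ValueError("cells_per_cluster must be >= 1")
        if not 0.0 <= self.tc_fraction <= 0.5:
            raise ValueError("tc_fraction must lie in [0, 0.5]")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.dispersion < 0:
            raise ValueError("dispersion must be nonnegative")
        if self.n_timepoints < 1:
            raise ValueError("n_timepoints must be >= 1")
        if self.sync_mode not in ("synchronous", "asynchronous"):
            raise ValueError(f"unknown sync_mode {self.sync_mode!r}")
        n_pathway = len(pathway.all_genes) if pathway is not None else 0
        if self.markers_per_cluster * self.n_clusters + n_pathway > self.n_genes:
            raise ValueError(
                "marker and pathway genes exceed n_genes: "
                f"{self.markers_per_cluster * self.n_clusters} markers + "
                f"{n_pathway} pathway genes > {self.n_genes}"
            )


@dataclass
class SynthDataset:
    """A generated dataset together with its planted ground truth."""

    expression: ExpressionMatrix
    true_membership: np.ndarray  # cells x K, rows on the simplex
    true_labels: np.ndarray  # argmax of membership
    true_path: list[int]  # planted trajectory (cluster indices in order)
    time_labels: list[int]
    pathway: PathwaySpec
    planted_signaling: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return self.true_membership.shape[1]

    @property
    def tc_mask(self) -> np.ndarray:
        """Cells with substantial membership in two clusters."""
        return (self.true_membership >= 0.25).sum(axis=1) >= 2

    @property
    def marker_genes(self) -> dict[int, list[str]]:
        prefix = {k: f"M{k}_" for k in range(self.n_clusters)}
        return {
            k: [g for g in self.expression.gene_ids if g.startswith(p)]
            for k, p in prefix.items()
        }


def generate_pathway_spec(
    n_pairs: int, n_up: int, n_down: int, seed: int = 0
) -> PathwaySpec:
    """Build a synthetic pathway: ligand-receptor pairs with shared targets.

    Gene names are self-describing (``LIG{i}``/``REC{i}`` per pair,
    ``TUP{j}``/``TDN{j}`` shared target sets), and ligands, receptors and
    targets are disjoint by construction.
    """
    if n_pairs < 1 or n_up < 1 or n_down < 1:
        raise ValueError("n_pairs, n_up and n_down must all be >= 1")
    del seed  # naming is deterministic; accepted for interface symmetry
    pairs = [{"ligand": f"LIG{i}", "receptor": f"REC{i}"} for i in range(n_pairs)]
    return PathwaySpec(
        pathway_name="SYNTH",
        pairs=pairs,
        targets_up=[f"TUP{j}" for j in range(n_up)],
        targets_down=[f"TDN{j}" for j in range(n_down)],
    )


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float
               ) -> np.ndarray:
    """Negative binomial with var = mean + dispersion * mean^2 (Poisson at 0)."""
    counts = np.zeros(mean.shape, dtype=float)
    pos = mean > 0
    if dispersion <= 0:
        counts[pos] = rng.poisson(mean[pos])
        return counts
    r = 1.0 / dispersion
    p = r / (r + mean[pos])
    counts[pos] = rng.negative_binomial(r, p)
    return counts


def generate_emt_dataset(
    config: SynthConfig, pathway: PathwaySpec | None = None
) -> SynthDataset:
    """Generate one synthetic EMT dataset; deterministic given the config seed."""
    if pathway is None:
        pathway = generate_pathway_spec(1, 3, 2, seed=config.seed)
    config.validate(pathway)
    K = config.n_clusters
    n = K * config.cells_per_cluster
    rng = np.random.default_rng(config.seed)

    path = [int(c) for c in rng.permutation(K)]
    pos_of = np.empty(K)
    for i, c in enumerate(path):
        pos_of[c] = i

    # memberships: one-hot base, a random subset become transition cells
    membership = np.zeros((n, K))
    base = np.repeat(np.arange(K), config.cells_per_cluster)
    membership[np.arange(n), base] = 1.0
    n_tc = int(round(config.tc_fraction * n))
    tc_idx = rng.choice(n, size=n_tc, replace=False) if n_tc else np.array([], int)
    for i in tc_idx:
        edge = int(rng.integers(K - 1))  # adjacent pair on the planted path
        a, b = path[edge], path[edge + 1]
        w = rng.uniform(0.25, 0.75)
        membership[i] = 0.0
        membership[i, a], membership[i, b] = w, 1.0 - w
    labels = np.argmax(membership, axis=1)

    # planted signaling pairs; default: trajectory start signals trajectory end
    if config.signaling_pairs is None:
        planted = [(path[0], path[-1])]
    else:
        planted = [tuple(int(x) for x in p) for p in config.signaling_pairs]

    # per-cluster mean expression profiles
    marker_genes = [
        f"M{k}_{j}" for k in range(K) for j in range(config.markers_per_cluster)
    ]
    pathway_genes = pathway.all_genes
    n_filler = config.n_genes - len(marker_genes) - len(pathway_genes)
    gene_ids = marker_genes + pathway_genes + [f"G{j}" for j in range(n_filler)]
    col = {g: i for i, g in enumerate(gene_ids)}

    means = np.full((K, config.n_genes), config.mean_low)
    for k in range(K):
        for j in range(config.markers_per_cluster):
            means[k, col[f"M{k}_{j}"]] = config.mean_high
    for sender, receiver in planted:
        for pair in pathway.pairs:
            means[sender, col[pair["ligand"]]] = config.mean_high
            means[receiver, col[pair["receptor"]]] = config.mean_high
        for t in pathway.targets_up:
            means[receiver, col[t]] = config.mean_high
        for t in pathway.targets_down:
            # expressed everywhere, suppressed in the receiver state
            others = [k for k in range(K) if k != receiver]
            means[others, col[t]] = config.mean_high
            means[receiver, col[t]] = config.mean_low

    cell_means = membership @ means
    counts = _nb_sample(rng, cell_means, config.dispersion)
    if config.dropout_rate > 0:
        counts *= rng.random(counts.shape) >= config.dropout_rate

    # collection-time labels from trajectory position
    traj_pos = (membership @ pos_of) / max(K - 1, 1)
    T = config.n_timepoints
    if config.sync_mode == "synchronous":
        s = traj_pos + rng.normal(0.0, config.sync_jitter, size=n)
    else:
        s = config.async_drift * traj_pos + (1 - config.async_drift) * rng.random(n)
    time_labels = np.clip(np.floor(s * T), 0, T - 1).astype(int).tolist()

    expr = ExpressionMatrix(
        values=counts,
        cell_ids=[f"C{i:04d}" for i in range(n)],
        gene_ids=gene_ids,
        time_labels=time_labels,
    )
    return SynthDataset(
        expression=expr,
        true_membership=membership,
        true_labels=labels,
        true_path=path,
        time_labels=time_labels,
        pathway=pathway,
        planted_signaling=planted,
    )


def expected_cluster_signaling(dataset: SynthDataset) -> np.ndarray:
    """Ground-truth K x K indicator matrix of planted sender -> receiver pairs.

    Serves as the oracle for rank agreement with inferred cluster signaling.
    """
    if not dataset.planted_signaling:
        raise ValueError("dataset has no planted signaling pairs")
    K = dataset.n_clusters
    truth = np.zeros((K, K))
    for u, v in dataset.planted_signaling:
        truth[u, v] = 1.0
    return truth
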