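# Methods

This note documents the models and procedures implemented in `emtnet`, the
assumptions behind them, the tunable parameters that matter, and what the
synthetic-data generator does and does not emulate.

## Overview

The package analyzes an epithelial–mesenchymal transition (EMT) from a
single-cell expression matrix at three coupled scales:

1. **Cell states and trajectory** — consensus soft clustering identifies the
   epithelial (E) state, the mesenchymal (M) state and intermediate cell
   states (ICSs); transition cells (TCs) between states define the transition
   trajectory and a pseudotime.
2. **Cell–cell communication** — ligand–receptor co-expression yields
   sender→receiver signaling probabilities, aggregated into a directed
   cluster–cluster signaling network whose centralities identify signaling
   hubs, senders and receivers.
3. **Gene regulation per state** — partial-information-decomposition network
   inference scores gene–gene dependencies within each cell state, for
   pathway target genes and for cluster marker genes.

The three scales assemble into one multilayer network with a hierarchy
aspect (communication / target genes / marker genes) and a cell-state aspect
(one layer per state, ordered by trajectory position).

## Preprocessing

`filter_cells` keeps cells whose fraction of expressed genes, among genes
detected anywhere in the matrix, is at least `min_detected_fraction`. The
function default (0.95) encodes a near-saturating-coverage rule appropriate
for dense matrices; the pipeline default is 0.05, a conventional droplet-style
QC cut, because on sparse count data a 95% rule removes every cell. The
threshold is always explicit in the run manifest.

`select_genes` ranks genes by a bimodality index computed from a
two-component equal-variance Gaussian mixture on log1p expression:

    BI = |mu1 - mu2| / sigma * sqrt(p (1 - p)),

with p the mixing weight. The mixture is fit by EM initialized from the
10%/90% quantiles, making scores deterministic and permutation-invariant.
The mixture variance is floored at 0.1 (log1p units): integer counts make
near-two-spike sparse genes otherwise score arbitrarily high on what is
measurement granularity, not biology. Downstream stages consume log1p values
of the selected genes; no library-size normalization is applied.

## Consensus similarity and soft clustering

Cell–cell similarity is a co-clustering frequency over a grid of k-means
runs: cells are projected onto the top-d principal components
(d ∈ {4, 6, 8, 10}) and clustered at k ∈ {3..8}, 10 runs per setting. Each
run clusters a random 80% subsample of cells, and S[i, j] is the fraction of
runs containing both cells in which they co-cluster. The resampling is
essential: without it k-means settles into the same partition in nearly
every run, S degenerates toward 0/1, and the soft structure that downstream
plasticity estimates rely on collapses onto a single cluster boundary.

The number of clusters K is the largest gap in the ascending eigenvalues of
the symmetric normalized graph Laplacian L = I − D^(−1/2) S D^(−1/2),
searched from K = 3 (an EMT model needs at least E, M and one ICS).

Soft memberships minimize ‖S − H Hᵀ‖²_F over H ≥ 0 by the damped
multiplicative update H ← H ∘ (1/2 + 1/2 (SH)/(HHᵀH)), initialized from the
absolute top-K eigenvectors scaled by the square root of their eigenvalues
(plus a seeded 0.01 jitter). The objective is non-increasing; iteration
stops at a relative decrease below 1e-8 or after 500 iterations (a warning,
not an error — memberships are then still usable). Rows are normalized onto
the simplex.

## Plasticity, transition cells, trajectory, pseudotime

The Cell Plasticity Index is the normalized entropy of a membership row,
CPI = −Σ_k H[i,k] ln H[i,k] / ln K ∈ [0, 1]. TCs are either cells with CPI
above a threshold or the top fraction of cells by CPI (default: top 20%;
both modes exposed because the appropriate cut is dataset-dependent). Each
TC is attributed to the unordered pair of its two largest memberships.

The cluster graph weights W[u, v] are the fraction of all cells that are
TCs attributed to {u, v}. Terminal (E/M) candidates are the clusters with
the least total TC involvement; which terminal is epithelial must be decided
from marker expression (e.g. CDH1-high), so the start state is
caller-supplied and the package only ranks candidates. The trajectory is the
maximum-weight Hamiltonian path from the start cluster, found exhaustively
(K ≤ 10; ties resolved lexicographically). Pseudotime is the
membership-weighted path position, (H·pos)/(K−1) ∈ [0, 1] — a monotone
surrogate chosen because no closed form is standard; averaging over the two
best paths is available but the single best path is the default.

Marker genes are scored by nonnegative least squares of each gene's
expression onto the membership columns; a gene's score for cluster k is its
NNLS coefficient share, so cluster-exclusive genes score 1. Transition genes
for a state pair are ranked by |Spearman ρ| between expression and
pseudotime over the cells attributed to that pair.

## Ligand–receptor signaling

For ligand ℓ and receptor r (log1p values), the probability that cell i
signals to cell j combines α_ij = exp(−1/(ℓ_i r_j)) (zero when either is
silent), β_j = exp(−1/ū_j) for mean up-target activity (zero when up-targets
are listed but silent; 1 when none are listed), and γ_j = exp(−d̄_j) for mean
down-target activity. Rows are normalized over receivers; a cell with no
ligand has an all-zero row. Self-signaling (i = j) is retained: autocrine
signaling is meaningful and nothing excludes it. Pathways with several
ligand–receptor pairs average the per-pair matrices.

Cluster-level signaling is the plain mean over cell pairs,
P_{u,v} = Σ_{i∈C_u, j∈C_v} P_ij / (|C_u||C_v|), reported together with the
count of cell pairs with nonzero probability. Note the scale: because rows
sum to 1 over all receivers, P_{u,v} is bounded by ≈ 1/|C_v|, so thresholds
for drawing layer-1 edges must be read relative to that scale on large
datasets.

## Partial-information-decomposition networks

Expression is discretized per gene into uniform-width bins (Sturges count
max(2, ⌈log₂ n + 1⌉) by default; constant genes get one bin; the top bin is
right-closed). All information quantities are plug-in estimates in bits.

Redundancy uses the Williams–Beer measure: with specific information
I_spec(Y=y; A) = D_KL(p(a|y) ‖ p(a)) ≥ 0,

    I_min(Y; {X, Z}) = Σ_y p(y) min(I_spec(y; X), I_spec(y; Z)),

and unique information U_Z(X→Y) = I(X;Y) − I_min(Y;{X,Z}) ≥ 0. The
proportional unique contribution of a pair accumulates both directions over
all third genes, normalized by the pair's mutual information (0 when
I(X;Y) = 0), giving a symmetric matrix U. Edge confidence rescales U against
each gene's own score distribution with empirical CDFs,
c = F_X(U_XY) + F_Y(U_XY) ∈ (0, 2] — an ECDF, not a fitted parametric CDF,
so confidences are invariant under monotone per-gene transforms of the
scores. Per-state networks keep the top 30% of edges by confidence
(ceiling, ties by gene-id pair) and rescale linearly so the strongest kept
edge has weight 2, making networks comparable across states and datasets.

The O(g³) accumulation is vectorized per target gene: specific-information
tables are O(g²), and the minimum over source pairs is an einsum; a test
checks the vectorized path against the naive pairwise definition.

## Multilayer network and centralities

Node–layer tuples: one communication node per state on hierarchy layer 1,
every target gene per state on layer 2, every marker gene per state on
layer 3 (N_c (1 + |T| + |A|) tuples). Layer-1 intra edges are cluster
signaling entries strictly above the threshold (default 0.5; 0.7 also
accepted — both appear as reasonable drawing cuts and neither changes the
analysis, so the parameter is exposed). Layer 2/3 intra edges are the
per-state pruned confidence networks. Inter-layer edges: state → target
weighted by mean target expression in the state (global top 20% kept), and
target → marker weighted by state-specific confidence (global top 1.5%
kept); pruning fractions are applied globally across states, matching a
single "top X%" rule per edge class.

Centralities of the directed, weighted cluster network follow common
graph-library semantics. Strength is the weighted in-/out-degree. Closeness
treats weights as path costs — Dijkstra distances, closeness(v) =
(r_v/Σdist)(r_v/(K−1)) with r_v the number of reachable nodes — so a state
receiving heavy (high-probability) edges has high in-strength but low
in-closeness: the receiver signature. An affinity mode (cost = 1/weight) is
available behind a flag. Pagerank is the weight-proportional random walk
with damping 0.85, uniform teleport and uniform redistribution of dangling
mass, computed by power iteration to an L1 tolerance of 1e-12; high-pagerank
states are signaling hubs. Centralities are computed on the full (not
thresholded) cluster network by default.

## Synthetic data generator

The generator plants everything the pipeline later infers. K clusters (default
4 × 50 cells) lie on a linear trajectory (a seeded permutation of cluster
indices). A fraction of cells (default 10%) are TCs: their membership mixes
two trajectory-adjacent clusters with a weight drawn uniformly from
[0.25, 0.75], guaranteeing clear CPI separation from the one-hot bulk. Each
cluster has 10 exclusive marker genes (mean 8 on, 0.2 off); a planted
sender→receiver pair (default: trajectory start → trajectory end) makes the
ligand high in the sender and the receptor plus up-targets high — and
down-targets suppressed — in the receiver. Cell means are the
membership-weighted mixture of cluster means; counts are negative binomial
(var = μ + 0.3 μ²) with 10% dropout. Collection-time labels (5 time points)
either track trajectory position with Gaussian jitter of 0.05 trajectory
units (synchronous mode) or are near-uniform with a weak 0.15 linear drift
(asynchronous mode).

What the generator does **not** emulate: library-size variation, batch
effects, cell-cycle structure, doublets, branching trajectories, or any
claim about the noise law of real post-normalization data. Passing recovery
tests therefore shows the pipeline is correct and sensitive under clean
linear-trajectory conditions, not that it is robust to every artifact of
real droplet data.

## Problem sizes and numerical choices

Validation uses 200-cell, 150-gene datasets, 20 generator seeds for recovery
rates, 10 matched seed pairs for the synchrony contrast and 50 random
instances per brute-force oracle — sizes chosen so the full suite re-runs in
minutes while keeping binomial noise on reported rates near ±5%. All
tie-breaks (gene ranking, TC pairs, path search, edge pruning) resolve by
smallest index or lexicographic order, making every stage bit-reproducible
under a fixed seed; the run manifest echoes every effective parameter.

Known limitations: consensus k-means compresses true mixture weights, so
recovered memberships are sharper than planted ones (CPI separates TCs by
rank, not by calibrated value); the Hamiltonian-path search is exhaustive
and limited to K ≤ 10; PUC scales as O(g³) and is intended for the
dozens-of-genes regime of per-state target/marker panels, not genome-wide
inference.
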