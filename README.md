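# emtnet

Multiscale analysis of the epithelial–mesenchymal transition (EMT) from
single-cell transcriptomes: soft clustering with transition-cell
quantification and trajectory/pseudotime inference, ligand–receptor
cell–cell communication probabilities, partial-information-decomposition
(PID) gene-network inference per cell state, and assembly of a hierarchical
multilayer network with centrality analysis of the signaling layer.

It is written for computational biologists studying cell-state transitions
— EMT in cancer cell lines being the motivating case — who want one
reproducible pipeline connecting *which states exist and in what order*,
*which states talk to which through a pathway*, and *how gene regulation
differs between states*.

## The model in brief

- **States and plasticity.** A consensus co-clustering similarity S (k-means
  over a PCA/k/seed grid with cell resampling) is factorized by symmetric
  NMF, min‖S − HHᵀ‖², giving each cell a membership distribution over K
  clusters (K chosen by the Laplacian eigen-gap). The Cell Plasticity Index
  CPI_i = −Σ_k H_ik ln H_ik / ln K flags transition cells (TCs); the
  TC-weighted cluster graph yields the transition trajectory (maximum-weight
  Hamiltonian path) and pseudotime (membership-weighted path position).
- **Communication.** For a ligand–receptor pair, the probability that cell i
  signals cell j is P_ij ∝ exp(−1/(ℓ_i r_j)) · exp(−1/ū_j) · exp(−d̄_j),
  row-normalized over receivers (ū, d̄ = mean up-/down-target activity);
  cluster-level signaling is P_uv = Σ_{i∈C_u, j∈C_v} P_ij / (|C_u||C_v|).
  Strength, closeness (weights as path costs) and pagerank of the directed
  cluster network identify receivers and signaling hubs.
- **Regulation.** Within each state, gene pairs are scored by the
  proportional unique contribution: Williams–Beer unique information summed
  over third genes and normalized by the pair's mutual information; edge
  confidence c = F_X(U_XY) + F_Y(U_XY) uses each gene's empirical score CDF.
  Top edges (30%) are kept and rescaled to max weight 2.
- **Multilayer network.** Hierarchy aspect {communication, target genes,
  marker genes} × cell-state aspect {one layer per state, in trajectory
  order}, with thresholded signaling edges in layer 1, per-state PID
  networks in layers 2–3, and expression/confidence inter-layer links.

A synthetic-data module generates datasets with planted clusters, transition
cells, trajectory, time-point synchrony and sender→receiver signaling, so
every stage is validated against ground truth. See `docs/methods.md` for
details and assumptions.

## Worked example

Run the full pipeline on a generated dataset (4 planted states, 200 cells,
10% transition cells, a planted sender→receiver signal):

```python
from emtnet.pipeline import PipelineConfig, run_pipeline

bundle = run_pipeline(PipelineConfig(output_dir="out", seed=1))
m = bundle["manifest"]
print(m["n_clusters"], m["n_transition_cells"], m["trajectory"])
print(bundle["centrality"].round(4))
```

prints

```
4 40 [1, 3, 0, 2]
       in_strength  out_strength  in_closeness  out_closeness  pagerank
state
0           0.0000        0.0035  5.833882e+05      1865.0855    0.0376
1           0.0255        0.0040  6.348933e+02    112787.5003    0.8816
2           0.0000        0.0167  1.053448e+06      1851.1043    0.0378
3           0.0003        0.0016  3.749327e+04      1926.2261    0.0431
```

Reading the output: the eigen-gap recovered the 4 planted states; 40 cells
(top 20% by CPI) are transition cells; the inferred trajectory 1–3–0–2 is
the planted path up to label permutation and orientation. The generator
planted a signal from the trajectory-start state into the trajectory-end
state, and the centralities show exactly the expected signature: inferred
state 1 (the planted receiver) has the largest in-strength (0.0255), the
*lowest* in-closeness (heavy incoming edges are long paths under cost
semantics, 6.3e2 vs ≥3.7e4 for every other state) and a dominant pagerank
(0.88) — the receiver is the signaling hub. Inferred state 2 (the planted
sender) has the largest out-strength. Cluster-level probabilities are means
over receiver cells, so their scale is ≈ 1/|C_v|; thresholds for drawing
layer-1 edges should be read against that scale.

All artifacts (soft assignments, CPI, cluster graph, trajectory and
pseudotime, cluster signaling, per-state networks, multilayer JSON,
centralities, manifest) are written to `out/` as plain text; re-running with
the same config is byte-identical.

The same stages are available from the shell:

```bash
emtnet simulate --outdir data --seed 1
emtnet run-all --outdir out --seed 1
```

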