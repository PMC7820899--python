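"""End-to-end orchestration: preprocessing through multilayer centralities.

``run_pipeline`` executes, in order: cell filtering, bimodal gene selection,
consensus soft clustering (with eigen-gap cluster-number selection),
transition-cell and trajectory inference, pseudotime, marker genes,
ligand-receptor signaling, per-state PID gene networks, multilayer assembly
and signaling centralities. Every artifact is written as plain text together
with a manifest echoing all effective parameters, so a run is reproducible
from its output directory alone.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import comm, grn, io, mlnet, preprocess, synthdata, trajectory
from .cluster import DEFAULT_D_VALUES, DEFAULT_K_VALUES, ConsensusSoftCluster
from .containers import ExpressionMatrix, PathwaySpec

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("emtnet")


@dataclass
class PipelineConfig:
    """All tunable parameters of a pipeline run."""

    output_dir: str = "emtnet_out"
    expression_path: str | None = None  # None -> simulate a synthetic dataset
    expression_format: str = "csv"
    pathway_json: str | None = None
    seed: int = 0

    # preprocessing; the filter keeps cells expressing at least this fraction
    # of detected genes. 0.05 is a droplet-style QC default appropriate for
    # sparse count matrices such as the synthetic generator's; the strict
    # 0.95 of filter_cells() applies to dense, near-saturating matrices.
    min_detected_fraction: float = 0.05
    n_top_genes: int | None = None

    # clustering
    k_values: tuple = DEFAULT_K_VALUES
    d_values: tuple = DEFAULT_D_VALUES
    n_consensus_seeds: int = 10
    n_clusters: int | None = None
    k_min: int = 3
    k_max: int = 8

    # transition cells / trajectory
    tc_top_fraction: float | None = 0.2
    tc_cpi_threshold: float | None = None
    start_cluster: int | None = None
    top_m_markers: int = 5

    # gene networks
    grn_keep_fraction: float = 0.30
    grn_max_weight: float = 2.0
    n_bins: int | None = None

    # multilayer network
    expr_link_keep: float = 0.20
    cross_link_keep: float = 0.015
    signaling_threshold: float = 0.5
    damping: float = 0.85

    # synthetic-data settings (used when expression_path is None)
    synth: dict = dataclasses.field(default_factory=dict)

    def validate(self) -> None:
        if (self.tc_top_fraction is None) == (self.tc_cpi_threshold is None):
            raise ValueError(
                "configure exactly one of tc_top_fraction / tc_cpi_threshold"
            )
        for name in ("grn_keep_fraction", "expr_link_keep", "cross_link_keep"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if not 0 < self.min_detected_fraction <= 1:
            raise ValueError("min_detected_fraction must lie in (0, 1]")
        if not 0 < self.damping < 1:
            raise ValueError("damping must lie in (0, 1)")
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**payload)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["k_values"] = list(self.k_values)
        d["d_values"] = list(self.d_values)
        return d


def _stage(name: str):
    log.info("stage: %s", name)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write all artifacts; returns the result bundle."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- input ---------------------------------------------------------
    _stage("input")
    dataset = None
    if config.expression_path is None:
        synth_cfg = synthdata.SynthConfig(seed=config.seed, **config.synth)
        dataset = synthdata.generate_emt_dataset(synth_cfg)
        X = dataset.expression
        pathway = dataset.pathway
        io.write_expression(X, out / "expression.csv")
    else:
        X = io.read_expression(config.expression_path, config.expression_format)
        if config.pathway_json is None:
            raise ValueError("pathway_json is required with an external matrix")
        pathway = PathwaySpec.from_json(config.pathway_json)

    # --- preprocess ----------------------------------------------------
    _stage("preprocess")
    filtered = preprocess.filter_cells(X, config.min_detected_fraction)
    log.info("cells retained: %d / %d", filtered.n_cells, X.n_cells)
    selection = preprocess.select_genes(filtered, config.n_top_genes)
    io.write_tsv(
        pd.DataFrame({"gene_id": selection.gene_ids, "score": selection.scores}),
        out / "gene_selection.tsv",
        index=False,
    )
    selected = filtered.subset_genes(selection.gene_ids).log1p()

    # --- clustering ----------------------------------------------------
    _stage("cluster")
    model = ConsensusSoftCluster(
        n_clusters=config.n_clusters,
        k_values=config.k_values,
        d_values=config.d_values,
        n_seeds=config.n_consensus_seeds,
        k_min=config.k_min,
        k_max=config.k_max,
        random_state=config.seed,
    ).fit(selected.values)
    K = model.n_clusters_
    log.info("clusters: %d", K)
    assign = pd.DataFrame(
        model.memberships_,
        index=pd.Index(filtered.cell_ids, name="cell_id"),
        columns=[f"cluster_{k}" for k in range(K)],
    )
    assign["label"] = model.labels_
    assign["cpi"] = model.cpi_
    io.write_tsv(assign, out / "soft_assignment.tsv")

    # --- trajectory ----------------------------------------------------
    _stage("trajectory")
    if config.tc_top_fraction is not None:
        tcs = trajectory.identify_transition_cells(
            model.memberships_, top_fraction=config.tc_top_fraction
        )
    else:
        tcs = trajectory.identify_transition_cells(
            model.memberships_, cpi_threshold=config.tc_cpi_threshold
        )
    W = trajectory.cluster_transition_weights(tcs, filtered.n_cells, K)
    ranking = trajectory.select_terminal_states(W)
    start = ranking[0] if config.start_cluster is None else config.start_cluster
    path = trajectory.infer_trajectory(W, start)
    pt = trajectory.compute_pseudotime(model.memberships_, path)
    edges = [
        {"u": u, "v": v, "tc_fraction": float(W[u, v])}
        for u in range(K)
        for v in range(u + 1, K)
        if W[u, v] > 0
    ]
    io.write_tsv(pd.DataFrame(edges), out / "cluster_graph.tsv", index=False)
    io.write_json(
        {
            "path": path,
            "start": int(start),
            "terminal_ranking": ranking,
            "pseudotime": {c: float(t) for c, t in zip(filtered.cell_ids, pt)},
            "transition_cells": [filtered.cell_ids[i] for i in tcs.indices],
        },
        out / "trajectory.json",
    )

    # --- marker genes --------------------------------------------------
    _stage("markers")
    markers = trajectory.infer_marker_genes(
        selected, model.memberships_, top_m=config.top_m_markers
    )
    io.write_tsv(markers.scores, out / "marker_scores.tsv")
    marker_union = sorted({g for top in markers.top_markers.values() for g in top})

    # --- cell-cell communication --------------------------------------
    _stage("communication")
    full_log = filtered.log1p()
    signaling = comm.LigandReceptorSignaling(pathway).fit(full_log.to_frame())
    cluster_sig = signaling.cluster_matrix(model.labels_, K)
    sig_rows = [
        {
            "sender": u,
            "receiver": v,
            "probability": float(cluster_sig.probabilities[u, v]),
            "support_count": int(cluster_sig.support_counts[u, v]),
        }
        for u in range(K)
        for v in range(K)
    ]
    io.write_tsv(pd.DataFrame(sig_rows), out / "cluster_signaling.tsv", index=False)

    # --- per-state gene networks --------------------------------------
    _stage("grn")
    target_list = [
        t for t in pathway.targets_up + pathway.targets_down
        if t in selection.gene_ids
    ]
    target_grns, marker_grns = {}, {}
    grn_rows = []
    for k in range(K):
        for genes, bag, layer in (
            (target_list, target_grns, "targets"),
            (marker_union, marker_grns, "markers"),
        ):
            bag[k] = grn.state_grn(
                full_log.to_frame(),
                model.labels_,
                k,
                genes,
                keep_fraction=config.grn_keep_fraction,
                max_weight_norm=config.grn_max_weight,
                n_bins=config.n_bins,
            )
            grn_rows += [
                {"state": k, "layer": layer, "gene_x": gx, "gene_y": gy, "weight": w}
                for gx, gy, w in bag[k].edges
            ]
    io.write_tsv(pd.DataFrame(grn_rows), out / "state_grns.tsv", index=False)

    # --- multilayer network & centralities ----------------------------
    _stage("multilayer")
    expr_links = mlnet.target_expression_links(
        full_log.to_frame(), model.labels_, target_list, config.expr_link_keep
    )
    cross_links = mlnet.target_marker_links(
        full_log.to_frame(),
        model.labels_,
        target_list,
        marker_union,
        config.cross_link_keep,
        n_bins=config.n_bins,
    )
    network = mlnet.assemble_multilayer(
        cluster_sig,
        target_grns,
        marker_grns,
        expr_links,
        cross_links,
        signaling_threshold=config.signaling_threshold,
        state_order=path,
    )
    io.write_json(network.to_dict(), out / "multilayer.json")

    _stage("centrality")
    centrality = mlnet.compute_centralities(cluster_sig, damping=config.damping)
    io.write_tsv(centrality, out / "centrality.tsv")

    manifest = {
        "parameters": config.to_dict(),
        "n_cells_input": X.n_cells,
        "n_cells_retained": filtered.n_cells,
        "n_genes_selected": len(selection.gene_ids),
        "n_clusters": K,
        "n_transition_cells": len(tcs),
        "trajectory": path,
        "layer1_edges": network.edge_count("intra1"),
        "artifacts": sorted(
            {p.name for p in out.iterdir() if p.is_file()} | {"manifest.json"}
        ),
    }
    io.write_json(manifest, out / "manifest.json")

    return {
        "dataset": dataset,
        "expression": filtered,
        "selection": selection,
        "model": model,
        "transition_cells": tcs,
        "cluster_graph": W,
        "trajectory": path,
        "pseudotime": pt,
        "markers": markers,
        "cluster_signaling": cluster_sig,
        "target_grns": target_grns,
        "marker_grns": marker_grns,
        "network": network,
        "centrality": centrality,
        "manifest": manifest,
    }
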