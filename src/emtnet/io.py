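"""Readers and writers for the pipeline's plain-text formats.

Expression matrices are exchanged either as a dense CSV (cells x genes,
header row of gene names, first column of cell ids) or as a MatrixMarket
triple (``matrix.mtx`` genes x cells, ``genes.tsv``, ``barcodes.tsv``) in
the style of common single-cell repositories. All derived artifacts (gene
selections, soft assignments, edge lists) are TSV; structured results
(trajectory, multilayer network, run manifest) are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .containers import ExpressionMatrix

__all__ = ["read_expression", "write_expression"]


def read_expression(path: str | Path, format: str = "csv") -> ExpressionMatrix:
    """Read an expression matrix from CSV or an MTX directory.

    CSV: cells x genes with cell ids in the first column. MTX: ``path`` is a
    directory containing matrix.mtx (genes x cells), genes.tsv and
    barcodes.tsv.
    """
    path = Path(path)
    if format == "csv":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(",")[1:]
        if len(set(header)) != len(header):
            dupes = sorted({g for g in header if header.count(g) > 1})
            raise ValueError(f"duplicate gene columns in {path}: {dupes[:5]}")
        try:
            df = pd.read_csv(path, index_col=0)
        except Exception as exc:  # surface parse context
            raise ValueError(f"failed to parse {path}: {exc}") from exc
        return ExpressionMatrix.from_frame(df)
    if format == "mtx":
        mtx = spio.mmread(path / "matrix.mtx")
        genes = [ln.split("\t")[0] for ln in
                 (path / "genes.tsv").read_text().splitlines() if ln]
        barcodes = [ln.strip() for ln in
                    (path / "barcodes.tsv").read_text().splitlines() if ln]
        values = np.asarray(
            mtx.todense() if sparse.issparse(mtx) else mtx, dtype=float
        ).T  # stored genes x cells
        if values.shape != (len(barcodes), len(genes)):
            raise ValueError(
                f"dimension mismatch: matrix {mtx.shape} (genes x cells) vs "
                f"{len(genes)} genes / {len(barcodes)} barcodes"
            )
        return ExpressionMatrix(values=values, cell_ids=barcodes, gene_ids=genes)
    raise ValueError(f"unknown format {format!r}; use 'csv' or 'mtx'")


def write_expression(X: ExpressionMatrix, path: str | Path, format: str = "csv") -> None:
    """Write an expression matrix in the dialect `read_expression` accepts."""
    path = Path(path)
    if format == "csv":
        X.to_frame().to_csv(path)
        return
    if format == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        spio.mmwrite(path / "matrix.mtx", sparse.csr_matrix(X.values.T))
        (path / "genes.tsv").write_text("".join(f"{g}\t{g}\n" for g in X.gene_ids))
        (path / "barcodes.tsv").write_text("".join(f"{c}\n" for c in X.cell_ids))
        return
    raise ValueError(f"unknown format {format!r}; use 'csv' or 'mtx'")


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
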