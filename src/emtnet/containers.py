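"""Core data containers shared by every pipeline stage.

The pipeline's common currency is a nonnegative cell x gene matrix with
string identifiers on both axes, an optional per-cell collection-time label,
and a pathway specification listing ligand-receptor pairs together with the
target genes that respond (up or down) when the pathway fires in a receiver
cell.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "PathwaySpec"]


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen, dupes = set(), []
        for i in ids:
            if i in seen:
                dupes.append(i)
            seen.add(i)
        raise ValueError(f"duplicate {what} ids: {sorted(set(dupes))[:5]}")


@dataclass
class ExpressionMatrix:
    """Nonnegative cell x gene expression with identifiers.

    Parameters
    ----------
    values : ndarray of shape (n_cells, n_genes)
        Nonnegative expression values (counts or transformed).
    cell_ids, gene_ids : sequences of unique strings.
    time_labels : optional per-cell categorical label (collection time).
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    time_labels: list | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = list(self.cell_ids)
        self.gene_ids = list(self.gene_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (cells x genes)")
        n, g = self.values.shape
        if len(self.cell_ids) != n or len(self.gene_ids) != g:
            raise ValueError(
                f"id lists ({len(self.cell_ids)}, {len(self.gene_ids)}) do not match "
                f"matrix shape {self.values.shape}"
            )
        _check_unique(self.cell_ids, "cell")
        _check_unique(self.gene_ids, "gene")
        if np.any(self.values < 0):
            raise ValueError("expression values must be nonnegative")
        if self.time_labels is not None:
            self.time_labels = list(self.time_labels)
            if len(self.time_labels) != n:
                raise ValueError("time_labels length does not match cell count")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not present in expression matrix") from None

    def gene_vector(self, gene: str) -> np.ndarray:
        return self.values[:, self.gene_index(gene)]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.gene_index(g) for g in genes]
        return replace(self, values=self.values[:, idx], gene_ids=list(genes))

    def subset_cells(self, index: Sequence[int]) -> "ExpressionMatrix":
        index = list(index)
        return replace(
            self,
            values=self.values[index],
            cell_ids=[self.cell_ids[i] for i in index],
            time_labels=None if self.time_labels is None
            else [self.time_labels[i] for i in index],
        )

    def log1p(self) -> "ExpressionMatrix":
        """Return a copy with log1p-transformed values (the downstream default)."""
        return replace(self, values=np.log1p(self.values))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, time_labels=None) -> "ExpressionMatrix":
        return cls(
            values=df.to_numpy(dtype=float),
            cell_ids=[str(c) for c in df.index],
            gene_ids=[str(g) for g in df.columns],
            time_labels=time_labels,
        )


@dataclass
class PathwaySpec:
    """A signaling pathway: ligand-receptor pairs plus responsive target genes.

    ``targets_up`` are genes induced when the pathway is active in the
    receiving cell; ``targets_down`` are repressed. Target sets are shared
    across the pairs of the pathway.
    """

    pathway_name: str
    pairs: list[dict]  # each {"ligand": str, "receptor": str}
    targets_up: list[str] = field(default_factory=list)
    targets_down: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for pair in self.pairs:
            if pair["ligand"] == pair["receptor"]:
                raise ValueError(f"ligand equals receptor in pair {pair}")
        _check_unique(self.targets_up, "up-target")
        _check_unique(self.targets_down, "down-target")
        _check_unique([p["ligand"] for p in self.pairs], "ligand")
        _check_unique([p["receptor"] for p in self.pairs], "receptor")

    @property
    def all_genes(self) -> list[str]:
        genes: list[str] = []
        for p in self.pairs:
            genes.extend((p["ligand"], p["receptor"]))
        genes.extend(self.targets_up)
        genes.extend(self.targets_down)
        return genes

    def to_json(self, path: str | Path) -> None:
        payload = {
            "pathway": self.pathway_name,
            "pairs": self.pairs,
            "targets_up": self.targets_up,
            "targets_down": self.targets_down,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PathwaySpec":
        payload = json.loads(Path(path).read_text())
        return cls(
            pathway_name=payload["pathway"],
            pairs=payload["pairs"],
            targets_up=payload.get("targets_up", []),
            targets_down=payload.get("targets_down", []),
        )
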