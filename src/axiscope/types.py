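"""Core in-memory container for single-cell count data."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class CountMatrix:
    """Genes x cells non-negative integer transcript counts.

    ``cell_meta`` (indexed by cell id) may carry a ``depth_multiplier``
    column recorded by the simulator; :attr:`depth` falls back to per-cell
    total counts when no recorded depth is available, which is the usual
    situation with real libraries.
    """

    genes: list[str]
    cells: list[str]
    X: np.ndarray
    cell_meta: pd.DataFrame | None = field(default=None, repr=False)
    line: str | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        if self.X.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"count matrix shape {self.X.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if self.X.size and self.X.min() < 0:
            raise ValueError("counts must be non-negative")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene identifiers must be unique")
        if len(set(self.cells)) != len(self.cells):
            raise ValueError("cell identifiers must be unique")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def depth(self) -> np.ndarray:
        """Per-cell depth: recorded multiplier if present, else total counts."""
        if self.cell_meta is not None and "depth_multiplier" in self.cell_meta:
            return self.cell_meta["depth_multiplier"].to_numpy(float)
        return self.X.sum(axis=0).astype(float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=pd.Index(self.genes, name="gene"), columns=self.cells)

    def subset_cells(self, cell_idx: np.ndarray) -> "CountMatrix":
        cells = [self.cells[i] for i in cell_idx]
        meta = None if self.cell_meta is None else self.cell_meta.iloc[cell_idx]
        return CountMatrix(
            genes=list(self.genes), cells=cells, X=self.X[:, cell_idx],
            cell_meta=meta, line=self.line,
        )

    def subset_genes(self, keep: list[str]) -> "CountMatrix":
        idx = [self.genes.index(g) for g in keep]
        return CountMatrix(
            genes=keep, cells=list(self.cells), X=self.X[idx, :],
            cell_meta=self.cell_meta, line=self.line,
        )
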