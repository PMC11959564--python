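"""Core in-memory containers: the spot lattice and the count matrix."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial import cKDTree

GRID_COLUMNS = (
    "spot_id",
    "section_id",
    "array_row",
    "array_col",
    "x_um",
    "y_um",
    "in_tissue",
    "brightness",
)


@dataclass
class SpotGrid:
    """Spot identities and lattice/physical coordinates for >= 1 sections.

    ``table`` holds one row per spot with the columns in :data:`GRID_COLUMNS`.
    ``array_row``/``array_col`` follow the hexagonal convention of
    :mod:`spotdist.hexgrid`; ``x_um``/``y_um`` are physical coordinates with a
    constant nearest-neighbor spacing per section (nominally 100 µm).
    ``brightness`` is a unitless mean-luminance proxy (higher = lighter).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in GRID_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"SpotGrid table missing columns: {missing}")
        t = self.table
        if t.duplicated(["section_id", "spot_id"]).any():
            dup = t.loc[t.duplicated(["section_id", "spot_id"]), "spot_id"]
            raise ValueError(f"duplicate spot_id within a section: {list(dup[:5])}")
        if t["spot_id"].duplicated().any():
            dup = t.loc[t["spot_id"].duplicated(), "spot_id"]
            raise ValueError(f"duplicate spot_id across sections: {list(dup[:5])}")
        if t.duplicated(["section_id", "array_row", "array_col"]).any():
            raise ValueError("duplicate (array_row, array_col) within a section")
        parity = (t["array_row"].to_numpy() - t["array_col"].to_numpy()) % 2
        if np.any(parity != 0):
            raise ValueError("array_row and array_col must have equal parity")
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def spot_ids(self) -> np.ndarray:
        return self.table["spot_id"].to_numpy()

    @property
    def sections(self) -> list[str]:
        return list(pd.unique(self.table["section_id"]))

    def section(self, section_id: str) -> "SpotGrid":
        sub = self.table[self.table["section_id"] == section_id]
        if sub.empty:
            raise KeyError(f"unknown section {section_id!r}")
        return SpotGrid(sub.reset_index(drop=True))

    def positions(self) -> np.ndarray:
        """(n, 2) array of physical coordinates in µm."""
        return self.table[["x_um", "y_um"]].to_numpy(dtype=float)

    def spacing(self, section_id: str | None = None) -> float:
        """Nearest-neighbor center spacing (µm) of one section.

        By the lattice invariant this is constant per section; the minimum
        pairwise nearest-neighbor distance is returned.  Singleton sections
        have no defined spacing and yield ``nan``.
        """
        if section_id is None:
            secs = self.sections
            if len(secs) != 1:
                raise ValueError("section_id required for multi-section grids")
            section_id = secs[0]
        pos = self.section(section_id).positions()
        if len(pos) < 2:
            return float("nan")
        tree = cKDTree(pos)
        d, _ = tree.query(pos, k=2)
        return float(np.min(d[:, 1]))


@dataclass
class CountMatrix:
    """Sparse nonnegative integer gene-by-spot counts with names.

    ``counts`` is genes x spots; ``genes`` and ``spots`` give the row/column
    names in order.
    """

    genes: np.ndarray
    spots: np.ndarray
    counts: sp.csr_matrix = field(repr=False)

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.spots = np.asarray(self.spots, dtype=object)
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        self.counts = self.counts.tocsr()
        if self.counts.shape != (len(self.genes), len(self.spots)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.spots)} spots"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("count matrix contains negative entries")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene names")
        if len(set(self.spots)) != len(self.spots):
            raise ValueError("duplicate spot barcodes")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def spot_totals(self) -> np.ndarray:
        """Total counts (library size) per spot."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def genes_detected_per_spot(self) -> np.ndarray:
        """Number of genes with count > 0 in each spot."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def subset_spots(self, spot_ids) -> "CountMatrix":
        idx = pd.Index(self.spots)
        locs = idx.get_indexer(list(spot_ids))
        if (locs < 0).any():
            missing = [s for s, l in zip(spot_ids, locs) if l < 0]
            raise KeyError(f"unknown spot barcodes: {missing[:5]}")
        return CountMatrix(self.genes, np.asarray(list(spot_ids), dtype=object),
                           self.counts[:, locs])

    def subset_genes(self, gene_names) -> "CountMatrix":
        idx = pd.Index(self.genes)
        locs = idx.get_indexer(list(gene_names))
        if (locs < 0).any():
            missing = [g for g, l in zip(gene_names, locs) if l < 0]
            raise KeyError(f"unknown genes: {missing[:5]}")
        return CountMatrix(np.asarray(list(gene_names), dtype=object), self.spots,
                           self.counts[locs, :])

    def dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())
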