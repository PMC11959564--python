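"""Hexagonal spot-lattice helpers.

Visium arrays pack 55 µm capture spots on a hexagonal lattice with ~100 µm
center-to-center spacing.  Array coordinates follow the Space Ranger
convention: ``array_row`` and ``array_col`` have equal parity, in-row
neighbors differ by ``(0, ±2)`` and diagonal neighbors by ``(±1, ±1)``, so
every interior spot has exactly six lattice neighbors at equal physical
distance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial import cKDTree

#: Array-coordinate offsets of the six hexagonal lattice neighbors.
NEIGHBOR_OFFSETS: tuple[tuple[int, int], ...] = (
    (0, 2),
    (0, -2),
    (1, 1),
    (1, -1),
    (-1, 1),
    (-1, -1),
)


def adjacency_matrix(table: pd.DataFrame) -> sp.csr_matrix:
    """Sparse symmetric 6-neighbor adjacency over the rows of a spot table.

    Neighbors are resolved within a section only; spots of different
    sections are never adjacent.

    Parameters
    ----------
    table
        DataFrame with ``section_id``, ``array_row`` and ``array_col``
        columns; row order defines the node order of the output.
    """
    index = {
        (s, int(r), int(c)): i
        for i, (s, r, c) in enumerate(
            zip(table["section_id"], table["array_row"], table["array_col"])
        )
    }
    rows: list[int] = []
    cols: list[int] = []
    for (s, r, c), i in index.items():
        for dr, dc in NEIGHBOR_OFFSETS:
            j = index.get((s, r + dr, c + dc))
            if j is not None:
                rows.append(i)
                cols.append(j)
    n = len(table)
    data = np.ones(len(rows), dtype=float)
    return sp.csr_matrix((data, (rows, cols)), shape=(n, n))


def nearest_anchor_distance(
    positions: np.ndarray, anchor_positions: np.ndarray
) -> np.ndarray:
    """Euclidean distance from each position to its nearest anchor.

    Returns ``inf`` for every position when there are no anchors.
    """
    positions = np.asarray(positions, dtype=float)
    if len(anchor_positions) == 0:
        return np.full(len(positions), np.inf)
    tree = cKDTree(np.asarray(anchor_positions, dtype=float))
    d, _ = tree.query(positions, k=1)
    return np.asarray(d, dtype=float)
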