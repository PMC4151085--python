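"""Hexagonal cell lattice for planar-polarity simulations.

Cells are pointy-top hexagons laid out in offset rows ("odd-r" layout), so
every cell has a direct left (proximal) and right (distal) neighbour in the
same row.  Each cell carries six edges whose outward unit normals sit at
0°, 60°, 120°, 180°, 240° and 300° from the +x axis; the tissue
proximal–distal axis is +x (distal) and +y points posterior (image
convention, y down).  Interior edges are paired with the apposed edge of the
neighbouring cell; lattice-boundary edges have no partner (no-flux).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: outward unit normal of edge slot k, angle k*60 degrees from +x
EDGE_ANGLES_DEG = np.arange(6) * 60.0
EDGE_NORMALS = np.stack(
    [np.cos(np.deg2rad(EDGE_ANGLES_DEG)), np.sin(np.deg2rad(EDGE_ANGLES_DEG))],
    axis=1,
)

# odd-r offset neighbour displacement (drow, dcol) for each edge slot,
# split by row parity; derived from pointy-top axial coordinates.
_NEIGHBOR_EVEN = [(0, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0)]
_NEIGHBOR_ODD = [(0, 1), (1, 1), (1, 0), (0, -1), (-1, 0), (-1, 1)]


def opposite_edge(e: int) -> int:
    """Edge slot whose outward normal is rotated by 180 degrees."""
    return (e + 3) % 6


@dataclass(frozen=True)
class HexGrid:
    """A ``n_rows`` x ``n_cols`` arena of hexagonal cells.

    Cell index is ``row * n_cols + col``; ``col`` increases distally.
    """

    n_rows: int = 6
    n_cols: int = 30
    # (n_cells, 6) neighbour cell index per edge slot, -1 at the boundary
    neighbor: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        nb = np.full((self.n_cells, 6), -1, dtype=np.int64)
        for r in range(self.n_rows):
            offsets = _NEIGHBOR_ODD if (r % 2) else _NEIGHBOR_EVEN
            for c in range(self.n_cols):
                i = r * self.n_cols + c
                for e, (dr, dc) in enumerate(offsets):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < self.n_rows and 0 <= cc < self.n_cols:
                        nb[i, e] = rr * self.n_cols + cc
        object.__setattr__(self, "neighbor", nb)
        nb.setflags(write=False)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def cell_index(self, row: int, col: int) -> int:
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise IndexError(f"cell ({row}, {col}) outside grid")
        return row * self.n_cols + col

    def row_col(self, i: int) -> tuple[int, int]:
        return divmod(int(i), self.n_cols)

    @property
    def columns(self) -> np.ndarray:
        """Column index of every cell, shape (n_cells,)."""
        return np.arange(self.n_cells) % self.n_cols

    def centers(self, spacing: float = 1.0) -> np.ndarray:
        """Cartesian cell centres, shape (n_cells, 2); odd rows shifted +x/2."""
        rows, cols = np.divmod(np.arange(self.n_cells), self.n_cols)
        x = spacing * (cols + 0.5 * (rows % 2))
        y = spacing * (np.sqrt(3.0) / 2.0) * rows
        return np.stack([x, y], axis=1)

    def interior_mask(self) -> np.ndarray:
        """(n_cells, 6) boolean mask of edges that have a junction partner."""
        return self.neighbor >= 0

    def partner_edges(self) -> tuple[np.ndarray, np.ndarray]:
        """For each (cell, edge): apposed (cell, edge) across the junction.

        Boundary edges map onto themselves; mask with :meth:`interior_mask`.
        """
        j = self.neighbor.copy()
        idx = np.arange(self.n_cells)[:, None].repeat(6, axis=1)
        j[j < 0] = idx[j < 0]
        e_opp = np.tile((np.arange(6) + 3) % 6, (self.n_cells, 1))
        e_self = np.tile(np.arange(6), (self.n_cells, 1))
        e_opp[self.neighbor < 0] = e_self[self.neighbor < 0]
        return j, e_opp

    def rotate180_map(self) -> tuple[np.ndarray, np.ndarray]:
        """Index maps of the lattice's 180-degree rotation automorphism.

        Returns ``(cell_map, edge_map)`` such that cell ``i`` with edge ``e``
        maps to cell ``cell_map[i]`` with edge slot ``edge_map[e]``
        (normals rotate by 180 degrees).  Exact for any n_rows, n_cols.
        """
        rows, cols = np.divmod(np.arange(self.n_cells), self.n_cols)
        r2 = self.n_rows - 1 - rows
        c2 = self.n_cols - 1 - cols
        cell_map = r2 * self.n_cols + c2
        edge_map = (np.arange(6) + 3) % 6
        # the half-column row shift only cancels when paired rows swap
        # parity (even n_rows) or there is a single row; validate instead
        # of assuming
        nb = self.neighbor
        mapped = np.where(nb >= 0, cell_map[nb], -1)
        rotated = nb[cell_map][:, edge_map]
        rotated = np.where(nb[cell_map][:, edge_map] >= 0, rotated, -1)
        if not np.array_equal(mapped, rotated):
            raise ValueError(
                "180-degree rotation is not a lattice automorphism for "
                f"n_rows={self.n_rows}; use an even row count"
            )
        return cell_map, edge_map

    def __repr__(self) -> str:  # dataclass repr would dump the array
        return f"HexGrid(n_rows={self.n_rows}, n_cols={self.n_cols})"
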