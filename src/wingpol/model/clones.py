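"""Mutant clone specifications for grid simulations.

A clone is a set of cells in which one gene's product is absent: the
corresponding per-cell total is set to zero (loss-of-function, no synthesis
in the model).  ``ft`` and ``ds`` clones act on the binding layer; ``fz``,
``vang``, ``dsh`` and ``pk`` clones act on the core-layer totals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import InvalidParameterError
from ..hexgrid import HexGrid

NULL_SPECIES = ("fz", "dsh", "ft", "ds", "vang", "pk")


@dataclass(frozen=True)
class CloneSpec:
    """Cells (grid indices) in which ``species`` is null."""

    species: str
    cells: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.species not in NULL_SPECIES:
            raise InvalidParameterError(
                f"unknown null species {self.species!r}; one of {NULL_SPECIES}"
            )
        object.__setattr__(self, "cells", tuple(int(c) for c in self.cells))

    def validate(self, grid: HexGrid) -> None:
        for c in self.cells:
            if not (0 <= c < grid.n_cells):
                raise InvalidParameterError(f"clone cell {c} outside grid")

    @classmethod
    def block(
        cls, grid: HexGrid, species: str, row0: int, col0: int, n_rows: int, n_cols: int
    ) -> "CloneSpec":
        """Rectangular clone covering rows [row0, row0+n_rows) x cols [col0, col0+n_cols)."""
        cells = [
            grid.cell_index(r, c)
            for r in range(row0, row0 + n_rows)
            for c in range(col0, col0 + n_cols)
        ]
        return cls(species, tuple(cells))


def apply_clones(
    grid: HexGrid,
    clones: list[CloneSpec] | tuple[CloneSpec, ...],
    totals: dict[str, np.ndarray],
) -> dict[str, np.ndarray]:
    """Zero the relevant per-cell totals inside each clone.

    ``totals`` maps species name -> per-cell array; returns modified copies.
    """
    out = {k: v.copy() for k, v in totals.items()}
    for clone in clones:
        clone.validate(grid)
        if clone.species not in out:
            raise InvalidParameterError(
                f"no per-cell total supplied for species {clone.species!r}"
            )
        out[clone.species][list(clone.cells)] = 0.0
    return out
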