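"""Microtubule polarity bias derived from the Ft-Ds layer.

Apical MT minus ends anchor at junctions in proportion to bound Ft, so the
MT array's plus ends point, on average, away from the Ft-rich side of the
cell.  Directed vesicle transport delivers cargo toward plus ends; the
delivery weight of each edge is a soft-max-like function of the projection
of the per-cell bias vector onto the edge normal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import InvalidParameterError
from ..hexgrid import EDGE_NORMALS, HexGrid
from .ftds import FtDsLayerState

MODES = ("coupled", "random", "oriented_unbiased", "imposed")


@dataclass(frozen=True)
class MTBiasField:
    """Per-cell MT bias and per-edge transport delivery weights.

    ``m[i, e] >= 0`` with ``sum_e m[i, e] = 1`` in every cell: the fraction
    of directed Dsh transport delivered to edge ``e`` of cell ``i``.
    """

    grid: HexGrid
    mode: str
    bias: np.ndarray  # (n_cells, 2)
    m: np.ndarray     # (n_cells, 6)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise InvalidParameterError(f"unknown MT mode {self.mode!r}")
        if np.any(self.m < 0):
            raise InvalidParameterError("delivery weights must be >= 0")
        if not np.allclose(self.m.sum(axis=1), 1.0, atol=1e-9):
            raise InvalidParameterError("delivery weights must sum to 1 per cell")


def mt_bias_from_ftds(
    layer: FtDsLayerState,
    mode: str = "coupled",
    *,
    exponent: float = 1.0,
    floor: float = 0.05,
    imposed_m: np.ndarray | None = None,
    region: np.ndarray | None = None,
) -> MTBiasField:
    """Build transport delivery weights from bound-Ft anchoring.

    Modes
    -----
    ``coupled``
        ``m[i,e] ∝ floor + max(b_i · n_e, 0) ** exponent`` with
        ``b_i = -sum_e H[i,e] n_e`` (delivery toward plus ends, away from
        the Ft-rich anchoring side).
    ``random``
        uniform 1/6 per edge (unoriented MTs).
    ``oriented_unbiased``
        1/2 on each of the two P-D edges (normals ±x): MTs aligned with the
        axis but with no plus-end bias.
    ``imposed``
        user-supplied weights, normalized per cell.

    ``region`` (boolean per cell) restricts the named mode to those cells,
    keeping ``coupled`` weights elsewhere — used to enforce a distal MT
    architecture while the proximal gradient region stays coupled.
    """
    if mode not in MODES:
        raise InvalidParameterError(f"unknown MT mode {mode!r}")
    if floor <= 0:
        raise InvalidParameterError("floor must be > 0")
    grid = layer.grid
    n = grid.n_cells

    b = layer.bias_vectors()
    proj = b @ EDGE_NORMALS.T                      # (n_cells, 6)
    m_coupled = floor + np.clip(proj, 0.0, None) ** exponent
    m_coupled /= m_coupled.sum(axis=1, keepdims=True)

    if mode == "coupled":
        m = m_coupled
    elif mode == "random":
        m = np.full((n, 6), 1.0 / 6.0)
    elif mode == "oriented_unbiased":
        m = np.zeros((n, 6))
        m[:, 0] = 0.5   # +x (distal) edge
        m[:, 3] = 0.5   # -x (proximal) edge
    else:
        if imposed_m is None:
            raise InvalidParameterError("mode='imposed' requires imposed_m")
        m = np.asarray(imposed_m, dtype=float).copy()
        if m.shape != (n, 6) or np.any(m < 0) or not np.all(np.isfinite(m)):
            raise InvalidParameterError("imposed_m must be (n_cells, 6), finite, >= 0")
        sums = m.sum(axis=1)
        if np.any(sums <= 0):
            raise InvalidParameterError("imposed weights not normalizable (zero row)")
        m /= sums[:, None]

    if region is not None and mode != "coupled":
        region = np.asarray(region, dtype=bool)
        if region.shape != (n,):
            raise InvalidParameterError("region mask must have shape (n_cells,)")
        m = np.where(region[:, None], m, m_coupled)

    return MTBiasField(grid=grid, mode=mode, bias=b, m=m)
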