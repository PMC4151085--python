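"""Quasi-static Ft-Ds heterodimer binding layer.

Ft and Ds are atypical cadherins that form intercellular heterodimers across
apical junctions; the Golgi kinase Fj phosphorylates both, increasing Ft's
affinity for Ds and decreasing Ds's affinity for Ft.  Opposing tissue
gradients of Ds and Fj therefore bias heterodimer occupancy between the two
sides of every junction, producing a per-cell asymmetry of *bound* Ft that
downstream orients the microtubule network.

The layer is treated as an equilibrium (gradients are fixed inputs, binding
is fast relative to core-PCP dynamics).  At each junction between cell ``i``
(edge ``e``) and neighbour ``j``::

    H[i, e] = (k_on / k_off) * a_Ft(Fj_i) * a_Ds(Fj_j) * Ft_free_i * Ds_free_j

with ``a_Ft(F) = 1 + alpha_ft * F`` and ``a_Ds(F) = 1 / (1 + alpha_ds * F)``,
subject to per-cell conservation of total Ft and Ds.  The fixed point is
found by iterating the equivalent Langmuir form on the free pools, which
keeps every quantity non-negative at every step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import ConvergenceError, InvalidParameterError
from ..gradients import GradientSpec
from ..hexgrid import EDGE_NORMALS, HexGrid


@dataclass(frozen=True)
class FtDsParams:
    """Rate constants of the binding layer (nondimensional defaults)."""

    k_on: float = 1.0
    k_off: float = 1.0
    alpha_ft: float = 1.0   # Fj boost of Ft->Ds affinity
    alpha_ds: float = 1.0   # Fj reduction of Ds->Ft affinity
    max_iter: int = 10_000
    tol: float = 1e-12

    def __post_init__(self) -> None:
        if min(self.k_on, self.k_off) <= 0:
            raise InvalidParameterError("rate constants must be > 0")
        if min(self.alpha_ft, self.alpha_ds) < 0:
            raise InvalidParameterError("alpha factors must be >= 0")


@dataclass(frozen=True)
class FtDsLayerState:
    """Equilibrium heterodimer occupancies on a grid.

    ``H[i, e]`` is the heterodimer whose Ft belongs to cell ``i`` at edge
    slot ``e`` (its Ds partner belongs to the neighbour across that edge).
    Bound Ds of cell ``i`` at edge ``e`` is therefore ``H[j, e']`` of the
    apposed edge.
    """

    grid: HexGrid
    ds_tot: np.ndarray       # (n_cells,)
    ft_tot: np.ndarray       # (n_cells,)
    fj: np.ndarray           # (n_cells,)
    H: np.ndarray            # (n_cells, 6)
    ft_free: np.ndarray      # (n_cells,)
    ds_free: np.ndarray      # (n_cells,)
    residual: float = 0.0

    @property
    def bound_ft(self) -> np.ndarray:
        """Bound Ft per (cell, edge) — the MT anchoring weight."""
        return self.H

    def bias_vectors(self) -> np.ndarray:
        """Per-cell MT bias vector  b_i = -sum_e H[i, e] * n_e.

        Anchoring (minus ends) sits on Ft-rich edges; plus ends point away,
        so the bias points from the Ft-rich side toward the opposite side.
        """
        return -(self.H[:, :, None] * EDGE_NORMALS[None, :, :]).sum(axis=1)

    def asymmetry(self) -> np.ndarray:
        """Magnitude of the per-cell bound-Ft asymmetry |b_i|."""
        return np.linalg.norm(self.bias_vectors(), axis=1)


def _per_cell_levels(grid: HexGrid, spec: GradientSpec | np.ndarray, name: str) -> np.ndarray:
    if isinstance(spec, GradientSpec):
        if spec.n_columns != grid.n_cols:
            raise InvalidParameterError(
                f"{name} gradient has {spec.n_columns} columns, grid has {grid.n_cols}"
            )
        return spec.values[grid.columns]
    arr = np.asarray(spec, dtype=float)
    if arr.shape != (grid.n_cells,):
        raise InvalidParameterError(f"{name} per-cell array must have shape (n_cells,)")
    return arr


def solve_ftds_layer(
    grid: HexGrid,
    ds: GradientSpec | np.ndarray,
    fj: GradientSpec | np.ndarray,
    params: FtDsParams = FtDsParams(),
    *,
    ft_tot: float | np.ndarray = 1.0,
) -> FtDsLayerState:
    """Solve the junctional Ft-Ds binding equilibrium on a grid.

    ``ds`` and ``fj`` may be per-column :class:`GradientSpec` profiles or
    per-cell arrays (used for clones).  ``ft_tot`` is the per-cell total Ft
    (uniform 1 by default; an array for *ft* clones).
    """
    ds_tot = _per_cell_levels(grid, ds, "Ds")
    fj_cell = _per_cell_levels(grid, fj, "Fj")
    if np.isscalar(ft_tot):
        ft_arr = np.full(grid.n_cells, float(ft_tot))
    else:
        ft_arr = np.asarray(ft_tot, dtype=float).copy()
        if ft_arr.shape != (grid.n_cells,):
            raise InvalidParameterError("ft_tot array must have shape (n_cells,)")
    if np.any(ft_arr < 0) or np.any(ds_tot < 0):
        raise InvalidParameterError("totals must be >= 0")

    # mirror (reflective) boundary: a lattice-boundary edge is apposed to
    # the cell's own mirror image, so a uniform tissue stays exactly
    # uniform out to the edge; nothing crosses the boundary
    nbr = grid.neighbor
    nbr_safe = np.where(nbr >= 0, nbr, np.arange(grid.n_cells)[:, None])

    # K[i, e] = (k_on/k_off) * a_Ft(Fj_i) * a_Ds(Fj_j)
    a_ft = 1.0 + params.alpha_ft * fj_cell
    a_ds = 1.0 / (1.0 + params.alpha_ds * fj_cell)
    K = (params.k_on / params.k_off) * a_ft[:, None] * a_ds[nbr_safe]

    ft_free = ft_arr.copy()
    ds_free = ds_tot.copy()
    for _ in range(params.max_iter):
        # Langmuir update keeps pools in (0, total]
        ft_new = ft_arr / (1.0 + (K * ds_free[nbr_safe]).sum(axis=1))
        # Ds of cell i is consumed by the apposed Ft across every edge
        consume = np.zeros(grid.n_cells)
        np.add.at(consume, nbr_safe.ravel(), (K * ft_new[:, None]).ravel())
        ds_new = ds_tot / (1.0 + consume)
        delta = max(
            np.abs(ft_new - ft_free).max(initial=0.0),
            np.abs(ds_new - ds_free).max(initial=0.0),
        )
        ft_free, ds_free = ft_new, ds_new
        if delta < params.tol:
            break
    else:
        raise ConvergenceError(
            f"Ft-Ds layer did not converge in {params.max_iter} iterations",
            residual=float(delta),
        )

    H = K * ft_free[:, None] * ds_free[nbr_safe]
    # consistency residual of the fixed point, for reporting
    resid = float(
        np.abs(H - K * (ft_arr - H.sum(axis=1))[:, None] * ds_free[nbr_safe]).max()
    )
    return FtDsLayerState(
        grid=grid,
        ds_tot=ds_tot,
        ft_tot=ft_arr,
        fj=fj_cell,
        H=H,
        ft_free=ft_free,
        ds_free=ds_free,
        residual=resid,
    )


def measure_propagation_columns(
    layer: FtDsLayerState,
    step_column: int,
    threshold_frac: float = 0.05,
) -> int:
    """Columns of above-threshold Ft-Ds asymmetry distal to a Ds step.

    ``step_column`` is the first column at the low/flat level.  The
    per-cell asymmetry ``A_i = |sum_e H[i,e] n_e|`` is averaged per column;
    the count is the number of consecutive flat-region columns (starting at
    ``step_column``) whose mean exceeds ``threshold_frac`` times the
    maximum column mean.  Measures how far junctional (not core) polarity
    propagates into the flat region.
    """
    grid = layer.grid
    if not (0 <= step_column < grid.n_cols):
        raise InvalidParameterError("step_column outside grid")
    A = layer.asymmetry()
    # lattice-boundary cells carry a spurious transverse asymmetry from the
    # missing neighbours; average over fully interior cells when any exist
    full = grid.interior_mask().all(axis=1)
    use = full if full.any() else np.ones(grid.n_cells, bool)
    cols = grid.columns
    col_mean = np.array(
        [A[use & (cols == c)].mean() if (use & (cols == c)).any() else 0.0
         for c in range(grid.n_cols)]
    )
    if col_mean.max() < 1e-9:   # numerically symmetric layer
        return 0
    thresh = threshold_frac * col_mean.max()
    count = 0
    for c in range(step_column, grid.n_cols):
        if col_mean[c] > thresh:
            count += 1
        else:
            break
    return count
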