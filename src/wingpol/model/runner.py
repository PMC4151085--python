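"""High-level drivers for standard simulation experiments.

These wrap grid construction, gradient setup, the binding layer, MT bias
and the core ODE into the named experiments of the study: gradient-shape
comparisons, the Ft-Ds propagation bound, kinetic-delay runs and clone
phenotypes.  All analysis scripts, the CLI and the acceptance checks call
these entry points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..gradients import GradientSpec, make_gradient
from ..hexgrid import HexGrid
from .clones import CloneSpec, apply_clones
from .core import CoreParams, CoreTrajectory, simulate_core
from .ftds import FtDsParams, FtDsLayerState, solve_ftds_layer, measure_propagation_columns
from .mtbias import MTBiasField, mt_bias_from_ftds
from .readout import PolarityReadout, polarity_readout, polarization_kinetics

#: default Fj profile: opposes the Ds gradient (low proximal, high distal)
def default_fj(columns: int) -> GradientSpec:
    return make_gradient("linear", columns, high=0.0, low=1.0)


def named_ds_gradient(kind: str, columns: int) -> GradientSpec:
    """The study's Ds gradient shapes on a given column count."""
    if kind == "linear":
        return make_gradient("linear", columns, high=1.0, low=0.0)
    if kind == "step":
        return make_gradient("step", columns, high=1.0, low=0.1, step_column=8)
    if kind == "steep_flat":
        return make_gradient("steep_flat", columns, high=1.0, low=0.1, ramp_columns=8)
    if kind == "zero_distal":
        return make_gradient("zero_distal", columns, high=1.0, ramp_columns=8)
    if kind == "uniform":
        return make_gradient("uniform", columns, high=0.5)
    raise ValueError(f"unknown named gradient {kind!r}")


@dataclass
class SimulationResult:
    grid: HexGrid
    layer: FtDsLayerState
    bias: MTBiasField
    trajectory: CoreTrajectory
    readout: PolarityReadout

    def interior(self) -> np.ndarray:
        return self.grid.interior_mask().all(axis=1)

    def mean_polarity(self, columns: slice | None = None) -> float:
        """Mean |P| over fully interior cells (optionally a column range)."""
        sel = self.interior()
        if not sel.any():   # tiny grids have no fully interior cells
            sel = np.ones(self.grid.n_cells, dtype=bool)
        if columns is not None:
            cols = self.grid.columns
            sel = sel & (cols >= (columns.start or 0)) & (
                cols < (columns.stop if columns.stop is not None else self.grid.n_cols)
            )
        return float(self.readout.magnitude[sel].mean())


def run_simulation(
    ds: GradientSpec | str = "linear",
    fj: GradientSpec | None = None,
    grid: HexGrid | None = None,
    mt_mode: str = "coupled",
    mt_region_min_col: int | None = None,
    clones: list[CloneSpec] | None = None,
    core_params: CoreParams = CoreParams(),
    ftds_params: FtDsParams = FtDsParams(),
    t_end: float = 1200.0,
    dt_sample: float = 5.0,
    tol_ss: float = 1e-6,
    floor: float = 0.02,
    init_noise: float = 0.0,
    seed: int | None = None,
) -> SimulationResult:
    """One full experiment: gradients -> Ft-Ds layer -> MT bias -> core ODE.

    ``mt_mode`` other than "coupled" applies to cells with column >=
    ``mt_region_min_col`` (whole grid if None).  ``clones`` may null any
    species; ft/ds clones act on the binding layer, core species on the
    core totals.
    """
    grid = grid or HexGrid(6, 30)
    if isinstance(ds, str):
        ds = named_ds_gradient(ds, grid.n_cols)
    fj = fj or default_fj(grid.n_cols)
    clones = list(clones or [])

    layer_totals = {
        "ft": np.ones(grid.n_cells),
        "ds": ds.values[grid.columns].copy(),
    }
    layer_clones = [c for c in clones if c.species in ("ft", "ds")]
    layer_totals = apply_clones(grid, layer_clones, layer_totals)
    layer = solve_ftds_layer(
        grid, layer_totals["ds"], fj, ftds_params, ft_tot=layer_totals["ft"]
    )

    region = None
    if mt_region_min_col is not None:
        region = grid.columns >= mt_region_min_col
    bias = mt_bias_from_ftds(layer, mode=mt_mode, region=region, floor=floor)

    rng = np.random.default_rng(seed) if seed is not None else None
    traj = simulate_core(
        grid, bias, clones=clones, params=core_params,
        t_end=t_end, dt_sample=dt_sample, tol_ss=tol_ss,
        init_noise=init_noise, rng=rng,
    )
    return SimulationResult(
        grid=grid, layer=layer, bias=bias, trajectory=traj,
        readout=polarity_readout(traj),
    )


def gradient_shape_comparison(
    kinds: tuple[str, ...] = ("linear", "step", "steep_flat"),
    t_end: float = 1200.0,
    **kwargs,
) -> dict[str, SimulationResult]:
    """Steady-state polarization under each named Ds gradient shape."""
    return {k: run_simulation(ds=k, t_end=t_end, **kwargs) for k in kinds}


def propagation_bound(
    step_column: int = 8,
    threshold_frac: float = 0.05,
    grid: HexGrid | None = None,
    ftds_params: FtDsParams = FtDsParams(),
) -> tuple[int, FtDsLayerState]:
    """Columns of Ft-Ds asymmetry distal to a steep Ds step (flat beyond).

    Uses a step Ds gradient and uniform Fj so the flat region carries no
    other cue; returns the column count and the solved layer.
    """
    grid = grid or HexGrid(6, 30)
    ds = make_gradient("step", grid.n_cols, high=1.0, low=0.1, step_column=step_column)
    fj = make_gradient("uniform", grid.n_cols, high=0.5)
    layer = solve_ftds_layer(grid, ds, fj, ftds_params)
    return measure_propagation_columns(layer, step_column, threshold_frac), layer


def kinetic_delay_experiment(
    columns: tuple[int, ...] = (8, 15, 23),
    mt_mode: str = "coupled",
    t_end: float = 1200.0,
    dt_sample: float = 2.0,
    **kwargs,
) -> tuple[SimulationResult, dict[int, float]]:
    """Zero-distal Ds run; returns the result and per-column t90."""
    res = run_simulation(
        ds="zero_distal", mt_mode=mt_mode,
        mt_region_min_col=8 if mt_mode != "coupled" else None,
        t_end=t_end, dt_sample=dt_sample, **kwargs,
    )
    kin = polarization_kinetics(res.trajectory, list(columns))
    return res, kin.attrs["t90"]


@dataclass
class CloneOutcome:
    result: SimulationResult
    clone_cells: tuple[int, ...]
    neighbor_cells: tuple[int, ...]
    max_neighbor_deviation_deg: float
    mean_clone_polarity: float


def clone_experiment(
    species: str,
    clone_cols: tuple[int, int] = (14, 16),
    clone_rows: tuple[int, int] = (2, 4),
    grid: HexGrid | None = None,
    **kwargs,
) -> CloneOutcome:
    """Simulate a null clone in a linearly graded field and score
    non-autonomy.

    The clone is the block rows [clone_rows) x cols [clone_cols).  The
    score is the largest angular deviation of polarity from the distal
    direction among wildtype cells adjacent to the clone; domineering
    non-autonomy shows as neighbours repolarized away from +x.
    """
    grid = grid or HexGrid(6, 30)
    clone = CloneSpec.block(
        grid, species, clone_rows[0], clone_cols[0],
        clone_rows[1] - clone_rows[0], clone_cols[1] - clone_cols[0],
    )
    res = run_simulation(ds="linear", grid=grid, clones=[clone], **kwargs)
    clone_set = set(clone.cells)
    neighbors = sorted(
        {int(j) for i in clone.cells for j in grid.neighbor[i] if j >= 0} - clone_set
    )
    ang = res.readout.angle_deg[neighbors]
    dev = np.abs((ang + 180.0) % 360.0 - 180.0)   # deviation from 0 (distal)
    mag = res.readout.magnitude
    # ignore unpolarized neighbours (deviation is noise there)
    strong = mag[neighbors] > 0.1 * np.median(mag[res.interior()])
    max_dev = float(dev[strong].max()) if strong.any() else 0.0
    return CloneOutcome(
        result=res,
        clone_cells=clone.cells,
        neighbor_cells=tuple(neighbors),
        max_neighbor_deviation_deg=max_dev,
        mean_clone_polarity=float(mag[list(clone.cells)].mean()),
    )
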