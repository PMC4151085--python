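"""Polarity readouts: per-cell Dsh vector sums and polarization kinetics.

The model's observable, matching what the Dsh reporter shows in imaging, is
the per-cell vector sum of membrane-associated Dsh over the six edges.  A
cell fully polarized along +x (distal) has angle 0 and magnitude equal to
the Dsh on its distal edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..errors import InvalidParameterError
from ..hexgrid import EDGE_NORMALS, HexGrid
from .core import CoreTrajectory


@dataclass(frozen=True)
class PolarityReadout:
    """Per-cell polarity vectors at one time point.

    ``P`` (n_cells, 2) is the vector sum of membrane Dsh times the outward
    edge normals; ``boundary_dsh`` (n_cells, 6) is the combined Dsh on both
    sides of each shared boundary (what light microscopy would see).
    """

    grid: HexGrid
    time: float
    P: np.ndarray
    dsh_edge: np.ndarray
    boundary_dsh: np.ndarray

    @property
    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.P, axis=1)

    @property
    def angle_deg(self) -> np.ndarray:
        """Polarity angle in degrees in [0, 360); 0 = distal (+x)."""
        return np.degrees(np.arctan2(self.P[:, 1], self.P[:, 0])) % 360.0


def polarity_readout(traj: CoreTrajectory, k: int = -1) -> PolarityReadout:
    """Build the polarity readout from trajectory sample ``k`` (default last)."""
    dsh_edge = traj.dsh_edge(k)
    P = (dsh_edge[:, :, None] * EDGE_NORMALS[None, :, :]).sum(axis=1)
    jj, ee = traj.grid.partner_edges()
    interior = traj.grid.interior_mask()
    boundary = dsh_edge + np.where(interior, dsh_edge[jj, ee], 0.0)
    return PolarityReadout(
        grid=traj.grid,
        time=float(traj.times[k]),
        P=P,
        dsh_edge=dsh_edge,
        boundary_dsh=boundary,
    )


def render_polarity(readout: PolarityReadout) -> pd.DataFrame:
    """Cell-map table for plotting hair-like polarity vectors.

    One row per cell: row, col, centre coordinates, polarity components,
    magnitude, angle, plus the combined boundary Dsh per edge slot.
    """
    g = readout.grid
    centers = g.centers()
    rows, cols = np.divmod(np.arange(g.n_cells), g.n_cols)
    df = pd.DataFrame(
        {
            "cell": np.arange(g.n_cells),
            "row": rows,
            "col": cols,
            "x": centers[:, 0],
            "y": centers[:, 1],
            "Px": readout.P[:, 0],
            "Py": readout.P[:, 1],
            "magnitude": readout.magnitude,
            "angle_deg": readout.angle_deg,
        }
    )
    for e in range(6):
        df[f"boundary_dsh_e{e}"] = readout.boundary_dsh[:, e]
    return df


def polarization_kinetics(
    traj: CoreTrajectory,
    columns: list[int] | tuple[int, ...],
    *,
    frac: float = 0.9,
) -> pd.DataFrame:
    """Mean polarity magnitude per column over time, with time-to-90%.

    Returns a tidy frame (time, column, mean_magnitude) whose ``attrs``
    carry ``t90`` (per requested column, time at which the column mean
    first reaches ``frac`` of its final value) and ``steady`` (whether the
    trajectory reached steady state; if not, t90 values carry a warning
    flag in ``attrs['warning']``).
    """
    g = traj.grid
    for c in columns:
        if not (0 <= c < g.n_cols):
            raise InvalidParameterError(f"column {c} outside grid")
    dsh = traj.edge["M"] + traj.edge["DF"] + traj.edge["C1"]
    P = (dsh[:, :, :, None] * EDGE_NORMALS[None, None, :, :]).sum(axis=2)
    mag = np.linalg.norm(P, axis=2)  # (n_times, n_cells)
    col_of = g.columns
    records = []
    t90 = {}
    for c in columns:
        series = mag[:, col_of == c].mean(axis=1)
        final = series[-1]
        if final > 0:
            above = np.nonzero(series >= frac * final)[0]
            t90[c] = float(traj.times[above[0]]) if above.size else float("nan")
        else:
            t90[c] = float("nan")
        for t, v in zip(traj.times, series):
            records.append({"time": t, "column": c, "mean_magnitude": v})
    df = pd.DataFrame.from_records(records)
    df.attrs["t90"] = t90
    df.attrs["steady"] = bool(traj.steady)
    if not traj.steady:
        df.attrs["warning"] = "trajectory did not reach steady state; t90 is provisional"
    return df
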