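import numpy as np
import pytest
from scipy.optimize import least_squares

from wingpol.errors import InvalidParameterError
from wingpol.gradients import make_gradient
from wingpol.hexgrid import HexGrid
from wingpol.model import (
    FtDsParams, measure_propagation_columns, solve_ftds_layer,
)


def brute_force_1x3(ds_levels, fj_levels, params):
    """Independent fixed-point solve of the 1x3 chain with mirror boundaries.

    Unknowns: free Ft and free Ds per cell; H on every (cell, edge) follows
    from the mass-action equilibrium.  Solved with scipy least_squares on
    the conservation residuals, no shared code with the package solver.
    """
    g = HexGrid(1, 3)
    K = params.k_on / params.k_off
    a_ft = 1.0 + params.alpha_ft * np.asarray(fj_levels)
    a_ds = 1.0 / (1.0 + params.alpha_ds * np.asarray(fj_levels))
    nbr = [[g.neighbor[i, e] if g.neighbor[i, e] >= 0 else i for e in range(6)]
           for i in range(3)]

    def residual(z):
        ftf, dsf = z[:3], z[3:]
        r = np.zeros(6)
        for i in range(3):
            bound_ft = sum(
                K * a_ft[i] * a_ds[nbr[i][e]] * ftf[i] * dsf[nbr[i][e]]
                for e in range(6)
            )
            bound_ds = sum(
                K * a_ft[nbr[i][e]] * a_ds[i] * ftf[nbr[i][e]] * dsf[i]
                for e in range(6)
            )
            r[i] = ftf[i] + bound_ft - 1.0
            r[3 + i] = dsf[i] + bound_ds - ds_levels[i]
        return r

    sol = least_squares(residual, x0=np.full(6, 0.3), bounds=(0, np.inf),
                        xtol=1e-15, ftol=1e-15, gtol=1e-15)
    ftf, dsf = sol.x[:3], sol.x[3:]
    H = np.zeros((3, 6))
    for i in range(3):
        for e in range(6):
            j = nbr[i][e]
            H[i, e] = K * a_ft[i] * a_ds[j] * ftf[i] * dsf[j]
    return H


def test_uniform_tissue_has_symmetric_occupancy_and_zero_bias(small_grid):
    ds = make_gradient("uniform", small_grid.n_cols, high=0.8)
    fj = make_gradient("uniform", small_grid.n_cols, high=0.3)
    layer = solve_ftds_layer(small_grid, ds, fj)
    assert np.allclose(layer.H, layer.H[0, 0])
    assert np.allclose(layer.bias_vectors(), 0.0, atol=1e-10)


def test_oracle_equivalence_on_1x3_chain():
    g = HexGrid(1, 3)
    ds_levels = [1.0, 0.6, 0.2]
    fj_levels = [0.1, 0.5, 0.9]
    params = FtDsParams()
    layer = solve_ftds_layer(
        g,
        np.array(ds_levels),
        np.array(fj_levels),
        params,
    )
    H_ref = brute_force_1x3(ds_levels, fj_levels, params)
    assert np.abs(layer.H - H_ref).max() < 1e-8


def test_decreasing_ds_gradient_anchors_ft_proximally(default_grid):
    ds = make_gradient("linear", 30, high=1.0, low=0.0)
    fj = make_gradient("uniform", 30, high=0.5)
    layer = solve_ftds_layer(default_grid, ds, fj)
    interior = default_grid.interior_mask().all(axis=1)
    # bound Ft on the proximal edge (toward high Ds) exceeds the distal edge
    assert np.all(layer.H[interior, 3] > layer.H[interior, 0])
    # so the MT bias (plus ends) points distally
    assert np.all(layer.bias_vectors()[interior, 0] > 0)


def test_ft_null_clone_neighbors_accumulate_ft_facing_clone(default_grid):
    g = default_grid
    ds = make_gradient("uniform", 30, high=0.8)
    fj = make_gradient("uniform", 30, high=0.3)
    ft_tot = np.ones(g.n_cells)
    clone = [g.cell_index(2, 14), g.cell_index(2, 15), g.cell_index(3, 14)]
    ft_tot[clone] = 0.0
    layer = solve_ftds_layer(g, ds, fj, ft_tot=ft_tot)
    # wildtype cell just proximal of the clone: clone-facing (distal) edge
    # binds the clone's un-competed Ds hardest
    wt = g.cell_index(2, 13)
    assert layer.H[wt].argmax() == 0
    assert layer.H[wt, 0] > 1.2 * layer.H[wt, 3]


def test_conservation_of_totals(default_grid):
    ds = make_gradient("linear", 30, high=1.0, low=0.1)
    fj = make_gradient("linear", 30, high=0.0, low=1.0)
    layer = solve_ftds_layer(default_grid, ds, fj)
    jj, ee = default_grid.partner_edges()
    bound_ds = layer.H[jj, ee]   # Ds of cell i bound at edge e
    ft_total = layer.ft_free + layer.H.sum(axis=1)
    ds_total = layer.ds_free + bound_ds.sum(axis=1)
    assert np.allclose(ft_total, layer.ft_tot, atol=1e-9)
    assert np.allclose(ds_total, layer.ds_tot, atol=1e-9)


def test_gradient_length_mismatch_rejected(small_grid):
    ds = make_gradient("linear", small_grid.n_cols + 1)
    fj = make_gradient("uniform", small_grid.n_cols, high=0.5)
    with pytest.raises(InvalidParameterError):
        solve_ftds_layer(small_grid, ds, fj)


class TestPropagation:
    def test_uniform_ds_gives_zero_columns(self, default_grid):
        ds = make_gradient("uniform", 30, high=0.5)
        fj = make_gradient("uniform", 30, high=0.5)
        layer = solve_ftds_layer(default_grid, ds, fj)
        assert measure_propagation_columns(layer, 8) == 0

    def test_steep_step_propagates_at_most_two_columns(self, default_grid):
        ds = make_gradient("step", 30, high=1.0, low=0.1, step_column=8)
        fj = make_gradient("uniform", 30, high=0.5)
        layer = solve_ftds_layer(default_grid, ds, fj)
        assert measure_propagation_columns(layer, 8) <= 2

    def test_hand_enumerated_1x3_case(self):
        # 1x3 chain with a hard step: high Ds on the proximal cell only
        g = HexGrid(1, 3)
        layer = solve_ftds_layer(
            g, np.array([1.0, 0.0, 0.0]), np.array([0.5, 0.5, 0.5])
        )
        # cells 1 and 2 have zero Ds everywhere except cell 1's proximal
        # junction with cell 0, so only column 1 carries asymmetry
        assert measure_propagation_columns(layer, 1, threshold_frac=0.05) == 1

    def test_step_outside_grid_rejected(self, default_grid):
        ds = make_gradient("uniform", 30, high=0.5)
        fj = make_gradient("uniform", 30, high=0.5)
        layer = solve_ftds_layer(default_grid, ds, fj)
        with pytest.raises(InvalidParameterError):
            measure_propagation_columns(layer, 30)
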