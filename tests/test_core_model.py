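import dataclasses

import numpy as np
import pytest

from wingpol.errors import InvalidParameterError
from wingpol.gradients import make_gradient
from wingpol.hexgrid import HexGrid
from wingpol.model import (
    CloneSpec, CoreParams, mt_bias_from_ftds, simulate_core, solve_ftds_layer,
    polarity_readout,
)
from wingpol.model.core import make_rhs, _initial_state


@pytest.fixture(scope="module")
def grid():
    return HexGrid(4, 8)


@pytest.fixture(scope="module")
def graded_bias(grid):
    layer = solve_ftds_layer(
        grid,
        make_gradient("linear", 8, high=1.0, low=0.0),
        make_gradient("linear", 8, high=0.0, low=1.0),
    )
    return mt_bias_from_ftds(layer)


@pytest.fixture(scope="module")
def uniform_bias(grid):
    layer = solve_ftds_layer(
        grid,
        make_gradient("uniform", 8, high=0.5),
        make_gradient("uniform", 8, high=0.5),
    )
    return mt_bias_from_ftds(layer, mode="random")


@pytest.fixture(scope="module")
def graded_traj(grid, graded_bias):
    return simulate_core(grid, graded_bias, t_end=800.0, dt_sample=10.0)


def test_numba_and_numpy_rhs_agree(grid, graded_bias, rng):
    p = CoreParams()
    r_np = make_rhs(grid, graded_bias, p, numpy_only=True)
    r_nb = make_rhs(grid, graded_bias, p)
    y0, _ = _initial_state(grid, p, [], None, 0.0)
    y = y0 + 0.01 * rng.random(y0.size)
    assert np.abs(r_np(0.0, y) - r_nb(0.0, y)).max() < 1e-12


def test_symmetric_tissue_stays_unpolarized(grid, uniform_bias):
    traj = simulate_core(grid, uniform_bias, t_end=300.0, dt_sample=50.0)
    ro = polarity_readout(traj)
    assert ro.magnitude.max() < 1e-12
    # and at every sampled time, not only the end
    for k in range(traj.n_times):
        P = polarity_readout(traj, k).magnitude
        assert P.max() < 1e-12


def test_graded_field_polarizes_distally(grid, graded_traj):
    ro = polarity_readout(graded_traj)
    interior = grid.interior_mask().all(axis=1)
    assert ro.magnitude[interior].min() > 0.1
    dev = np.abs((ro.angle_deg[interior] + 180.0) % 360.0 - 180.0)
    assert dev.max() < 15.0


def test_per_cell_totals_conserved(graded_traj):
    err = graded_traj.conservation_error()
    for name, e in err.items():
        assert e < 1e-6, name


def test_fz_null_cells_never_form_dsh_fz(grid, graded_bias):
    clone = CloneSpec("fz", (grid.cell_index(1, 3), grid.cell_index(2, 3)))
    traj = simulate_core(grid, graded_bias, clones=[clone], t_end=300.0, dt_sample=50.0)
    cells = list(clone.cells)
    assert np.abs(traj.edge["DF"][:, cells]).max() == 0.0
    assert np.abs(traj.edge["C1"][:, cells]).max() == 0.0
    # wildtype cells do form complexes
    assert traj.edge["C1"][-1].max() > 0.01


def test_polarity_persists_after_cue_removal(grid, graded_traj, uniform_bias):
    from wingpol.model.core import EDGE_SPECIES
    y_last = np.concatenate(
        [graded_traj.cell["Dc"][-1], graded_traj.cell["Pc"][-1]]
        + [graded_traj.edge[k][-1].ravel() for k in EDGE_SPECIES]
    )
    relaxed = simulate_core(grid, uniform_bias, t_end=600.0, dt_sample=100.0, y0=y_last)
    interior = grid.interior_mask().all(axis=1)
    before = polarity_readout(graded_traj).magnitude[interior].mean()
    after = polarity_readout(relaxed).magnitude[interior].mean()
    assert after > 0.6 * before
    dev = np.abs((polarity_readout(relaxed).angle_deg[interior] + 180) % 360 - 180)
    assert np.median(dev) < 20.0


def test_step_size_robustness(grid, graded_bias):
    kw = dict(t_end=400.0, dt_sample=100.0, tol_ss=0.0)
    t1 = simulate_core(grid, graded_bias, max_step=0.5, **kw)
    t2 = simulate_core(grid, graded_bias, max_step=0.25, **kw)
    interior = grid.interior_mask().all(axis=1)
    p1 = polarity_readout(t1).magnitude[interior].mean()
    p2 = polarity_readout(t2).magnitude[interior].mean()
    assert abs(p1 - p2) / p1 < 1e-3


def test_transport_rate_does_not_decrease_polarity(grid, graded_bias):
    means = []
    for k_T in (0.05, 0.1, 0.2):
        p = dataclasses.replace(CoreParams(), k_T=k_T)
        traj = simulate_core(grid, graded_bias, params=p, t_end=600.0, dt_sample=100.0)
        interior = grid.interior_mask().all(axis=1)
        means.append(polarity_readout(traj).magnitude[interior].mean())
    assert means[0] <= means[1] + 1e-3
    assert means[1] <= means[2] + 1e-3


def test_init_noise_requires_rng(grid, graded_bias):
    with pytest.raises(InvalidParameterError):
        simulate_core(grid, graded_bias, init_noise=0.1, t_end=10.0)


def test_seeded_noise_is_reproducible(grid, uniform_bias):
    a = simulate_core(grid, uniform_bias, t_end=50.0, dt_sample=25.0,
                      init_noise=0.05, rng=np.random.default_rng(3))
    b = simulate_core(grid, uniform_bias, t_end=50.0, dt_sample=25.0,
                      init_noise=0.05, rng=np.random.default_rng(3))
    assert np.array_equal(a.edge["F"][-1], b.edge["F"][-1])
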