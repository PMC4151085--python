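"""Core planar-cell-polarity reaction network on the cell grid.

Species
-------
Per cell (well-mixed cytoplasmic pools):

* ``Dc`` — cytoplasmic Dsh
* ``Pc`` — cytoplasmic Pk

Per (cell, edge) membrane compartment:

* ``F``  — free Fz
* ``V``  — free Vang
* ``M``  — membrane Dsh (delivered by directed transport, not Fz-bound)
* ``DF`` — Dsh-Fz complex (unbridged)
* ``PV`` — membrane Pk, bound at Vang-rich membrane (the "proximal"
  complex); it sequesters Pk but not Vang, which stays available for
  intercellular bridges
* ``C0`` — intercellular bridge Fz(i) : Vang(neighbour), no Dsh
* ``C1`` — intercellular bridge DshFz(i) : Vang(neighbour)

Bridges are indexed on their Fz side; the Vang they hold belongs to the
neighbour across the junction.

Reactions
---------
1. Directed transport: ``Dc -> M(i,e)`` at ``k_T * m(i,e) * Dc``;
   return flux ``k_ret * M``.  ``m`` comes from the MT bias field.
2. Dsh capture: ``M + F -> DF`` and ``M + C0 -> C1`` at rate
   ``k1 * (1 + chi * (DF + C1)) * phi / (1 + beta * PV(i,e))`` — capture
   is autocatalytic (Fz-Dsh clusters recruit more Dsh, the cooperative
   nonlinearity of this model family), membrane Pk inhibits it
   (intracellular antagonism), and ``phi = max(0, 1 - (DF+C0+C1)/site_cap)``
   encodes a finite junctional scaffold: each edge holds at most
   ``site_cap`` Fz-side complexes, so a saturated winning edge overflows
   into its neighbours and the fully polarized pattern (complexes on the
   distal half of the cell) is the same whether or not delivery is
   focused; reverse ``k1_off``.  Existing clusters also recruit Dsh
   directly from the cytoplasm: ``Dc + F -> DF`` at
   ``k1_cyto * Dc * F * (DF + C1) * phi / (1 + beta * PV)`` — zero
   without clusters, so nucleation (and hence kinetics) is controlled by
   MT-delivered Dsh while the saturated amplitude is not.
3. Bridge formation across each junction: ``F(i,e) + V(j,e') -> C0``
   (rate ``k2 * phi``, occupying a site) and ``DF(i,e) + V(j,e') -> C1``
   at ``k2`` (conversion, no new site); dissociation ``k2_off`` for
   ``C0`` and ``s_D * k2_off`` for ``C1`` (Dsh-bound bridges are
   stabilized; the same factor slows Dsh release from the bridged
   complex, making ``C1`` the long-lived polarity ratchet).
4. Pk recruitment: ``Pc -> PV(i,e)`` at rate
   ``k3 * Vtot(i,e) * (1 + delta * H(S(j,e'))) / (1 + beta2 * (DF + C1)(i,e))``
   where ``Vtot`` is total local Vang (free plus bridge-held),
   ``S = DF + C1 + gamma0 * C0`` on the apposed membrane and
   ``H(S) = S^n / (K^n + S^n)`` is a cooperative switch
   (trans-junctional recruitment by Fz-side complexes turns on sharply
   once the apposed Dsh-Fz signal crosses ``hill_K``; Dsh-Fz on the
   *same* membrane antagonizes recruitment — the intracellular arm of the
   mutual feedback); reverse ``k3_off``.
5. Lateral diffusion: hopping of the free species ``F, V, M`` between
   adjacent edges of the same cell at rate ``D_m``; bound complexes
   (``DF, PV, C0, C1``) are junction-anchored and do not diffuse.

No synthesis or degradation: per-cell totals of Dsh, Fz, Vang and Pk are
conserved.  Cytoplasmic pools are well mixed.  The lattice boundary is
mirror-reflective: a boundary edge is apposed to the cell's own mirror
image (bridges pair the edge with itself), so nothing crosses the tissue
edge and a uniform tissue is an exact fixed point out to the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from ..errors import IntegrationError, InvalidParameterError
from ..hexgrid import HexGrid
from . import _kernels as _k
from .clones import CloneSpec, apply_clones
from .mtbias import MTBiasField

EDGE_SPECIES = ("F", "V", "M", "DF", "PV", "C0", "C1")


@dataclass(frozen=True)
class CoreParams:
    """Rate constants of the core feedback network (nondimensional)."""

    k_T: float = 0.1        # directed Dsh delivery
    k_ret: float = 10.0     # Dsh return to cytoplasm
    k1: float = 20.0         # Dsh-Fz association
    k1_off: float = 0.5    # Dsh-Fz dissociation
    chi: float = 0.0       # autocatalytic Dsh-Fz capture (cooperativity)
    k1_cyto: float = 5.0    # cluster-driven Dsh recruitment from cytoplasm
    site_cap: float = 0.25   # junctional scaffold capacity per edge
    beta: float = 200.0      # membrane-Pk inhibition of Dsh-Fz association
    k2: float = 5.0         # Fz:Vang bridge formation
    k2_off: float = 1.0     # bridge dissociation (Dsh-free)
    s_D: float = 0.02        # stabilization factor for Dsh-bound bridges
    k3: float = 1.0         # Pk-Vang recruitment
    k3_off: float = 2.0     # Pk-Vang dissociation
    delta: float = 200.0     # trans-junctional enhancement of recruitment
    hill_K: float = 0.1     # half-activation of the trans signal
    hill_n: float = 4.0     # cooperativity of the trans signal
    beta2: float = 10.0     # Dsh-Fz inhibition of same-membrane recruitment
    gamma0: float = 0.1     # weight of Dsh-free bridges in the trans signal
    D_m: float = 0.5        # lateral membrane diffusion between edges
    # totals per cell (uniform unless clones modify them)
    fz_tot: float = 1.0
    vang_tot: float = 1.0
    dsh_tot: float = 1.0
    pk_tot: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k_T", "k_ret", "k1", "k2", "k3"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.s_D < 0 or self.D_m < 0:
            raise InvalidParameterError("s_D and D_m must be >= 0")


@dataclass
class CoreTrajectory:
    """Sampled trajectory of the core network.

    ``edge[name]`` has shape (n_times, n_cells, 6); ``cell[name]`` has
    shape (n_times, n_cells).
    """

    grid: HexGrid
    params: CoreParams
    times: np.ndarray
    cell: dict[str, np.ndarray]
    edge: dict[str, np.ndarray]
    totals: dict[str, np.ndarray]
    steady: bool
    steady_residual: float

    @property
    def n_times(self) -> int:
        return self.times.size

    def dsh_edge(self, k: int | slice = slice(None)) -> np.ndarray:
        """Membrane-associated Dsh per edge (M + DF + C1) at time index k."""
        return self.edge["M"][k] + self.edge["DF"][k] + self.edge["C1"][k]

    def conservation_error(self) -> dict[str, float]:
        """Max relative drift of each per-cell total along the trajectory."""
        g = self.grid
        jj, ee = g.partner_edges()
        out = {}
        e = self.edge
        tot_dsh = self.cell["Dc"] + (e["M"] + e["DF"] + e["C1"]).sum(axis=2)
        tot_fz = (e["F"] + e["DF"] + e["C0"] + e["C1"]).sum(axis=2)
        # Vang held in bridges is indexed on the partner's Fz side
        # (mirror boundary edges hold their own Vang)
        bridge_v = (e["C0"] + e["C1"])[:, jj, ee]
        tot_vang = e["V"].sum(axis=2) + bridge_v.sum(axis=2)
        tot_pk = self.cell["Pc"] + e["PV"].sum(axis=2)
        for name, tot in (
            ("dsh", tot_dsh), ("fz", tot_fz), ("vang", tot_vang), ("pk", tot_pk)
        ):
            ref = np.maximum(np.abs(tot[0]), 1e-30)
            out[name] = float(np.abs(tot - tot[0]).max() / ref.max())
        return out


def _initial_state(
    grid: HexGrid, params: CoreParams, clones: list[CloneSpec],
    rng: np.random.Generator | None, noise: float,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    n = grid.n_cells
    totals = {
        "fz": np.full(n, params.fz_tot),
        "vang": np.full(n, params.vang_tot),
        "dsh": np.full(n, params.dsh_tot),
        "pk": np.full(n, params.pk_tot),
    }
    core_clones = [c for c in clones if c.species in totals]
    totals = apply_clones(grid, core_clones, totals)
    F = np.repeat(totals["fz"][:, None] / 6.0, 6, axis=1)
    V = np.repeat(totals["vang"][:, None] / 6.0, 6, axis=1)
    if noise > 0:
        if rng is None:
            raise InvalidParameterError("initial noise requires a seeded rng")
        F = F * (1.0 + noise * rng.standard_normal(F.shape)).clip(min=0.0)
        V = V * (1.0 + noise * rng.standard_normal(V.shape)).clip(min=0.0)
    Dc = totals["dsh"].copy()
    Pc = totals["pk"].copy()
    zeros = np.zeros((n, 6))
    y0 = np.concatenate(
        [Dc, Pc] + [arr.ravel() for arr in (F, V, zeros, zeros, zeros, zeros, zeros)]
    )
    return y0, totals


def _unpack(y: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    Dc = y[:n]
    Pc = y[n: 2 * n]
    edges = {}
    off = 2 * n
    for name in EDGE_SPECIES:
        edges[name] = y[off: off + 6 * n].reshape(n, 6)
        off += 6 * n
    return Dc, Pc, edges


def make_rhs(grid: HexGrid, bias: MTBiasField, params: CoreParams, *, numpy_only: bool = False):
    """Time-derivative of the packed state vector.

    Uses the numba kernel when available; ``numpy_only`` forces the
    reference numpy implementation (used by the equivalence test).
    """
    n = grid.n_cells
    jj, ee = grid.partner_edges()
    flat_partner = (jj * 6 + ee).ravel()
    m = bias.m
    p = params

    if _k.HAVE_NUMBA and not numpy_only:
        partner = np.ascontiguousarray(flat_partner)
        m_flat = np.ascontiguousarray(m.ravel())

        def rhs(t: float, y: np.ndarray) -> np.ndarray:
            out = np.empty_like(y)
            _k.core_rhs_kernel(
                y, out, partner, m_flat,
                p.k_T, p.k_ret, p.k1, p.k1_off, p.chi, p.k1_cyto, p.site_cap,
                p.beta, p.k2, p.k2_off, p.s_D, p.k3, p.k3_off, p.delta,
                p.hill_K, p.hill_n, p.beta2, p.gamma0, p.D_m, n,
            )
            return out

        return rhs

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        Dc, Pc, E = _unpack(y, n)
        F, V, M, DF, PV, C0, C1 = (E[k] for k in EDGE_SPECIES)

        # mirror boundary: partner of a boundary edge is the edge itself
        V_across = V[jj, ee]
        S_across = (DF + C1 + p.gamma0 * C0)[jj, ee]
        # Vang held at this membrane by bridges (indexed on partner's Fz side)
        v_bridged = (C0 + C1)[jj, ee]

        r_T = p.k_T * m * Dc[:, None]
        r_ret = p.k_ret * M
        phi = np.clip(1.0 - (DF + C0 + C1) / p.site_cap, 0.0, None)
        coop = 1.0 + p.chi * (DF + C1)
        inh = phi * coop / (1.0 + p.beta * PV)
        r_1 = p.k1 * M * F * inh
        r_1b = p.k1 * M * C0 * coop / (1.0 + p.beta * PV)
        r_1c = p.k1_cyto * Dc[:, None] * F * (DF + C1) * phi / (1.0 + p.beta * PV)
        r_1r = p.k1_off * DF
        r_1br = p.s_D * p.k1_off * C1   # Dsh release is slowed in stabilized bridges
        r_2 = p.k2 * F * V_across * phi
        r_2r = p.k2_off * C0
        r_2d = p.k2 * DF * V_across
        r_2dr = p.s_D * p.k2_off * C1
        Sn = S_across ** p.hill_n
        hill = Sn / (p.hill_K ** p.hill_n + Sn)
        r_3 = (
            p.k3 * Pc[:, None] * (V + v_bridged) * (1.0 + p.delta * hill)
            / (1.0 + p.beta2 * (DF + C1))
        )
        r_3r = p.k3_off * PV

        dDc = -p.k_T * Dc + r_ret.sum(axis=1) - r_1c.sum(axis=1)
        dPc = (-r_3 + r_3r).sum(axis=1)
        dM = r_T - r_ret - r_1 - r_1b + r_1r + r_1br
        dF = -r_1 - r_1c + r_1r - r_2 + r_2r
        dDF = r_1 + r_1c - r_1r - r_2d + r_2dr
        dC0 = r_2 - r_2r - r_1b + r_1br
        dC1 = r_2d + r_1b - r_2dr - r_1br
        dV = np.zeros_like(V)
        dPV = r_3 - r_3r

        # bridge formation consumes free Vang on the apposed membrane;
        # the junction pairing is a permutation, so a fancy-indexed add
        # touches each target exactly once
        v_flux = (-r_2 - r_2d + r_2r + r_2dr).ravel()
        dV_flat = dV.ravel()
        dV_flat[flat_partner] += v_flux
        dV = dV_flat.reshape(n, 6)

        if p.D_m > 0:
            for arr, darr in ((F, dF), (V, dV), (M, dM)):
                darr += p.D_m * (
                    np.roll(arr, 1, axis=1) + np.roll(arr, -1, axis=1) - 2.0 * arr
                )

        return np.concatenate(
            [dDc, dPc]
            + [d.ravel() for d in (dF, dV, dM, dDF, dPV, dC0, dC1)]
        )

    return rhs


def simulate_core(
    grid: HexGrid,
    bias: MTBiasField,
    clones: list[CloneSpec] | None = None,
    params: CoreParams = CoreParams(),
    *,
    t_end: float = 1200.0,
    dt_sample: float = 5.0,
    tol_ss: float = 1e-6,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    init_noise: float = 0.0,
    rng: np.random.Generator | None = None,
    max_step: float = np.inf,
    y0: np.ndarray | None = None,
) -> CoreTrajectory:
    """Integrate the core network to steady state (or ``t_end``).

    The system is integrated in chunks; after each chunk the chunk-averaged
    rate of change ``max|y(t+T) - y(t)| / T`` is evaluated and integration
    stops early once it falls below ``tol_ss`` (robust against fast,
    bounded micro-dynamics that keep the instantaneous derivative large).
    Raises :class:`IntegrationError` on NaN or on negative concentrations
    beyond integration tolerance.
    """
    clones = list(clones or [])
    if y0 is None:
        y0, totals = _initial_state(grid, params, clones, rng, init_noise)
    else:
        y0 = np.asarray(y0, dtype=float).copy()
        _, _, E0 = _unpack(y0, grid.n_cells)
        totals = {
            "fz": (E0["F"] + E0["DF"] + E0["C0"] + E0["C1"]).sum(axis=1),
            "dsh": y0[: grid.n_cells]
            + (E0["M"] + E0["DF"] + E0["C1"]).sum(axis=1),
        }
    rhs = make_rhs(grid, bias, params)
    n = grid.n_cells

    times = [0.0]
    states = [y0.copy()]
    t = 0.0
    y = y0
    steady = False
    resid = float(np.abs(rhs(0.0, y)).max())
    chunk = max(dt_sample * 25.0, 10.0)
    while t < t_end - 1e-12:
        t_next = min(t + chunk, t_end)
        t_eval = np.arange(t + dt_sample, t_next + dt_sample / 2, dt_sample)
        y_chunk_start, t_chunk_start = y, t
        sol = solve_ivp(
            rhs, (t, t_next), y, method="RK45", t_eval=t_eval,
            rtol=rtol, atol=atol, max_step=max_step,
        )
        if not sol.success:
            raise IntegrationError(f"integrator failed at t={t:.3f}: {sol.message}")
        if np.any(~np.isfinite(sol.y)):
            raise IntegrationError(f"NaN in state during chunk starting t={t:.3f}")
        times.extend(sol.t.tolist())
        states.extend(list(sol.y.T))
        y = sol.y[:, -1]
        t = t_next
        if y.min() < -1000 * atol:
            raise IntegrationError(
                f"negative concentration {y.min():.3e} at t={t:.3f}"
            )
        resid = float(np.abs(y - y_chunk_start).max() / (t_next - t_chunk_start))
        if resid < tol_ss:
            steady = True
            break

    arr = np.stack(states, axis=0)
    tarr = np.asarray(times)
    cell = {"Dc": arr[:, :n], "Pc": arr[:, n: 2 * n]}
    edge = {}
    off = 2 * n
    for name in EDGE_SPECIES:
        edge[name] = arr[:, off: off + 6 * n].reshape(arr.shape[0], n, 6)
        off += 6 * n
    return CoreTrajectory(
        grid=grid, params=params, times=tarr, cell=cell, edge=edge,
        totals=totals, steady=steady, steady_residual=resid,
    )
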