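"""Numba-accelerated time derivative of the core network.

Same mathematics as the numpy implementation in ``core.make_rhs``; kept in
one flat-array kernel so the ODE integrator's inner loop is cheap.  The
numpy path remains the reference implementation and the test suite checks
the two agree to machine precision.
"""

from __future__ import annotations

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency normally
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True, fastmath=False)
def core_rhs_kernel(
    y, out, partner, m,
    k_T, k_ret, k1, k1_off, chi, k1_cyto, site_cap, beta,
    k2, k2_off, s_D, k3, k3_off, delta, hill_K, hill_n, beta2, gamma0, D_m,
    n,
):
    ne = 6 * n
    # views into the packed state
    Dc = y[0:n]
    Pc = y[n:2 * n]
    F = y[2 * n + 0 * ne: 2 * n + 1 * ne]
    V = y[2 * n + 1 * ne: 2 * n + 2 * ne]
    M = y[2 * n + 2 * ne: 2 * n + 3 * ne]
    DF = y[2 * n + 3 * ne: 2 * n + 4 * ne]
    PV = y[2 * n + 4 * ne: 2 * n + 5 * ne]
    C0 = y[2 * n + 5 * ne: 2 * n + 6 * ne]
    C1 = y[2 * n + 6 * ne: 2 * n + 7 * ne]

    dDc = out[0:n]
    dPc = out[n:2 * n]
    dF = out[2 * n + 0 * ne: 2 * n + 1 * ne]
    dV = out[2 * n + 1 * ne: 2 * n + 2 * ne]
    dM = out[2 * n + 2 * ne: 2 * n + 3 * ne]
    dDF = out[2 * n + 3 * ne: 2 * n + 4 * ne]
    dPV = out[2 * n + 4 * ne: 2 * n + 5 * ne]
    dC0 = out[2 * n + 5 * ne: 2 * n + 6 * ne]
    dC1 = out[2 * n + 6 * ne: 2 * n + 7 * ne]
    out[:] = 0.0

    for i in range(n):
        dc = Dc[i]
        pc = Pc[i]
        sum_ret = 0.0
        sum_r1c = 0.0
        sum_r3 = 0.0
        sum_r3r = 0.0
        for e in range(6):
            idx = 6 * i + e
            p = partner[idx]
            v_across = V[p]
            s_across = DF[p] + C1[p] + gamma0 * C0[p]
            v_bridged = C0[p] + C1[p]

            occ = DF[idx] + C0[idx] + C1[idx]
            phi = 1.0 - occ / site_cap
            if phi < 0.0:
                phi = 0.0
            coop = 1.0 + chi * (DF[idx] + C1[idx])
            inv_pv = 1.0 / (1.0 + beta * PV[idx])

            r_T = k_T * m[idx] * dc
            r_ret = k_ret * M[idx]
            r_1 = k1 * M[idx] * F[idx] * phi * coop * inv_pv
            r_1b = k1 * M[idx] * C0[idx] * coop * inv_pv
            r_1c = k1_cyto * dc * F[idx] * (DF[idx] + C1[idx]) * phi * inv_pv
            r_1r = k1_off * DF[idx]
            r_1br = s_D * k1_off * C1[idx]
            r_2 = k2 * F[idx] * v_across * phi
            r_2r = k2_off * C0[idx]
            r_2d = k2 * DF[idx] * v_across
            r_2dr = s_D * k2_off * C1[idx]

            sn = s_across ** hill_n
            hill = sn / (hill_K ** hill_n + sn) if sn > 0.0 else 0.0
            r_3 = (
                k3 * pc * (V[idx] + v_bridged) * (1.0 + delta * hill)
                / (1.0 + beta2 * (DF[idx] + C1[idx]))
            )
            r_3r = k3_off * PV[idx]

            sum_ret += r_ret
            sum_r1c += r_1c
            sum_r3 += r_3
            sum_r3r += r_3r

            dM[idx] += r_T - r_ret - r_1 - r_1b + r_1r + r_1br
            dF[idx] += -r_1 - r_1c + r_1r - r_2 + r_2r
            dDF[idx] += r_1 + r_1c - r_1r - r_2d + r_2dr
            dC0[idx] += r_2 - r_2r - r_1b + r_1br
            dC1[idx] += r_2d + r_1b - r_2dr - r_1br
            dPV[idx] += r_3 - r_3r
            # bridge formation consumes free Vang on the apposed membrane
            dV[p] += -r_2 - r_2d + r_2r + r_2dr

        dDc[i] = -k_T * dc + sum_ret - sum_r1c
        dPc[i] = -sum_r3 + sum_r3r

    if D_m > 0.0:
        for i in range(n):
            base = 6 * i
            for e in range(6):
                idx = base + e
                prv = base + (e + 5) % 6
                nxt = base + (e + 1) % 6
                dF[idx] += D_m * (F[prv] + F[nxt] - 2.0 * F[idx])
                dV[idx] += D_m * (V[prv] + V[nxt] - 2.0 * V[idx])
                dM[idx] += D_m * (M[prv] + M[nxt] - 2.0 * M[idx])
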