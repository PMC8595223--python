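"""Numba kernels for the 1D pulse-wave solver.

All quantities here are CGS (cm, g, s, dyn/cm^2).  The network state is
flattened: vessel ``v`` occupies entries ``off[v] .. off[v] + ncell[v] + 1``
of the cell arrays, where the first and last entries are ghost cells holding
the boundary (star) states computed from characteristic matching at the
inlet, junctions and Windkessel outlets.

Interior cells advance with a MacCormack predictor–corrector; the pressure
gradient is applied non-conservatively from the tube-law pressure evaluated
at cell centres, which keeps the scheme well-balanced (a uniform-pressure
network at rest stays exactly at rest even with varying reference area).
"""

import numpy as np
from numba import njit

# status codes returned by _run_cycle
OK = 0
NEGATIVE_AREA = 1
NEWTON_FAIL = 2


@njit(cache=True, inline="always")
def _pres(a, ad, be):
    return be / ad * (np.sqrt(a) - np.sqrt(ad))


@njit(cache=True, inline="always")
def _wspeed(a, ad, be, rho):
    return np.sqrt(be * np.sqrt(a) / (2.0 * rho * ad))


@njit(cache=True)
def _qin_at(t, T, qphase, qflow):
    """Periodic linear interpolation of the inflow waveform."""
    s = (t / T) % 1.0
    m = qphase.shape[0]
    # qphase ascending in [0, 1); find bracket
    if s < qphase[0]:
        s = qphase[0]
    hi = m
    lo = 0
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if qphase[mid] <= s:
            lo = mid
        else:
            hi = mid
    if lo == m - 1:
        s0, s1 = qphase[m - 1], 1.0 + qphase[0]
        f0, f1 = qflow[m - 1], qflow[0]
    else:
        s0, s1 = qphase[lo], qphase[lo + 1]
        f0, f1 = qflow[lo], qflow[lo + 1]
    w = (s - s0) / (s1 - s0)
    return f0 + w * (f1 - f0)


@njit(cache=True)
def _inlet_star(qin, a_int, q_int, ad, be, rho):
    """Inlet state from prescribed flow and the backward characteristic."""
    c_int = _wspeed(a_int, ad, be, rho)
    w2 = q_int / a_int - 4.0 * c_int
    a = a_int
    for _ in range(80):
        c = _wspeed(a, ad, be, rho)
        g = qin / a - 4.0 * c - w2
        dg = -qin / (a * a) - c / a
        step = g / dg
        anew = a - step
        if anew <= 0.0:
            anew = 0.5 * a
        if abs(anew - a) < 1e-12 * a + 1e-16:
            a = anew
            break
        a = anew
    return a, qin


@njit(cache=True)
def _outlet_star(a_int, q_int, ad, be, rho, r1, pc):
    """Terminal state matching the forward characteristic to the Windkessel
    proximal resistance: p(A) - pc = R1 * A * u."""
    c_int = _wspeed(a_int, ad, be, rho)
    w1 = q_int / a_int + 4.0 * c_int
    a = a_int
    for _ in range(80):
        c = _wspeed(a, ad, be, rho)
        u = w1 - 4.0 * c
        g = _pres(a, ad, be) - pc - r1 * a * u
        dg = rho * c * c / a - r1 * (u - c)
        step = g / dg
        anew = a - step
        if anew <= 0.0:
            anew = 0.5 * a
        if abs(anew - a) < 1e-12 * a + 1e-16:
            a = anew
            break
        a = anew
    c = _wspeed(a, ad, be, rho)
    u = w1 - 4.0 * c
    return a, a * u


@njit(cache=True)
def _gauss_solve(M, b, n):
    """In-place Gaussian elimination with partial pivoting (n <= 4)."""
    for col in range(n):
        piv = col
        big = abs(M[col, col])
        for r in range(col + 1, n):
            if abs(M[r, col]) > big:
                big = abs(M[r, col])
                piv = r
        if piv != col:
            for c in range(n):
                tmp = M[col, c]
                M[col, c] = M[piv, c]
                M[piv, c] = tmp
            tmp = b[col]
            b[col] = b[piv]
            b[piv] = tmp
        d = M[col, col]
        if d == 0.0:
            return False
        for r in range(col + 1, n):
            f = M[r, col] / d
            for c in range(col, n):
                M[r, c] -= f * M[col, c]
            b[r] -= f * b[col]
    for r in range(n - 1, -1, -1):
        s = b[r]
        for c in range(r + 1, n):
            s -= M[r, c] * b[c]
        b[r] = s / M[r, r]
    return True


@njit(cache=True)
def _junction_star(w1p, adp, bep, w2c, adc, bec, nchild, a, rho, M, b):
    """Star states at a junction: mass conservation + total-pressure
    continuity, with outgoing characteristics from parent and children.

    ``a`` holds the current guess [A_parent, A_child_1, ...] and is updated
    in place; ``M`` (4x4) and ``b`` (4) are caller-provided scratch.
    Returns (ok, scaled mass residual).
    """
    n = nchild + 1
    mass_res = 0.0
    for it in range(60):
        cp = _wspeed(a[0], adp, bep, rho)
        up = w1p - 4.0 * cp
        mass = a[0] * up
        scale = a[0] * cp
        for i in range(nchild):
            ci = _wspeed(a[1 + i], adc[i], bec[i], rho)
            ui = w2c[i] + 4.0 * ci
            mass -= a[1 + i] * ui
            scale += a[1 + i] * ci
        pp = _pres(a[0], adp, bep) + 0.5 * rho * up * up
        # residuals
        b[0] = -mass
        for i in range(nchild):
            ci = _wspeed(a[1 + i], adc[i], bec[i], rho)
            ui = w2c[i] + 4.0 * ci
            b[1 + i] = -(pp - _pres(a[1 + i], adc[i], bec[i]) - 0.5 * rho * ui * ui)
        # convergence check
        pscale = rho * cp * cp
        done = abs(mass) < 1e-10 * scale
        for i in range(nchild):
            if abs(b[1 + i]) > 1e-10 * pscale:
                done = False
        mass_res = abs(mass) / scale
        if done:
            return True, mass_res
        # Jacobian
        for r in range(4):
            for c in range(4):
                M[r, c] = 0.0
        M[0, 0] = up - cp
        for i in range(nchild):
            ci = _wspeed(a[1 + i], adc[i], bec[i], rho)
            ui = w2c[i] + 4.0 * ci
            M[0, 1 + i] = -(ui + ci)
            M[1 + i, 0] = rho * cp * (cp - up) / a[0]
            M[1 + i, 1 + i] = -rho * ci * (ci + ui) / a[1 + i]
        if not _gauss_solve(M, b, n):
            return False, mass_res
        for i in range(n):
            anew = a[i] + b[i]
            if anew <= 0.0:
                anew = 0.5 * a[i]
            a[i] = anew
    return False, mass_res


@njit(cache=True)
def _run_cycle(A, Q, Ad, Be, Ze, CP, SQ, dxv, off, ncell,
               jpar, jnch, jch,
               ov, oR1, oC, oR2, oPout, pc,
               qphase, qflow, T, t0, dt, nsteps, inlet_v,
               scell, skind, rec,
               rho, alpha_p, fric, ajunc):
    """Advance one cardiac cycle; record site samples at each step start.

    Returns (status, max scaled junction mass residual).
    """
    nv = off.shape[0]
    nj = jpar.shape[0]
    no = ov.shape[0]
    ns = scell.shape[0]
    total = A.shape[0]
    As = np.empty(total)
    Qs = np.empty(total)
    P = np.empty(total)
    Ps = np.empty(total)
    w2c = np.empty(3)
    adc = np.empty(3)
    bec = np.empty(3)
    Mwork = np.zeros((4, 4))
    bwork = np.zeros(4)
    max_jres = 0.0

    for k in range(nsteps):
        t = t0 + k * dt
        _record_sites(A, Q, CP, SQ, scell, skind, rec, k)

        # --- boundary star states -> ghost cells -------------------------
        i1 = off[inlet_v] + 1
        qin = _qin_at(t, T, qphase, qflow)
        a0, q0 = _inlet_star(qin, A[i1], Q[i1], Ad[i1], Be[i1], rho)
        A[off[inlet_v]] = a0
        Q[off[inlet_v]] = q0

        for j in range(nj):
            pv = jpar[j]
            ip = off[pv] + ncell[pv]  # parent last interior cell
            cp = _wspeed(A[ip], Ad[ip], Be[ip], rho)
            w1p = Q[ip] / A[ip] + 4.0 * cp
            m = jnch[j]
            for i in range(m):
                cv = jch[j, i]
                ic = off[cv] + 1
                ci = _wspeed(A[ic], Ad[ic], Be[ic], rho)
                w2c[i] = Q[ic] / A[ic] - 4.0 * ci
                adc[i] = Ad[ic]
                bec[i] = Be[ic]
                ajunc[j, 1 + i] = A[ic]
            ajunc[j, 0] = A[ip]
            ok, jres = _junction_star(w1p, Ad[ip], Be[ip], w2c, adc, bec, m,
                                      ajunc[j], rho, Mwork, bwork)
            if not ok:
                return NEWTON_FAIL, max_jres
            if jres > max_jres:
                max_jres = jres
            ap = ajunc[j, 0]
            upar = w1p - 4.0 * _wspeed(ap, Ad[ip], Be[ip], rho)
            A[off[pv] + ncell[pv] + 1] = ap
            Q[off[pv] + ncell[pv] + 1] = ap * upar
            for i in range(m):
                cv = jch[j, i]
                ac = ajunc[j, 1 + i]
                uc = w2c[i] + 4.0 * _wspeed(ac, adc[i], bec[i], rho)
                A[off[cv]] = ac
                Q[off[cv]] = ac * uc

        for o in range(no):
            tv = ov[o]
            it = off[tv] + ncell[tv]
            a1, q1 = _outlet_star(A[it], Q[it], Ad[it], Be[it], rho, oR1[o], pc[o])
            A[off[tv] + ncell[tv] + 1] = a1
            Q[off[tv] + ncell[tv] + 1] = q1
            # semi-implicit capacitor update
            pc[o] = (pc[o] + dt / oC[o] * (q1 + oPout[o] / oR2[o])) / (
                1.0 + dt / (oC[o] * oR2[o]))

        # --- MacCormack interior update ----------------------------------
        # CP = beta/Ad and SQ = sqrt(Ad) are precomputed (static geometry)
        for j in range(total):
            P[j] = CP[j] * (np.sqrt(A[j]) - SQ[j])
        for v in range(nv):
            o0 = off[v]
            n = ncell[v]
            dx = dxv[v]
            As[o0] = A[o0]
            Qs[o0] = Q[o0]
            As[o0 + n + 1] = A[o0 + n + 1]
            Qs[o0 + n + 1] = Q[o0 + n + 1]
            r = dt / dx
            for j in range(o0 + 1, o0 + n + 1):
                f2r = alpha_p * Q[j + 1] * Q[j + 1] / A[j + 1]
                f2l = alpha_p * Q[j] * Q[j] / A[j]
                As[j] = A[j] - r * (Q[j + 1] - Q[j])
                Qs[j] = (Q[j] - r * (f2r - f2l)
                         - r * (A[j] / rho) * (P[j + 1] - P[j])
                         - dt * fric * Q[j] / A[j]
                         - dt * 0.5 * Ze[j] * Q[j] * abs(Q[j]) / A[j])
                if As[j] <= 0.0:
                    return NEGATIVE_AREA, max_jres
        for j in range(total):
            Ps[j] = CP[j] * (np.sqrt(As[j]) - SQ[j])
        for v in range(nv):
            o0 = off[v]
            n = ncell[v]
            dx = dxv[v]
            r = dt / dx
            for j in range(o0 + 1, o0 + n + 1):
                f2c = alpha_p * Qs[j] * Qs[j] / As[j]
                f2l = alpha_p * Qs[j - 1] * Qs[j - 1] / As[j - 1]
                anew = 0.5 * (A[j] + As[j]) - 0.5 * r * (Qs[j] - Qs[j - 1])
                qnew = (0.5 * (Q[j] + Qs[j])
                        - 0.5 * r * (f2c - f2l)
                        - 0.5 * r * (As[j] / rho) * (Ps[j] - Ps[j - 1])
                        - 0.5 * dt * fric * Qs[j] / As[j]
                        - 0.5 * dt * 0.5 * Ze[j] * Qs[j] * abs(Qs[j]) / As[j])
                A[j] = anew
                Q[j] = qnew
                if anew <= 0.0:
                    return NEGATIVE_AREA, max_jres
    return OK, max_jres


@njit(cache=True)
def _min_dt(A, Q, Ad, Be, dxv, off, ncell, rho):
    """Smallest dx / (|u| + c) over interior cells."""
    nv = off.shape[0]
    best = 1e30
    for v in range(nv):
        o0 = off[v]
        for j in range(o0 + 1, o0 + ncell[v] + 1):
            c = _wspeed(A[j], Ad[j], Be[j], rho)
            u = abs(Q[j] / A[j])
            val = dxv[v] / (u + c)
            if val < best:
                best = val
    return best


@njit(cache=True)
def _record_sites(A, Q, CP, SQ, scell, skind, rec, k):
    for i in range(scell.shape[0]):
        j = scell[i]
        if skind[i] == 0:
            rec[i, k] = CP[j] * (np.sqrt(A[j]) - SQ[j])
        else:
            rec[i, k] = Q[j]
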