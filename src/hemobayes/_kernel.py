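"""Compiled inner loop of the pulse-wave solver.

Everything here operates on flat numpy arrays prepared by
:mod:`hemobayes.solver`; no Python objects cross into the jitted
region.  The state is the set of orthonormal-Legendre modal
coefficients of (A, u) per artery and element; one call advances the
whole network through ``nt`` Adams-Bashforth-2 steps (forward-Euler
bootstrap) and writes sensor samples and boundary-flux bookkeeping
in place.

Status codes returned: 0 ok, 1 non-physical area (blow-up), 2 CFL
bound violated, 3 junction Newton failure, 4 boundary characteristic
failure.
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_BLOWUP = 1
STATUS_CFL = 2
STATUS_JUNCTION = 3
STATUS_BOUNDARY = 4


@njit(cache=True)
def _wave_speed(a, B, rho):
    return np.sqrt(B / (2.0 * rho)) * a**0.25


@njit(cache=True)
def _area_from_speed(c, B, rho):
    # invert c = sqrt(B/(2 rho)) A^{1/4}
    s = 2.0 * rho * c * c / B
    return s * s


@njit(cache=True)
def _junction_newton(W1, W2a, W2b, B1, A01, B2, A02, B3, A03,
                     a1, a2, a3, rho, tol, maxit):
    """Solve the six coupled bifurcation conditions.

    Characteristic relations eliminate the velocities, leaving a 3x3
    Newton iteration in the areas (A1, A2, A3): conservation of mass
    plus continuity of total pressure p + rho u^2 / 2 into each
    daughter, with the parent's outgoing invariant u+4c and each
    daughter's outgoing invariant u-4c held fixed.
    Returns (ok, A1, u1, A2, u2, A3, u3).
    """
    for _ in range(maxit):
        c1 = _wave_speed(a1, B1, rho)
        c2 = _wave_speed(a2, B2, rho)
        c3 = _wave_speed(a3, B3, rho)
        u1 = W1 - 4.0 * c1
        u2 = W2a + 4.0 * c2
        u3 = W2b + 4.0 * c3
        r1 = a1 * u1 - a2 * u2 - a3 * u3
        p1 = B1 * (np.sqrt(a1) - np.sqrt(A01)) / rho
        p2 = B2 * (np.sqrt(a2) - np.sqrt(A02)) / rho
        p3 = B3 * (np.sqrt(a3) - np.sqrt(A03)) / rho
        r2 = p1 - p2 + 0.5 * (u1 * u1 - u2 * u2)
        r3 = p1 - p3 + 0.5 * (u1 * u1 - u3 * u3)
        if abs(r1) < tol and abs(r2) < tol and abs(r3) < tol:
            return True, a1, u1, a2, u2, a3, u3
        # Jacobian
        j11 = u1 - c1
        j12 = -(u2 + c2)
        j13 = -(u3 + c3)
        g1 = B1 / (2.0 * rho * np.sqrt(a1)) - u1 * c1 / a1
        j21 = g1
        j22 = -B2 / (2.0 * rho * np.sqrt(a2)) - u2 * c2 / a2
        j31 = g1
        j33 = -B3 / (2.0 * rho * np.sqrt(a3)) - u3 * c3 / a3
        # Cramer solve of [[j11,j12,j13],[j21,j22,0],[j31,0,j33]] d = r
        det = (j11 * j22 * j33 - j12 * j21 * j33 - j13 * j22 * j31)
        if det == 0.0 or not np.isfinite(det):
            return False, a1, 0.0, a2, 0.0, a3, 0.0
        d1 = (r1 * j22 * j33 - j12 * r2 * j33 - j13 * j22 * r3) / det
        d2 = (j11 * r2 * j33 - r1 * j21 * j33 + j13 * (j21 * r3 - r2 * j31)) / det
        d3 = (j11 * j22 * r3 - j12 * j21 * r3 - r1 * j22 * j31
              + j12 * r2 * j31) / det
        a1n = a1 - d1
        a2n = a2 - d2
        a3n = a3 - d3
        # keep iterates physical
        if a1n <= 0.0:
            a1n = 0.5 * a1
        if a2n <= 0.0:
            a2n = 0.5 * a2
        if a3n <= 0.0:
            a3n = 0.5 * a3
        a1, a2, a3 = a1n, a2n, a3n
    return False, a1, 0.0, a2, 0.0, a3, 0.0


@njit(cache=True)
def _compute_rhs(a_coef, u_coef, h, A0, B, c_rest,
                 parent, child1, child2, terminals,
                 uin, rho, Kr, p_ext,
                 phi_q, dphi_q, wq, phi_L, phi_R,
                 newton_tol, newton_max,
                 Ra, Ru, Su, aL, uL, aR, uR, FhA, FhU, err):
    """Fill Ra, Ru with d/dt of the modal coefficients.

    Returns (status, artery, element, smax) where smax is the largest
    |u| + c seen at a quadrature point (for the CFL check).
    err[0:2] receives inlet mass flux and summed terminal mass flux.
    """
    nart, nelem, nm = a_coef.shape
    nq = wq.shape[0]
    smax = 0.0

    # element volume terms, sources and edge traces
    for i in range(nart):
        Bi = B[i]
        A0i = A0[i]
        sA0 = np.sqrt(A0i)
        for e in range(nelem):
            for k in range(nm):
                Ra[i, e, k] = 0.0
                Ru[i, e, k] = 0.0
                Su[i, e, k] = 0.0
            for q in range(nq):
                av = 0.0
                uv = 0.0
                for k in range(nm):
                    av += a_coef[i, e, k] * phi_q[k, q]
                    uv += u_coef[i, e, k] * phi_q[k, q]
                if not (av > 0.0) or not np.isfinite(av) or not np.isfinite(uv):
                    return STATUS_BLOWUP, i, e, smax
                cv = _wave_speed(av, Bi, rho)
                s = abs(uv) + cv
                if s > smax:
                    smax = s
                F1 = av * uv
                F2 = 0.5 * uv * uv + (p_ext + Bi * (np.sqrt(av) - sA0)) / rho
                src = Kr * uv / (rho * av)
                for k in range(nm):
                    Ra[i, e, k] += wq[q] * F1 * dphi_q[k, q]
                    Ru[i, e, k] += wq[q] * F2 * dphi_q[k, q]
                    Su[i, e, k] += wq[q] * src * phi_q[k, q]
            # edge traces
            al = 0.0
            ul = 0.0
            ar = 0.0
            ur = 0.0
            for k in range(nm):
                al += a_coef[i, e, k] * phi_L[k]
                ul += u_coef[i, e, k] * phi_L[k]
                ar += a_coef[i, e, k] * phi_R[k]
                ur += u_coef[i, e, k] * phi_R[k]
            if al <= 0.0 or ar <= 0.0:
                return STATUS_BLOWUP, i, e, smax
            aL[i, e] = al
            uL[i, e] = ul
            aR[i, e] = ar
            uR[i, e] = ur

    # interior interface upwind fluxes (characteristics of the same artery)
    for i in range(nart):
        Bi = B[i]
        A0i = A0[i]
        sA0 = np.sqrt(A0i)
        for f in range(1, nelem):
            W1 = uR[i, f - 1] + 4.0 * _wave_speed(aR[i, f - 1], Bi, rho)
            W2 = uL[i, f] - 4.0 * _wave_speed(aL[i, f], Bi, rho)
            cs = (W1 - W2) / 8.0
            if cs <= 0.0:
                return STATUS_BOUNDARY, i, f, smax
            us = 0.5 * (W1 + W2)
            As = _area_from_speed(cs, Bi, rho)
            FhA[i, f] = As * us
            FhU[i, f] = 0.5 * us * us + (p_ext + Bi * (np.sqrt(As) - sA0)) / rho

    # inlet of the root artery: prescribed velocity, reflection-free area
    W2 = uL[0, 0] - 4.0 * _wave_speed(aL[0, 0], B[0], rho)
    cs = (uin - W2) / 4.0
    if cs <= 0.0:
        return STATUS_BOUNDARY, 0, 0, smax
    As = _area_from_speed(cs, B[0], rho)
    FhA[0, 0] = As * uin
    FhU[0, 0] = 0.5 * uin * uin + (p_ext + B[0] * (np.sqrt(As) - np.sqrt(A0[0]))) / rho
    err[0] = FhA[0, 0]

    # terminal outlets: fully absorbing (incoming invariant at rest value)
    tot = 0.0
    for tt in range(terminals.shape[0]):
        i = terminals[tt]
        W1 = uR[i, nelem - 1] + 4.0 * _wave_speed(aR[i, nelem - 1], B[i], rho)
        W2r = -4.0 * c_rest[i]
        cs = (W1 - W2r) / 8.0
        if cs <= 0.0:
            return STATUS_BOUNDARY, i, nelem - 1, smax
        us = 0.5 * (W1 + W2r)
        As = _area_from_speed(cs, B[i], rho)
        FhA[i, nelem] = As * us
        FhU[i, nelem] = (0.5 * us * us
                         + (p_ext + B[i] * (np.sqrt(As) - np.sqrt(A0[i]))) / rho)
        tot += FhA[i, nelem]
    err[1] = tot

    # bifurcations: coupled parent-outlet / daughter-inlet values
    for j in range(parent.shape[0]):
        ip = parent[j]
        ia = child1[j]
        ib = child2[j]
        W1 = uR[ip, nelem - 1] + 4.0 * _wave_speed(aR[ip, nelem - 1], B[ip], rho)
        W2a = uL[ia, 0] - 4.0 * _wave_speed(aL[ia, 0], B[ia], rho)
        W2b = uL[ib, 0] - 4.0 * _wave_speed(aL[ib, 0], B[ib], rho)
        ok, a1, u1, a2, u2, a3, u3 = _junction_newton(
            W1, W2a, W2b, B[ip], A0[ip], B[ia], A0[ia], B[ib], A0[ib],
            aR[ip, nelem - 1], aL[ia, 0], aL[ib, 0],
            rho, newton_tol, newton_max)
        if not ok:
            return STATUS_JUNCTION, ip, nelem - 1, smax
        FhA[ip, nelem] = a1 * u1
        FhU[ip, nelem] = (0.5 * u1 * u1
                          + (p_ext + B[ip] * (np.sqrt(a1) - np.sqrt(A0[ip]))) / rho)
        FhA[ia, 0] = a2 * u2
        FhU[ia, 0] = (0.5 * u2 * u2
                      + (p_ext + B[ia] * (np.sqrt(a2) - np.sqrt(A0[ia]))) / rho)
        FhA[ib, 0] = a3 * u3
        FhU[ib, 0] = (0.5 * u3 * u3
                      + (p_ext + B[ib] * (np.sqrt(a3) - np.sqrt(A0[ib]))) / rho)

    # assemble dU/dt = S_hat + (2/h) (V - [Fhat phi]); the source
    # projection S_hat = int S phi dxi carries no 2/h factor.
    for i in range(nart):
        inv = 2.0 / h[i]
        for e in range(nelem):
            for k in range(nm):
                Ra[i, e, k] = inv * (Ra[i, e, k]
                                     - (FhA[i, e + 1] * phi_R[k] - FhA[i, e] * phi_L[k]))
                Ru[i, e, k] = (Su[i, e, k]
                               + inv * (Ru[i, e, k]
                                        - (FhU[i, e + 1] * phi_R[k]
                                           - FhU[i, e] * phi_L[k])))
    return STATUS_OK, -1, -1, smax


@njit(cache=True)
def run_simulation(a_coef, u_coef, h, A0, B, c_rest,
                   parent, child1, child2, terminals,
                   inflow_u, dt, nt, rho, Kr, p_ext,
                   phi_q, dphi_q, wq, phi_L, phi_R,
                   newton_tol, newton_max, h_min, cfl_limit,
                   stride, sens_art, sens_elem, sens_phi,
                   out, bflux):
    """March the network forward ``nt`` steps, sampling sensors every
    ``stride`` steps.  Returns (status, artery, element, step)."""
    nart, nelem, nm = a_coef.shape
    ns = sens_art.shape[0]
    Ra = np.empty((nart, nelem, nm))
    Ru = np.empty((nart, nelem, nm))
    Su = np.empty((nart, nelem, nm))
    Rap = np.zeros((nart, nelem, nm))
    Rup = np.zeros((nart, nelem, nm))
    aL = np.empty((nart, nelem))
    uL = np.empty((nart, nelem))
    aR = np.empty((nart, nelem))
    uR = np.empty((nart, nelem))
    FhA = np.empty((nart, nelem + 1))
    FhU = np.empty((nart, nelem + 1))
    err = np.empty(2)
    isample = 0

    for n in range(nt):
        status, ei, ee, smax = _compute_rhs(
            a_coef, u_coef, h, A0, B, c_rest,
            parent, child1, child2, terminals,
            inflow_u[n], rho, Kr, p_ext,
            phi_q, dphi_q, wq, phi_L, phi_R,
            newton_tol, newton_max,
            Ra, Ru, Su, aL, uL, aR, uR, FhA, FhU, err)
        if status != STATUS_OK:
            return status, ei, ee, n
        if dt * smax > cfl_limit * h_min:
            return STATUS_CFL, -1, -1, n
        bflux[n, 0] = err[0]
        bflux[n, 1] = err[1]
        if n == 0:
            for i in range(nart):
                for e in range(nelem):
                    for k in range(nm):
                        a_coef[i, e, k] += dt * Ra[i, e, k]
                        u_coef[i, e, k] += dt * Ru[i, e, k]
        else:
            for i in range(nart):
                for e in range(nelem):
                    for k in range(nm):
                        a_coef[i, e, k] += dt * (1.5 * Ra[i, e, k] - 0.5 * Rap[i, e, k])
                        u_coef[i, e, k] += dt * (1.5 * Ru[i, e, k] - 0.5 * Rup[i, e, k])
        for i in range(nart):
            for e in range(nelem):
                for k in range(nm):
                    Rap[i, e, k] = Ra[i, e, k]
                    Rup[i, e, k] = Ru[i, e, k]
        if (n + 1) % stride == 0:
            for s in range(ns):
                v = 0.0
                for k in range(nm):
                    v += u_coef[sens_art[s], sens_elem[s], k] * sens_phi[s, k]
                out[s, isample] = v
            isample += 1
    return STATUS_OK, -1, -1, nt
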