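"""Numba kernels for analytic nuclear-gradient contractions.

Derivative integrals are obtained with the raise/lower identity
d/dA x^i exp(-a r^2) -> 2a |i+1> - i |i-1>, and the nuclear-center term of
the attraction integrals via translational invariance. All contractions
are performed on the fly with the (Cartesian-representation) density and
energy-weighted density matrices; nothing four-index is stored.
"""

import numpy as np
from numba import njit

from ._kernels import (_CCOMP, _COFF, _bra_sum, _ecoef, _eri_quartet,
                       _ket_contract, _rhermite, _rhermite_buf)


@njit(cache=True)
def grad_s_t_contract(shell_l, shell_atom, centers, nprim, pptr, pexp, pcoef,
                      cart_off, natm, Wc, Dc):
    """grad[A] += sum_ab Wc_ab dS_ab/dA + Dc_ab dT_ab/dA (bra derivative over
    all ordered pairs covers the ket terms)."""
    grad = np.zeros((natm, 3))
    nsh = len(shell_l)
    for s1 in range(nsh):
        l1 = shell_l[s1]
        n1 = _COFF[l1 + 1] - _COFF[l1]
        A = centers[s1]
        ia = shell_atom[s1]
        for s2 in range(nsh):
            l2 = shell_l[s2]
            n2 = _COFF[l2 + 1] - _COFF[l2]
            B = centers[s2]
            AB2 = (A[0] - B[0]) ** 2 + (A[1] - B[1]) ** 2 + (A[2] - B[2]) ** 2
            Ex = np.zeros((l1 + 2, l2 + 3, l1 + l2 + 5))
            Ey = np.zeros((l1 + 2, l2 + 3, l1 + l2 + 5))
            Ez = np.zeros((l1 + 2, l2 + 3, l1 + l2 + 5))
            for ip in range(pptr[s1], pptr[s1 + 1]):
                a = pexp[ip]
                for jp in range(pptr[s2], pptr[s2 + 1]):
                    b = pexp[jp]
                    p = a + b
                    K = np.exp(-a * b / p * AB2) * pcoef[ip] * pcoef[jp] * (np.pi / p) ** 1.5
                    if abs(K) < 1e-18:
                        continue
                    Px = (a * A[0] + b * B[0]) / p
                    Py = (a * A[1] + b * B[1]) / p
                    Pz = (a * A[2] + b * B[2]) / p
                    _ecoef(l1 + 1, l2 + 2, Px - A[0], Px - B[0], 0.5 / p, Ex)
                    _ecoef(l1 + 1, l2 + 2, Py - A[1], Py - B[1], 0.5 / p, Ey)
                    _ecoef(l1 + 1, l2 + 2, Pz - A[2], Pz - B[2], 0.5 / p, Ez)
                    for i in range(n1):
                        ax = _CCOMP[_COFF[l1] + i, 0]
                        ay = _CCOMP[_COFF[l1] + i, 1]
                        az = _CCOMP[_COFF[l1] + i, 2]
                        for j in range(n2):
                            bx = _CCOMP[_COFF[l2] + j, 0]
                            by = _CCOMP[_COFF[l2] + j, 1]
                            bz = _CCOMP[_COFF[l2] + j, 2]
                            w = Wc[cart_off[s1] + i, cart_off[s2] + j]
                            d = Dc[cart_off[s1] + i, cart_off[s2] + j]
                            if abs(w) < 1e-16 and abs(d) < 1e-16:
                                continue
                            # 1D overlap factors and their bra-derivatives
                            sx = Ex[ax, bx, 0]
                            sy = Ey[ay, by, 0]
                            sz = Ez[az, bz, 0]
                            dsx = 2.0 * a * Ex[ax + 1, bx, 0]
                            if ax > 0:
                                dsx -= ax * Ex[ax - 1, bx, 0]
                            dsy = 2.0 * a * Ey[ay + 1, by, 0]
                            if ay > 0:
                                dsy -= ay * Ey[ay - 1, by, 0]
                            dsz = 2.0 * a * Ez[az + 1, bz, 0]
                            if az > 0:
                                dsz -= az * Ez[az - 1, bz, 0]
                            # 1D kinetic factors (operator on ket) at bra index q
                            tx = -2.0 * b * b * Ex[ax, bx + 2, 0] + b * (2 * bx + 1) * sx
                            if bx >= 2:
                                tx -= 0.5 * bx * (bx - 1) * Ex[ax, bx - 2, 0]
                            ty = -2.0 * b * b * Ey[ay, by + 2, 0] + b * (2 * by + 1) * sy
                            if by >= 2:
                                ty -= 0.5 * by * (by - 1) * Ey[ay, by - 2, 0]
                            tz = -2.0 * b * b * Ez[az, bz + 2, 0] + b * (2 * bz + 1) * sz
                            if bz >= 2:
                                tz -= 0.5 * bz * (bz - 1) * Ez[az, bz - 2, 0]
                            dtx = -2.0 * b * b * Ex[ax + 1, bx + 2, 0] + b * (2 * bx + 1) * Ex[ax + 1, bx, 0]
                            if bx >= 2:
                                dtx -= 0.5 * bx * (bx - 1) * Ex[ax + 1, bx - 2, 0]
                            dtx *= 2.0 * a
                            if ax > 0:
                                tmp = -2.0 * b * b * Ex[ax - 1, bx + 2, 0] + b * (2 * bx + 1) * Ex[ax - 1, bx, 0]
                                if bx >= 2:
                                    tmp -= 0.5 * bx * (bx - 1) * Ex[ax - 1, bx - 2, 0]
                                dtx -= ax * tmp
                            dty = -2.0 * b * b * Ey[ay + 1, by + 2, 0] + b * (2 * by + 1) * Ey[ay + 1, by, 0]
                            if by >= 2:
                                dty -= 0.5 * by * (by - 1) * Ey[ay + 1, by - 2, 0]
                            dty *= 2.0 * a
                            if ay > 0:
                                tmp = -2.0 * b * b * Ey[ay - 1, by + 2, 0] + b * (2 * by + 1) * Ey[ay - 1, by, 0]
                                if by >= 2:
                                    tmp -= 0.5 * by * (by - 1) * Ey[ay - 1, by - 2, 0]
                                dty -= ay * tmp
                            dtz = -2.0 * b * b * Ez[az + 1, bz + 2, 0] + b * (2 * bz + 1) * Ez[az + 1, bz, 0]
                            if bz >= 2:
                                dtz -= 0.5 * bz * (bz - 1) * Ez[az + 1, bz - 2, 0]
                            dtz *= 2.0 * a
                            if az > 0:
                                tmp = -2.0 * b * b * Ez[az - 1, bz + 2, 0] + b * (2 * bz + 1) * Ez[az - 1, bz, 0]
                                if bz >= 2:
                                    tmp -= 0.5 * bz * (bz - 1) * Ez[az - 1, bz - 2, 0]
                                dtz -= az * tmp
                            gx = w * dsx * sy * sz + d * (dtx * sy * sz + dsx * ty * sz + dsx * sy * tz)
                            gy = w * sx * dsy * sz + d * (tx * dsy * sz + sx * dty * sz + sx * dsy * tz)
                            gz = w * sx * sy * dsz + d * (tx * sy * dsz + sx * ty * dsz + sx * sy * dtz)
                            # bra term only; the ket term equals the bra term
                            # of the transposed pair, hence the factor 2
                            grad[ia, 0] += 2.0 * K * gx
                            grad[ia, 1] += 2.0 * K * gy
                            grad[ia, 2] += 2.0 * K * gz
    return grad


@njit(cache=True)
def _vsum(Ex, Ey, Ez, R, ax, ay, az, bx, by, bz):
    acc = 0.0
    if ax < 0 or ay < 0 or az < 0 or bx < 0 or by < 0 or bz < 0:
        return 0.0
    for t in range(ax + bx + 1):
        ex = Ex[ax, bx, t]
        if ex == 0.0:
            continue
        for u in range(ay + by + 1):
            ey = Ey[ay, by, u]
            if ey == 0.0:
                continue
            for v in range(az + bz + 1):
                ez = Ez[az, bz, v]
                if ez != 0.0:
                    acc += ex * ey * ez * R[t, u, v]
    return acc


@njit(cache=True)
def grad_nuclear_contract(shell_l, shell_atom, centers, nprim, pptr, pexp, pcoef,
                          cart_off, natm, Dc, atom_coords, atom_charges):
    """Nuclear-attraction gradient, including the operator-center terms."""
    grad = np.zeros((natm, 3))
    nsh = len(shell_l)
    for s1 in range(nsh):
        l1 = shell_l[s1]
        n1 = _COFF[l1 + 1] - _COFF[l1]
        A = centers[s1]
        ia = shell_atom[s1]
        for s2 in range(nsh):
            l2 = shell_l[s2]
            n2 = _COFF[l2 + 1] - _COFF[l2]
            B = centers[s2]
            ib = shell_atom[s2]
            AB2 = (A[0] - B[0]) ** 2 + (A[1] - B[1]) ** 2 + (A[2] - B[2]) ** 2
            L = l1 + l2 + 2
            Ex = np.zeros((l1 + 2, l2 + 2, L + 3))
            Ey = np.zeros((l1 + 2, l2 + 2, L + 3))
            Ez = np.zeros((l1 + 2, l2 + 2, L + 3))
            R = np.zeros((L + 1, L + 1, L + 1))
            for ip in range(pptr[s1], pptr[s1 + 1]):
                a = pexp[ip]
                for jp in range(pptr[s2], pptr[s2 + 1]):
                    b = pexp[jp]
                    p = a + b
                    K = np.exp(-a * b / p * AB2) * pcoef[ip] * pcoef[jp] * 2.0 * np.pi / p
                    if abs(K) < 1e-18:
                        continue
                    Px = (a * A[0] + b * B[0]) / p
                    Py = (a * A[1] + b * B[1]) / p
                    Pz = (a * A[2] + b * B[2]) / p
                    _ecoef(l1 + 1, l2 + 1, Px - A[0], Px - B[0], 0.5 / p, Ex)
                    _ecoef(l1 + 1, l2 + 1, Py - A[1], Py - B[1], 0.5 / p, Ey)
                    _ecoef(l1 + 1, l2 + 1, Pz - A[2], Pz - B[2], 0.5 / p, Ez)
                    for ic in range(natm):
                        _rhermite(L, L, L, p,
                                  Px - atom_coords[ic, 0],
                                  Py - atom_coords[ic, 1],
                                  Pz - atom_coords[ic, 2], R)
                        Z = atom_charges[ic]
                        for i in range(n1):
                            ax = _CCOMP[_COFF[l1] + i, 0]
                            ay = _CCOMP[_COFF[l1] + i, 1]
                            az = _CCOMP[_COFF[l1] + i, 2]
                            for j in range(n2):
                                d = Dc[cart_off[s1] + i, cart_off[s2] + j]
                                if abs(d) < 1e-16:
                                    continue
                                bx = _CCOMP[_COFF[l2] + j, 0]
                                by = _CCOMP[_COFF[l2] + j, 1]
                                bz = _CCOMP[_COFF[l2] + j, 2]
                                c = -K * Z * d
                                dax = 2.0 * a * _vsum(Ex, Ey, Ez, R, ax + 1, ay, az, bx, by, bz) \
                                    - ax * _vsum(Ex, Ey, Ez, R, ax - 1, ay, az, bx, by, bz)
                                day = 2.0 * a * _vsum(Ex, Ey, Ez, R, ax, ay + 1, az, bx, by, bz) \
                                    - ay * _vsum(Ex, Ey, Ez, R, ax, ay - 1, az, bx, by, bz)
                                daz = 2.0 * a * _vsum(Ex, Ey, Ez, R, ax, ay, az + 1, bx, by, bz) \
                                    - az * _vsum(Ex, Ey, Ez, R, ax, ay, az - 1, bx, by, bz)
                                dbx = 2.0 * b * _vsum(Ex, Ey, Ez, R, ax, ay, az, bx + 1, by, bz) \
                                    - bx * _vsum(Ex, Ey, Ez, R, ax, ay, az, bx - 1, by, bz)
                                dby = 2.0 * b * _vsum(Ex, Ey, Ez, R, ax, ay, az, bx, by + 1, bz) \
                                    - by * _vsum(Ex, Ey, Ez, R, ax, ay, az, bx, by - 1, bz)
                                dbz = 2.0 * b * _vsum(Ex, Ey, Ez, R, ax, ay, az, bx, by, bz + 1) \
                                    - bz * _vsum(Ex, Ey, Ez, R, ax, ay, az, bx, by, bz - 1)
                                grad[ia, 0] += c * dax
                                grad[ia, 1] += c * day
                                grad[ia, 2] += c * daz
                                grad[ib, 0] += c * dbx
                                grad[ib, 1] += c * dby
                                grad[ib, 2] += c * dbz
                                # operator center by translational invariance
                                grad[ic, 0] -= c * (dax + dbx)
                                grad[ic, 1] -= c * (day + dby)
                                grad[ic, 2] -= c * (daz + dbz)
    return grad


@njit(cache=True)
def grad_coulomb_contract(shell_l, shell_atom, centers, nprim, pptr, pexp, pcoef,
                          cart_off, natm, Pc, screen):
    """Coulomb-energy gradient: dE_J/dR with E_J = 1/2 sum P P (ab|cd).

    Only bra-center derivatives are assembled: summed over all bra/ket pair
    combinations they cover the ket terms too (the integral and the density
    weights are invariant under the bra<->ket swap). The ket side is
    precontracted with the Hermite table once per element pair.
    """
    grad = np.zeros((natm, 3))
    nsh = len(shell_l)
    # Schwarz factors and block max densities
    Q = np.zeros((nsh, nsh))
    blk = np.empty((10, 10, 10, 10))
    for s1 in range(nsh):
        l1 = shell_l[s1]
        n1 = _COFF[l1 + 1] - _COFF[l1]
        for s2 in range(s1 + 1):
            l2 = shell_l[s2]
            n2 = _COFF[l2 + 1] - _COFF[l2]
            _eri_quartet(l1, l2, l1, l2, centers[s1], centers[s2], centers[s1], centers[s2],
                         pexp[pptr[s1]:pptr[s1 + 1]], pcoef[pptr[s1]:pptr[s1 + 1]],
                         pexp[pptr[s2]:pptr[s2 + 1]], pcoef[pptr[s2]:pptr[s2 + 1]],
                         pexp[pptr[s1]:pptr[s1 + 1]], pcoef[pptr[s1]:pptr[s1 + 1]],
                         pexp[pptr[s2]:pptr[s2 + 1]], pcoef[pptr[s2]:pptr[s2 + 1]],
                         blk)
            qmax = 0.0
            for i in range(n1):
                for j in range(n2):
                    v = abs(blk[i, j, i, j])
                    if v > qmax:
                        qmax = v
            Q[s1, s2] = np.sqrt(qmax)
            Q[s2, s1] = Q[s1, s2]
    Pmax = np.zeros((nsh, nsh))
    for s1 in range(nsh):
        n1 = _COFF[shell_l[s1] + 1] - _COFF[shell_l[s1]]
        for s2 in range(nsh):
            n2 = _COFF[shell_l[s2] + 1] - _COFF[shell_l[s2]]
            m = 0.0
            for i in range(n1):
                for j in range(n2):
                    v = abs(Pc[cart_off[s1] + i, cart_off[s2] + j])
                    if v > m:
                        m = v
            Pmax[s1, s2] = m

    Ex1 = np.zeros((6, 6, 14))
    Ey1 = np.zeros((6, 6, 14))
    Ez1 = np.zeros((6, 6, 14))
    Ex2 = np.zeros((5, 5, 13))
    Ey2 = np.zeros((5, 5, 13))
    Ez2 = np.zeros((5, 5, 13))
    Rw = np.zeros((15, 15, 15))
    Rn = np.zeros((43, 15, 15, 15))
    Fb = np.zeros(43)
    K3 = np.zeros((15, 15, 15))
    # loop over unordered bra pairs x unordered ket pairs
    for s1 in range(nsh):
        l1 = shell_l[s1]
        n1 = _COFF[l1 + 1] - _COFF[l1]
        A = centers[s1]
        ia1 = shell_atom[s1]
        for s2 in range(s1 + 1):
            l2 = shell_l[s2]
            n2 = _COFF[l2 + 1] - _COFF[l2]
            B = centers[s2]
            ia2 = shell_atom[s2]
            w12 = 1.0 if s1 == s2 else 2.0
            AB2 = (A[0] - B[0]) ** 2 + (A[1] - B[1]) ** 2 + (A[2] - B[2]) ** 2
            for s3 in range(nsh):
                l3 = shell_l[s3]
                n3 = _COFF[l3 + 1] - _COFF[l3]
                C = centers[s3]
                for s4 in range(s3 + 1):
                    if Q[s1, s2] * Q[s3, s4] * max(Pmax[s1, s2] * Pmax[s3, s4], 1e-8) < screen:
                        continue
                    l4 = shell_l[s4]
                    n4 = _COFF[l4 + 1] - _COFF[l4]
                    D = centers[s4]
                    w = w12 * (1.0 if s3 == s4 else 2.0)
                    CD2 = (C[0] - D[0]) ** 2 + (C[1] - D[1]) ** 2 + (C[2] - D[2]) ** 2
                    L12 = l1 + l2 + 1
                    L34 = l3 + l4
                    gA = np.zeros(3)
                    gB = np.zeros(3)
                    for ip in range(pptr[s1], pptr[s1 + 1]):
                        a = pexp[ip]
                        for jp in range(pptr[s2], pptr[s2 + 1]):
                            b = pexp[jp]
                            p = a + b
                            Kab = np.exp(-a * b / p * AB2)
                            if Kab * abs(pcoef[ip] * pcoef[jp]) < 1e-15:
                                continue
                            Px = (a * A[0] + b * B[0]) / p
                            Py = (a * A[1] + b * B[1]) / p
                            Pz = (a * A[2] + b * B[2]) / p
                            _ecoef(l1 + 1, l2 + 1, Px - A[0], Px - B[0], 0.5 / p, Ex1)
                            _ecoef(l1 + 1, l2 + 1, Py - A[1], Py - B[1], 0.5 / p, Ey1)
                            _ecoef(l1 + 1, l2 + 1, Pz - A[2], Pz - B[2], 0.5 / p, Ez1)
                            for kp in range(pptr[s3], pptr[s3 + 1]):
                                c = pexp[kp]
                                for mp in range(pptr[s4], pptr[s4 + 1]):
                                    d = pexp[mp]
                                    q = c + d
                                    Kcd = np.exp(-c * d / q * CD2)
                                    pref = (2.0 * np.pi ** 2.5 / (p * q * np.sqrt(p + q))
                                            * Kab * Kcd * pcoef[ip] * pcoef[jp]
                                            * pcoef[kp] * pcoef[mp])
                                    if abs(pref) < 1e-15:
                                        continue
                                    Qx = (c * C[0] + d * D[0]) / q
                                    Qy = (c * C[1] + d * D[1]) / q
                                    Qz = (c * C[2] + d * D[2]) / q
                                    _ecoef(l3, l4, Qx - C[0], Qx - D[0], 0.5 / q, Ex2)
                                    _ecoef(l3, l4, Qy - C[1], Qy - D[1], 0.5 / q, Ey2)
                                    _ecoef(l3, l4, Qz - C[2], Qz - D[2], 0.5 / q, Ez2)
                                    theta = p * q / (p + q)
                                    _rhermite_buf(L12 + L34, L12 + L34, L12 + L34, theta,
                                                  Px - Qx, Py - Qy, Pz - Qz, Rw, Rn, Fb)
                                    for k in range(n3):
                                        cx = _CCOMP[_COFF[l3] + k, 0]
                                        cy = _CCOMP[_COFF[l3] + k, 1]
                                        cz = _CCOMP[_COFF[l3] + k, 2]
                                        for m in range(n4):
                                            dx = _CCOMP[_COFF[l4] + m, 0]
                                            dy = _CCOMP[_COFF[l4] + m, 1]
                                            dz = _CCOMP[_COFF[l4] + m, 2]
                                            pcd = Pc[cart_off[s3] + k, cart_off[s4] + m]
                                            if abs(pcd) * Pmax[s1, s2] * Q[s1, s2] * Q[s3, s4] * abs(pref) < 1e-16:
                                                continue
                                            _ket_contract(Ex2, Ey2, Ez2, Rw, cx, cy, cz,
                                                          dx, dy, dz, L12, K3)
                                            for i in range(n1):
                                                ax = _CCOMP[_COFF[l1] + i, 0]
                                                ay = _CCOMP[_COFF[l1] + i, 1]
                                                az = _CCOMP[_COFF[l1] + i, 2]
                                                for j in range(n2):
                                                    pab = Pc[cart_off[s1] + i, cart_off[s2] + j]
                                                    gam = pref * pab * pcd
                                                    if abs(gam) < 1e-15:
                                                        continue
                                                    bx = _CCOMP[_COFF[l2] + j, 0]
                                                    by = _CCOMP[_COFF[l2] + j, 1]
                                                    bz = _CCOMP[_COFF[l2] + j, 2]
                                                    dax = 2.0 * a * _bra_sum(Ex1, Ey1, Ez1, K3, ax + 1, ay, az, bx, by, bz) \
                                                        - ax * _bra_sum(Ex1, Ey1, Ez1, K3, ax - 1, ay, az, bx, by, bz)
                                                    day = 2.0 * a * _bra_sum(Ex1, Ey1, Ez1, K3, ax, ay + 1, az, bx, by, bz) \
                                                        - ay * _bra_sum(Ex1, Ey1, Ez1, K3, ax, ay - 1, az, bx, by, bz)
                                                    daz = 2.0 * a * _bra_sum(Ex1, Ey1, Ez1, K3, ax, ay, az + 1, bx, by, bz) \
                                                        - az * _bra_sum(Ex1, Ey1, Ez1, K3, ax, ay, az - 1, bx, by, bz)
                                                    dbx = 2.0 * b * _bra_sum(Ex1, Ey1, Ez1, K3, ax, ay, az, bx + 1, by, bz)
                                                    if bx > 0:
                                                        dbx -= bx * _bra_sum(Ex1, Ey1, Ez1, K3, ax, ay, az, bx - 1, by, bz)
                                                    dby = 2.0 * b * _bra_sum(Ex1, Ey1, Ez1, K3, ax, ay, az, bx, by + 1, bz)
                                                    if by > 0:
                                                        dby -= by * _bra_sum(Ex1, Ey1, Ez1, K3, ax, ay, az, bx, by - 1, bz)
                                                    dbz = 2.0 * b * _bra_sum(Ex1, Ey1, Ez1, K3, ax, ay, az, bx, by, bz + 1)
                                                    if bz > 0:
                                                        dbz -= bz * _bra_sum(Ex1, Ey1, Ez1, K3, ax, ay, az, bx, by, bz - 1)
                                                    gA[0] += gam * dax
                                                    gA[1] += gam * day
                                                    gA[2] += gam * daz
                                                    gB[0] += gam * dbx
                                                    gB[1] += gam * dby
                                                    gB[2] += gam * dbz
                    for x in range(3):
                        grad[ia1, x] += w * gA[x]
                        grad[ia2, x] += w * gB[x]
    return grad
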