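"""Numba kernels: McMurchie-Davidson Gaussian integrals and grid AO evaluation.

All kernels work in the Cartesian primitive representation with
axial-normalized contraction coefficients; the spherical transform is
applied by the callers. Units are atomic throughout.
"""

import numpy as np
from numba import njit

# Cartesian component tables for l = 0..3, concatenated; _COFF[l] indexes the
# start of the l-block in _CCOMP.
_COFF = np.array([0, 1, 4, 10, 20], dtype=np.int64)


def _make_ccomp():
    rows = []
    for l in range(4):
        for lx in range(l, -1, -1):
            for ly in range(l - lx, -1, -1):
                rows.append((lx, ly, l - lx - ly))
    return np.array(rows, dtype=np.int64)


_CCOMP = _make_ccomp()


@njit(cache=True)
def _boys(mmax, x, out):
    if x < 1e-13:
        for m in range(mmax + 1):
            out[m] = 1.0 / (2 * m + 1)
        return
    if x > 35.0:
        out[0] = 0.5 * np.sqrt(np.pi / x)
        ex = np.exp(-x)
        for m in range(mmax):
            out[m + 1] = ((2 * m + 1) * out[m] - ex) / (2 * x)
        return
    ex = np.exp(-x)
    s = 1.0 / (2 * mmax + 1)
    term = s
    k = 0
    while True:
        k += 1
        term *= 2 * x / (2 * mmax + 2 * k + 1)
        s += term
        if term < 1e-17 * s or k > 300:
            break
    out[mmax] = s * ex
    for m in range(mmax - 1, -1, -1):
        out[m] = (2 * x * out[m + 1] + ex) / (2 * m + 1)


@njit(cache=True)
def _ecoef(la, lb, PA, PB, oo2p, E):
    """Hermite expansion coefficients E[i,j,t] for one dimension (no K factor)."""
    for i in range(la + 1):
        for j in range(lb + 1):
            for t in range(la + lb + 1):
                E[i, j, t] = 0.0
    E[0, 0, 0] = 1.0
    for i in range(la):
        for t in range(i + 2):
            v = 0.0
            if t >= 1:
                v += oo2p * E[i, 0, t - 1]
            if t <= i:
                v += PA * E[i, 0, t]
            if t + 1 <= i:
                v += (t + 1) * E[i, 0, t + 1]
            E[i + 1, 0, t] = v
    for i in range(la + 1):
        for j in range(lb):
            for t in range(i + j + 2):
                v = 0.0
                if t >= 1:
                    v += oo2p * E[i, j, t - 1]
                if t <= i + j:
                    v += PB * E[i, j, t]
                if t + 1 <= i + j:
                    v += (t + 1) * E[i, j, t + 1]
                E[i, j + 1, t] = v


@njit(cache=True)
def _rhermite(tmax, umax, vmax, p, X, Y, Z, R):
    """Hermite Coulomb integrals R[t,u,v] = R^0_{tuv}(p, (X,Y,Z))."""
    nmax = tmax + umax + vmax
    F = np.empty(nmax + 1)
    _boys(nmax, p * (X * X + Y * Y + Z * Z), F)
    Rn = np.zeros((nmax + 1, tmax + 1, umax + 1, vmax + 1))
    pw = 1.0
    for n in range(nmax + 1):
        Rn[n, 0, 0, 0] = pw * F[n]
        pw *= -2.0 * p
    for v in range(vmax):
        for n in range(nmax - v):
            if v >= 1:
                Rn[n, 0, 0, v + 1] = v * Rn[n + 1, 0, 0, v - 1] + Z * Rn[n + 1, 0, 0, v]
            else:
                Rn[n, 0, 0, v + 1] = Z * Rn[n + 1, 0, 0, v]
    for u in range(umax):
        for n in range(nmax - u):
            for v in range(vmax + 1):
                if u >= 1:
                    Rn[n, 0, u + 1, v] = u * Rn[n + 1, 0, u - 1, v] + Y * Rn[n + 1, 0, u, v]
                else:
                    Rn[n, 0, u + 1, v] = Y * Rn[n + 1, 0, u, v]
    for t in range(tmax):
        for n in range(nmax - t):
            for u in range(umax + 1):
                for v in range(vmax + 1):
                    if t >= 1:
                        Rn[n, t + 1, u, v] = t * Rn[n + 1, t - 1, u, v] + X * Rn[n + 1, t, u, v]
                    else:
                        Rn[n, t + 1, u, v] = X * Rn[n + 1, t, u, v]
    for t in range(tmax + 1):
        for u in range(umax + 1):
            for v in range(vmax + 1):
                R[t, u, v] = Rn[0, t, u, v]


@njit(cache=True)
def _pair_overlap_kinetic(l1, l2, A, B, e1, c1, e2, c2, Sb, Tb):
    """Overlap and kinetic blocks for one shell pair (Cartesian)."""
    n1 = _COFF[l1 + 1] - _COFF[l1]
    n2 = _COFF[l2 + 1] - _COFF[l2]
    for i in range(n1):
        for j in range(n2):
            Sb[i, j] = 0.0
            Tb[i, j] = 0.0
    AB2 = (A[0] - B[0]) ** 2 + (A[1] - B[1]) ** 2 + (A[2] - B[2]) ** 2
    # E tables with ket raised by 2 for the kinetic form
    Ex = np.zeros((l1 + 1, l2 + 3, l1 + l2 + 3))
    Ey = np.zeros((l1 + 1, l2 + 3, l1 + l2 + 3))
    Ez = np.zeros((l1 + 1, l2 + 3, l1 + l2 + 3))
    for ip in range(len(e1)):
        a = e1[ip]
        for jp in range(len(e2)):
            b = e2[jp]
            p = a + b
            oo2p = 0.5 / p
            K = np.exp(-a * b / p * AB2) * c1[ip] * c2[jp] * (np.pi / p) ** 1.5
            Px = (a * A[0] + b * B[0]) / p
            Py = (a * A[1] + b * B[1]) / p
            Pz = (a * A[2] + b * B[2]) / p
            _ecoef(l1, l2 + 2, Px - A[0], Px - B[0], oo2p, Ex)
            _ecoef(l1, l2 + 2, Py - A[1], Py - B[1], oo2p, Ey)
            _ecoef(l1, l2 + 2, Pz - A[2], Pz - B[2], oo2p, Ez)
            for i in range(n1):
                ax = _CCOMP[_COFF[l1] + i, 0]
                ay = _CCOMP[_COFF[l1] + i, 1]
                az = _CCOMP[_COFF[l1] + i, 2]
                for j in range(n2):
                    bx = _CCOMP[_COFF[l2] + j, 0]
                    by = _CCOMP[_COFF[l2] + j, 1]
                    bz = _CCOMP[_COFF[l2] + j, 2]
                    sx = Ex[ax, bx, 0]
                    sy = Ey[ay, by, 0]
                    sz = Ez[az, bz, 0]
                    # 1D kinetic: -2b^2 S_{i,j+2} + b(2j+1) S_{ij} - j(j-1)/2 S_{i,j-2}
                    tx = -2.0 * b * b * Ex[ax, bx + 2, 0] + b * (2 * bx + 1) * sx
                    if bx >= 2:
                        tx -= 0.5 * bx * (bx - 1) * Ex[ax, bx - 2, 0]
                    ty = -2.0 * b * b * Ey[ay, by + 2, 0] + b * (2 * by + 1) * sy
                    if by >= 2:
                        ty -= 0.5 * by * (by - 1) * Ey[ay, by - 2, 0]
                    tz = -2.0 * b * b * Ez[az, bz + 2, 0] + b * (2 * bz + 1) * sz
                    if bz >= 2:
                        tz -= 0.5 * bz * (bz - 1) * Ez[az, bz - 2, 0]
                    Sb[i, j] += K * sx * sy * sz
                    Tb[i, j] += K * (tx * sy * sz + sx * ty * sz + sx * sy * tz)


@njit(cache=True)
def build_s_t(shell_l, centers, nprim, pptr, pexp, pcoef, cart_off, ncart):
    nsh = len(shell_l)
    S = np.zeros((ncart, ncart))
    T = np.zeros((ncart, ncart))
    Sb = np.empty((10, 10))
    Tb = np.empty((10, 10))
    for s1 in range(nsh):
        l1 = shell_l[s1]
        n1 = _COFF[l1 + 1] - _COFF[l1]
        for s2 in range(s1 + 1):
            l2 = shell_l[s2]
            n2 = _COFF[l2 + 1] - _COFF[l2]
            _pair_overlap_kinetic(
                l1, l2, centers[s1], centers[s2],
                pexp[pptr[s1]:pptr[s1 + 1]], pcoef[pptr[s1]:pptr[s1 + 1]],
                pexp[pptr[s2]:pptr[s2 + 1]], pcoef[pptr[s2]:pptr[s2 + 1]],
                Sb[:n1, :n2], Tb[:n1, :n2])
            for i in range(n1):
                for j in range(n2):
                    S[cart_off[s1] + i, cart_off[s2] + j] = Sb[i, j]
                    S[cart_off[s2] + j, cart_off[s1] + i] = Sb[i, j]
                    T[cart_off[s1] + i, cart_off[s2] + j] = Tb[i, j]
                    T[cart_off[s2] + j, cart_off[s1] + i] = Tb[i, j]
    return S, T


@njit(cache=True)
def build_nuclear(shell_l, centers, nprim, pptr, pexp, pcoef, cart_off, ncart,
                  atom_coords, atom_charges):
    """Nuclear-attraction matrix V (Cartesian)."""
    nsh = len(shell_l)
    V = np.zeros((ncart, ncart))
    for s1 in range(nsh):
        l1 = shell_l[s1]
        n1 = _COFF[l1 + 1] - _COFF[l1]
        A = centers[s1]
        for s2 in range(s1 + 1):
            l2 = shell_l[s2]
            n2 = _COFF[l2 + 1] - _COFF[l2]
            B = centers[s2]
            AB2 = (A[0] - B[0]) ** 2 + (A[1] - B[1]) ** 2 + (A[2] - B[2]) ** 2
            L = l1 + l2
            Ex = np.zeros((l1 + 1, l2 + 1, L + 1))
            Ey = np.zeros((l1 + 1, l2 + 1, L + 1))
            Ez = np.zeros((l1 + 1, l2 + 1, L + 1))
            R = np.zeros((L + 1, L + 1, L + 1))
            Vb = np.zeros((n1, n2))
            for ip in range(pptr[s1], pptr[s1 + 1]):
                a = pexp[ip]
                for jp in range(pptr[s2], pptr[s2 + 1]):
                    b = pexp[jp]
                    p = a + b
                    oo2p = 0.5 / p
                    K = np.exp(-a * b / p * AB2) * pcoef[ip] * pcoef[jp] * 2.0 * np.pi / p
                    Px = (a * A[0] + b * B[0]) / p
                    Py = (a * A[1] + b * B[1]) / p
                    Pz = (a * A[2] + b * B[2]) / p
                    _ecoef(l1, l2, Px - A[0], Px - B[0], oo2p, Ex)
                    _ecoef(l1, l2, Py - A[1], Py - B[1], oo2p, Ey)
                    _ecoef(l1, l2, Pz - A[2], Pz - B[2], oo2p, Ez)
                    for ic in range(len(atom_charges)):
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
                                bx = _CCOMP[_COFF[l2] + j, 0]
                                by = _CCOMP[_COFF[l2] + j, 1]
                                bz = _CCOMP[_COFF[l2] + j, 2]
                                acc = 0.0
                                for t in range(ax + bx + 1):
                                    ex = Ex[ax, bx, t]
                                    if ex == 0.0:
                                        continue
                                    for u in range(ay + by + 1):
                                        ey = Ey[ay, by, u]
                                        if ey == 0.0:
                                            continue
                                        for v in range(az + bz + 1):
                                            acc += ex * ey * Ez[az, bz, v] * R[t, u, v]
                                Vb[i, j] -= K * Z * acc
            for i in range(n1):
                for j in range(n2):
                    V[cart_off[s1] + i, cart_off[s2] + j] += Vb[i, j]
                    if s1 != s2:
                        V[cart_off[s2] + j, cart_off[s1] + i] += Vb[i, j]
                    Vb[i, j] = 0.0
    return V


@njit(cache=True)
def _eri_quartet(l1, l2, l3, l4, A, B, C, D, e1, c1, e2, c2, e3, c3, e4, c4, out):
    """One shell quartet (ab|cd) of Cartesian ERIs, accumulated into out."""
    n1 = _COFF[l1 + 1] - _COFF[l1]
    n2 = _COFF[l2 + 1] - _COFF[l2]
    n3 = _COFF[l3 + 1] - _COFF[l3]
    n4 = _COFF[l4 + 1] - _COFF[l4]
    for i in range(n1):
        for j in range(n2):
            for k in range(n3):
                for m in range(n4):
                    out[i, j, k, m] = 0.0
    AB2 = (A[0] - B[0]) ** 2 + (A[1] - B[1]) ** 2 + (A[2] - B[2]) ** 2
    CD2 = (C[0] - D[0]) ** 2 + (C[1] - D[1]) ** 2 + (C[2] - D[2]) ** 2
    L12 = l1 + l2
    L34 = l3 + l4
    Ex1 = np.zeros((l1 + 1, l2 + 1, L12 + 1))
    Ey1 = np.zeros((l1 + 1, l2 + 1, L12 + 1))
    Ez1 = np.zeros((l1 + 1, l2 + 1, L12 + 1))
    Ex2 = np.zeros((l3 + 1, l4 + 1, L34 + 1))
    Ey2 = np.zeros((l3 + 1, l4 + 1, L34 + 1))
    Ez2 = np.zeros((l3 + 1, l4 + 1, L34 + 1))
    R = np.zeros((L12 + L34 + 1, L12 + L34 + 1, L12 + L34 + 1))
    for ip in range(len(e1)):
        a = e1[ip]
        for jp in range(len(e2)):
            b = e2[jp]
            p = a + b
            Kab = np.exp(-a * b / p * AB2)
            if Kab * abs(c1[ip] * c2[jp]) < 1e-16:
                continue
            Px = (a * A[0] + b * B[0]) / p
            Py = (a * A[1] + b * B[1]) / p
            Pz = (a * A[2] + b * B[2]) / p
            _ecoef(l1, l2, Px - A[0], Px - B[0], 0.5 / p, Ex1)
            _ecoef(l1, l2, Py - A[1], Py - B[1], 0.5 / p, Ey1)
            _ecoef(l1, l2, Pz - A[2], Pz - B[2], 0.5 / p, Ez1)
            for kp in range(len(e3)):
                c = e3[kp]
                for mp in range(len(e4)):
                    d = e4[mp]
                    q = c + d
                    Kcd = np.exp(-c * d / q * CD2)
                    pref = (2.0 * np.pi ** 2.5 / (p * q * np.sqrt(p + q))
                            * Kab * Kcd * c1[ip] * c2[jp] * c3[kp] * c4[mp])
                    if abs(pref) < 1e-16:
                        continue
                    Qx = (c * C[0] + d * D[0]) / q
                    Qy = (c * C[1] + d * D[1]) / q
                    Qz = (c * C[2] + d * D[2]) / q
                    _ecoef(l3, l4, Qx - C[0], Qx - D[0], 0.5 / q, Ex2)
                    _ecoef(l3, l4, Qy - C[1], Qy - D[1], 0.5 / q, Ey2)
                    _ecoef(l3, l4, Qz - C[2], Qz - D[2], 0.5 / q, Ez2)
                    theta = p * q / (p + q)
                    _rhermite(L12 + L34, L12 + L34, L12 + L34, theta,
                              Px - Qx, Py - Qy, Pz - Qz, R)
                    for i in range(n1):
                        ax = _CCOMP[_COFF[l1] + i, 0]
                        ay = _CCOMP[_COFF[l1] + i, 1]
                        az = _CCOMP[_COFF[l1] + i, 2]
                        for j in range(n2):
                            bx = _CCOMP[_COFF[l2] + j, 0]
                            by = _CCOMP[_COFF[l2] + j, 1]
                            bz = _CCOMP[_COFF[l2] + j, 2]
                            for k in range(n3):
                                cx = _CCOMP[_COFF[l3] + k, 0]
                                cy = _CCOMP[_COFF[l3] + k, 1]
                                cz = _CCOMP[_COFF[l3] + k, 2]
                                for m in range(n4):
                                    dx = _CCOMP[_COFF[l4] + m, 0]
                                    dy = _CCOMP[_COFF[l4] + m, 1]
                                    dz = _CCOMP[_COFF[l4] + m, 2]
                                    acc = 0.0
                                    for t in range(ax + bx + 1):
                                        e1x = Ex1[ax, bx, t]
                                        if e1x == 0.0:
                                            continue
                                        for u in range(ay + by + 1):
                                            e1y = Ey1[ay, by, u]
                                            if e1y == 0.0:
                                                continue
                                            for v in range(az + bz + 1):
                                                e1z = Ez1[az, bz, v]
                                                if e1z == 0.0:
                                                    continue
                                                inner = 0.0
                                                for tt in range(cx + dx + 1):
                                                    e2x = Ex2[cx, dx, tt]
                                                    if e2x == 0.0:
                                                        continue
                                                    for uu in range(cy + dy + 1):
                                                        e2y = Ey2[cy, dy, uu]
                                                        if e2y == 0.0:
                                                            continue
                                                        for vv in range(cz + dz + 1):
                                                            e2z = Ez2[cz, dz, vv]
                                                            if e2z == 0.0:
                                                                continue
                                                            sgn = 1.0 if (tt + uu + vv) % 2 == 0 else -1.0
                                                            inner += sgn * e2x * e2y * e2z * R[t + tt, u + uu, v + vv]
                                                acc += e1x * e1y * e1z * inner
                                    out[i, j, k, m] += pref * acc
    return


@njit(cache=True)
def build_eri_cart(shell_l, centers, nprim, pptr, pexp, pcoef, cart_off, ncart,
                   screen_thresh):
    """Full Cartesian ERI tensor with 8-fold permutational symmetry and
    Schwarz screening."""
    nsh = len(shell_l)
    eri = np.zeros((ncart, ncart, ncart, ncart))
    blk = np.empty((10, 10, 10, 10))
    # Schwarz factors
    Q = np.zeros((nsh, nsh))
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
    Ex1 = np.zeros((5, 5, 13))
    Ey1 = np.zeros((5, 5, 13))
    Ez1 = np.zeros((5, 5, 13))
    Ex2 = np.zeros((5, 5, 13))
    Ey2 = np.zeros((5, 5, 13))
    Ez2 = np.zeros((5, 5, 13))
    Rw = np.zeros((14, 14, 14))
    Rn = np.zeros((40, 14, 14, 14))
    Fb = np.zeros(40)
    K3 = np.zeros((14, 14, 14))
    for s1 in range(nsh):
        l1 = shell_l[s1]
        n1 = _COFF[l1 + 1] - _COFF[l1]
        o1 = cart_off[s1]
        for s2 in range(s1 + 1):
            l2 = shell_l[s2]
            n2 = _COFF[l2 + 1] - _COFF[l2]
            o2 = cart_off[s2]
            for s3 in range(s1 + 1):
                l3 = shell_l[s3]
                n3 = _COFF[l3 + 1] - _COFF[l3]
                o3 = cart_off[s3]
                s4max = s2 if s3 == s1 else s3
                for s4 in range(s4max + 1):
                    if Q[s1, s2] * Q[s3, s4] < screen_thresh:
                        continue
                    l4 = shell_l[s4]
                    n4 = _COFF[l4 + 1] - _COFF[l4]
                    o4 = cart_off[s4]
                    _eri_quartet_fast(l1, l2, l3, l4, centers[s1], centers[s2], centers[s3], centers[s4],
                                 pexp[pptr[s1]:pptr[s1 + 1]], pcoef[pptr[s1]:pptr[s1 + 1]],
                                 pexp[pptr[s2]:pptr[s2 + 1]], pcoef[pptr[s2]:pptr[s2 + 1]],
                                 pexp[pptr[s3]:pptr[s3 + 1]], pcoef[pptr[s3]:pptr[s3 + 1]],
                                 pexp[pptr[s4]:pptr[s4 + 1]], pcoef[pptr[s4]:pptr[s4 + 1]],
                                 blk, Ex1, Ey1, Ez1, Ex2, Ey2, Ez2, Rw, Rn, Fb, K3)
                    for i in range(n1):
                        for j in range(n2):
                            for k in range(n3):
                                for m in range(n4):
                                    v = blk[i, j, k, m]
                                    I = o1 + i
                                    J = o2 + j
                                    K = o3 + k
                                    M = o4 + m
                                    eri[I, J, K, M] = v
                                    eri[J, I, K, M] = v
                                    eri[I, J, M, K] = v
                                    eri[J, I, M, K] = v
                                    eri[K, M, I, J] = v
                                    eri[M, K, I, J] = v
                                    eri[K, M, J, I] = v
                                    eri[M, K, J, I] = v
    return eri


@njit(cache=True)
def eval_ao_cart(shell_l, centers, nprim, pptr, pexp, pcoef, cart_off, ncart,
                 pts, deriv):
    """AO values (and derivatives) on grid points.

    Returns array (ncomp, npts, ncart) with ncomp = 1 (values), 4 (+gradient)
    or 10 (+second derivatives xx,xy,xz,yy,yz,zz).
    """
    npts = pts.shape[0]
    ncomp = 1
    if deriv == 1:
        ncomp = 4
    elif deriv == 2:
        ncomp = 10
    out = np.zeros((ncomp, npts, ncart))
    nsh = len(shell_l)
    for s in range(nsh):
        l = shell_l[s]
        n = _COFF[l + 1] - _COFF[l]
        o = cart_off[s]
        cx = centers[s, 0]
        cy = centers[s, 1]
        cz = centers[s, 2]
        for g in range(npts):
            dx = pts[g, 0] - cx
            dy = pts[g, 1] - cy
            dz = pts[g, 2] - cz
            r2 = dx * dx + dy * dy + dz * dz
            s0 = 0.0
            s1 = 0.0
            s2 = 0.0
            for ip in range(pptr[s], pptr[s + 1]):
                a = pexp[ip]
                ar2 = a * r2
                if ar2 > 40.0:
                    continue
                e = pcoef[ip] * np.exp(-ar2)
                s0 += e
                s1 += a * e
                s2 += a * a * e
            if s0 == 0.0 and s1 == 0.0:
                continue
            # monomial powers
            for i in range(n):
                axp = _CCOMP[_COFF[l] + i, 0]
                ayp = _CCOMP[_COFF[l] + i, 1]
                azp = _CCOMP[_COFF[l] + i, 2]
                px = dx ** axp
                py = dy ** ayp
                pz = dz ** azp
                P = px * py * pz
                out[0, g, o + i] = P * s0
                if deriv >= 1:
                    Pdx = axp * dx ** (axp - 1) * py * pz if axp > 0 else 0.0
                    Pdy = ayp * px * dy ** (ayp - 1) * pz if ayp > 0 else 0.0
                    Pdz = azp * px * py * dz ** (azp - 1) if azp > 0 else 0.0
                    out[1, g, o + i] = Pdx * s0 - 2.0 * dx * P * s1
                    out[2, g, o + i] = Pdy * s0 - 2.0 * dy * P * s1
                    out[3, g, o + i] = Pdz * s0 - 2.0 * dz * P * s1
                    if deriv >= 2:
                        Pxx = axp * (axp - 1) * dx ** (axp - 2) * py * pz if axp > 1 else 0.0
                        Pyy = ayp * (ayp - 1) * px * dy ** (ayp - 2) * pz if ayp > 1 else 0.0
                        Pzz = azp * (azp - 1) * px * py * dz ** (azp - 2) if azp > 1 else 0.0
                        Pxy = (axp * ayp * dx ** (axp - 1) * dy ** (ayp - 1) * pz
                               if axp > 0 and ayp > 0 else 0.0)
                        Pxz = (axp * azp * dx ** (axp - 1) * py * dz ** (azp - 1)
                               if axp > 0 and azp > 0 else 0.0)
                        Pyz = (ayp * azp * px * dy ** (ayp - 1) * dz ** (azp - 1)
                               if ayp > 0 and azp > 0 else 0.0)
                        out[4, g, o + i] = (Pxx * s0 - 2.0 * s1 * (2.0 * dx * Pdx + P)
                                            + 4.0 * dx * dx * P * s2)
                        out[5, g, o + i] = (Pxy * s0 - 2.0 * s1 * (dx * Pdy + dy * Pdx)
                                            + 4.0 * dx * dy * P * s2)
                        out[6, g, o + i] = (Pxz * s0 - 2.0 * s1 * (dx * Pdz + dz * Pdx)
                                            + 4.0 * dx * dz * P * s2)
                        out[7, g, o + i] = (Pyy * s0 - 2.0 * s1 * (2.0 * dy * Pdy + P)
                                            + 4.0 * dy * dy * P * s2)
                        out[8, g, o + i] = (Pyz * s0 - 2.0 * s1 * (dy * Pdz + dz * Pdy)
                                            + 4.0 * dy * dz * P * s2)
                        out[9, g, o + i] = (Pzz * s0 - 2.0 * s1 * (2.0 * dz * Pdz + P)
                                            + 4.0 * dz * dz * P * s2)
    return out


@njit(cache=True)
def _rhermite_buf(tmax, umax, vmax, p, X, Y, Z, R, Rn, F):
    """As _rhermite but with caller-provided work buffers (hot path)."""
    nmax = tmax + umax + vmax
    _boys(nmax, p * (X * X + Y * Y + Z * Z), F)
    pw = 1.0
    for n in range(nmax + 1):
        Rn[n, 0, 0, 0] = pw * F[n]
        pw *= -2.0 * p
    for v in range(vmax):
        for n in range(nmax - v):
            if v >= 1:
                Rn[n, 0, 0, v + 1] = v * Rn[n + 1, 0, 0, v - 1] + Z * Rn[n + 1, 0, 0, v]
            else:
                Rn[n, 0, 0, v + 1] = Z * Rn[n + 1, 0, 0, v]
    for u in range(umax):
        for n in range(nmax - u):
            for v in range(vmax + 1):
                if u >= 1:
                    Rn[n, 0, u + 1, v] = u * Rn[n + 1, 0, u - 1, v] + Y * Rn[n + 1, 0, u, v]
                else:
                    Rn[n, 0, u + 1, v] = Y * Rn[n + 1, 0, u, v]
    for t in range(tmax):
        for n in range(nmax - t):
            for u in range(umax + 1):
                for v in range(vmax + 1):
                    if t >= 1:
                        Rn[n, t + 1, u, v] = t * Rn[n + 1, t - 1, u, v] + X * Rn[n + 1, t, u, v]
                    else:
                        Rn[n, t + 1, u, v] = X * Rn[n + 1, t, u, v]
    for t in range(tmax + 1):
        for u in range(umax + 1):
            for v in range(vmax + 1):
                R[t, u, v] = Rn[0, t, u, v]


@njit(cache=True, inline="always")
def _ket_contract(Ex2, Ey2, Ez2, R, cx, cy, cz, dx, dy, dz, tmax, K3):
    """K3[t,u,v] = sum_ket (-1)^(tt+uu+vv) E2x E2y E2z R[t+tt, u+uu, v+vv]."""
    for t in range(tmax + 1):
        for u in range(tmax + 1):
            for v in range(tmax + 1):
                acc = 0.0
                for tt in range(cx + dx + 1):
                    e2x = Ex2[cx, dx, tt]
                    if e2x == 0.0:
                        continue
                    for uu in range(cy + dy + 1):
                        e2y = Ey2[cy, dy, uu]
                        if e2y == 0.0:
                            continue
                        for vv in range(cz + dz + 1):
                            e2z = Ez2[cz, dz, vv]
                            if e2z == 0.0:
                                continue
                            if (tt + uu + vv) % 2 == 0:
                                acc += e2x * e2y * e2z * R[t + tt, u + uu, v + vv]
                            else:
                                acc -= e2x * e2y * e2z * R[t + tt, u + uu, v + vv]
                K3[t, u, v] = acc


@njit(cache=True, inline="always")
def _bra_sum(Ex1, Ey1, Ez1, K3, ax, ay, az, bx, by, bz):
    if ax < 0 or ay < 0 or az < 0:
        return 0.0
    acc = 0.0
    for t in range(ax + bx + 1):
        e1x = Ex1[ax, bx, t]
        if e1x == 0.0:
            continue
        for u in range(ay + by + 1):
            e1y = Ey1[ay, by, u]
            if e1y == 0.0:
                continue
            for v in range(az + bz + 1):
                e1z = Ez1[az, bz, v]
                if e1z != 0.0:
                    acc += e1x * e1y * e1z * K3[t, u, v]
    return acc


@njit(cache=True)
def _eri_quartet_fast(l1, l2, l3, l4, A, B, C, D, e1, c1, e2, c2, e3, c3, e4, c4,
                      out, Ex1, Ey1, Ez1, Ex2, Ey2, Ez2, R, Rn, Fb, K3):
    """Shell-quartet ERIs with ket precontraction and shared work buffers."""
    n1 = _COFF[l1 + 1] - _COFF[l1]
    n2 = _COFF[l2 + 1] - _COFF[l2]
    n3 = _COFF[l3 + 1] - _COFF[l3]
    n4 = _COFF[l4 + 1] - _COFF[l4]
    for i in range(n1):
        for j in range(n2):
            for k in range(n3):
                for m in range(n4):
                    out[i, j, k, m] = 0.0
    AB2 = (A[0] - B[0]) ** 2 + (A[1] - B[1]) ** 2 + (A[2] - B[2]) ** 2
    CD2 = (C[0] - D[0]) ** 2 + (C[1] - D[1]) ** 2 + (C[2] - D[2]) ** 2
    L12 = l1 + l2
    L34 = l3 + l4
    for ip in range(len(e1)):
        a = e1[ip]
        for jp in range(len(e2)):
            b = e2[jp]
            p = a + b
            Kab = np.exp(-a * b / p * AB2)
            if Kab * abs(c1[ip] * c2[jp]) < 1e-16:
                continue
            Px = (a * A[0] + b * B[0]) / p
            Py = (a * A[1] + b * B[1]) / p
            Pz = (a * A[2] + b * B[2]) / p
            _ecoef(l1, l2, Px - A[0], Px - B[0], 0.5 / p, Ex1)
            _ecoef(l1, l2, Py - A[1], Py - B[1], 0.5 / p, Ey1)
            _ecoef(l1, l2, Pz - A[2], Pz - B[2], 0.5 / p, Ez1)
            for kp in range(len(e3)):
                c = e3[kp]
                for mp in range(len(e4)):
                    d = e4[mp]
                    q = c + d
                    Kcd = np.exp(-c * d / q * CD2)
                    pref = (2.0 * np.pi ** 2.5 / (p * q * np.sqrt(p + q))
                            * Kab * Kcd * c1[ip] * c2[jp] * c3[kp] * c4[mp])
                    if abs(pref) < 1e-16:
                        continue
                    Qx = (c * C[0] + d * D[0]) / q
                    Qy = (c * C[1] + d * D[1]) / q
                    Qz = (c * C[2] + d * D[2]) / q
                    _ecoef(l3, l4, Qx - C[0], Qx - D[0], 0.5 / q, Ex2)
                    _ecoef(l3, l4, Qy - C[1], Qy - D[1], 0.5 / q, Ey2)
                    _ecoef(l3, l4, Qz - C[2], Qz - D[2], 0.5 / q, Ez2)
                    theta = p * q / (p + q)
                    _rhermite_buf(L12 + L34, L12 + L34, L12 + L34, theta,
                                  Px - Qx, Py - Qy, Pz - Qz, R, Rn, Fb)
                    for k in range(n3):
                        cx = _CCOMP[_COFF[l3] + k, 0]
                        cy = _CCOMP[_COFF[l3] + k, 1]
                        cz = _CCOMP[_COFF[l3] + k, 2]
                        for m in range(n4):
                            dx = _CCOMP[_COFF[l4] + m, 0]
                            dy = _CCOMP[_COFF[l4] + m, 1]
                            dz = _CCOMP[_COFF[l4] + m, 2]
                            _ket_contract(Ex2, Ey2, Ez2, R, cx, cy, cz,
                                          dx, dy, dz, L12, K3)
                            for i in range(n1):
                                ax = _CCOMP[_COFF[l1] + i, 0]
                                ay = _CCOMP[_COFF[l1] + i, 1]
                                az = _CCOMP[_COFF[l1] + i, 2]
                                for j in range(n2):
                                    bx = _CCOMP[_COFF[l2] + j, 0]
                                    by = _CCOMP[_COFF[l2] + j, 1]
                                    bz = _CCOMP[_COFF[l2] + j, 2]
                                    out[i, j, k, m] += pref * _bra_sum(
                                        Ex1, Ey1, Ez1, K3, ax, ay, az, bx, by, bz)
    return
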