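"""Becke molecular quadrature grid.

Radial points follow the Mura-Knowles log-3 mapping; the angular part is a
Gauss-Legendre (cos theta) x uniform (phi) product rule, which integrates
spherical harmonics exactly up to degree 2*n_theta - 1. Atomic weights use
Becke's fuzzy-cell partitioning with Bragg-radius size adjustment.
"""

from __future__ import annotations

import numpy as np

# Bragg-Slater radii, angstrom
_BRAGG = {"H": 0.35, "C": 0.70, "N": 0.65, "O": 0.60, "S": 1.00, "Fe": 1.40}
_BOHR = 0.529177210903

GRID_LEVELS = {
    "coarse": (40, 10),
    "medium": (55, 14),
    "fine": (75, 18),
    "ultrafine": (99, 24),
}


def _radial_mura_knowles(n: int, alpha: float = 5.0):
    x = (np.arange(n) + 0.5) / n
    r = -alpha * np.log1p(-x ** 3)
    w = alpha * 3.0 * x ** 2 / ((1.0 - x ** 3) * n) * r ** 2
    return r, w


def _angular_product(n_theta: int):
    ct, wt = np.polynomial.legendre.leggauss(n_theta)
    st = np.sqrt(1.0 - ct ** 2)
    nphi = 2 * n_theta
    phi = 2.0 * np.pi * np.arange(nphi) / nphi
    wphi = 2.0 * np.pi / nphi
    pts = np.empty((n_theta * nphi, 3))
    w = np.empty(n_theta * nphi)
    k = 0
    for i in range(n_theta):
        for j in range(nphi):
            pts[k] = (st[i] * np.cos(phi[j]), st[i] * np.sin(phi[j]), ct[i])
            w[k] = wt[i] * wphi
            k += 1
    return pts, w


def _becke_step(mu):
    f = mu
    for _ in range(3):
        f = 0.5 * f * (3.0 - f ** 2)
    return 0.5 * (1.0 - f)


def build_grid(elements: list[str], atom_coords_bohr: np.ndarray,
               level: str = "medium"):
    """Return (points (n,3) bohr, weights (n,)) for the whole molecule."""
    n_rad, n_theta = GRID_LEVELS[level]
    coords = np.asarray(atom_coords_bohr, float)
    natm = len(elements)
    radii = np.array([_BRAGG.get(el, 1.0) / _BOHR for el in elements])
    sph_pts, sph_w = _angular_product(n_theta)

    all_pts, all_w, all_parent = [], [], []
    for ia in range(natm):
        r, wr = _radial_mura_knowles(n_rad)
        pts = coords[ia] + r[:, None, None] * sph_pts[None, :, :]
        pts = pts.reshape(-1, 3)
        w = (wr[:, None] * sph_w[None, :]).reshape(-1)
        if natm > 1:
            # Becke partition weight of atom ia at each point
            d = np.linalg.norm(pts[:, None, :] - coords[None, :, :], axis=2)
            P = np.ones((len(pts), natm))
            for i in range(natm):
                for j in range(natm):
                    if i == j:
                        continue
                    Rij = np.linalg.norm(coords[i] - coords[j])
                    mu = (d[:, i] - d[:, j]) / Rij
                    chi = radii[i] / radii[j]
                    u = (chi - 1.0) / (chi + 1.0)
                    a = np.clip(u / (u * u - 1.0), -0.45, 0.45)
                    nu = mu + a * (1.0 - mu * mu)
                    P[:, i] *= _becke_step(nu)
            w = w * P[:, ia] / P.sum(axis=1)
        keep = w > 1e-13
        all_pts.append(pts[keep])
        all_w.append(w[keep])
        all_parent.append(np.full(int(keep.sum()), ia, dtype=np.int64))
    return np.concatenate(all_pts), np.concatenate(all_w), np.concatenate(all_parent)
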