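"""BLYP exchange-correlation functional (closed shell).

The energy density is written symbolically once (Becke 1988 gradient
exchange; Lee-Yang-Parr correlation in the Miehlich reformulation,
specialized to a spin-compensated density) and the potential ingredients
de/drho and de/dsigma are generated by symbolic differentiation, which
removes hand-derivation errors. sigma = |grad rho|^2.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

_RHO_FLOOR = 1e-11


@lru_cache(maxsize=1)
def _blyp_lambdified():
    import sympy as sp

    rho, sigma = sp.symbols("rho sigma", positive=True)

    # Becke 88 exchange, closed shell (per-spin density rho/2, sigma/4)
    beta = sp.Float("0.0042")
    cx = sp.Rational(3, 2) * (3 / (4 * sp.pi)) ** sp.Rational(1, 3)
    rs = rho / 2
    x = sp.sqrt(sigma / 4) / rs ** sp.Rational(4, 3)
    ex_spin = (-cx * rs ** sp.Rational(4, 3)
               - beta * rs ** sp.Rational(4, 3) * x ** 2 / (1 + 6 * beta * x * sp.asinh(x)))
    e_x = 2 * ex_spin

    # LYP correlation, closed shell
    a = sp.Float("0.04918")
    b = sp.Float("0.132")
    c = sp.Float("0.2533")
    d = sp.Float("0.349")
    cf = sp.Rational(3, 10) * (3 * sp.pi ** 2) ** sp.Rational(2, 3)
    rm13 = rho ** sp.Rational(-1, 3)
    den = 1 + d * rm13
    omega = sp.exp(-c * rm13) * rho ** sp.Rational(-11, 3) / den
    delta = c * rm13 + d * rm13 / den
    e_c = -a * (rho / den
                + b * omega * (cf * rho ** sp.Rational(14, 3)
                               - (3 + 7 * delta) / 72 * rho ** 2 * sigma))

    e = e_x + e_c
    vrho = sp.diff(e, rho)
    vsigma = sp.diff(e, sigma)
    return sp.lambdify((rho, sigma), [e, vrho, vsigma], modules="numpy", cse=True)


def blyp(rho: np.ndarray, sigma: np.ndarray):
    """Energy density per volume and its rho/sigma derivatives.

    Points with rho below a floor return zeros (they carry no weight in any
    integral at double precision).
    """
    fn = _blyp_lambdified()
    rho = np.asarray(rho, float)
    sigma = np.asarray(sigma, float)
    e = np.zeros_like(rho)
    vr = np.zeros_like(rho)
    vs = np.zeros_like(rho)
    mask = rho > _RHO_FLOOR
    if np.any(mask):
        r = rho[mask]
        s = np.maximum(sigma[mask], 1e-24)
        ev, vrv, vsv = fn(r, s)
        e[mask] = ev
        vr[mask] = vrv
        vs[mask] = vsv
    return e, vr, vs
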