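"""Gaussian basis-set handling.

Contracted Gaussian shells are read from a plain-text table (cc-pVDZ for
H, O, S; for Fe only the published contraction pattern is recorded, which
is sufficient for dimension counting). Integrals are evaluated over
Cartesian Gaussians and transformed to real solid-harmonic (pure)
functions, the convention in which the density matrices of this package
are expressed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np

ATOMIC_NUMBER = {"H": 1, "C": 6, "N": 7, "O": 8, "S": 16, "Fe": 26}
_L_OF = {"S": 0, "P": 1, "D": 2, "F": 3, "G": 4}

BOHR_PER_ANGSTROM = 1.0 / 0.529177210903


def _dfact(n: int) -> float:
    """Double factorial with (-1)!! = 1."""
    out = 1.0
    while n > 1:
        out *= n
        n -= 2
    return out


def n_cart(l: int) -> int:
    return (l + 1) * (l + 2) // 2


def n_sph(l: int) -> int:
    return 2 * l + 1


def cart_components(l: int) -> list[tuple[int, int, int]]:
    comps = []
    for lx in range(l, -1, -1):
        for ly in range(l - lx, -1, -1):
            comps.append((lx, ly, l - lx - ly))
    return comps


def primitive_norm(alpha: float, l: int) -> float:
    """Normalization of the axial Cartesian primitive x^l exp(-a r^2)."""
    return (2 * alpha / np.pi) ** 0.75 * (4 * alpha) ** (l / 2) / np.sqrt(_dfact(2 * l - 1))


# Real solid harmonics as monomial combinations (unnormalized; the rows are
# renormalized numerically below, so only the ratios matter). Ordering is
# m = -l ... +l.
_SOLID = {
    0: [[(1.0, (0, 0, 0))]],
    1: [
        [(1.0, (0, 1, 0))],   # p_y
        [(1.0, (0, 0, 1))],   # p_z
        [(1.0, (1, 0, 0))],   # p_x
    ],
    2: [
        [(1.0, (1, 1, 0))],                                        # xy
        [(1.0, (0, 1, 1))],                                        # yz
        [(2.0, (0, 0, 2)), (-1.0, (2, 0, 0)), (-1.0, (0, 2, 0))],  # 3z^2-r^2
        [(1.0, (1, 0, 1))],                                        # xz
        [(1.0, (2, 0, 0)), (-1.0, (0, 2, 0))],                     # x^2-y^2
    ],
    3: [
        [(3.0, (2, 1, 0)), (-1.0, (0, 3, 0))],                     # y(3x^2-y^2)
        [(1.0, (1, 1, 1))],                                        # xyz
        [(4.0, (0, 1, 2)), (-1.0, (2, 1, 0)), (-1.0, (0, 3, 0))],  # y(5z^2-r^2)
        [(2.0, (0, 0, 3)), (-3.0, (2, 0, 1)), (-3.0, (0, 2, 1))],  # z(5z^2-3r^2)
        [(4.0, (1, 0, 2)), (-1.0, (3, 0, 0)), (-1.0, (1, 2, 0))],  # x(5z^2-r^2)
        [(1.0, (2, 0, 1)), (-1.0, (0, 2, 1))],                     # z(x^2-y^2)
        [(1.0, (3, 0, 0)), (-3.0, (1, 2, 0))],                     # x(x^2-3y^2)
    ],
}


def _mono_overlap(a: tuple, b: tuple) -> float:
    """<x^a1 y^a2 z^a3 | x^b1 y^b2 z^b3> for unit exponents, up to a common factor."""
    s = 1.0
    for p in (a[0] + b[0], a[1] + b[1], a[2] + b[2]):
        if p % 2:
            return 0.0
        s *= _dfact(p - 1) / 2.0 ** p
    return s


@lru_cache(maxsize=None)
def sph_transform(l: int) -> np.ndarray:
    """(2l+1, ncart) matrix mapping axial-normalized Cartesian integrals to
    normalized real solid-harmonic integrals."""
    comps = cart_components(l)
    ax = (l, 0, 0)
    norm_ax = _mono_overlap(ax, ax)
    T = np.zeros((n_sph(l), n_cart(l)))
    for m, terms in enumerate(_SOLID[l]):
        t = np.zeros(len(comps))
        for coef, mono in terms:
            t[comps.index(mono)] = coef
        tmt = 0.0
        for i, ci in enumerate(comps):
            for j, cj in enumerate(comps):
                if t[i] != 0.0 and t[j] != 0.0:
                    tmt += t[i] * t[j] * _mono_overlap(ci, cj)
        T[m] = t * np.sqrt(norm_ax / tmt)
    return T


class InvalidBasisError(ValueError):
    pass


@dataclass
class Shell:
    l: int
    atom: int
    center: np.ndarray          # bohr
    exps: np.ndarray
    coefs: np.ndarray           # axial-normalized, contraction-normalized


@lru_cache(maxsize=4)
def _load_basis_table(name: str):
    fname = {"cc-pvdz": "cc-pvdz.dat"}.get(name.lower())
    if fname is None:
        raise InvalidBasisError(f"unknown basis set: {name!r}")
    text = resources.files("dmguess.engine").joinpath(f"data/{fname}").read_text()
    table: dict[str, list] = {}
    patterns: dict[str, list[tuple[int, int]]] = {}
    cur = None
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if parts[0] in ATOMIC_NUMBER or parts[0].capitalize() in ATOMIC_NUMBER:
            el = parts[0].capitalize()
            if parts[1].upper() == "PATTERN":
                counts = []
                for tok in parts[2:]:
                    mm = re.fullmatch(r"(\d+)([SPDFG])", tok.upper())
                    counts.append((int(mm.group(1)), _L_OF[mm.group(2)]))
                patterns[el] = counts
                cur = None
            else:
                cur = (el, _L_OF[parts[1].upper()])
                table.setdefault(el, []).append((cur[1], [], []))
        else:
            if cur is None:
                raise InvalidBasisError(f"malformed basis file line: {line!r}")
            _, exps, coefs = table[cur[0]][-1]
            exps.append(float(parts[0]))
            coefs.append(float(parts[1]))
    return table, patterns


def shell_pattern(element: str, basis: str = "cc-pvdz") -> list[tuple[int, int]]:
    """List of (count, l) contracted-shell multiplicities for an element."""
    table, patterns = _load_basis_table(basis)
    if element in table:
        counts: dict[int, int] = {}
        for l, _, _ in table[element]:
            counts[l] = counts.get(l, 0) + 1
        return [(counts[l], l) for l in sorted(counts)]
    if element in patterns:
        return patterns[element]
    raise InvalidBasisError(f"element {element!r} not available in basis {basis!r}")


def element_dimension(element: str, basis: str = "cc-pvdz") -> int:
    """Number of (spherical) contracted basis functions on one atom."""
    return sum(cnt * n_sph(l) for cnt, l in shell_pattern(element, basis))


def has_parameters(element: str, basis: str = "cc-pvdz") -> bool:
    table, _ = _load_basis_table(basis)
    return element in table


@dataclass
class BasisSet:
    """A molecule's contracted shell list plus flattened arrays for the
    integral kernels and the Cartesian-to-spherical block transform."""

    shells: list[Shell]
    atom_coords: np.ndarray     # (natm, 3), bohr
    atom_charges: np.ndarray    # (natm,)
    nao: int = field(init=False)
    nao_cart: int = field(init=False)

    def __post_init__(self):
        self.nao = sum(n_sph(sh.l) for sh in self.shells)
        self.nao_cart = sum(n_cart(sh.l) for sh in self.shells)
        # flattened arrays for numba kernels
        nsh = len(self.shells)
        self.shell_l = np.array([sh.l for sh in self.shells], dtype=np.int64)
        self.shell_atom = np.array([sh.atom for sh in self.shells], dtype=np.int64)
        self.centers = np.array([sh.center for sh in self.shells])
        self.nprim = np.array([len(sh.exps) for sh in self.shells], dtype=np.int64)
        self.prim_ptr = np.zeros(nsh + 1, dtype=np.int64)
        np.cumsum(self.nprim, out=self.prim_ptr[1:])
        self.prim_exps = np.concatenate([sh.exps for sh in self.shells])
        self.prim_coefs = np.concatenate([sh.coefs for sh in self.shells])
        self.cart_off = np.zeros(nsh, dtype=np.int64)
        self.sph_off = np.zeros(nsh, dtype=np.int64)
        co = so = 0
        for i, sh in enumerate(self.shells):
            self.cart_off[i], self.sph_off[i] = co, so
            co += n_cart(sh.l)
            so += n_sph(sh.l)
        # block transform: sph = T @ cart
        T = np.zeros((self.nao, self.nao_cart))
        for i, sh in enumerate(self.shells):
            blk = sph_transform(sh.l)
            T[self.sph_off[i]:self.sph_off[i] + n_sph(sh.l),
              self.cart_off[i]:self.cart_off[i] + n_cart(sh.l)] = blk
        self.T = T
        self.ao_atom = np.concatenate(
            [np.full(n_sph(sh.l), sh.atom, dtype=np.int64) for sh in self.shells])

    def to_sph(self, mat_cart: np.ndarray) -> np.ndarray:
        return self.T @ mat_cart @ self.T.T

    def to_cart_density(self, dm_sph: np.ndarray) -> np.ndarray:
        """Contravariant density in the Cartesian representation: any
        Tr[D_sph M_sph] equals Tr[(T' D_sph T) M_cart]."""
        return self.T.T @ dm_sph @ self.T


def build_basis(elements: list[str], coords_angstrom: np.ndarray,
                basis: str = "cc-pvdz") -> BasisSet:
    table, _ = _load_basis_table(basis)
    shells = []
    coords = np.asarray(coords_angstrom, dtype=float) * BOHR_PER_ANGSTROM
    for ia, el in enumerate(elements):
        if el not in table:
            raise InvalidBasisError(
                f"basis parameters for element {el!r} are not bundled "
                f"(only the shell pattern is known); SCF is unavailable")
        for l, exps, coefs in table[el]:
            exps = np.asarray(exps)
            coefs = np.asarray(coefs) * np.array([primitive_norm(a, l) for a in exps])
            # normalize contracted axial function
            p = exps[:, None] + exps[None, :]
            ss = (np.pi / p) ** 1.5 * _dfact(2 * l - 1) / (2 * p) ** l
            norm = np.einsum("i,j,ij->", coefs, coefs, ss)
            coefs = coefs / np.sqrt(norm)
            shells.append(Shell(l, ia, coords[ia].copy(), exps, coefs))
    charges = np.array([ATOMIC_NUMBER[el] for el in elements], dtype=float)
    return BasisSet(shells, coords, charges)
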