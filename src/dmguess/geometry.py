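"""Molecular geometries, canonical frames, and minimal feature vectors.

A dense network cannot represent an equivariant quantity, so every
geometry is first brought into a canonical pose: the anchor atom (O for
water, the central S for S2O, Fe for the hexaaqua complex) sits at the
origin; for triatomics one designated atom lies on the negative x axis and
the other in the x-y half-plane with y >= 0; for the hexaaqua complex the
six ligand oxygens lie on the Cartesian axes. The resulting internal
coordinates (3 for a triatomic, 6 Fe-O distances for the complex) are the
only model inputs, and the frame rotation is what maps predicted forces
back to the laboratory frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml


class InvalidMoleculeError(ValueError):
    pass


class DegenerateGeometryError(ValueError):
    """Triatomic is collinear: the in-plane constraint is undefined."""


class FrameViolationError(ValueError):
    """Geometry claimed canonical is not in the canonical pose."""


_DIST_FLOOR = 0.3      # angstrom, sanity floor on interatomic distances
_COLLINEAR_TOL = 1e-6  # sin(angle) below which a triatomic is degenerate

FE_O_EQUILIBRIUM = 2.0525          # angstrom
WATER_OH = 0.9751                  # angstrom, static BLYP/cc-pVDZ
WATER_ANGLE = 104.14               # degrees, static BLYP/cc-pVDZ

TEMPLATE_CHARGES = {"h2o": 0, "s2o": 0, "fe_hexaaqua": 2}
TEMPLATE_NFEATURES = {"h2o": 3, "s2o": 3, "fe_hexaaqua": 6}


@dataclass(frozen=True)
class MolecularGeometry:
    elements: tuple
    coords: np.ndarray          # (n, 3), angstrom, lab frame
    charge: int = 0
    name: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "elements", tuple(self.elements))
        object.__setattr__(self, "coords", np.array(self.coords, dtype=float))
        if len(self.elements) != len(self.coords):
            raise InvalidMoleculeError("element and coordinate counts differ")
        n = len(self.elements)
        for i in range(n):
            for j in range(i):
                if np.linalg.norm(self.coords[i] - self.coords[j]) < _DIST_FLOOR:
                    raise InvalidMoleculeError(
                        f"atoms {j} and {i} closer than {_DIST_FLOOR} angstrom")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def with_coords(self, coords) -> "MolecularGeometry":
        return replace(self, coords=np.asarray(coords, float))

    # ---- XYZ I/O -------------------------------------------------------
    def to_xyz(self, comment: str = "") -> str:
        lines = [str(self.n_atoms), comment]
        for el, xyz in zip(self.elements, self.coords):
            lines.append(f"{el:<3s} {xyz[0]:18.10f} {xyz[1]:18.10f} {xyz[2]:18.10f}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_xyz(cls, text: str, charge: int = 0, name: str | None = None):
        lines = [ln for ln in text.strip().splitlines()]
        n = int(lines[0].split()[0])
        els, xyz = [], []
        for ln in lines[2:2 + n]:
            parts = ln.split()
            els.append(parts[0])
            xyz.append([float(x) for x in parts[1:4]])
        return cls(els, np.array(xyz), charge=charge, name=name)


@dataclass(frozen=True)
class FrameTransform:
    """Rigid transform: canonical = rotation @ (lab - translation)."""

    translation: np.ndarray
    rotation: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "translation", np.asarray(self.translation, float))
        object.__setattr__(self, "rotation", np.asarray(self.rotation, float))
        R = self.rotation
        if np.linalg.norm(R.T @ R - np.eye(3)) > 1e-8 or np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper orthogonal")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return (np.asarray(coords) - self.translation) @ self.rotation.T

    def invert(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation + self.translation

    def rotate_vectors(self, vectors: np.ndarray) -> np.ndarray:
        return np.asarray(vectors) @ self.rotation.T

    def invert_vectors(self, vectors: np.ndarray) -> np.ndarray:
        return np.asarray(vectors) @ self.rotation

    def to_yaml(self) -> str:
        return yaml.safe_dump({"translation": self.translation.tolist(),
                               "rotation": self.rotation.tolist()})

    @classmethod
    def from_yaml(cls, text: str) -> "FrameTransform":
        d = yaml.safe_load(text)
        return cls(np.array(d["translation"]), np.array(d["rotation"]))


def infer_template(geom: MolecularGeometry) -> str:
    if geom.name in TEMPLATE_CHARGES:
        return geom.name
    comp = sorted(geom.elements)
    if comp == ["H", "H", "O"]:
        return "h2o"
    if comp == ["O", "S", "S"]:
        return "s2o"
    if comp == sorted(["Fe"] + ["O"] * 6 + ["H"] * 12):
        return "fe_hexaaqua"
    raise InvalidMoleculeError(f"no template matches composition {comp}")


def _check_composition(geom: MolecularGeometry, template: str):
    want = {"h2o": ["H", "H", "O"], "s2o": ["O", "S", "S"],
            "fe_hexaaqua": sorted(["Fe"] + ["O"] * 6 + ["H"] * 12)}
    if template not in want:
        raise InvalidMoleculeError(f"unknown molecule template {template!r}")
    if sorted(geom.elements) != want[template]:
        raise InvalidMoleculeError(
            f"composition {sorted(geom.elements)} does not match {template}")


def _triatomic_anchor_and_pair(geom: MolecularGeometry, template: str):
    els = geom.elements
    if template == "h2o":
        anchor = els.index("O")
    else:  # s2o: the central sulfur is the one nearer to the oxygen
        io = els.index("O")
        ss = [i for i, e in enumerate(els) if e == "S"]
        d = [np.linalg.norm(geom.coords[i] - geom.coords[io]) for i in ss]
        anchor = ss[int(np.argmin(d))]
    others = [i for i in range(3) if i != anchor]
    # lower input index goes to the negative x axis (deterministic labeling;
    # swapping gives the mirror-equivalent pose)
    return anchor, others[0], others[1]


def canonical_frame(geom: MolecularGeometry, template: str | None = None):
    """Canonicalize a geometry; returns (canonical geometry, transform)."""
    template = template or infer_template(geom)
    _check_composition(geom, template)
    if template in ("h2o", "s2o"):
        anchor, ax_atom, pl_atom = _triatomic_anchor_and_pair(geom, template)
        t = geom.coords[anchor].copy()
        va = geom.coords[ax_atom] - t
        vb = geom.coords[pl_atom] - t
        na = np.linalg.norm(va)
        cross = np.cross(va, vb)
        sin_angle = np.linalg.norm(cross) / (na * np.linalg.norm(vb))
        if sin_angle < _COLLINEAR_TOL:
            raise DegenerateGeometryError(
                f"triatomic is collinear (sin angle {sin_angle:.2e}); "
                "the x-y plane constraint is undefined")
        row1 = -va / na
        w = vb - (vb @ row1) * row1
        row2 = w / np.linalg.norm(w)
        row3 = np.cross(row1, row2)
        R = np.vstack([row1, row2, row3])
        tf = FrameTransform(t, R)
        return geom.with_coords(tf.apply(geom.coords)), tf
    # fe_hexaaqua
    ife = geom.elements.index("Fe")
    oxy = [i for i, e in enumerate(geom.elements) if e == "O"]
    t = geom.coords[ife].copy()
    vo = geom.coords[oxy] - t
    e1 = vo[0] / np.linalg.norm(vo[0])
    # the most orthogonal ligand defines the second axis
    proj = np.abs(vo @ e1) / np.linalg.norm(vo, axis=1)
    j = int(np.argmax(proj < 0.5)) if np.any(proj < 0.5) else int(np.argmin(proj))
    w = vo[j] - (vo[j] @ e1) * e1
    e2 = w / np.linalg.norm(w)
    e3 = np.cross(e1, e2)
    R = np.vstack([e1, e2, e3])
    tf = FrameTransform(t, R)
    return geom.with_coords(tf.apply(geom.coords)), tf


_AXES = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                  [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=float)


def features(canonical_geom: MolecularGeometry, template: str | None = None,
             tol: float = 1e-6) -> np.ndarray:
    """Minimal internal coordinates of a canonically posed geometry.

    Triatomics: (x_A, x_B, y_B) with A the negative-x-axis atom and B the
    in-plane atom. Hexaaqua: the six Fe-O distances ordered by axis
    (+x, -x, +y, -y, +z, -z). The pose is verified, not assumed.
    """
    template = template or infer_template(canonical_geom)
    _check_composition(canonical_geom, template)
    c = canonical_geom.coords
    # pose checks scale with the coordinate magnitude (double precision)
    tol = tol * max(1.0, float(np.max(np.abs(c))))
    if template in ("h2o", "s2o"):
        anchor, ax_atom, pl_atom = _triatomic_anchor_and_pair(canonical_geom, template)
        if np.linalg.norm(c[anchor]) > tol:
            raise FrameViolationError("anchor atom is not at the origin")
        xa = c[ax_atom]
        if abs(xa[1]) > tol or abs(xa[2]) > tol or xa[0] > -tol:
            raise FrameViolationError("axis atom is not on the negative x axis")
        xb = c[pl_atom]
        if abs(xb[2]) > tol or xb[1] < -tol:
            raise FrameViolationError("plane atom is not in the upper x-y plane")
        return np.array([xa[0], xb[0], max(xb[1], 0.0)])
    ife = canonical_geom.elements.index("Fe")
    if np.linalg.norm(c[ife]) > tol:
        raise FrameViolationError("Fe is not at the origin")
    oxy = [i for i, e in enumerate(canonical_geom.elements) if e == "O"]
    vo = c[oxy]
    d = np.linalg.norm(vo, axis=1)
    units = vo / d[:, None]
    out = np.zeros(6)
    used = set()
    for k, ax in enumerate(_AXES):
        dots = units @ ax
        order = np.argsort(-dots)
        pick = next((i for i in order if i not in used), None)
        if pick is None or dots[pick] < 1.0 - 1e-6:
            raise FrameViolationError("ligand oxygens are not on the Cartesian axes")
        used.add(pick)
        out[k] = d[pick]
    return out


def apply_inverse_frame(vectors: np.ndarray, transform: FrameTransform) -> np.ndarray:
    """Back-rotate per-atom vector quantities (forces) to the lab frame.

    Vectors are covariant: only the rotation is undone, never the
    translation."""
    return transform.invert_vectors(vectors)


# rigid-water internal geometry for the hexaaqua ligands (static BLYP water)
_WATER_OH_LIGAND = 0.9751
_WATER_ANGLE_LIGAND = np.deg2rad(104.14)


def build_hexaaqua(bond_lengths, water_oh: float = _WATER_OH_LIGAND,
                   water_angle_rad: float = _WATER_ANGLE_LIGAND) -> MolecularGeometry:
    """Octahedral [Fe(H2O)6]2+ with ligand O atoms at the given distances
    along +x, -x, +y, -y, +z, -z.

    Each rigid water lies in a plane containing its Fe-O axis with the H
    atoms symmetric about it and pointing away from Fe; the in-plane
    partner axis is fixed per ligand index (x->y, y->z, z->x), which makes
    the construction deterministic.
    """
    bl = np.asarray(bond_lengths, float)
    if bl.shape != (6,):
        raise InvalidMoleculeError("six Fe-O bond lengths are required")
    if np.any(bl <= 0):
        raise InvalidMoleculeError("bond lengths must be positive")
    partners = [2, 2, 4, 4, 0, 0]  # axis index whose direction spans the water plane
    els = ["Fe"]
    coords = [np.zeros(3)]
    half = 0.5 * water_angle_rad
    for k in range(6):
        axis = _AXES[k]
        o_pos = bl[k] * axis
        u = axis                       # outward unit vector
        v = _AXES[partners[k]]
        els.append("O")
        coords.append(o_pos)
        for sgn in (+1.0, -1.0):
            h_dir = np.cos(half) * u + sgn * np.sin(half) * v
            els.append("H")
            coords.append(o_pos + water_oh * h_dir)
    return MolecularGeometry(els, np.array(coords), charge=2, name="fe_hexaaqua")


def random_rigid_transform(rng: np.random.Generator,
                           max_translation: float = 5.0) -> FrameTransform:
    """A uniformly random proper rotation plus a random translation."""
    A = rng.normal(size=(3, 3))
    Q, Rr = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(Rr))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.uniform(-max_translation, max_translation, size=3)
    return FrameTransform(t, Q)


def equilibrium_geometry(template: str) -> MolecularGeometry:
    """Reference geometries in canonical pose (used as sampling centers)."""
    if template == "h2o":
        r, th = WATER_OH, np.deg2rad(WATER_ANGLE)
        coords = np.array([[0.0, 0.0, 0.0],
                           [-r, 0.0, 0.0],
                           [r * np.cos(np.pi - th), r * np.sin(np.pi - th), 0.0]])
        return MolecularGeometry(["O", "H", "H"], coords, name="h2o")
    if template == "s2o":
        # experimental S-S 1.8834, S-O 1.4650, angle 117.876 deg (S-S-O);
        # central S anchored at the origin, terminal S on the negative x axis
        rss, rso, th = 1.8834, 1.4650, np.deg2rad(117.876)
        coords = np.array([[0.0, 0.0, 0.0],
                           [-rss, 0.0, 0.0],
                           [rso * np.cos(np.pi - th), rso * np.sin(np.pi - th), 0.0]])
        return MolecularGeometry(["S", "S", "O"], coords, name="s2o")
    if template == "fe_hexaaqua":
        return build_hexaaqua(np.full(6, FE_O_EQUILIBRIUM))
    raise InvalidMoleculeError(f"unknown template {template!r}")
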