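"""Deterministic mock engine.

A tiny stand-in for the DFT engine with the same call surface: the
"converged" DM is a fixed smooth function of the canonical-frame features,
the energy is a harmonic bowl around the template equilibrium, and
iteration counts shrink monotonically with the quality of the initial
guess. It lets the data/benchmark/MD/CLI plumbing be exercised in
milliseconds (including for the hexaaqua complex, whose real SCF is far
beyond desk scale), and is labelled synthetic throughout.
"""

from __future__ import annotations

import numpy as np

from ..geometry import canonical_frame, equilibrium_geometry, features as extract_features, infer_template
from .api import DensityMatrix, SCFConfig, SCFResult
from .rks import BOHR, HARTREE_TO_EV


class MockEngine:
    """Synthetic engine: quadratic energy model + feature-linear DM."""

    name = "mock"

    def __init__(self, dm_dim: int = 6, spring: float = 2.0, seed: int = 1234):
        self.d = dm_dim
        self.spring = spring          # eV/A^2 per feature coordinate
        rng = np.random.default_rng(seed)
        a0 = rng.normal(size=(self.d, self.d))
        self._A0 = 0.05 * (a0 + a0.T) + np.eye(self.d)
        self._Ai = []
        for _ in range(6):
            m = rng.normal(size=(self.d, self.d))
            self._Ai.append(0.02 * (m + m.T))
        self._f_eq = {}

    # ---- helpers -------------------------------------------------------
    def _feq(self, mol):
        if mol not in self._f_eq:
            self._f_eq[mol] = extract_features(equilibrium_geometry(mol), mol)
        return self._f_eq[mol]

    def dm_star(self, feats) -> np.ndarray:
        m = self._A0.copy()
        for i, f in enumerate(np.asarray(feats, float)):
            m = m + f * self._Ai[i]
        return m

    def _energy(self, feats, mol):
        df = np.asarray(feats) - self._feq(mol)
        return -10.0 + 0.5 * self.spring * float(df @ df) / HARTREE_TO_EV

    def _forces(self, geom, mol):
        """-dE/dx by central differences of the harmonic feature energy."""
        h = 1e-5
        f = np.zeros((geom.n_atoms, 3))
        for i in range(geom.n_atoms):
            for c in range(3):
                for s, sign in ((h, 1.0), (-h, -1.0)):
                    cc = geom.coords.copy()
                    cc[i, c] += s
                    g2, _ = canonical_frame(geom.with_coords(cc), mol)
                    e = self._energy(extract_features(g2, mol), mol)
                    f[i, c] -= sign * e
        return f / (2 * h) * HARTREE_TO_EV     # eV/A

    def _components(self, e_tot):
        return (0.6 * e_tot, 0.1 * e_tot, 0.1 * e_tot, 0.2 * e_tot)

    # ---- engine surface -------------------------------------------------
    def basis_dimension(self, geom, basis: str = "cc-pvdz") -> int:
        from .basis import element_dimension

        if isinstance(geom, str):
            return element_dimension(geom, basis)
        return sum(element_dimension(el, basis) for el in geom.elements)

    def baseline_guess_dm(self, geom, scheme, config=None) -> DensityMatrix:
        mol = infer_template(geom)
        cgeom, _ = canonical_frame(geom, mol)
        dstar = self.dm_star(extract_features(cgeom, mol))
        offsets = {"minao": 0.02, "atom": 0.03, "huckel": 0.025, "vsap": 0.04,
                   "one_electron": 0.6}
        if scheme not in offsets:
            from .rks import EngineError

            raise EngineError(f"unknown guess scheme {scheme!r}")
        return DensityMatrix(dstar + offsets[scheme] * np.eye(self.d),
                             molecule=mol)

    def run_scf(self, geom, config=None, initial_dm=None) -> SCFResult:
        config = config or SCFConfig()
        mol = infer_template(geom)
        cgeom, _ = canonical_frame(geom, mol)
        feats = extract_features(cgeom, mol)
        dstar = self.dm_star(feats)
        if initial_dm is not None:
            if initial_dm.basis_dimension != self.d:
                from .api import InvalidDMError

                raise InvalidDMError("mock engine DM dimension mismatch")
            d0 = initial_dm.matrix
        else:
            d0 = self.baseline_guess_dm(geom, config.guess).matrix
        err0 = float(np.linalg.norm(d0 - dstar))
        # error contracts by 1e-2 per iteration until below tolerance
        iters = 1
        err = err0
        while err > config.energy_tolerance and iters < config.max_iterations:
            err *= 1e-2
            iters += 1
        converged = err <= config.energy_tolerance
        if config.solver == "diis":
            iters = min(iters + 2, config.max_iterations)
        e = self._energy(feats, mol)
        energies = list(e + err0 * (1e-2) ** np.arange(iters + 1))
        res = SCFResult(
            total_energy=e, iteration_count=iters, converged=converged,
            dm=DensityMatrix(dstar, molecule=mol), overlap=np.eye(self.d),
            energy_components=self._components(e),
            per_iteration_energies=energies,
            per_iteration_dms=([d0] + [dstar] * iters
                               if config.record_dms else None))
        # finite differences over the coordinates as supplied -> lab frame
        res._forces = self._forces(geom, mol)
        return res

    def single_point_from_dm(self, geom, dm, n_scf_steps=0, config=None):
        config = config or SCFConfig()
        mol = infer_template(geom)
        cgeom, _ = canonical_frame(geom, mol)
        feats = extract_features(cgeom, mol)
        dstar = self.dm_star(feats)
        if dm.basis_dimension != self.d:
            from .api import InvalidDMError

            raise InvalidDMError("mock engine DM dimension mismatch")
        err = float(np.linalg.norm(dm.matrix - dstar)) * (1e-2 ** n_scf_steps)
        e = self._energy(feats, mol) + 0.5 * err ** 2
        forces = self._forces(geom, mol)
        # DM error perturbs forces linearly (so the oracle predictor is exact)
        forces = forces + err * 0.1 * HARTREE_TO_EV / BOHR
        return e, forces, self._components(e)
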