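"""Contract layer over the DFT engine.

`run_scf`, `baseline_guess_dm`, `single_point_from_dm` and
`basis_dimension` are the operations the rest of the package builds on;
everything below them (integrals, grids, solvers) lives in the sibling
modules. Energies are in hartree, forces in eV/angstrom at this boundary,
density matrices in atomic units with the convention Tr[D S] = N_e.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ..geometry import MolecularGeometry
from .basis import InvalidBasisError, element_dimension
from .rks import (
    BOHR,
    HARTREE_TO_EV,
    EngineError,
    System,
    energy_weighted_dm,
    guess_density,
    scf_diis,
    scf_sos,
    GUESS_SCHEMES,
    _GUESS_ALIASES,
)


class InvalidDMError(ValueError):
    pass


_SOLVERS = ("diis", "sos")


@dataclass
class SCFConfig:
    functional: str = "BLYP"
    basis: str = "cc-pvdz"
    solver: str = "diis"
    guess: str = "minao"
    energy_tolerance: float = 1e-9
    max_iterations: int = 50
    grid_level: str = "medium"
    record_dms: bool = False

    def __post_init__(self):
        if self.energy_tolerance <= 0:
            raise ValueError("energy_tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be at least 1")
        if self.solver not in _SOLVERS:
            raise ValueError(f"solver must be one of {_SOLVERS}")
        g = _GUESS_ALIASES.get(self.guess, self.guess)
        if g not in GUESS_SCHEMES + ("custom",):
            raise EngineError(f"unknown guess scheme {self.guess!r}")
        self.guess = g


@dataclass
class DensityMatrix:
    matrix: np.ndarray
    molecule: Optional[str] = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise InvalidDMError("density matrix must be square")
        if np.max(np.abs(self.matrix - self.matrix.T)) > 1e-8:
            raise InvalidDMError("density matrix must be symmetric")

    @property
    def basis_dimension(self) -> int:
        return self.matrix.shape[0]


@dataclass
class SCFResult:
    total_energy: float
    iteration_count: int
    converged: bool
    dm: DensityMatrix
    overlap: np.ndarray
    energy_components: tuple          # (H_one, H_C, H_XC, H_NN), hartree
    per_iteration_energies: list
    per_iteration_dms: Optional[list] = None
    _system: Optional[System] = field(default=None, repr=False)
    _forces: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def forces(self) -> np.ndarray:
        """Nuclear forces, eV/angstrom (computed on first access)."""
        if self._forces is None:
            if self._system is None:
                raise EngineError("no engine context attached to this result")
            sys = self._system
            D = self.dm.matrix
            W = energy_weighted_dm(sys, D, converged=True)
            grad = sys.gradient(D, W)          # hartree/bohr
            self._forces = -grad * HARTREE_TO_EV / BOHR
        return self._forces

    def to_hdf5(self, path: str):
        import h5py

        with h5py.File(path, "w") as f:
            f["dm"] = self.dm.matrix
            f["overlap"] = self.overlap
            f["forces"] = self.forces
            f["per_iteration_energies"] = np.asarray(self.per_iteration_energies)
            f.attrs["total_energy"] = self.total_energy
            f.attrs["iteration_count"] = self.iteration_count
            f.attrs["converged"] = self.converged
            for k, v in zip(("H_one", "H_C", "H_XC", "H_NN"), self.energy_components):
                f.attrs[k] = v

    @classmethod
    def from_hdf5(cls, path: str) -> "SCFResult":
        import h5py

        with h5py.File(path, "r") as f:
            res = cls(
                total_energy=float(f.attrs["total_energy"]),
                iteration_count=int(f.attrs["iteration_count"]),
                converged=bool(f.attrs["converged"]),
                dm=DensityMatrix(f["dm"][...]),
                overlap=f["overlap"][...],
                energy_components=tuple(float(f.attrs[k])
                                        for k in ("H_one", "H_C", "H_XC", "H_NN")),
                per_iteration_energies=list(f["per_iteration_energies"][...]),
            )
            res._forces = f["forces"][...]
        return res


class RealEngine:
    """The package's own all-electron Gaussian-basis KS-DFT engine."""

    name = "rks"

    def __init__(self, cache_systems: int = 8):
        self._cache = {}
        self._cache_size = cache_systems

    # ---- plumbing ------------------------------------------------------
    def system(self, geom: MolecularGeometry, config: SCFConfig) -> System:
        key = (tuple(geom.elements), geom.coords.tobytes(), geom.charge,
               config.functional, config.basis, config.grid_level)
        if key not in self._cache:
            if len(self._cache) >= self._cache_size:
                self._cache.pop(next(iter(self._cache)))
            self._cache[key] = System(geom.elements, geom.coords,
                                      charge=geom.charge, basis=config.basis,
                                      grid_level=config.grid_level,
                                      xc=config.functional)
        return self._cache[key]

    # ---- spec operations ----------------------------------------------
    def basis_dimension(self, geom, basis: str = "cc-pvdz") -> int:
        if isinstance(geom, str):
            return element_dimension(geom, basis)
        return sum(element_dimension(el, basis) for el in geom.elements)

    def baseline_guess_dm(self, geom: MolecularGeometry, scheme: str,
                          config: SCFConfig | None = None) -> DensityMatrix:
        config = config or SCFConfig()
        sys = self.system(geom, config)
        return DensityMatrix(guess_density(sys, scheme), molecule=geom.name)

    def run_scf(self, geom: MolecularGeometry, config: SCFConfig | None = None,
                initial_dm: Optional[DensityMatrix] = None) -> SCFResult:
        config = config or SCFConfig()
        sys = self.system(geom, config)
        if sys.nocc is None:
            raise EngineError("odd electron count: restricted closed shell only")
        if config.guess == "custom" or initial_dm is not None:
            if initial_dm is None:
                raise InvalidDMError("guess='custom' requires initial_dm")
            if initial_dm.basis_dimension != sys.bset.nao:
                raise InvalidDMError(
                    f"DM dimension {initial_dm.basis_dimension} != basis "
                    f"dimension {sys.bset.nao}")
            D0 = initial_dm.matrix
        else:
            D0 = guess_density(sys, config.guess)
        solver = scf_diis if config.solver == "diis" else scf_sos
        try:
            sol = solver(sys, D0, tol=config.energy_tolerance,
                         max_iter=config.max_iterations,
                         record_dms=config.record_dms)
        except np.linalg.LinAlgError as exc:   # pragma: no cover
            raise EngineError(f"SCF linear algebra failure: {exc}") from exc
        comps = sys.energy_components(sol.D)
        return SCFResult(
            total_energy=sol.energy,
            iteration_count=sol.iterations,
            converged=sol.converged,
            dm=DensityMatrix(0.5 * (sol.D + sol.D.T), molecule=geom.name),
            overlap=sys.S,
            energy_components=comps,
            per_iteration_energies=list(sol.energies),
            per_iteration_dms=sol.dms,
            _system=sys,
        )

    def single_point_from_dm(self, geom: MolecularGeometry, dm: DensityMatrix,
                             n_scf_steps: int = 0,
                             config: SCFConfig | None = None):
        """Non-self-consistent energy/forces from a supplied DM.

        n_scf_steps=0: one Fock build with the DM as given; n_scf_steps=1:
        a single diagonalization (SCF update) first. Returns
        (energy, forces eV/A, components)."""
        config = config or SCFConfig()
        if n_scf_steps not in (0, 1):
            raise ValueError("n_scf_steps must be 0 or 1")
        sys = self.system(geom, config)
        if dm.basis_dimension != sys.bset.nao:
            raise InvalidDMError(
                f"DM dimension {dm.basis_dimension} != basis dimension {sys.bset.nao}")
        D = dm.matrix
        F, E, _, _ = sys.fock_energy(D)
        if n_scf_steps == 1:
            _, C = sys.solve_fock(F)
            D = sys.dm_from_mo(C)
            F, E, _, _ = sys.fock_energy(D)
        # generalized energy-weighted DM: (1/2) D F D = 2 C eps C^T at
        # convergence under the D = 2 C C^T convention
        W = 0.5 * D @ F @ D
        grad = sys.gradient(D, W)
        forces = -grad * HARTREE_TO_EV / BOHR
        comps = sys.energy_components(D)
        return E, forces, comps


_DEFAULT_ENGINE = RealEngine()


def basis_dimension(geom, basis: str = "cc-pvdz") -> int:
    """Total contracted (spherical) basis-function count."""
    return _DEFAULT_ENGINE.basis_dimension(geom, basis)


def run_scf(geom, config=None, initial_dm=None) -> SCFResult:
    return _DEFAULT_ENGINE.run_scf(geom, config, initial_dm)


def baseline_guess_dm(geom, scheme, config=None) -> DensityMatrix:
    return _DEFAULT_ENGINE.baseline_guess_dm(geom, scheme, config)


def single_point_from_dm(geom, dm, n_scf_steps=0, config=None):
    return _DEFAULT_ENGINE.single_point_from_dm(geom, dm, n_scf_steps, config)
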