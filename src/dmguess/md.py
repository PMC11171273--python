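"""Molecular dynamics driven by ML-predicted density matrices.

The ml force provider executes the canonical-frame workflow each step:
translate/rotate the molecule into the canonical pose, predict the DM,
rescale it to the right electron count, run a single SCF step, evaluate
forces, and rotate them back to the laboratory frame. Reference providers
are full SCF convergence per step and a single step from the superposed-
atomic-density (minao) guess.

Integration is velocity Verlet; NVT sampling uses a Nose-Hoover chain
(length 3) with the Martyna-Tuckerman half-step splitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    MolecularGeometry,
    apply_inverse_frame,
    canonical_frame,
    features as extract_features,
    infer_template,
)
from .model import electron_count, predict_dm, rescale_dm

MASSES = {"H": 1.008, "O": 15.999, "S": 32.06, "Fe": 55.845}   # amu
KB_EV = 8.617333262e-5                  # eV/K
ACC = 9.6485332e-3                      # (eV/A)/amu -> A/fs^2


@dataclass
class TrajectoryFrame:
    time_fs: float
    geometry: MolecularGeometry
    velocities: np.ndarray          # A/fs
    forces: np.ndarray              # eV/A
    total_energy: float             # Ha
    energy_components: tuple        # (H_one, H_C, H_XC, H_NN), Ha
    temperature: float              # K
    extended_energy: float | None = None   # NVT conserved quantity, eV


class MDFailure(RuntimeError):
    def __init__(self, msg, frames):
        super().__init__(msg)
        self.frames = frames


def _temperature(v, masses):
    ke = 0.5 * float(np.sum(masses[:, None] * v ** 2)) / ACC    # eV
    dof = max(3 * len(masses) - 3, 1)
    return 2.0 * ke / (dof * KB_EV)


class _NoseHooverChain:
    """MTK chain thermostat (length 3) acting on all particle DOF."""

    def __init__(self, n_dof, temperature_K, tau_fs=50.0, length=3):
        self.n_dof = n_dof
        self.kT = KB_EV * temperature_K          # eV
        omega2 = (2.0 * np.pi / tau_fs) ** 2
        # Q in eV fs^2
        self.Q = np.full(length, self.kT / omega2)
        self.Q[0] *= n_dof
        self.xi = np.zeros(length)               # thermostat velocities, 1/fs
        self.eta = np.zeros(length)              # positions (for the conserved quantity)

    def half_step(self, v, masses, dt):
        """Advance thermostat dt/2 and scale particle velocities."""
        ke2 = float(np.sum(masses[:, None] * v ** 2)) / ACC      # 2*KE, eV
        L = len(self.Q)
        G = np.zeros(L)
        G[0] = (ke2 - self.n_dof * self.kT) / self.Q[0]
        for j in range(1, L):
            G[j] = (self.Q[j - 1] * self.xi[j - 1] ** 2 - self.kT) / self.Q[j]
        dt2, dt4 = 0.5 * dt, 0.25 * dt
        self.xi[L - 1] += G[L - 1] * dt4
        for j in range(L - 2, -1, -1):
            s = np.exp(-self.xi[j + 1] * dt4 / 2)
            self.xi[j] = (self.xi[j] * s + G[j] * dt4) * s
        scale = np.exp(-self.xi[0] * dt2)
        v = v * scale
        self.eta += self.xi * dt2
        ke2 *= scale ** 2
        G[0] = (ke2 - self.n_dof * self.kT) / self.Q[0]
        for j in range(L - 1):
            s = np.exp(-self.xi[j + 1] * dt4 / 2)
            self.xi[j] = (self.xi[j] * s + G[j] * dt4) * s
            G[j + 1] = (self.Q[j] * self.xi[j] ** 2 - self.kT) / self.Q[j + 1]
        self.xi[L - 1] += G[L - 1] * dt4
        return v

    def conserved_extra(self):
        """Thermostat contribution to the extended conserved quantity, eV."""
        ke_bath = 0.5 * float(np.sum(self.Q * self.xi ** 2))
        pot = self.n_dof * self.kT * self.eta[0] + self.kT * float(np.sum(self.eta[1:]))
        return ke_bath + pot


def make_force_provider(mode, model=None, engine=None, scf_config=None,
                        n_scf_steps: int = 1):
    """Returns f(geometry) -> (forces eV/A lab frame, energy Ha, components)."""
    from .engine.api import RealEngine, SCFConfig

    engine = engine or RealEngine()
    scf_config = scf_config or SCFConfig()
    if mode == "full_scf":
        last = {"dm": None}

        def provider(geom):
            from .engine.api import DensityMatrix

            init = (DensityMatrix(last["dm"]) if last["dm"] is not None else None)
            res = engine.run_scf(geom, scf_config, initial_dm=init)
            if res.converged:
                last["dm"] = res.dm.matrix     # warm start the next step
            return res.forces, res.total_energy, res.energy_components
        return provider
    if mode == "minao_one_step":
        def provider(geom):
            dm = engine.baseline_guess_dm(geom, "minao", scf_config)
            e, forces, comps = engine.single_point_from_dm(geom, dm, 1, scf_config)
            return forces, e, comps
        return provider
    if mode == "ml":
        if model is None:
            raise ValueError("ml force provider needs a trained model")

        def provider(geom):
            mol = infer_template(geom)
            cgeom, tf = canonical_frame(geom, mol)
            fv = extract_features(cgeom, mol)
            dm = predict_dm(model, fv)
            sys_ = engine.system(cgeom, scf_config) if hasattr(engine, "system") else None
            if sys_ is not None:
                dm = rescale_dm(dm, sys_.S, sys_.nelec)
            e, forces_c, comps = engine.single_point_from_dm(
                cgeom, dm, n_scf_steps, scf_config)
            forces = apply_inverse_frame(forces_c, tf)
            return forces, e, comps
        return provider
    raise ValueError(f"unknown force provider {mode!r}")


def run_md(geometry: MolecularGeometry | str, force_provider="full_scf",
           model=None, temperature_K: float = 150.0, dt_fs: float = 0.5,
           n_steps: int = 100, thermostat: str | None = "nose-hoover",
           seed: int = 0, engine=None, scf_config=None, record_every: int = 1,
           tau_fs: float = 50.0):
    """NVT (or NVE with thermostat=None) trajectory; returns TrajectoryFrames.

    Initial velocities are Maxwell-Boltzmann at the target temperature with
    the total momentum removed; deterministic under a fixed seed.
    """
    if isinstance(geometry, str):
        from .geometry import equilibrium_geometry

        geometry = equilibrium_geometry(geometry)
    if dt_fs <= 0:
        raise ValueError("dt must be positive")
    provider = (force_provider if callable(force_provider)
                else make_force_provider(force_provider, model, engine, scf_config))
    masses = np.array([MASSES[e] for e in geometry.elements])
    rng = np.random.default_rng(seed)
    x = geometry.coords.copy()
    if temperature_K > 0:
        sig = np.sqrt(KB_EV * temperature_K * ACC / masses)     # A/fs
        v = rng.normal(size=x.shape) * sig[:, None]
        v -= np.sum(masses[:, None] * v, axis=0) / masses.sum()
    else:
        v = np.zeros_like(x)
    chain = (_NoseHooverChain(3 * len(masses) - 3, temperature_K, tau_fs)
             if thermostat else None)

    frames = []
    geom = geometry.with_coords(x)
    try:
        f, e, comps = provider(geom)
    except Exception as exc:
        raise MDFailure(f"force provider failed on the initial frame: {exc}", frames)
    for step in range(n_steps + 1):
        if step % record_every == 0:
            ext = None
            if chain is not None:
                ke = 0.5 * float(np.sum(masses[:, None] * v ** 2)) / ACC
                ext = (e * 27.211386245988 + ke + chain.conserved_extra())
            frames.append(TrajectoryFrame(
                time_fs=step * dt_fs, geometry=geom, velocities=v.copy(),
                forces=f.copy(), total_energy=e, energy_components=comps,
                temperature=_temperature(v, masses), extended_energy=ext))
        if step == n_steps:
            break
        if chain is not None:
            v = chain.half_step(v, masses, dt_fs)
        v = v + 0.5 * dt_fs * ACC * f / masses[:, None]
        x = x + dt_fs * v
        geom = geom.with_coords(x)
        try:
            f, e, comps = provider(geom)
        except Exception as exc:
            raise MDFailure(f"force provider failed at step {step + 1}: {exc}",
                            frames)
        v = v + 0.5 * dt_fs * ACC * f / masses[:, None]
        if chain is not None:
            v = chain.half_step(v, masses, dt_fs)
    return frames


def kinetic_energy_ev(frame: TrajectoryFrame) -> float:
    m = np.array([MASSES[e] for e in frame.geometry.elements])
    return 0.5 * float(np.sum(m[:, None] * frame.velocities ** 2)) / ACC


def total_energy_ev(frame: TrajectoryFrame) -> float:
    """Potential + kinetic energy in eV (for NVE drift checks)."""
    from .engine.rks import HARTREE_TO_EV

    return frame.total_energy * HARTREE_TO_EV + kinetic_energy_ev(frame)


# ---------------------------------------------------------------------------
# trajectory analysis
# ---------------------------------------------------------------------------

class InvalidDefinitionError(IndexError):
    pass


@dataclass
class StructureStats:
    """Histograms, means, and variances of named bonds/angles."""

    bonds: dict = field(default_factory=dict)
    angles: dict = field(default_factory=dict)
    n_frames: int = 0


def _hist(values, bins=60):
    counts, edges = np.histogram(values, bins=bins)
    return {"mean": float(np.mean(values)), "var": float(np.var(values)),
            "counts": counts, "edges": edges, "values": np.asarray(values)}


def analyze_structure(trajectory, bonds, angles) -> StructureStats:
    """bonds: {label: (i, j)}; angles: {label: (i, j, k)} with j the vertex."""
    n_at = trajectory[0].geometry.n_atoms
    for label, idx in {**bonds, **angles}.items():
        if any(i < 0 or i >= n_at for i in idx):
            raise InvalidDefinitionError(f"{label}: atom index out of range")
    stats = StructureStats(n_frames=len(trajectory))
    for label, (i, j) in bonds.items():
        d = [float(np.linalg.norm(fr.geometry.coords[i] - fr.geometry.coords[j]))
             for fr in trajectory]
        stats.bonds[label] = _hist(d)
    for label, (i, j, k) in angles.items():
        vals = []
        for fr in trajectory:
            a = fr.geometry.coords[i] - fr.geometry.coords[j]
            b = fr.geometry.coords[k] - fr.geometry.coords[j]
            cosv = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
            vals.append(float(np.degrees(np.arccos(np.clip(cosv, -1.0, 1.0)))))
        stats.angles[label] = _hist(vals)
    return stats


class IncompleteFrameError(ValueError):
    pass


def analyze_energy_components(trajectory):
    """Histograms of H_one, H_C, H_XC, H_NN; verifies per-frame closure."""
    names = ("H_one", "H_C", "H_XC", "H_NN")
    for fr in trajectory:
        if fr.energy_components is None or len(fr.energy_components) != 4:
            raise IncompleteFrameError("frame lacks energy components")
        if abs(sum(fr.energy_components) - fr.total_energy) > 1e-8:
            raise IncompleteFrameError(
                "energy components do not sum to the frame total")
    out = {}
    for i, name in enumerate(names):
        out[name] = _hist([fr.energy_components[i] for fr in trajectory])
    return out


def trajectory_to_xyz(trajectory) -> str:
    return "".join(fr.geometry.to_xyz(comment=f"t={fr.time_fs:.2f} fs "
                                      f"E={fr.total_energy:.8f} Ha")
                   for fr in trajectory)


def trajectory_to_dataframe(trajectory):
    import pandas as pd

    rows = []
    for fr in trajectory:
        h1, hc, hxc, hnn = fr.energy_components
        rows.append({"time_fs": fr.time_fs, "total_energy": fr.total_energy,
                     "H_one": h1, "H_C": hc, "H_XC": hxc, "H_NN": hnn,
                     "temperature": fr.temperature})
    return pd.DataFrame(rows)
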