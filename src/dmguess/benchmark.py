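"""Evaluation harness: iteration-count statistics per guess scheme and
solver, convergence histories, DM-distance metrics, the element-magnitude
census, and force parity analysis."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .geometry import canonical_frame, features as extract_features, infer_template
from .model import electron_count, predict_dm, rescale_dm

log = logging.getLogger(__name__)

MEV_PER_EV = 1000.0


@dataclass
class GuessBenchmarkTable:
    """Per-(guess, solver) iteration statistics over a geometry ensemble."""

    rows: list = field(default_factory=list)
    ensemble_size: int = 0

    def add(self, guess, solver, counts, capped):
        counts = np.asarray(counts, float)
        conv = counts[~capped] if capped.any() else counts
        self.rows.append({
            "guess": guess, "solver": solver,
            "mean_iterations": float(counts.mean()),
            "variance": float(counts.var()),
            "mean_iterations_converged_only": float(conv.mean()) if len(conv) else np.nan,
            "non_convergence_count": int(capped.sum()),
            "ensemble_size": len(counts),
        })

    def row(self, guess, solver):
        for r in self.rows:
            if r["guess"] == guess and r["solver"] == solver:
                return r
        raise KeyError((guess, solver))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.rows)

    def to_csv(self, path):
        self.to_dataframe().to_csv(path, index=False)


def _ml_initial_dm(engine, geom, model, scf_config, rescale=True):
    """Predict, symmetrize, and (by default) charge-rescale an initial DM."""
    mol = infer_template(geom)
    cgeom, _ = canonical_frame(geom, mol)
    fv = extract_features(cgeom, mol)
    dm = predict_dm(model, fv)
    if rescale:
        sys_ = engine.system(cgeom, scf_config) if hasattr(engine, "system") else None
        if sys_ is not None:
            dm = rescale_dm(dm, sys_.S, sys_.nelec)
        else:
            from .engine.api import SCFConfig

            plain = SCFConfig(functional=scf_config.functional,
                              basis=scf_config.basis,
                              grid_level=scf_config.grid_level)
            res = engine.run_scf(cgeom, plain)
            dm = rescale_dm(dm, res.overlap, round(electron_count(res.dm, res.overlap)))
    return cgeom, dm


def guess_iteration_stats(geometries, guesses, solvers, scf_config,
                          model=None, engine=None) -> GuessBenchmarkTable:
    """SCF iteration counts for each (guess, solver) over an ensemble.

    The 'ml' guess requires a trained model; its prediction is
    electron-count rescaled before use. Non-convergent runs enter the
    statistics at the iteration cap and are counted separately.
    """
    from .engine.api import RealEngine, SCFConfig

    engine = engine or RealEngine()
    if "ml" in guesses and model is None:
        raise ValueError("the 'ml' guess needs a trained model")
    table = GuessBenchmarkTable(ensemble_size=len(geometries))
    for solver in solvers:
        for guess in guesses:
            counts, capped = [], []
            for geom in geometries:
                cfg = SCFConfig(functional=scf_config.functional,
                                basis=scf_config.basis, solver=solver,
                                guess="custom" if guess == "ml" else guess,
                                energy_tolerance=scf_config.energy_tolerance,
                                max_iterations=scf_config.max_iterations,
                                grid_level=scf_config.grid_level)
                try:
                    if guess == "ml":
                        cgeom, dm = _ml_initial_dm(engine, geom, model, cfg)
                        res = engine.run_scf(cgeom, cfg, initial_dm=dm)
                    else:
                        res = engine.run_scf(geom, cfg)
                except Exception as exc:
                    log.warning("(%s, %s): engine failure on a geometry (%s)",
                                guess, solver, exc)
                    continue
                counts.append(res.iteration_count)
                capped.append(not res.converged)
            table.add(guess, solver, counts, np.asarray(capped, bool))
    return table


@dataclass
class ConvergenceHistory:
    iteration: np.ndarray          # n = 0, 1, ...
    energy_above_gs: np.ndarray    # E(n) - E_GS, hartree
    dm_distance: np.ndarray        # ||rho_GS - rho_n||_F, au
    percent_variation: np.ndarray  # vs the previous iterate, percent
    e_gs: float
    converged: bool

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"n": self.iteration,
                             "energy_above_gs": self.energy_above_gs,
                             "dm_distance": self.dm_distance,
                             "percent_variation": self.percent_variation})


class ReferenceError(RuntimeError):
    pass


def convergence_history(geom, guess, solver, scf_config, model=None,
                        engine=None, reference=None) -> ConvergenceHistory:
    """Per-iteration E(n) - E_GS and ||rho_GS - rho_n||_F along one SCF run.

    The ground state comes from a fully converged reference run (computed
    internally when not supplied)."""
    from .engine.api import RealEngine, SCFConfig

    engine = engine or RealEngine()
    cfg = SCFConfig(functional=scf_config.functional, basis=scf_config.basis,
                    solver=solver, guess="custom" if guess == "ml" else guess,
                    energy_tolerance=scf_config.energy_tolerance,
                    max_iterations=scf_config.max_iterations,
                    grid_level=scf_config.grid_level, record_dms=True)
    if guess == "ml":
        geom, dm = _ml_initial_dm(engine, geom, model, cfg)
        res = engine.run_scf(geom, cfg, initial_dm=dm)
    else:
        res = engine.run_scf(geom, cfg)
    if reference is None:
        ref_cfg = SCFConfig(functional=scf_config.functional,
                            basis=scf_config.basis, solver="diis",
                            guess="minao",
                            energy_tolerance=min(1e-10, scf_config.energy_tolerance),
                            max_iterations=max(80, scf_config.max_iterations),
                            grid_level=scf_config.grid_level)
        reference = engine.run_scf(geom, ref_cfg)
        if not reference.converged:
            reference = engine.run_scf(
                geom, SCFConfig(functional=scf_config.functional,
                                basis=scf_config.basis, solver="sos",
                                guess="minao",
                                energy_tolerance=1e-10, max_iterations=80,
                                grid_level=scf_config.grid_level))
    if not reference.converged:
        raise ReferenceError("no converged reference state is available")
    e_gs = reference.total_energy
    rho_gs = reference.dm.matrix
    dms = res.per_iteration_dms
    energies = np.asarray(res.per_iteration_energies)
    n = np.arange(len(energies))
    dist = np.array([np.linalg.norm(rho_gs - d) for d in dms[:len(energies)]])
    pv = np.zeros(len(energies))
    for k in range(1, len(energies)):
        pv[k] = dm_percent_variation(dms[k], dms[k - 1])
    return ConvergenceHistory(n, energies - e_gs, dist, pv, e_gs, res.converged)


class UndefinedMetricError(ZeroDivisionError):
    pass


def dm_percent_variation(dm_a, dm_b) -> float:
    """100 * ||a - b||_F / ||b||_F, with b the reference matrix."""
    a = dm_a.matrix if hasattr(dm_a, "matrix") else np.asarray(dm_a)
    b = dm_b.matrix if hasattr(dm_b, "matrix") else np.asarray(dm_b)
    if a.shape != b.shape:
        raise ValueError("matrix dimensions differ")
    nb = np.linalg.norm(b)
    if nb == 0.0:
        raise UndefinedMetricError("reference matrix has zero norm")
    return float(100.0 * np.linalg.norm(a - b) / nb)


class MagnitudeCensus(NamedTuple):
    high: float       # 0.1 < |rho| < 1
    mid: float        # 1e-3 < |rho| < 0.1
    low: float        # |rho| < 1e-3
    overflow: float   # |rho| >= 1

    def as_percent(self):
        return tuple(100.0 * x for x in self)


def element_magnitude_fractions(dm, thresholds=(1e-3, 0.1, 1.0)) -> MagnitudeCensus:
    """Fractions of DM elements by magnitude bin (open intervals as
    printed; |rho| >= 1 lands in a separate overflow bin)."""
    m = np.abs(dm.matrix if hasattr(dm, "matrix") else np.asarray(dm))
    lo, mid, hi = thresholds
    n = m.size
    return MagnitudeCensus(
        high=float(np.sum((m > mid) & (m < hi))) / n,
        mid=float(np.sum((m > lo) & (m <= mid))) / n,
        low=float(np.sum(m <= lo)) / n,
        overflow=float(np.sum(m >= hi)) / n,
    )


@dataclass
class ForceBenchmark:
    mae: dict                      # per Cartesian component, meV/angstrom
    pairs: dict                    # component -> (F_ml, F_ref) arrays, eV/angstrom
    n_geometries: int

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for comp, (fml, fref) in self.pairs.items():
            for a, b in zip(fml, fref):
                rows.append({"component": comp, "f_ml": a, "f_ref": b})
        return pd.DataFrame(rows)


def force_benchmark(model, geometries, rescale=True, n_scf_steps=0,
                    scf_config=None, engine=None,
                    atom_index=None) -> ForceBenchmark:
    """Forces from the (optionally rescaled) predicted DM vs fully
    converged forces, in the canonical frame.

    Per-component MAEs are reported in meV/angstrom; for planar triatomics
    the z components are verified to vanish. By default the comparison
    uses the in-plane atom (the Fig-5 convention); atom_index=None falls
    back to that atom, -1 pools all atoms."""
    from .engine.api import RealEngine, SCFConfig

    engine = engine or RealEngine()
    scf_config = scf_config or SCFConfig()
    fml = {c: [] for c in "xyz"}
    fref = {c: [] for c in "xyz"}
    n_ok = 0
    for geom in geometries:
        mol = infer_template(geom)
        cgeom, _ = canonical_frame(geom, mol)
        try:
            ref = engine.run_scf(cgeom, scf_config)
            fv = extract_features(cgeom, mol)
            dm = predict_dm(model, fv)
            if rescale:
                ne = round(electron_count(ref.dm, ref.overlap))
                dm = rescale_dm(dm, ref.overlap, ne)
            _, forces, _ = engine.single_point_from_dm(cgeom, dm, n_scf_steps,
                                                       scf_config)
        except Exception as exc:
            log.warning("force benchmark: engine failure on a geometry (%s)", exc)
            continue
        n_ok += 1
        ref_forces = ref.forces
        if atom_index == -1:
            sel = list(range(geom.n_atoms))
        else:
            sel = [2 if atom_index is None else atom_index]
        for ia in sel:
            for ic, comp in enumerate("xyz"):
                fml[comp].append(forces[ia, ic])
                fref[comp].append(ref_forces[ia, ic])
    mae = {c: float(np.mean(np.abs(np.array(fml[c]) - np.array(fref[c])))
                    * MEV_PER_EV) if fml[c] else np.nan
           for c in "xyz"}
    pairs = {c: (np.array(fml[c]), np.array(fref[c])) for c in "xyz"}
    return ForceBenchmark(mae, pairs, n_ok)
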