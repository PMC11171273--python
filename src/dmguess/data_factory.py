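"""Training/validation/test data generation.

Geometry ensembles come from three samplers: NVT molecular dynamics on the
engine's forces (the reference procedure), a harmonic thermal-perturbation
sampler (the documented desk-scale surrogate, Gaussian displacements of
the internal coordinates with 150 K classical amplitudes), and uniform
rigid ligand displacements for the hexaaqua complex. Each sampled geometry
is canonicalized, SCF-converged, and stored as (features, upper-triangle
of the ground-state DM).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    FE_O_EQUILIBRIUM,
    InvalidMoleculeError,
    MolecularGeometry,
    build_hexaaqua,
    canonical_frame,
    equilibrium_geometry,
    features as extract_features,
    infer_template,
)
from .model import dm_to_triangle, triangle_size

log = logging.getLogger(__name__)

KB_HARTREE = 3.166811563e-6          # Ha/K

# Classical thermal widths of the internal coordinates (stretches in
# angstrom, bends in radians) from harmonic force constants:
# sigma = sqrt(kB T / k). Force constants: OH stretch 8.45 aJ/A^2, HOH bend
# 0.76 aJ/rad^2; SO 9.1, SS 4.9 aJ/A^2, SSO bend 1.1 aJ/rad^2.
_KBT_AJ = 1.380649e-2 * 1e-3          # aJ per kelvin (1.380649e-23 J/K)


def _sigma(k_aj: float, temperature_K: float) -> float:
    return float(np.sqrt(_KBT_AJ * temperature_K / k_aj))


_STIFFNESS = {        # (k_bond1, k_bond2, k_angle) in aJ/A^2, aJ/rad^2
    "h2o": (8.45, 8.45, 0.76),
    "s2o": (4.90, 9.10, 1.10),   # order: axis atom (S-S), in-plane atom (S-O)
}


def sample_thermal_geometries(molecule: str, temperature_K: float = 150.0,
                              n_frames: int = 100, mode: str = "perturbation",
                              seed: int = 0, engine=None, scf_config=None,
                              dt_fs: float = 0.5, sample_every: int = 20,
                              equilibration_steps: int = 100):
    """Thermally distorted triatomic geometries in canonical pose.

    mode="md" subsamples an NVT trajectory driven by converged engine
    forces; mode="perturbation" draws Gaussian displacements of the
    internal coordinates with the matching classical amplitudes.
    Deterministic under a fixed seed.
    """
    if molecule not in ("h2o", "s2o"):
        raise InvalidMoleculeError(
            f"thermal sampling supports the triatomics, not {molecule!r}")
    if n_frames < 1:
        raise ValueError("n_frames must be at least 1")
    eq = equilibrium_geometry(molecule)
    if mode == "perturbation":
        rng = np.random.default_rng(seed)
        f0 = extract_features(eq, molecule)
        r1_0 = -f0[0]
        r2_0 = float(np.hypot(f0[1], f0[2]))
        th_0 = float(np.arccos(np.clip(-f0[1] / r2_0, -1.0, 1.0)))
        k1, k2, ka = _STIFFNESS[molecule]
        geoms = []
        for _ in range(n_frames):
            r1 = r1_0 + _sigma(k1, temperature_K) * rng.normal()
            r2 = r2_0 + _sigma(k2, temperature_K) * rng.normal()
            th = th_0 + _sigma(ka, temperature_K) * rng.normal()
            coords = np.array([
                [0.0, 0.0, 0.0],
                [-r1, 0.0, 0.0],
                [r2 * np.cos(np.pi - th), r2 * np.sin(np.pi - th), 0.0]])
            geoms.append(eq.with_coords(coords))
        return geoms
    if mode == "md":
        from .md import run_md

        traj = run_md(eq, force_provider="full_scf",
                      temperature_K=temperature_K, dt_fs=dt_fs,
                      n_steps=equilibration_steps + n_frames * sample_every,
                      seed=seed, engine=engine, scf_config=scf_config)
        frames = traj[equilibration_steps::sample_every][:n_frames]
        return [fr.geometry for fr in frames]
    raise ValueError(f"unknown sampling mode {mode!r}")


def sample_fe_displacements(n_frames: int, fraction: float = 0.10,
                            seed: int = 0) -> np.ndarray:
    """Uniform Fe-O bond-length 6-tuples within +-fraction of equilibrium."""
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    lo = FE_O_EQUILIBRIUM * (1.0 - fraction)
    hi = FE_O_EQUILIBRIUM * (1.0 + fraction)
    return rng.uniform(lo, hi, size=(n_frames, 6))


@dataclass
class Dataset:
    """Features + DM upper triangles with split labels."""

    molecule: str
    features: np.ndarray            # (N, n_in), angstrom
    targets: np.ndarray             # (N, D(D+1)/2), au
    dm_dimension: int
    split: np.ndarray = None        # (N,) strings: train|validation|test|''
    provenance: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.features = np.asarray(self.features, float)
        self.targets = np.asarray(self.targets, float)
        if len(self.features) != len(self.targets):
            raise ValueError("feature/target row counts differ")
        if self.targets.shape[1] != triangle_size(self.dm_dimension):
            raise ValueError("target width is not D(D+1)/2")
        if self.split is None:
            self.split = np.array([""] * len(self.features), dtype=object)

    def __len__(self):
        return len(self.features)

    def rows(self, label: str):
        idx = np.where(self.split == label)[0]
        return self.features[idx], self.targets[idx]

    # ---- persistence ---------------------------------------------------
    def to_hdf5(self, path: str):
        import h5py

        with h5py.File(path, "w") as f:
            f["features"] = self.features
            f["targets"] = self.targets
            f["splits"] = np.array([s.encode() for s in self.split])
            g = f.create_group("meta")
            g.attrs["molecule"] = self.molecule
            g.attrs["dm_dimension"] = self.dm_dimension
            for k, v in self.meta.items():
                g.attrs[k] = v

    @classmethod
    def from_hdf5(cls, path: str) -> "Dataset":
        import h5py

        with h5py.File(path, "r") as f:
            meta = dict(f["meta"].attrs)
            return cls(molecule=str(meta.pop("molecule")),
                       features=f["features"][...],
                       targets=f["targets"][...],
                       dm_dimension=int(meta.pop("dm_dimension")),
                       split=np.array([s.decode() for s in f["splits"][...]],
                                      dtype=object),
                       meta=meta)


def build_dataset(geometries, scf_config=None, engine=None,
                  molecule: str | None = None, warm_start: bool = True) -> Dataset:
    """Canonicalize, converge, and store each geometry.

    Non-convergent frames are dropped and logged, not fatal. With
    warm_start the previous frame's converged DM seeds the next SCF (the
    converged target is guess-independent; this only saves cycles).
    """
    from .engine.api import DensityMatrix, RealEngine, SCFConfig

    engine = engine or RealEngine()
    scf_config = scf_config or SCFConfig()
    feats, tris, prov = [], [], []
    dm_dim = None
    prev_dm = None
    for i, geom in enumerate(geometries):
        mol = molecule or infer_template(geom)
        cgeom, _ = canonical_frame(geom, mol)
        fv = extract_features(cgeom, mol)
        try:
            init = None
            if warm_start and prev_dm is not None:
                init = DensityMatrix(prev_dm, molecule=mol)
            res = engine.run_scf(cgeom, scf_config, initial_dm=init)
        except Exception as exc:            # engine failure: skip the frame
            log.warning("frame %d: engine failure (%s); skipped", i, exc)
            continue
        if not res.converged:
            log.warning("frame %d: SCF did not converge in %d iterations; "
                        "skipped", i, res.iteration_count)
            continue
        prev_dm = res.dm.matrix
        dm_dim = res.dm.basis_dimension
        feats.append(fv)
        tris.append(dm_to_triangle(res.dm.matrix))
        prov.append({"index": i, "iterations": res.iteration_count,
                     "energy": res.total_energy})
    if dm_dim is None:
        raise RuntimeError("no geometry converged; dataset is empty")
    ds = Dataset(molecule=molecule or infer_template(geometries[0]),
                 features=np.array(feats), targets=np.array(tris),
                 dm_dimension=dm_dim, provenance=prov,
                 meta={"basis": scf_config.basis,
                       "functional": scf_config.functional,
                       "engine": getattr(engine, "name", "unknown")})
    return ds


class InvalidSplitError(ValueError):
    pass


def split_dataset(dataset: Dataset, sizes=(9000, 800, 1000), seed: int = 0) -> Dataset:
    """Disjoint random train/validation/test labels, deterministic under seed."""
    n_train, n_val, n_test = sizes
    if n_train + n_val + n_test > len(dataset):
        raise InvalidSplitError(
            f"split sizes {sizes} exceed dataset size {len(dataset)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(dataset))
    split = np.array([""] * len(dataset), dtype=object)
    split[perm[:n_train]] = "train"
    split[perm[n_train:n_train + n_val]] = "validation"
    split[perm[n_train + n_val:n_train + n_val + n_test]] = "test"
    dataset.split = split
    dataset.meta["split_seed"] = seed
    return dataset
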