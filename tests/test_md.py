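"""Molecular dynamics: integrator correctness, canonical-frame workflow
consistency, and trajectory analysis."""

import numpy as np
import pytest

from dmguess.data_factory import sample_thermal_geometries
from dmguess.geometry import MolecularGeometry, equilibrium_geometry, random_rigid_transform
from dmguess.md import (
    IncompleteFrameError,
    InvalidDefinitionError,
    analyze_energy_components,
    analyze_structure,
    run_md,
    total_energy_ev,
    trajectory_to_dataframe,
    trajectory_to_xyz,
)


def test_equilibrium_fixed_point(mock_engine, coarse_cfg):
    """Zero velocity at the equilibrium with no thermostat: stationary."""
    traj = run_md("h2o", "full_scf", temperature_K=0.0, dt_fs=0.5,
                  n_steps=50, thermostat=None, seed=0, engine=mock_engine,
                  scf_config=coarse_cfg)
    drift = np.max(np.abs(traj[-1].geometry.coords - traj[0].geometry.coords))
    assert drift < 1e-6


def test_nve_drift_halves_quadratically(mock_engine, coarse_cfg):
    """Halving the timestep cuts the energy-conservation error ~4x."""
    def fluct(dt, n):
        traj = run_md("h2o", "full_scf", temperature_K=150.0, dt_fs=dt,
                      n_steps=n, thermostat=None, seed=3, engine=mock_engine,
                      scf_config=coarse_cfg)
        e = np.array([total_energy_ev(fr) for fr in traj])
        return np.std(e - e.mean())

    f1 = fluct(1.0, 300)
    f2 = fluct(0.5, 600)
    assert f1 / f2 == pytest.approx(4.0, rel=0.5)


def test_nve_real_engine_bounded_drift(engine):
    """Short real NVE run: total energy conserved to the force-consistency
    floor of the quadrature grid."""
    from dmguess.engine.api import SCFConfig

    traj = run_md("h2o", "full_scf", temperature_K=150.0, dt_fs=0.5,
                  n_steps=30, thermostat=None, seed=4, engine=engine,
                  scf_config=SCFConfig(grid_level="medium"))
    e = np.array([total_energy_ev(fr) for fr in traj])
    assert abs(e[-1] - e[0]) < 5e-4          # eV over 15 fs
    assert np.std(e) < 5e-4


def test_nvt_extended_energy_conserved(mock_engine, coarse_cfg):
    """The Nose-Hoover chain conserves its extended energy over 1000 steps
    (stated tolerance: 1e-3 eV with exact synthetic forces)."""
    traj = run_md("h2o", "full_scf", temperature_K=150.0, dt_fs=0.5,
                  n_steps=1000, thermostat="nose-hoover", seed=6,
                  engine=mock_engine, scf_config=coarse_cfg, record_every=5)
    ext = np.array([fr.extended_energy for fr in traj])
    assert abs(ext[-1] - ext[0]) < 1e-3
    assert ext.std() < 1e-3


def test_md_mode_sampler(mock_engine, coarse_cfg):
    """Trajectory-subsampling mode of the thermal sampler."""
    gs = sample_thermal_geometries("h2o", 150.0, 3, "md", seed=1,
                                   engine=mock_engine, scf_config=coarse_cfg,
                                   equilibration_steps=40, sample_every=10)
    assert len(gs) == 3
    assert all(g.n_atoms == 3 for g in gs)
    # deterministic under the seed
    gs2 = sample_thermal_geometries("h2o", 150.0, 3, "md", seed=1,
                                    engine=mock_engine, scf_config=coarse_cfg,
                                    equilibration_steps=40, sample_every=10)
    assert np.array_equal(gs[-1].coords, gs2[-1].coords)


def test_md_determinism(mock_engine, coarse_cfg):
    a = run_md("h2o", "full_scf", temperature_K=150.0, dt_fs=0.5, n_steps=20,
               seed=7, engine=mock_engine, scf_config=coarse_cfg)
    b = run_md("h2o", "full_scf", temperature_K=150.0, dt_fs=0.5, n_steps=20,
               seed=7, engine=mock_engine, scf_config=coarse_cfg)
    assert np.array_equal(a[-1].geometry.coords, b[-1].geometry.coords)


def test_ml_mode_rotated_initial_condition(mock_engine, mock_oracle_model,
                                           coarse_cfg):
    """ml-mode MD commutes with a rigid rotation of the initial condition."""
    g0 = equilibrium_geometry("h2o")
    distorted = g0.with_coords(g0.coords * 1.03)
    tf = random_rigid_transform(np.random.default_rng(0), max_translation=0.0)
    rotated = distorted.with_coords(tf.invert(distorted.coords))
    kw = dict(force_provider="ml", model=mock_oracle_model, temperature_K=0.0,
              dt_fs=0.5, n_steps=40, thermostat=None, seed=0,
              engine=mock_engine, scf_config=coarse_cfg)
    t1 = run_md(distorted, **kw)
    t2 = run_md(rotated, **kw)
    back = tf.apply(t2[-1].geometry.coords)
    assert np.max(np.abs(back - t1[-1].geometry.coords)) < 1e-5


def test_thermostat_reaches_target_temperature():
    """Nose-Hoover chain equilibrates an ergodic anharmonic chain to the
    target temperature (a pure-harmonic toy would be non-ergodic)."""
    def chain_forces(geom):
        c = geom.coords
        f = np.zeros_like(c)
        e = 0.0
        n = len(c)
        for i in range(n - 1):
            d = c[i + 1] - c[i]
            r = np.linalg.norm(d)
            u = d / r
            dr = r - 1.5
            e += 0.5 * 3.0 * dr ** 2 + 4.0 * dr ** 4
            fmag = -(3.0 * dr + 16.0 * dr ** 3)
            f[i] -= fmag * u
            f[i + 1] += fmag * u
        for i in range(n):
            for j in range(i + 2, n):
                d = c[j] - c[i]
                r = np.linalg.norm(d)
                if r < 1.2:
                    e += 2.0 * (1.2 - r) ** 2
                    fm = 4.0 * (1.2 - r)
                    f[i] -= fm * d / r
                    f[j] += fm * d / r
        return f, e / 27.211386, (e / 27.211386, 0.0, 0.0, 0.0)

    g = MolecularGeometry(["O", "H", "O", "H", "O"],
                          [[0, 0, 0], [1.5, 0.1, 0], [3.0, 0, 0.1],
                           [4.5, 0.1, 0], [6.0, 0, 0]])
    traj = run_md(g, chain_forces, temperature_K=300.0, dt_fs=0.5,
                  n_steps=12000, thermostat="nose-hoover", seed=2,
                  record_every=10)
    temps = np.array([fr.temperature for fr in traj[300:]])
    assert temps.mean() == pytest.approx(300.0, rel=0.15)


def test_analyze_structure_single_frame_and_collinear(mock_engine, coarse_cfg):
    traj = run_md("h2o", "full_scf", temperature_K=150.0, dt_fs=0.5, n_steps=1,
                  seed=2, engine=mock_engine, scf_config=coarse_cfg)
    st = analyze_structure(traj[:1], {"OH": (0, 1)}, {"HOH": (1, 0, 2)})
    assert st.bonds["OH"]["var"] == 0.0
    d0 = np.linalg.norm(traj[0].geometry.coords[0] - traj[0].geometry.coords[1])
    assert st.bonds["OH"]["mean"] == pytest.approx(d0, abs=1e-12)
    # collinear artificial frame: angle exactly 180 degrees
    lin = MolecularGeometry(["O", "H", "H"],
                            [[0, 0, 0], [-1, 0, 0], [1, 0, 0]])
    fake = [type(traj[0])(0.0, lin, np.zeros((3, 3)), np.zeros((3, 3)),
                          0.0, (0, 0, 0, 0), 0.0)]
    st = analyze_structure(fake, {}, {"lin": (1, 0, 2)})
    assert st.angles["lin"]["mean"] == 180.0
    with pytest.raises(InvalidDefinitionError):
        analyze_structure(fake, {"bad": (0, 9)}, {})


def test_energy_component_analysis(mock_engine, coarse_cfg):
    traj = run_md("h2o", "full_scf", temperature_K=150.0, dt_fs=0.5,
                  n_steps=10, seed=3, engine=mock_engine, scf_config=coarse_cfg)
    out = analyze_energy_components(traj)
    assert set(out) == {"H_one", "H_C", "H_XC", "H_NN"}
    single = analyze_energy_components(traj[:1])
    assert single["H_C"]["var"] == 0.0
    broken = [type(traj[0])(0.0, traj[0].geometry, traj[0].velocities,
                            traj[0].forces, traj[0].total_energy,
                            (1.0, 0, 0, 0), 0.0)]
    with pytest.raises(IncompleteFrameError):
        analyze_energy_components(broken)


def test_trajectory_export(mock_engine, coarse_cfg):
    traj = run_md("h2o", "full_scf", temperature_K=150.0, dt_fs=0.5,
                  n_steps=5, seed=0, engine=mock_engine, scf_config=coarse_cfg)
    xyz = trajectory_to_xyz(traj)
    assert xyz.count("t=") == len(traj)
    df = trajectory_to_dataframe(traj)
    assert len(df) == len(traj)
    assert np.allclose(df["H_one"] + df["H_C"] + df["H_XC"] + df["H_NN"],
                       df["total_energy"], atol=1e-10)
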