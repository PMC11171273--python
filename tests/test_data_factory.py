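"""Sampling, dataset construction, and splitting."""

import numpy as np
import pytest

from dmguess.data_factory import (
    Dataset,
    InvalidSplitError,
    build_dataset,
    sample_fe_displacements,
    sample_thermal_geometries,
    split_dataset,
)
from dmguess.geometry import FE_O_EQUILIBRIUM, InvalidMoleculeError, equilibrium_geometry
from dmguess.model import dm_to_triangle, triangle_to_dm


def test_sampler_determinism():
    a = sample_thermal_geometries("h2o", 150, 10, "perturbation", seed=3)
    b = sample_thermal_geometries("h2o", 150, 10, "perturbation", seed=3)
    c = sample_thermal_geometries("h2o", 150, 10, "perturbation", seed=4)
    for ga, gb in zip(a, b):
        assert np.array_equal(ga.coords, gb.coords)
    assert not np.allclose(a[0].coords, c[0].coords)


def test_zero_temperature_gives_equilibrium():
    geoms = sample_thermal_geometries("h2o", 0.0, 5, "perturbation", seed=0)
    eq = equilibrium_geometry("h2o")
    for g in geoms:
        assert np.allclose(g.coords, eq.coords, atol=1e-12)


def test_unsupported_molecule_raises():
    with pytest.raises(InvalidMoleculeError):
        sample_thermal_geometries("fe_hexaaqua", 150, 5)


def test_fe_displacements_uniform_bounds():
    """10^5 uniform draws: all inside +-10%, extremes within 0.1% of the
    bounds (uniform-distribution oracle)."""
    draws = sample_fe_displacements(100000 // 6 + 1, 0.10, seed=1).ravel()
    lo, hi = 1.84725, 2.25775
    assert draws.min() >= lo and draws.max() <= hi
    span = hi - lo
    assert draws.min() - lo < 1e-3 * span * 10
    assert hi - draws.max() < 1e-3 * span * 10
    # degenerate range
    z = sample_fe_displacements(4, 0.0, seed=0)
    assert np.allclose(z, FE_O_EQUILIBRIUM)
    with pytest.raises(ValueError):
        sample_fe_displacements(3, 1.5)


def test_build_dataset_real_rows_and_roundtrip(engine, coarse_cfg):
    """H2O rows carry 3 features and 300 targets; the stored triangle,
    symmetrized, reproduces the engine DM exactly."""
    geoms = sample_thermal_geometries("h2o", 150, 3, "perturbation", seed=9)
    ds = build_dataset(geoms, coarse_cfg, engine)
    assert ds.features.shape == (3, 3)
    assert ds.targets.shape == (3, 300)          # 24*25/2
    # storage round trip is exact: triangle -> symmetrize == engine matrix
    res = engine.run_scf(geoms[1], coarse_cfg)
    stored = dm_to_triangle(res.dm.matrix)
    assert np.array_equal(triangle_to_dm(stored, 24), res.dm.matrix)
    # dataset row agrees with an independent SCF at the convergence level
    rebuilt = triangle_to_dm(ds.targets[1], 24)
    assert np.allclose(rebuilt, rebuilt.T)
    assert np.max(np.abs(rebuilt - res.dm.matrix)) < 1e-4


def test_build_dataset_skips_failures(mock_engine, coarse_cfg):
    class Flaky:
        name = "flaky"

        def run_scf(self, geom, config, initial_dm=None):
            if abs(geom.coords[1, 0] - self.fail_x) < 1e-12:
                raise RuntimeError("synthetic failure")
            return mock_engine.run_scf(geom, config, initial_dm)

    geoms = sample_thermal_geometries("h2o", 150, 4, "perturbation", seed=2)
    flaky = Flaky()
    flaky.fail_x = geoms[2].coords[1, 0]
    ds = build_dataset(geoms, coarse_cfg, flaky, warm_start=False)
    assert len(ds) == 3


def test_split_small_cover_and_determinism(mock_engine, coarse_cfg):
    geoms = sample_thermal_geometries("h2o", 150, 10, "perturbation", seed=5)
    ds = build_dataset(geoms, coarse_cfg, mock_engine)
    split_dataset(ds, (8, 1, 1), seed=1)
    labels = list(ds.split)
    assert labels.count("train") == 8
    assert labels.count("validation") == 1
    assert labels.count("test") == 1
    first = ds.split.copy()
    split_dataset(ds, (8, 1, 1), seed=1)
    assert np.array_equal(ds.split, first)
    split_dataset(ds, (8, 1, 1), seed=2)
    assert not np.array_equal(ds.split, first)
    with pytest.raises(InvalidSplitError):
        split_dataset(ds, (9, 1, 1), seed=0)


def test_dataset_hdf5_roundtrip(tmp_path, mock_engine, coarse_cfg):
    geoms = sample_thermal_geometries("h2o", 150, 6, "perturbation", seed=6)
    ds = build_dataset(geoms, coarse_cfg, mock_engine)
    split_dataset(ds, (4, 1, 1), seed=0)
    p = str(tmp_path / "ds.h5")
    ds.to_hdf5(p)
    back = Dataset.from_hdf5(p)
    assert back.molecule == ds.molecule
    assert np.array_equal(back.features, ds.features)
    assert np.array_equal(back.targets, ds.targets)
    assert list(back.split) == list(ds.split)


def test_feature_columns_invariant_under_rigid_motion(mock_engine, coarse_cfg):
    """End-to-end: datasets built from rigidly moved copies have identical
    feature and target columns."""
    from dmguess.geometry import random_rigid_transform

    geoms = sample_thermal_geometries("h2o", 150, 4, "perturbation", seed=7)
    rng = np.random.default_rng(0)
    moved = [g.with_coords(random_rigid_transform(rng).invert(g.coords))
             for g in geoms]
    d1 = build_dataset(geoms, coarse_cfg, mock_engine)
    d2 = build_dataset(moved, coarse_cfg, mock_engine)
    assert np.max(np.abs(d1.features - d2.features)) < 1e-8
    assert np.max(np.abs(d1.targets - d2.targets)) < 1e-8
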