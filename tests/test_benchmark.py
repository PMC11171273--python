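"""Benchmark harness: iteration tables, histories, DM metrics, forces."""

import numpy as np
import pytest

from dmguess.benchmark import (
    MagnitudeCensus,
    UndefinedMetricError,
    convergence_history,
    dm_percent_variation,
    element_magnitude_fractions,
    force_benchmark,
    guess_iteration_stats,
)
from dmguess.data_factory import sample_thermal_geometries
from dmguess.engine.api import SCFConfig


def test_census_hand_counted_cases():
    c = element_magnitude_fractions(np.eye(4))
    # 4 ones land in the overflow bin (open upper bound), 12 zeros below 1e-3
    assert c == MagnitudeCensus(high=0.0, mid=0.0, low=0.75, overflow=0.25)
    z = element_magnitude_fractions(np.zeros((3, 3)))
    assert z.low == 1.0 and z.high == z.mid == z.overflow == 0.0
    m = np.array([[0.5, 0.01], [0.01, 1e-5]])
    c = element_magnitude_fractions(m)
    assert c == MagnitudeCensus(0.25, 0.5, 0.25, 0.0)


def test_percent_variation_properties():
    rng = np.random.default_rng(0)
    b = rng.normal(size=(5, 5))
    assert dm_percent_variation(b, b) == 0.0
    eps = 1e-3
    assert dm_percent_variation(b * (1 + eps), b) == pytest.approx(100 * eps,
                                                                   rel=1e-10)
    with pytest.raises(UndefinedMetricError):
        dm_percent_variation(b, np.zeros_like(b))
    with pytest.raises(ValueError):
        dm_percent_variation(b, np.zeros((3, 3)))


def test_guess_table_single_geometry_variance(mock_engine, coarse_cfg):
    geoms = sample_thermal_geometries("h2o", 150, 1, "perturbation", seed=0)
    t = guess_iteration_stats(geoms, ["minao"], ["sos"], coarse_cfg,
                              engine=mock_engine)
    row = t.row("minao", "sos")
    assert row["variance"] == 0.0
    assert row["ensemble_size"] == 1
    assert row["mean_iterations"] >= 1


def test_ml_guess_never_worse_than_one_electron(mock_engine, mock_oracle_model,
                                                coarse_cfg):
    geoms = sample_thermal_geometries("h2o", 150, 5, "perturbation", seed=1)
    t = guess_iteration_stats(geoms, ["ml", "one_electron"], ["sos"],
                              coarse_cfg, model=mock_oracle_model,
                              engine=mock_engine)
    assert (t.row("ml", "sos")["mean_iterations"]
            <= t.row("one_electron", "sos")["mean_iterations"])


def test_ml_guess_requires_model(mock_engine, coarse_cfg):
    geoms = sample_thermal_geometries("h2o", 150, 1, "perturbation", seed=0)
    with pytest.raises(ValueError):
        guess_iteration_stats(geoms, ["ml"], ["sos"], coarse_cfg,
                              engine=mock_engine)


def test_force_benchmark_oracle_predictor_is_exact(mock_engine,
                                                   mock_oracle_model,
                                                   coarse_cfg):
    """A predictor returning the exact converged DM gives zero force MAE."""
    geoms = sample_thermal_geometries("h2o", 150, 3, "perturbation", seed=2)
    fb = force_benchmark(mock_oracle_model, geoms, rescale=False,
                         n_scf_steps=0, scf_config=coarse_cfg,
                         engine=mock_engine, atom_index=-1)
    assert fb.n_geometries == 3
    for comp in "xyz":
        assert fb.mae[comp] == 0.0


def test_convergence_history_real(engine):
    cfg = SCFConfig(grid_level="coarse")
    geom = sample_thermal_geometries("h2o", 150, 1, "perturbation", seed=4)[0]
    h = convergence_history(geom, "minao", "diis", cfg, engine=engine)
    assert h.converged
    assert np.all(h.dm_distance >= 0)
    assert abs(h.energy_above_gs[-1]) < 1e-8
    # iterates after the first update are idempotent, hence variational
    assert np.all(h.energy_above_gs[1:] > -1e-9)
    assert h.energy_above_gs[1] >= h.energy_above_gs[-1]
    assert h.percent_variation[0] == 0.0
    df = h.to_dataframe()
    assert list(df.columns) == ["n", "energy_above_gs", "dm_distance",
                                "percent_variation"]


def test_table_dataframe_roundtrip(tmp_path, mock_engine, coarse_cfg):
    geoms = sample_thermal_geometries("h2o", 150, 2, "perturbation", seed=5)
    t = guess_iteration_stats(geoms, ["minao", "one_electron"], ["diis", "sos"],
                              coarse_cfg, engine=mock_engine)
    df = t.to_dataframe()
    assert len(df) == 4
    p = tmp_path / "t.csv"
    t.to_csv(p)
    assert p.exists()
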