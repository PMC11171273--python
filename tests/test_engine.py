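"""Engine contract tests: integrals against literature anchors, SCF
behaviour, guesses, and non-self-consistent evaluations."""

import numpy as np
import pytest

from dmguess.engine import (
    DensityMatrix,
    EngineError,
    InvalidBasisError,
    InvalidDMError,
    SCFConfig,
)
from dmguess.engine.rks import System, guess_density, scf_diis
from dmguess.geometry import MolecularGeometry, equilibrium_geometry


def _h2o_geom(seed=0, scale=0.02):
    g = equilibrium_geometry("h2o")
    rng = np.random.default_rng(seed)
    return g.with_coords(g.coords + rng.normal(scale=scale, size=(3, 3)))


def test_h2_hartree_fock_literature_anchor():
    """RHF/cc-pVDZ for H2 at R = 1.4 bohr: literature value -1.128709 Ha."""
    r = 1.4 * 0.529177210903
    s = System(["H", "H"], [[0, 0, 0], [0, 0, r]], xc="HF")
    sol = scf_diis(s, guess_density(s, "one_electron"), tol=1e-10)
    assert sol.converged
    assert sol.energy == pytest.approx(-1.128709, abs=3e-5)


def test_h2o_hartree_fock_literature_anchor():
    """RHF/cc-pVDZ for water near its HF geometry: about -76.0268 Ha."""
    r, th = 0.9463, np.deg2rad(104.61)
    coords = [[0, 0, 0], [-r, 0, 0],
              [r * np.cos(np.pi - th), r * np.sin(np.pi - th), 0]]
    s = System(["O", "H", "H"], coords, xc="HF")
    sol = scf_diis(s, guess_density(s, "minao"), tol=1e-10)
    assert sol.converged
    assert sol.energy == pytest.approx(-76.0268, abs=5e-4)


def test_overlap_properties(engine, coarse_cfg, h2o_eq_result):
    S = h2o_eq_result.overlap
    assert np.allclose(S, S.T, atol=1e-12)
    w = np.linalg.eigvalsh(S)
    assert w.min() > 0
    assert np.allclose(np.diag(S), 1.0, atol=1e-10)   # normalized AOs


def test_converged_dm_traces_to_electron_count(h2o_eq_result):
    ne = np.trace(h2o_eq_result.dm.matrix @ h2o_eq_result.overlap)
    assert ne == pytest.approx(10.0, abs=1e-8)


def test_guess_independence_of_converged_energy(engine, coarse_cfg):
    """All guess schemes converge to the same total energy (<1e-8 Ha)."""
    for seed in range(3):
        geom = _h2o_geom(seed)
        energies = []
        for scheme in ("minao", "one_electron", "atom", "huckel", "vsap"):
            cfg = SCFConfig(guess=scheme, grid_level="coarse")
            res = engine.run_scf(geom, cfg)
            assert res.converged
            energies.append(res.total_energy)
        assert max(energies) - min(energies) < 1e-8


def test_solver_agreement(engine):
    geom = _h2o_geom(5)
    e = {}
    for solver in ("diis", "sos"):
        res = engine.run_scf(geom, SCFConfig(solver=solver, grid_level="coarse"))
        assert res.converged
        e[solver] = res.total_energy
    assert e["diis"] == pytest.approx(e["sos"], abs=1e-8)


def test_energy_component_closure(h2o_eq_result):
    assert sum(h2o_eq_result.energy_components) == pytest.approx(
        h2o_eq_result.total_energy, abs=1e-8)


def test_iteration_cap_reported(engine):
    res = engine.run_scf(_h2o_geom(1),
                         SCFConfig(guess="one_electron", max_iterations=2,
                                   grid_level="coarse"))
    assert not res.converged
    assert res.iteration_count == 2


def test_guess_quality_ordering(engine, coarse_cfg):
    """The one-electron guess is by far the worst starting point."""
    geom = _h2o_geom(2)
    ref = engine.run_scf(geom, coarse_cfg)
    errs = {}
    for scheme in ("minao", "one_electron", "atom", "huckel", "vsap"):
        dm = engine.baseline_guess_dm(geom, scheme, coarse_cfg)
        e0, _, _ = engine.single_point_from_dm(geom, dm, 0, coarse_cfg)
        errs[scheme] = e0 - ref.total_energy
        assert errs[scheme] > 0          # variational
    assert errs["one_electron"] > 5.0    # catastrophic, several hartree
    for scheme in ("minao", "atom", "huckel", "vsap"):
        assert errs[scheme] < 2.0
        assert errs[scheme] < errs["one_electron"]


def test_unknown_guess_scheme_raises(engine, coarse_cfg):
    with pytest.raises(EngineError):
        engine.baseline_guess_dm(_h2o_geom(0), "bogus", coarse_cfg)


def test_custom_guess_requires_matching_dimension(engine):
    cfg = SCFConfig(guess="custom", grid_level="coarse")
    with pytest.raises(InvalidDMError):
        engine.run_scf(_h2o_geom(0), cfg, initial_dm=DensityMatrix(np.eye(5)))
    with pytest.raises(InvalidDMError):
        engine.run_scf(_h2o_geom(0), cfg, initial_dm=None)


def test_single_point_fixed_point(engine, coarse_cfg, h2o_eq_result):
    """The converged DM is a fixed point: 0 or 1 extra step changes nothing."""
    geom = equilibrium_geometry("h2o")
    for n in (0, 1):
        e, forces, comps = engine.single_point_from_dm(geom, h2o_eq_result.dm,
                                                       n, coarse_cfg)
        assert e == pytest.approx(h2o_eq_result.total_energy, abs=1e-8)
        assert sum(comps) == pytest.approx(e, abs=1e-8)
        # the generalized energy-weighted DM reduces to the canonical one
        assert np.max(np.abs(forces - h2o_eq_result.forces)) < 1e-4


def test_per_iteration_energy_history(engine):
    cfg = SCFConfig(guess="minao", grid_level="coarse", record_dms=True)
    res = engine.run_scf(_h2o_geom(3), cfg)
    hist = res.per_iteration_energies
    assert len(hist) >= 2
    assert hist[-1] == pytest.approx(res.total_energy, abs=1e-12)
    assert abs(hist[-1] - hist[-2]) < 1e-9           # convergence criterion
    assert len(res.per_iteration_dms) >= len(hist)


def test_scfresult_hdf5_roundtrip(tmp_path, h2o_eq_result):
    path = str(tmp_path / "res.h5")
    h2o_eq_result.to_hdf5(path)
    back = type(h2o_eq_result).from_hdf5(path)
    assert back.total_energy == h2o_eq_result.total_energy
    assert np.allclose(back.dm.matrix, h2o_eq_result.dm.matrix)
    assert np.allclose(back.forces, h2o_eq_result.forces)


def test_fe_has_no_scf_parameters():
    from dmguess.geometry import build_hexaaqua

    g = build_hexaaqua(np.full(6, 2.0525))
    from dmguess.engine.api import RealEngine

    with pytest.raises(InvalidBasisError):
        RealEngine().run_scf(g, SCFConfig(grid_level="coarse"))


def test_unknown_basis_raises():
    from dmguess.engine.basis import element_dimension

    with pytest.raises(InvalidBasisError):
        element_dimension("H", "def2-qzvpp")
    with pytest.raises(InvalidBasisError):
        element_dimension("Xx", "cc-pvdz")


def test_grid_overlap_consistency(engine, coarse_cfg):
    """Quadrature-integrated AO products reproduce the analytic overlap."""
    sys_ = engine.system(equilibrium_geometry("h2o"), coarse_cfg)
    ao = sys_._ao(1)
    _, w = sys_._grid()
    Snum = ao[0].T @ (w[:, None] * ao[0])
    assert np.max(np.abs(Snum - sys_.S)) < 5e-4
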