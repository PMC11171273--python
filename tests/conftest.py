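import numpy as np
import pytest

from dmguess.engine.api import RealEngine, SCFConfig
from dmguess.engine.mock import MockEngine
from dmguess.geometry import equilibrium_geometry
from dmguess.model import dm_to_triangle


@pytest.fixture(scope="session")
def engine():
    return RealEngine(cache_systems=16)


@pytest.fixture(scope="session")
def mock_engine():
    return MockEngine()


@pytest.fixture(scope="session")
def coarse_cfg():
    return SCFConfig(grid_level="coarse")


@pytest.fixture(scope="session")
def h2o_eq_result(engine, coarse_cfg):
    """Converged equilibrium water (coarse grid), shared across tests."""
    return engine.run_scf(equilibrium_geometry("h2o"), coarse_cfg)


class OracleModel:
    """Duck-typed stand-in model that returns fixed triangles (synthetic)."""

    def __init__(self, fn, n_in=3, molecule="h2o"):
        self._fn = fn
        self.molecule = molecule

        class _Spec:
            pass

        self.spec = _Spec()
        self.spec.n_in = n_in

    def predict_triangles(self, X):
        X = np.atleast_2d(np.asarray(X, float))
        return np.array([self._fn(x) for x in X])


@pytest.fixture
def oracle_model_factory():
    return OracleModel


@pytest.fixture
def mock_oracle_model(mock_engine):
    """Model that reproduces the mock engine's exact converged DM."""
    return OracleModel(lambda f: dm_to_triangle(mock_engine.dm_star(f)))
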