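"""Network training, DM post-processing, and error metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dmguess.model import (
    DMModel,
    Hyperparams,
    ModelSpec,
    RescaleFailure,
    dm_to_triangle,
    electron_count,
    evaluate_model,
    idempotency_error,
    predict_dm,
    rescale_dm,
    train_model,
    triangle_size,
    triangle_to_dm,
)


def _toy_data(n=64, n_in=2, n_out=10, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, n_in))
    W = rng.normal(size=(n_in, n_out))
    Y = X @ W + 0.1 * np.sin(X @ rng.normal(size=(n_in, n_out)))
    if noise:
        Y = Y + noise * rng.normal(size=Y.shape)
    return X, Y


def test_triangle_roundtrip_exact():
    rng = np.random.default_rng(0)
    m = rng.normal(size=(9, 9))
    m = m + m.T
    tri = dm_to_triangle(m)
    assert tri.shape == (triangle_size(9),)
    assert np.array_equal(triangle_to_dm(tri, 9), m)


@settings(deadline=None, derandomize=True, max_examples=40)
@given(st.integers(min_value=1, max_value=12),
       st.integers(min_value=0, max_value=10 ** 6),
       st.floats(min_value=0.5, max_value=500.0))
def test_rescale_property(d, seed, ne):
    """For any symmetric positive-trace DM: rescaling hits the requested
    electron count exactly and is idempotent."""
    rng = np.random.default_rng(seed)
    m = rng.normal(size=(d, d))
    rho = 0.5 * (m + m.T) + d * np.eye(d)
    q = rng.normal(size=(d, d))
    S = q @ q.T + d * np.eye(d)
    out = rescale_dm(rho, S, ne)
    assert electron_count(out, S) == pytest.approx(ne, abs=1e-10 * max(ne, 1))
    again = rescale_dm(out, S, ne)
    assert np.allclose(again.matrix, out.matrix, rtol=1e-12, atol=0)


def test_default_architectures():
    spec = ModelSpec.for_molecule("h2o")
    assert (spec.n_in, spec.hidden_sizes, spec.n_out) == (3, (18, 32), 300)
    assert ModelSpec.for_molecule("s2o").hidden_sizes == (18, 28)
    assert ModelSpec.for_molecule("fe_hexaaqua").n_in == 6
    assert ModelSpec.for_molecule("fe_hexaaqua").n_out == 187 * 188 // 2


def test_training_determinism():
    X, Y = _toy_data()
    spec = ModelSpec(2, (8,), 10)
    hp = Hyperparams(max_epochs=30, patience=30)
    _, h1 = train_model(spec, X, Y, X[:8], Y[:8], hyper=hp, seed=5)
    _, h2 = train_model(spec, X, Y, X[:8], Y[:8], hyper=hp, seed=5)
    assert h1["train_loss"] == h2["train_loss"]          # bitwise
    _, h3 = train_model(spec, X, Y, X[:8], Y[:8], hyper=hp, seed=6)
    assert h1["train_loss"] != h3["train_loss"]


def test_training_reduces_loss():
    X, Y = _toy_data(n=128)
    spec = ModelSpec(2, (16,), 10)
    _, hist = train_model(spec, X, Y, X[:16], Y[:16],
                          hyper=Hyperparams(max_epochs=80, patience=80), seed=0)
    assert hist["train_loss"][-1] < hist["train_loss"][0]


def test_overfit_single_sample_reproduces_dm():
    """A model driven to zero loss on one sample returns that sample."""
    d = 6
    rng = np.random.default_rng(1)
    m = rng.normal(size=(d, d))
    dm = 0.1 * (m + m.T)
    tri = dm_to_triangle(dm)
    X = np.zeros((32, 3))                       # one repeated input
    Y = np.tile(tri, (32, 1))
    spec = ModelSpec(3, (8,), triangle_size(d))
    model, _ = train_model(spec, X, Y, X[:4], Y[:4],
                           hyper=Hyperparams(max_epochs=300, patience=300),
                           seed=0)
    pred = predict_dm(model, np.zeros(3), d)
    assert np.max(np.abs(pred.matrix - dm)) < 1e-6
    assert np.allclose(pred.matrix, pred.matrix.T)       # symmetric


def test_metrics_match_hand_computed_oracle():
    """2x2-style toy: metrics agree with explicit elementwise formulas."""
    pred = np.array([[1.0, 2.0, 3.0], [2.0, 0.0, -1.0]])
    targ = np.array([[1.5, 2.0, 2.0], [1.0, 0.5, -1.0]])

    class Fixed:
        spec = type("S", (), {"n_in": 1})()
        x_mean = 0.0

        def predict_triangles(self, X):
            return pred

    err = pred - targ
    mae = np.mean(np.abs(err))
    rmse = np.sqrt(np.mean(err ** 2))
    ss_res = np.sum(err ** 2)
    ss_tot = np.sum((targ - targ.mean()) ** 2)
    m = evaluate_model(Fixed(), np.zeros((2, 1)), targ)
    assert m.mae == pytest.approx(mae, abs=1e-14)
    assert m.rmse == pytest.approx(rmse, abs=1e-14)
    assert m.r_squared == pytest.approx(1 - ss_res / ss_tot, abs=1e-14)
    assert m.max_element_error == pytest.approx(np.max(np.abs(err)), abs=1e-14)
    assert m.mae <= m.rmse <= m.max_element_error


def test_electron_count_against_bruteforce_sum():
    rng = np.random.default_rng(2)
    d = 7
    m = rng.normal(size=(d, d))
    rho = m + m.T
    q = rng.normal(size=(d, d))
    S = q @ q.T + d * np.eye(d)
    brute = sum(rho[i, j] * S[j, i] for i in range(d) for j in range(d))
    assert electron_count(rho, S) == pytest.approx(brute, abs=1e-12)
    assert electron_count(np.zeros((d, d)), S) == 0.0
    with pytest.raises(ValueError):
        electron_count(rho, np.eye(3))


def test_rescale_dm_exact_and_idempotent():
    rng = np.random.default_rng(3)
    d = 6
    m = rng.normal(size=(d, d))
    rho = 0.5 * (m + m.T) + 2 * np.eye(d)
    S = np.eye(d)
    out = rescale_dm(rho, S, 10.0)
    assert electron_count(out, S) == pytest.approx(10.0, abs=1e-12)
    again = rescale_dm(out, S, 10.0)
    assert np.allclose(again.matrix, out.matrix, atol=1e-14)
    # pure scaling: direction preserved
    assert np.allclose(out.matrix / np.linalg.norm(out.matrix),
                       rho / np.linalg.norm(rho), atol=1e-12)
    with pytest.raises(RescaleFailure):
        rescale_dm(np.zeros((d, d)), S, 10.0)


def test_idempotency_error_constructed_dm():
    """A DM built from S-orthonormal occupied orbitals with occupation 2 is
    exactly idempotent under rho S rho = 2 rho."""
    rng = np.random.default_rng(4)
    d, nocc = 8, 3
    q = rng.normal(size=(d, d))
    S = q @ q.T + d * np.eye(d)
    w, v = np.linalg.eigh(S)
    X = (v / np.sqrt(w)) @ v.T
    C = X @ np.linalg.qr(rng.normal(size=(d, nocc)))[0]
    rho = 2.0 * C @ C.T
    assert idempotency_error(rho, S) < 1e-10
    # a perturbed DM is not idempotent
    assert idempotency_error(rho + 1e-3, S) > 1e-4


def test_noise_floor_recovery():
    """On a linear map plus Gaussian noise, the test MAE approaches the
    analytic floor sigma*sqrt(2/pi) within 20%."""
    sigma = 0.01
    rng = np.random.default_rng(8)
    X = rng.normal(size=(2000, 3))
    W = rng.normal(size=(3, 20))
    Y = X @ W + sigma * rng.normal(size=(2000, 20))
    spec = ModelSpec(3, (16, 16), 20)
    model, _ = train_model(spec, X[:1600], Y[:1600], X[1600:1800], Y[1600:1800],
                           hyper=Hyperparams(max_epochs=400, patience=100),
                           seed=0)
    m = evaluate_model(model, X[1800:], Y[1800:])
    floor = sigma * np.sqrt(2 / np.pi)
    assert abs(m.mae - floor) / floor < 0.20


def test_model_save_load_roundtrip(tmp_path):
    X, Y = _toy_data()
    spec = ModelSpec(2, (8,), 10)
    model, _ = train_model(spec, X, Y, X[:8], Y[:8],
                           hyper=Hyperparams(max_epochs=20, patience=20),
                           seed=1, molecule="h2o")
    p = str(tmp_path / "m.npz")
    model.save(p)
    back = DMModel.load(p)
    assert np.allclose(back.predict_triangles(X[:5]),
                       model.predict_triangles(X[:5]), atol=1e-15)
    assert back.molecule == "h2o"
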