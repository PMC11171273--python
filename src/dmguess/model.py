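"""Dense neural networks mapping canonical-frame coordinates to density
matrices, plus the post-processing (symmetrization, electron-count
rescaling) and error metrics.

The networks are deliberately tiny (two ELU hidden layers, tens of
neurons): the map from a handful of internal coordinates to the converged
DM elements is smooth, and small models train in seconds on a CPU. They
are implemented directly in numpy (forward pass, backprop, Adam), which
keeps training bitwise-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DM_DIMENSIONS = {"h2o": 24, "s2o": 50, "fe_hexaaqua": 187}

# hidden-layer layouts per molecule
DEFAULT_HIDDEN = {"h2o": (18, 32), "s2o": (18, 28), "fe_hexaaqua": (16, 32)}


def triangle_size(d: int) -> int:
    return d * (d + 1) // 2


def dm_to_triangle(dm: np.ndarray) -> np.ndarray:
    """Upper triangle, row-major (the independent elements)."""
    d = dm.shape[0]
    iu = np.triu_indices(d)
    return dm[iu]


def triangle_to_dm(tri: np.ndarray, d: int) -> np.ndarray:
    """Mirror a packed upper triangle into a symmetric matrix."""
    dm = np.zeros((d, d))
    iu = np.triu_indices(d)
    dm[iu] = tri
    dm.T[iu] = tri
    return dm


@dataclass
class ModelSpec:
    n_in: int
    hidden_sizes: tuple
    n_out: int
    activation: str = "elu"

    @classmethod
    def for_molecule(cls, molecule: str) -> "ModelSpec":
        d = DM_DIMENSIONS[molecule]
        n_in = 6 if molecule == "fe_hexaaqua" else 3
        return cls(n_in, DEFAULT_HIDDEN[molecule], triangle_size(d))


@dataclass
class Metrics:
    mae: float
    rmse: float
    r_squared: float
    max_element_error: float

    def as_dict(self):
        return {"mae": self.mae, "rmse": self.rmse,
                "r_squared": self.r_squared,
                "max_element_error": self.max_element_error}


def _elu(x):
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))


def _elu_grad(x):
    return np.where(x > 0, 1.0, np.exp(np.minimum(x, 0.0)))


class DMModel:
    """Feed-forward ELU network with input/output standardization baked in."""

    def __init__(self, spec: ModelSpec, weights, x_mean, x_std, y_mean, y_std,
                 molecule: str | None = None, seed: int | None = None):
        self.spec = spec
        self.weights = weights            # list of (W, b)
        self.x_mean, self.x_std = x_mean, x_std
        self.y_mean, self.y_std = y_mean, y_std
        self.molecule = molecule
        self.seed = seed

    # ---- inference -----------------------------------------------------
    def _forward_std(self, Xs):
        h = Xs
        for W, b in self.weights[:-1]:
            h = _elu(h @ W + b)
        W, b = self.weights[-1]
        return h @ W + b

    def predict_triangles(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != self.spec.n_in:
            raise ValueError(f"feature length {X.shape[1]} != n_in {self.spec.n_in}")
        Xs = (X - self.x_mean) / self.x_std
        Ys = self._forward_std(Xs)
        return Ys * self.y_std + self.y_mean

    # ---- persistence ---------------------------------------------------
    def save(self, path: str):
        arrs = {"x_mean": self.x_mean, "x_std": self.x_std,
                "y_mean": self.y_mean, "y_std": self.y_std}
        for i, (W, b) in enumerate(self.weights):
            arrs[f"W{i}"] = W
            arrs[f"b{i}"] = b
        np.savez_compressed(
            path, n_layers=len(self.weights), n_in=self.spec.n_in,
            hidden=np.array(self.spec.hidden_sizes), n_out=self.spec.n_out,
            molecule=np.bytes_((self.molecule or "").encode()),
            seed=-1 if self.seed is None else self.seed, **arrs)

    @classmethod
    def load(cls, path: str) -> "DMModel":
        z = np.load(path, allow_pickle=False)
        nl = int(z["n_layers"])
        weights = [(z[f"W{i}"], z[f"b{i}"]) for i in range(nl)]
        spec = ModelSpec(int(z["n_in"]), tuple(int(h) for h in z["hidden"]),
                         int(z["n_out"]))
        mol = bytes(z["molecule"]).decode() or None
        seed = int(z["seed"])
        return cls(spec, weights, z["x_mean"], z["x_std"], z["y_mean"],
                   z["y_std"], molecule=mol, seed=None if seed < 0 else seed)


class TrainingFailure(RuntimeError):
    def __init__(self, msg, history=None):
        super().__init__(msg)
        self.history = history


@dataclass
class Hyperparams:
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 4000
    patience: int = 300          # early stopping on validation MAE
    lr_decay: float = 0.5        # plateau decay factor
    lr_patience: int = 80
    min_lr: float = 1e-5


def train_model(spec: ModelSpec, features: np.ndarray, targets: np.ndarray,
                val_features: np.ndarray, val_targets: np.ndarray,
                hyper: Hyperparams | None = None, seed: int = 0,
                molecule: str | None = None):
    """Train on MSE of standardized elements; select on validation MAE (au).

    Returns (model, history) with per-epoch training loss and validation
    MAE. Deterministic under a fixed seed.
    """
    hyper = hyper or Hyperparams()
    rng = np.random.default_rng(seed)
    X = np.asarray(features, float)
    Y = np.asarray(targets, float)
    x_mean = X.mean(axis=0)
    x_std = np.where(X.std(axis=0) < 1e-12, 1.0, X.std(axis=0))
    y_mean = Y.mean(axis=0)
    y_std = np.where(Y.std(axis=0) < 1e-9, 1.0, Y.std(axis=0))
    Xs = (X - x_mean) / x_std
    Ys = (Y - y_mean) / y_std
    Xv = (np.asarray(val_features, float) - x_mean) / x_std
    Yv = np.asarray(val_targets, float)

    sizes = [spec.n_in, *spec.hidden_sizes, spec.n_out]
    weights = []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        W = rng.normal(0.0, np.sqrt(2.0 / (fan_in + fan_out)), (fan_in, fan_out))
        weights.append((W, np.zeros(fan_out)))

    mW = [np.zeros_like(W) for W, _ in weights]
    vW = [np.zeros_like(W) for W, _ in weights]
    mb = [np.zeros_like(b) for _, b in weights]
    vb = [np.zeros_like(b) for _, b in weights]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lr = hyper.learning_rate
    tstep = 0

    def forward_cache(Xb):
        acts = [Xb]
        pre = []
        h = Xb
        for W, b in weights[:-1]:
            z = h @ W + b
            pre.append(z)
            h = _elu(z)
            acts.append(h)
        W, b = weights[-1]
        out = h @ W + b
        return acts, pre, out

    def val_mae(model_weights):
        h = Xv
        for W, b in model_weights[:-1]:
            h = _elu(h @ W + b)
        W, b = model_weights[-1]
        pred = (h @ W + b) * y_std + y_mean
        return float(np.mean(np.abs(pred - Yv)))

    n = len(Xs)
    history = {"train_loss": [], "val_mae": []}
    best = (np.inf, [(W.copy(), b.copy()) for W, b in weights])
    stall = lr_stall = 0
    for epoch in range(hyper.max_epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        for start in range(0, n, hyper.batch_size):
            idx = order[start:start + hyper.batch_size]
            Xb, Yb = Xs[idx], Ys[idx]
            acts, pre, out = forward_cache(Xb)
            diff = out - Yb
            ep_loss += float(np.sum(diff ** 2))
            grad = 2.0 * diff / (len(idx) * spec.n_out)
            grads = []
            gW = acts[-1].T @ grad
            gb = grad.sum(axis=0)
            grads.append((gW, gb))
            gh = grad @ weights[-1][0].T
            for li in range(len(weights) - 2, -1, -1):
                gz = gh * _elu_grad(pre[li])
                grads.append((acts[li].T @ gz, gz.sum(axis=0)))
                if li > 0:
                    gh = gz @ weights[li][0].T
            grads.reverse()
            tstep += 1
            corr1 = 1.0 - beta1 ** tstep
            corr2 = 1.0 - beta2 ** tstep
            for li, (gW, gb) in enumerate(grads):
                mW[li] = beta1 * mW[li] + (1 - beta1) * gW
                vW[li] = beta2 * vW[li] + (1 - beta2) * gW ** 2
                mb[li] = beta1 * mb[li] + (1 - beta1) * gb
                vb[li] = beta2 * vb[li] + (1 - beta2) * gb ** 2
                W, b = weights[li]
                W = W - lr * (mW[li] / corr1) / (np.sqrt(vW[li] / corr2) + eps)
                b = b - lr * (mb[li] / corr1) / (np.sqrt(vb[li] / corr2) + eps)
                weights[li] = (W, b)
        ep_loss /= n * spec.n_out
        if not np.isfinite(ep_loss):
            raise TrainingFailure("training loss diverged (NaN/inf)", history)
        vm = val_mae(weights)
        history["train_loss"].append(ep_loss)
        history["val_mae"].append(vm)
        if vm < best[0] - 1e-12:
            best = (vm, [(W.copy(), b.copy()) for W, b in weights])
            stall = lr_stall = 0
        else:
            stall += 1
            lr_stall += 1
            if lr_stall >= hyper.lr_patience and lr > hyper.min_lr:
                lr = max(lr * hyper.lr_decay, hyper.min_lr)
                lr_stall = 0
            if stall >= hyper.patience:
                break
    model = DMModel(spec, best[1], x_mean, x_std, y_mean, y_std,
                    molecule=molecule, seed=seed)
    return model, history


# ---------------------------------------------------------------------------
# DM post-processing and metrics
# ---------------------------------------------------------------------------

def predict_dm(model: DMModel, feature_vector: np.ndarray, d: int | None = None):
    """Predict one symmetric DM from a feature vector."""
    from .engine.api import DensityMatrix

    tri = model.predict_triangles(feature_vector)[0]
    if d is None:
        d = int((np.sqrt(8 * len(tri) + 1) - 1) / 2)
    if triangle_size(d) != len(tri):
        raise ValueError(f"output length {len(tri)} is not a {d}x{d} triangle")
    return DensityMatrix(triangle_to_dm(tri, d), molecule=model.molecule)


def electron_count(dm, overlap: np.ndarray) -> float:
    """N_e = Tr[rho S]."""
    m = dm.matrix if hasattr(dm, "matrix") else np.asarray(dm)
    if m.shape != np.asarray(overlap).shape:
        raise ValueError("DM / overlap dimension mismatch")
    return float(np.trace(m @ overlap))


class RescaleFailure(RuntimeError):
    pass


def rescale_dm(dm, overlap: np.ndarray, n_electrons: float):
    """Scale the DM by N_e / Tr[rho S] so it holds the right charge."""
    from .engine.api import DensityMatrix

    m = dm.matrix if hasattr(dm, "matrix") else np.asarray(dm)
    ne_ml = electron_count(m, overlap)
    if ne_ml < 1e-6 * n_electrons:
        raise RescaleFailure(f"electron count of supplied DM is {ne_ml:.3e}; "
                             "rescaling is ill-defined")
    mol = dm.molecule if hasattr(dm, "molecule") else None
    return DensityMatrix(m * (n_electrons / ne_ml), molecule=mol)


def idempotency_error(dm, overlap: np.ndarray) -> float:
    """|| rho S rho - 2 rho ||_F (zero for a closed-shell ground-state DM
    under the Tr[rho S] = N_e convention)."""
    m = dm.matrix if hasattr(dm, "matrix") else np.asarray(dm)
    return float(np.linalg.norm(m @ overlap @ m - 2.0 * m))


def evaluate_model(model: DMModel, features: np.ndarray,
                   targets: np.ndarray) -> Metrics:
    """Pooled elementwise errors over a test split (atomic units)."""
    if len(features) == 0:
        raise ValueError("empty test split")
    pred = model.predict_triangles(features)
    err = pred - np.asarray(targets, float)
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err ** 2)))
    ss_res = float(np.sum(err ** 2))
    ss_tot = float(np.sum((targets - np.mean(targets)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return Metrics(mae, rmse, r2, float(np.max(np.abs(err))))
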