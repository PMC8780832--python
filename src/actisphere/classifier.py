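"""Deep LSTM for healthy-vs-stroke window classification.

The network mirrors the reference architecture for 300-timestep,
12-channel windows:

    LSTM(200, sequence output) -> BatchNorm(200) -> LSTM(50)
    -> Dropout -> Dense(50, ReLU) -> Dropout -> Dense(15, ReLU)
    -> Dense(1, sigmoid)

It is implemented directly in NumPy — forward pass, full backpropagation
through time, and an Adam optimizer — so training is reproducible bit-for-
bit from a seed in single-threaded use.  ``count_parameters`` computes the
per-layer trainable+tracked parameter counts analytically (the LSTM count
is 4*(u*(u+d) + u); batch norm tracks 4 values per channel: scale, shift
and the two running statistics).

Inputs are z-scored per channel with statistics computed on the training
set only.  The binary cross-entropy loss is fused with the output sigmoid
for numerical stability.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn import metrics as skmetrics


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture hyper-parameters (defaults fix the reference stack)."""

    timesteps: int = 300
    input_channels: int = 12
    lstm1_units: int = 200
    lstm2_units: int = 50
    dense1_units: int = 50
    dense2_units: int = 15
    dropout_p: float = 0.2

    def layer_names(self) -> list[str]:
        return [
            "lstm_1", "batch_norm", "lstm_2", "dropout_1",
            "dense_1", "dropout_2", "dense_2", "dense_out",
        ]


def count_parameters(spec: NetworkSpec | None = None) -> dict[str, int]:
    """Analytic per-layer parameter counts for the network.

    LSTM with u units and input dimension d: 4*(u*(u+d) + u).
    Batch norm over c channels: 4*c (gamma, beta, running mean, running var).
    Dense d -> u: (d+1)*u.  Dropout: 0.
    """
    spec = spec or NetworkSpec()
    d, u1, u2 = spec.input_channels, spec.lstm1_units, spec.lstm2_units
    h1, h2 = spec.dense1_units, spec.dense2_units
    return {
        "lstm_1": 4 * (u1 * (u1 + d) + u1),
        "batch_norm": 4 * u1,
        "lstm_2": 4 * (u2 * (u2 + u1) + u2),
        "dropout_1": 0,
        "dense_1": (u2 + 1) * h1,
        "dropout_2": 0,
        "dense_2": (h1 + 1) * h2,
        "dense_out": (h2 + 1) * 1,
    }


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _orthogonal(rng: np.random.Generator, n: int, dtype) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((n, n)))
    return (q * np.sign(np.diag(r))).astype(dtype)


class _LSTMLayer:
    """Standard LSTM (gate order i, f, g, o) with optional sequence output."""

    def __init__(self, input_dim, units, rng, dtype, return_sequences):
        self.d, self.u = input_dim, units
        self.return_sequences = return_sequences
        limit = np.sqrt(6.0 / (input_dim + units))
        self.W = rng.uniform(-limit, limit, size=(input_dim, 4 * units)).astype(dtype)
        self.U = np.concatenate(
            [_orthogonal(rng, units, dtype) for _ in range(4)], axis=1
        )
        self.b = np.zeros(4 * units, dtype=dtype)
        self.b[units : 2 * units] = 1.0  # forget-gate bias
        self.params = {"W": self.W, "U": self.U, "b": self.b}

    def forward(self, x: np.ndarray):
        B, T, _ = x.shape
        u = self.u
        dtype = self.W.dtype
        I = np.empty((T, B, u), dtype)
        F = np.empty((T, B, u), dtype)
        G = np.empty((T, B, u), dtype)
        O = np.empty((T, B, u), dtype)
        C = np.empty((T, B, u), dtype)
        TC = np.empty((T, B, u), dtype)
        H = np.empty((T, B, u), dtype)
        h = np.zeros((B, u), dtype)
        c = np.zeros((B, u), dtype)
        xW = x.reshape(B * T, self.d) @ self.W
        xW = xW.reshape(B, T, 4 * u)
        for t in range(T):
            z = xW[:, t] + h @ self.U + self.b
            i = _sigmoid(z[:, :u])
            f = _sigmoid(z[:, u : 2 * u])
            g = np.tanh(z[:, 2 * u : 3 * u])
            o = _sigmoid(z[:, 3 * u :])
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            I[t], F[t], G[t], O[t], C[t], TC[t], H[t] = i, f, g, o, c, tc, h
        cache = (x, I, F, G, O, C, TC, H)
        if self.return_sequences:
            return H.transpose(1, 0, 2), cache
        return h, cache

    def backward(self, dout: np.ndarray, cache):
        x, I, F, G, O, C, TC, H = cache
        B, T, _ = x.shape
        u = self.u
        dtype = self.W.dtype
        dW = np.zeros_like(self.W)
        dU = np.zeros_like(self.U)
        db = np.zeros_like(self.b)
        dZ = np.empty((T, B, 4 * u), dtype)
        dh_next = np.zeros((B, u), dtype)
        dc_next = np.zeros((B, u), dtype)
        if self.return_sequences:
            dout_seq = dout.transpose(1, 0, 2)
        for t in range(T - 1, -1, -1):
            dh = dh_next + (dout_seq[t] if self.return_sequences else 0)
            if not self.return_sequences and t == T - 1:
                dh = dh + dout
            i, f, g, o, tc = I[t], F[t], G[t], O[t], TC[t]
            c_prev = C[t - 1] if t > 0 else np.zeros((B, u), dtype)
            h_prev = H[t - 1] if t > 0 else np.zeros((B, u), dtype)
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = dZ[t]
            dz[:, :u] = di * i * (1.0 - i)
            dz[:, u : 2 * u] = df * f * (1.0 - f)
            dz[:, 2 * u : 3 * u] = dg * (1.0 - g * g)
            dz[:, 3 * u :] = do * o * (1.0 - o)
            dU += h_prev.T @ dz
            db += dz.sum(axis=0)
            dh_next = dz @ self.U.T
            dc_next = dc * f
        flat_dz = dZ.transpose(1, 0, 2).reshape(B * T, 4 * u)
        dW = x.reshape(B * T, self.d).T @ flat_dz
        dx = (flat_dz @ self.W.T).reshape(B, T, self.d)
        return dx, {"W": dW, "U": dU, "b": db}


class _BatchNormLayer:
    """Batch normalization over the channel axis of (B, T, C) sequences."""

    def __init__(self, channels, dtype, momentum=0.9, eps=1e-5):
        self.gamma = np.ones(channels, dtype)
        self.beta = np.zeros(channels, dtype)
        self.running_mean = np.zeros(channels, dtype)
        self.running_var = np.ones(channels, dtype)
        self.momentum = momentum
        self.eps = eps
        self.params = {"gamma": self.gamma, "beta": self.beta}

    def forward(self, x: np.ndarray, training: bool):
        if training:
            mu = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean *= self.momentum
            self.running_mean += (1 - self.momentum) * mu
            self.running_var *= self.momentum
            self.running_var += (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        return self.gamma * xhat + self.beta, (xhat, inv_std)

    def backward(self, dout: np.ndarray, cache):
        xhat, inv_std = cache
        n = dout.shape[0] * dout.shape[1]
        dgamma = (dout * xhat).sum(axis=(0, 1))
        dbeta = dout.sum(axis=(0, 1))
        dxhat = dout * self.gamma
        dx = (
            inv_std
            / n
            * (n * dxhat - dxhat.sum(axis=(0, 1)) - xhat * (dxhat * xhat).sum(axis=(0, 1)))
        )
        return dx, {"gamma": dgamma, "beta": dbeta}


class _DenseLayer:
    def __init__(self, input_dim, units, rng, dtype, activation):
        limit = np.sqrt(6.0 / (input_dim + units))
        self.W = rng.uniform(-limit, limit, size=(input_dim, units)).astype(dtype)
        self.b = np.zeros(units, dtype)
        self.activation = activation
        self.params = {"W": self.W, "b": self.b}

    def forward(self, x: np.ndarray):
        z = x @ self.W + self.b
        if self.activation == "relu":
            out = np.maximum(z, 0.0)
        else:  # linear (sigmoid is fused into the loss)
            out = z
        return out, (x, z)

    def backward(self, dout: np.ndarray, cache):
        x, z = cache
        if self.activation == "relu":
            dout = dout * (z > 0)
        dW = x.T @ dout
        db = dout.sum(axis=0)
        dx = dout @ self.W.T
        return dx, {"W": dW, "b": db}


class _DropoutLayer:
    def __init__(self, p):
        self.p = p

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator):
        if not training or self.p == 0.0:
            return x, None
        mask = (rng.random(x.shape) >= self.p).astype(x.dtype) / (1.0 - self.p)
        return x * mask, mask

    def backward(self, dout: np.ndarray, mask):
        if mask is None:
            return dout
        return dout * mask


class DeepLSTMClassifier:
    """The full sequence classifier with seeded, reproducible training."""

    def __init__(self, spec: NetworkSpec | None = None, seed: int = 0, dtype=np.float32):
        self.spec = spec or NetworkSpec()
        self.seed = seed
        self.dtype = np.dtype(dtype).type
        rng = np.random.default_rng(seed)
        s = self.spec
        self.lstm1 = _LSTMLayer(s.input_channels, s.lstm1_units, rng, self.dtype, True)
        self.bn = _BatchNormLayer(s.lstm1_units, self.dtype)
        self.lstm2 = _LSTMLayer(s.lstm1_units, s.lstm2_units, rng, self.dtype, False)
        self.drop1 = _DropoutLayer(s.dropout_p)
        self.dense1 = _DenseLayer(s.lstm2_units, s.dense1_units, rng, self.dtype, "relu")
        self.drop2 = _DropoutLayer(s.dropout_p)
        self.dense2 = _DenseLayer(s.dense1_units, s.dense2_units, rng, self.dtype, "relu")
        self.dense_out = _DenseLayer(s.dense2_units, 1, rng, self.dtype, "linear")
        self._param_layers = [self.lstm1, self.bn, self.lstm2, self.dense1, self.dense2, self.dense_out]
        self._rng = rng
        self.channel_mean: np.ndarray | None = None
        self.channel_sd: np.ndarray | None = None

    # -- parameter plumbing -------------------------------------------------
    def parameters(self) -> list[np.ndarray]:
        out = []
        for layer in self._param_layers:
            out.extend(layer.params.values())
        return out

    # -- forward / backward -------------------------------------------------
    def _standardize(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=self.dtype)
        if self.channel_mean is None:
            return X
        return (X - self.channel_mean) / self.channel_sd

    def fit_standardizer(self, X_train: np.ndarray) -> None:
        X_train = np.asarray(X_train, dtype=self.dtype)
        self.channel_mean = X_train.mean(axis=(0, 1), dtype=np.float64).astype(self.dtype)
        sd = X_train.std(axis=(0, 1), dtype=np.float64).astype(self.dtype)
        self.channel_sd = np.maximum(sd, self.dtype(1e-6))

    def _forward(self, X: np.ndarray, training: bool):
        h1, c1 = self.lstm1.forward(X)
        hb, cb = self.bn.forward(h1, training)
        h2, c2 = self.lstm2.forward(hb)
        hd1, m1 = self.drop1.forward(h2, training, self._rng)
        h3, c3 = self.dense1.forward(hd1)
        hd2, m2 = self.drop2.forward(h3, training, self._rng)
        h4, c4 = self.dense2.forward(hd2)
        logits, c5 = self.dense_out.forward(h4)
        return logits[:, 0], (c1, cb, c2, m1, c3, m2, c4, c5)

    def _backward(self, dlogits: np.ndarray, caches):
        c1, cb, c2, m1, c3, m2, c4, c5 = caches
        d, g5 = self.dense_out.backward(dlogits[:, None], c5)
        d, g4 = self.dense2.backward(d, c4)
        d = self.drop2.backward(d, m2)
        d, g3 = self.dense1.backward(d, c3)
        d = self.drop1.backward(d, m1)
        d, g2 = self.lstm2.backward(d, c2)
        d, gb = self.bn.backward(d, cb)
        _, g1 = self.lstm1.backward(d, c1)
        grads = []
        for layer, g in zip(
            self._param_layers, (g1, gb, g2, g3, g4, g5)
        ):
            grads.extend(g[k] for k in layer.params)
        return grads

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray, training: bool = True):
        """Mean BCE loss and parameter gradients for one (standardized) batch."""
        y = np.asarray(y, dtype=self.dtype)
        logits, caches = self._forward(X, training)
        p = _sigmoid(logits)
        eps = 1e-7
        pc = np.clip(p, eps, 1 - eps)
        loss = float(-np.mean(y * np.log(pc) + (1 - y) * np.log(1 - pc)))
        dlogits = (p - y).astype(self.dtype) / len(y)
        grads = self._backward(dlogits, caches)
        return loss, grads, p

    # -- training -----------------------------------------------------------
    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        X_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
        epochs: int = 20,
        batch_size: int = 64,
        lr: float = 1e-3,
        clip_norm: float = 5.0,
    ) -> dict[str, list[float]]:
        """Adam training with global gradient-norm clipping.

        Returns a per-epoch loss/accuracy history (and validation metrics
        when a validation set is given).
        """
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("training labels contain a single class")
        if X.shape[1:] != (self.spec.timesteps, self.spec.input_channels):
            raise ValueError(
                f"windows shaped {X.shape[1:]} do not match the network input "
                f"({self.spec.timesteps}, {self.spec.input_channels})"
            )
        self.fit_standardizer(X)
        Xs = self._standardize(X)
        params = self.parameters()
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        b1, b2, eps = 0.9, 0.999, 1e-7
        step = 0
        history: dict[str, list[float]] = {
            "loss": [], "accuracy": [], "val_loss": [], "val_accuracy": []
        }
        n = len(y)
        for _ in range(epochs):
            order = self._rng.permutation(n)
            losses, hits, seen = 0.0, 0, 0
            for s in range(0, n, batch_size):
                idx = order[s : s + batch_size]
                loss, grads, p = self.loss_and_grads(Xs[idx], y[idx], training=True)
                if clip_norm:
                    gnorm = np.sqrt(sum(float((g * g).sum()) for g in grads))
                    if gnorm > clip_norm:
                        scale = self.dtype(clip_norm / gnorm)
                        grads = [g * scale for g in grads]
                step += 1
                for k, (param, grad) in enumerate(zip(params, grads)):
                    m[k] = b1 * m[k] + (1 - b1) * grad
                    v[k] = b2 * v[k] + (1 - b2) * grad * grad
                    mhat = m[k] / (1 - b1**step)
                    vhat = v[k] / (1 - b2**step)
                    param -= (lr * mhat / (np.sqrt(vhat) + eps)).astype(param.dtype)
                losses += loss * len(idx)
                hits += int(((p >= 0.5) == y[idx]).sum())
                seen += len(idx)
            history["loss"].append(losses / seen)
            history["accuracy"].append(hits / seen)
            if X_val is not None and y_val is not None:
                pv = self.predict_proba(X_val)
                eps_ = 1e-7
                pvc = np.clip(pv, eps_, 1 - eps_)
                yv = np.asarray(y_val, dtype=float)
                history["val_loss"].append(
                    float(-np.mean(yv * np.log(pvc) + (1 - yv) * np.log(1 - pvc)))
                )
                history["val_accuracy"].append(float(((pv >= 0.5) == yv).mean()))
        return history

    def predict_proba(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        Xs = self._standardize(X)
        out = []
        for s in range(0, len(Xs), batch_size):
            logits, _ = self._forward(Xs[s : s + batch_size], training=False)
            out.append(_sigmoid(logits))
        return np.concatenate(out).astype(float)

    # -- persistence ----------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Save weights (npz) and a JSON architecture mirror alongside."""
        path = Path(path)
        arrays: dict[str, np.ndarray] = {}
        for li, layer in enumerate(self._param_layers):
            for name, arr in layer.params.items():
                arrays[f"{li}:{name}"] = arr
        arrays["bn:running_mean"] = self.bn.running_mean
        arrays["bn:running_var"] = self.bn.running_var
        if self.channel_mean is not None:
            arrays["std:mean"] = self.channel_mean
            arrays["std:sd"] = self.channel_sd
        np.savez(path, **arrays)
        path.with_suffix(".json").write_text(
            json.dumps({"network_spec": dataclasses.asdict(self.spec), "seed": self.seed})
        )

    @classmethod
    def load(cls, path: str | Path) -> "DeepLSTMClassifier":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        model = cls(NetworkSpec(**meta["network_spec"]), seed=meta.get("seed", 0))
        with np.load(path if path.suffix else path.with_suffix(".npz")) as data:
            for li, layer in enumerate(model._param_layers):
                for name in layer.params:
                    layer.params[name][...] = data[f"{li}:{name}"]
            model.bn.running_mean[...] = data["bn:running_mean"]
            model.bn.running_var[...] = data["bn:running_var"]
            if "std:mean" in data:
                model.channel_mean = data["std:mean"]
                model.channel_sd = data["std:sd"]
        return model


def train(
    train_windows: tuple[np.ndarray, np.ndarray],
    val_windows: tuple[np.ndarray, np.ndarray] | None = None,
    spec: NetworkSpec | None = None,
    seed: int = 0,
    epochs: int = 20,
    batch_size: int = 64,
    lr: float = 1e-3,
) -> tuple[DeepLSTMClassifier, dict[str, list[float]]]:
    """Train the reference network on (X, y) window arrays."""
    model = DeepLSTMClassifier(spec, seed=seed)
    X, y = train_windows
    Xv, yv = val_windows if val_windows is not None else (None, None)
    history = model.fit(X, y, Xv, yv, epochs=epochs, batch_size=batch_size, lr=lr)
    return model, history


@dataclass
class RocResult:
    """ROC sweep: per-threshold operating points and trapezoidal area."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float

    def threshold_for_sensitivity(self, target_tpr: float) -> float:
        """Highest score cutoff whose sensitivity still reaches the target."""
        ok = np.flatnonzero(self.tpr >= target_tpr)
        if ok.size == 0:
            raise ValueError(f"no threshold reaches sensitivity {target_tpr}")
        return float(self.thresholds[ok[0]])

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"threshold": self.thresholds, "tpr": self.tpr, "fpr": self.fpr}
        ).to_csv(path, index=False)


def evaluate_roc(
    model: DeepLSTMClassifier | None,
    windows: tuple[np.ndarray, np.ndarray],
    scores: np.ndarray | None = None,
) -> RocResult:
    """ROC curve and area for a model (or precomputed scores) on windows."""
    X, y = windows
    if len(np.unique(y)) < 2:
        raise ValueError("ROC evaluation needs both classes present")
    if scores is None:
        if model is None:
            raise ValueError("either a model or scores must be given")
        scores = model.predict_proba(X)
    fpr, tpr, thresholds = skmetrics.roc_curve(y, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc)
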