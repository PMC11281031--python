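"""Hybrid neural network: CNN over one-hot SMILES merged with an FFNN.

A compact, dependency-free numpy implementation. The convolutional branch
reads the K x L x M one-hot tensor through ``conv -> relu -> maxpool``
blocks, flattens, and passes a dense layer; the descriptor branch z-scores
the mixture descriptors with training-fold statistics and passes two dense
layers; the concatenated representations feed a merged dense layer and a
task head (sigmoid / softmax / linear). Training is mini-batch Adam on the
matching loss (binary cross-entropy, categorical cross-entropy, MSE), fully
deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from mixtox.featurize import OneHotTensor, SmilesVocabulary
from mixtox.models.base import (
    N_TOX_CLASSES,
    PredictionSet,
    Task,
    labels_from_scores,
)

__all__ = ["HNNConfig", "HNNModel", "train_hnn"]


@dataclass
class HNNConfig:
    conv_filters: tuple[int, ...] = (32, 64)
    kernel: int = 3
    pool: int = 2
    smiles_dense: int = 64
    desc_dense: tuple[int, ...] = (128, 64)
    merge_units: int = 64
    task: Task = Task.BINARY
    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        self.task = Task(self.task)
        counts = (*self.conv_filters, self.kernel, self.pool,
                  self.smiles_dense, *self.desc_dense, self.merge_units,
                  self.epochs, self.batch_size)
        if any(c <= 0 for c in counts) or self.learning_rate <= 0:
            raise ValueError("all HNN size/optimizer settings must be positive")


# --- layers -----------------------------------------------------------------


class _Dense:
    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int):
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, scale, size=(n_in, n_out))
        self.b = np.zeros(n_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [(self.W, "dW"), (self.b, "db")]


class _Relu:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class _Conv1D:
    """Valid-padding 1-D convolution via im2col; input (N, T, C_in)."""

    def __init__(self, rng: np.random.Generator, c_in: int, c_out: int, k: int):
        self.k = k
        scale = np.sqrt(2.0 / (k * c_in))
        self.W = rng.normal(0.0, scale, size=(k * c_in, c_out))
        self.b = np.zeros(c_out)

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, t, c = x.shape
        t_out = t - self.k + 1
        cols = np.empty((n, t_out, self.k * c), dtype=x.dtype)
        for j in range(self.k):
            cols[:, :, j * c:(j + 1) * c] = x[:, j:j + t_out, :]
        return cols

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        self._cols = self._im2col(x.astype(float))
        return self._cols @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, t, c = self._shape
        t_out = t - self.k + 1
        self.dW = np.einsum("ntk,ntf->kf", self._cols, grad)
        self.db = grad.sum(axis=(0, 1))
        dx = np.zeros((n, t, c))
        dcols = grad @ self.W.T
        for j in range(self.k):
            dx[:, j:j + t_out, :] += dcols[:, :, j * c:(j + 1) * c]
        return dx

    def params(self):
        return [(self.W, "dW"), (self.b, "db")]


class _MaxPool1D:
    def __init__(self, width: int):
        self.width = width

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, t, c = x.shape
        t_out = t // self.width
        if t_out == 0:
            raise ValueError(
                f"sequence length {t} too short for pool width {self.width}"
            )
        self._trim = (n, t, c, t_out)
        xr = x[:, : t_out * self.width, :].reshape(n, t_out, self.width, c)
        self._arg = xr.argmax(axis=2)
        return xr.max(axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, t, c, t_out = self._trim
        dx = np.zeros((n, t_out, self.width, c))
        idx_n, idx_t, idx_c = np.ogrid[:n, :t_out, :c]
        dx[idx_n, idx_t, self._arg, idx_c] = grad
        dx = dx.reshape(n, t_out * self.width, c)
        if dx.shape[1] < t:
            dx = np.pad(dx, ((0, 0), (0, t - dx.shape[1]), (0, 0)))
        return dx


class _Adam:
    def __init__(self, layers, lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.slots = []
        for layer in layers:
            if hasattr(layer, "params"):
                for param, gname in layer.params():
                    self.slots.append(
                        [layer, param, gname,
                         np.zeros_like(param), np.zeros_like(param)]
                    )

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for slot in self.slots:
            layer, param, gname, m, v = slot
            g = getattr(layer, gname)
            m[:] = b1 * m + (1 - b1) * g
            v[:] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            param -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


# --- model ------------------------------------------------------------------


@dataclass
class _Manifest:
    """Feature-space contract frozen at fit time."""

    L: int
    M: int
    vocab_json: str
    descriptor_names: list[str] = field(default_factory=list)


class HNNModel:
    def __init__(self, cfg: HNNConfig):
        self.cfg = cfg
        self._built = False

    # -- construction

    def _build(self, L: int, M: int, n_desc: int) -> None:
        rng = np.random.default_rng(self.cfg.seed)
        cfg = self.cfg
        self.conv_layers: list = []
        c_in, t = M, L
        for f in cfg.conv_filters:
            if t - cfg.kernel + 1 < cfg.pool:
                break  # input too short for another block
            self.conv_layers += [
                _Conv1D(rng, c_in, f, cfg.kernel), _Relu(), _MaxPool1D(cfg.pool),
            ]
            t = (t - cfg.kernel + 1) // cfg.pool
            c_in = f
        self._flat = t * c_in
        self.smiles_dense = _Dense(rng, self._flat, cfg.smiles_dense)
        self.smiles_act = _Relu()
        self.desc_layers = []
        d_in = n_desc
        for units in cfg.desc_dense:
            self.desc_layers += [_Dense(rng, d_in, units), _Relu()]
            d_in = units
        self.merge = _Dense(rng, cfg.smiles_dense + d_in, cfg.merge_units)
        self.merge_act = _Relu()
        n_out = {Task.BINARY: 1, Task.MULTICLASS: N_TOX_CLASSES,
                 Task.REGRESSION: 1}[cfg.task]
        self.head = _Dense(rng, cfg.merge_units, n_out)
        self._all_layers = (
            self.conv_layers + [self.smiles_dense, self.smiles_act]
            + self.desc_layers + [self.merge, self.merge_act, self.head]
        )
        self._built = True

    # -- forward/backward

    def _forward(self, X_smiles: np.ndarray, X_desc: np.ndarray) -> np.ndarray:
        h = X_smiles.astype(float)
        for layer in self.conv_layers:
            h = layer.forward(h)
        h = h.reshape(h.shape[0], -1)
        h = self.smiles_act.forward(self.smiles_dense.forward(h))
        d = X_desc
        for layer in self.desc_layers:
            d = layer.forward(d)
        self._split = h.shape[1]
        z = self.merge_act.forward(self.merge.forward(np.hstack([h, d])))
        return self.head.forward(z)

    def _backward(self, grad: np.ndarray) -> None:
        g = self.head.backward(grad)
        g = self.merge.backward(self.merge_act.backward(g))
        gh, gd = g[:, : self._split], g[:, self._split:]
        for layer in reversed(self.desc_layers):
            gd = layer.backward(gd)
        gh = self.smiles_dense.backward(self.smiles_act.backward(gh))
        gh = gh.reshape(-1, *self._conv_out_shape)
        for layer in reversed(self.conv_layers):
            gh = layer.backward(gh)

    # -- training

    def fit(self, X_tensor: OneHotTensor, X_desc: np.ndarray, y: np.ndarray,
            mixture_ids=None, descriptor_names: list[str] | None = None) -> "HNNModel":
        X_desc = np.asarray(X_desc, dtype=float)
        y = np.asarray(y)
        if not (X_tensor.K == X_desc.shape[0] == y.shape[0]):
            raise ValueError(
                f"shape mismatch: tensor K={X_tensor.K}, "
                f"descriptors n={X_desc.shape[0]}, targets n={y.shape[0]}"
            )
        if not np.all(np.isfinite(X_desc)):
            raise ValueError("descriptors contain non-finite values; impute first")
        cfg = self.cfg
        self.manifest = _Manifest(
            L=X_tensor.L, M=X_tensor.M, vocab_json=X_tensor.vocab.to_json(),
            descriptor_names=list(descriptor_names or []),
        )
        # z-score the descriptor branch with training statistics
        self._mu = X_desc.mean(axis=0)
        sd = X_desc.std(axis=0)
        self._sd = np.where(sd > 0, sd, 1.0)
        Xd = (X_desc - self._mu) / self._sd
        self._build(X_tensor.L, X_tensor.M, Xd.shape[1])

        task = cfg.task
        if task is Task.MULTICLASS:
            Y = np.zeros((y.size, N_TOX_CLASSES))
            Y[np.arange(y.size), y.astype(int)] = 1.0
        else:
            Y = y.astype(float).reshape(-1, 1)

        # record the conv stack's output shape once for backprop reshaping
        probe = X_tensor.data[:1].astype(float)
        for layer in self.conv_layers:
            probe = layer.forward(probe)
        self._conv_out_shape = probe.shape[1:]

        opt = _Adam(self._all_layers, cfg.learning_rate)
        rng = np.random.default_rng(cfg.seed + 1)
        n = X_tensor.K
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                logits = self._forward(X_tensor.data[idx], Xd[idx])
                m = idx.size
                if task is Task.BINARY:
                    grad = (_sigmoid(logits) - Y[idx]) / m
                elif task is Task.MULTICLASS:
                    grad = (_softmax(logits) - Y[idx]) / m
                else:
                    grad = 2.0 * (logits - Y[idx]) / m
                self._backward(grad)
                opt.step()
        return self

    # -- inference

    def predict(self, X_tensor: OneHotTensor, X_desc: np.ndarray,
                mixture_ids=None) -> PredictionSet:
        if not self._built:
            raise RuntimeError("model is not trained")
        if X_tensor.L != self.manifest.L or X_tensor.M != self.manifest.M:
            raise ValueError(
                f"tensor shape (L={X_tensor.L}, M={X_tensor.M}) does not match "
                f"training (L={self.manifest.L}, M={self.manifest.M})"
            )
        if X_tensor.vocab.to_json() != self.manifest.vocab_json:
            raise ValueError("SMILES vocabulary differs from the fitted one")
        X_desc = np.asarray(X_desc, dtype=float)
        if X_desc.shape[1] != self._mu.size:
            raise ValueError(
                f"descriptor width {X_desc.shape[1]} != fitted {self._mu.size}"
            )
        Xd = (X_desc - self._mu) / self._sd
        logits = self._forward(X_tensor.data, Xd)
        task = self.cfg.task
        if task is Task.BINARY:
            scores = _sigmoid(logits).ravel()
        elif task is Task.MULTICLASS:
            scores = _softmax(logits)
        else:
            scores = logits.ravel()
        if mixture_ids is None:
            mixture_ids = np.arange(X_tensor.K)
        return PredictionSet(
            mixture_ids=np.asarray(mixture_ids), task=task,
            scores=scores, labels=labels_from_scores(task, scores),
        )

    # -- persistence

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        cfg = asdict(self.cfg)
        cfg["task"] = self.cfg.task.value
        (d / "config.json").write_text(json.dumps({
            "config": cfg,
            "manifest": asdict(self.manifest),
            "conv_out_shape": [int(x) for x in self._conv_out_shape],
        }))
        arrays = {"mu": self._mu, "sd": self._sd}
        for i, layer in enumerate(self._all_layers):
            if hasattr(layer, "params"):
                arrays[f"W{i}"] = layer.W
                arrays[f"b{i}"] = layer.b
        np.savez(d / "weights.npz", **arrays)

    @classmethod
    def load(cls, directory) -> "HNNModel":
        d = Path(directory)
        meta = json.loads((d / "config.json").read_text())
        model = cls(HNNConfig(**{
            **meta["config"],
            "conv_filters": tuple(meta["config"]["conv_filters"]),
            "desc_dense": tuple(meta["config"]["desc_dense"]),
        }))
        man = meta["manifest"]
        model.manifest = _Manifest(**man)
        arrays = np.load(d / "weights.npz")
        model._mu, model._sd = arrays["mu"], arrays["sd"]
        model._build(man["L"], man["M"], model._mu.size)
        for i, layer in enumerate(model._all_layers):
            if hasattr(layer, "params"):
                layer.W[:] = arrays[f"W{i}"]
                layer.b[:] = arrays[f"b{i}"]
        model._conv_out_shape = tuple(meta["conv_out_shape"])
        return model


def train_hnn(
    X_tensor: OneHotTensor,
    X_desc: np.ndarray,
    y: np.ndarray,
    cfg: HNNConfig,
    descriptor_names: list[str] | None = None,
) -> HNNModel:
    """Train the hybrid network; deterministic for a fixed ``cfg.seed``."""
    return HNNModel(cfg).fit(
        X_tensor, X_desc, y, descriptor_names=descriptor_names
    )
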