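"""A small 1-D convolutional network for raw RR windows, in plain numpy.

Architecture: two convolutional blocks, each of two width-2 convolutions
with 5 filters and ReLU activations followed by max-pooling (size 2) and
dropout, then one fully connected ReLU layer and a final fully connected
layer with a sigmoid unit.  Trained with the Adam optimizer at its
default parameters on the binary cross-entropy loss.  All randomness
(init, shuffling, dropout) flows from one seed, so training is exactly
reproducible.

The network is intentionally tiny — a few hundred weights — matching the
small number of labelled samples the classification task provides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CNNConfig", "NumpyCNN"]

N_FILTERS = 5
KERNEL_WIDTH = 2
POOL = 2


@dataclass(frozen=True)
class CNNConfig:
    dropout: float = 0.2
    hidden: int = 12
    epochs: int = 200
    batch_size: int = 32
    learning_rate: float = 1e-3
    early_stopping_patience: int = 20
    validation_fraction: float = 0.1


def _relu(x):
    return np.maximum(x, 0.0)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class _Conv1d:
    """Width-2 'valid' convolution over (batch, time, channels)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (KERNEL_WIDTH * c_in + c_out))  # Glorot
        self.w = rng.uniform(-limit, limit, (KERNEL_WIDTH, c_in, c_out))
        self.b = np.zeros(c_out)

    def forward(self, x):
        self.x = x
        z = x[:, :-1, :] @ self.w[0] + x[:, 1:, :] @ self.w[1] + self.b
        self.z = z
        return _relu(z)

    def backward(self, dout):
        dz = dout * (self.z > 0)
        x = self.x
        self.dw = np.stack(
            [
                np.einsum("bti,bto->io", x[:, :-1, :], dz),
                np.einsum("bti,bto->io", x[:, 1:, :], dz),
            ]
        )
        self.db = dz.sum(axis=(0, 1))
        dx = np.zeros_like(x)
        dx[:, :-1, :] += dz @ self.w[0].T
        dx[:, 1:, :] += dz @ self.w[1].T
        return dx

    def params(self):
        return [(self.w, "dw"), (self.b, "db")]


class _MaxPool:
    def forward(self, x):
        b, t, c = x.shape
        t2 = t // POOL
        if t2 < 1:
            raise ValueError("window shorter than the receptive field")
        xr = x[:, : t2 * POOL, :].reshape(b, t2, POOL, c)
        self.arg = xr.argmax(axis=2)
        self.in_shape = x.shape
        return xr.max(axis=2)

    def backward(self, dout):
        b, t2, c = dout.shape
        dx = np.zeros(self.in_shape)
        bi, ti, ci = np.meshgrid(
            np.arange(b), np.arange(t2), np.arange(c), indexing="ij"
        )
        dx[bi, ti * POOL + self.arg, ci] = dout
        return dx


class _Dropout:
    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng
        self.training = True

    def forward(self, x):
        if not self.training or self.rate == 0.0:
            return x
        self.mask = (
            self.rng.random(x.shape) >= self.rate
        ) / (1.0 - self.rate)
        return x * self.mask

    def backward(self, dout):
        if not self.training or self.rate == 0.0:
            return dout
        return dout * self.mask


class _Dense:
    def __init__(self, n_in, n_out, rng, relu: bool):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.w = rng.uniform(-limit, limit, (n_in, n_out))
        self.b = np.zeros(n_out)
        self.relu = relu

    def forward(self, x):
        self.x = x
        z = x @ self.w + self.b
        self.z = z
        return _relu(z) if self.relu else z

    def backward(self, dout):
        dz = dout * (self.z > 0) if self.relu else dout
        self.dw = self.x.T @ dz
        self.db = dz.sum(axis=0)
        return dz @ self.w.T

    def params(self):
        return [(self.w, "dw"), (self.b, "db")]


class NumpyCNN:
    """Binary classifier over fixed-length RR windows.

    ``fit`` expects ``X`` of shape (n_samples, window_length) in ms and
    binary labels ``y``; ``predict_proba``/``decision_function`` expose
    the sigmoid output for ROC computation.
    """

    def __init__(self, config: CNNConfig = CNNConfig(), seed: int = 0):
        self.config = config
        self.seed = seed
        self._built = False

    def _build(self, window_len: int):
        rng = np.random.default_rng(self.seed)
        cfg = self.config
        self.layers = []
        c_in = 1
        t = window_len
        for _ in range(2):  # two convolutional blocks
            self.layers.append(_Conv1d(c_in, N_FILTERS, rng))
            t -= 1
            self.layers.append(_Conv1d(N_FILTERS, N_FILTERS, rng))
            t -= 1
            if t // POOL < 1:
                raise ValueError("window shorter than the receptive field")
            self.layers.append(_MaxPool())
            t //= POOL
            self.layers.append(_Dropout(cfg.dropout, rng))
            c_in = N_FILTERS
        self.flat_dim = t * N_FILTERS
        self.fc1 = _Dense(self.flat_dim, cfg.hidden, rng, relu=True)
        self.fc2 = _Dense(cfg.hidden, 1, rng, relu=False)
        self._rng = rng
        self._adam_state = {}
        self._adam_t = 0
        self._built = True

    def n_parameters(self) -> int:
        total = 0
        for lay in self.layers + [self.fc1, self.fc2]:
            if hasattr(lay, "params"):
                total += sum(p.size for p, _ in lay.params())
        return total

    # -- forward / backward ------------------------------------------------
    def _forward(self, x, training: bool):
        h = x[:, :, None]
        for lay in self.layers:
            if isinstance(lay, _Dropout):
                lay.training = training
            h = lay.forward(h)
        h = h.reshape(h.shape[0], -1)
        h = self.fc1.forward(h)
        logits = self.fc2.forward(h)[:, 0]
        return logits

    def _backward(self, dlogits):
        d = self.fc2.backward(dlogits[:, None])
        d = self.fc1.backward(d)
        d = d.reshape(dlogits.shape[0], -1, N_FILTERS)
        for lay in reversed(self.layers):
            d = lay.backward(d)

    def _adam_step(self):
        cfg = self.config
        self._adam_t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        t = self._adam_t
        for li, lay in enumerate(self.layers + [self.fc1, self.fc2]):
            if not hasattr(lay, "params"):
                continue
            for pi, (p, gname) in enumerate(lay.params()):
                g = getattr(lay, gname)
                key = (li, pi)
                m, v = self._adam_state.get(key, (np.zeros_like(p),
                                                  np.zeros_like(p)))
                m = b1 * m + (1 - b1) * g
                v = b2 * v + (1 - b2) * g * g
                self._adam_state[key] = (m, v)
                mhat = m / (1 - b1**t)
                vhat = v / (1 - b2**t)
                p -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)

    # -- training ----------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "NumpyCNN":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be (n_samples, window_length)")
        # scale ms inputs to O(1) for stable optimisation
        self._loc = X.mean()
        self._scl = X.std() or 1.0
        Xs = (X - self._loc) / self._scl
        self._build(X.shape[1])
        cfg = self.config
        n = X.shape[0]
        n_val = int(round(cfg.validation_fraction * n))
        rng = self._rng
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        if tr_idx.size == 0:
            tr_idx, val_idx = perm, perm[:0]
        best_val, best_state, patience = np.inf, None, 0
        for _ in range(cfg.epochs):
            order = rng.permutation(tr_idx.size)
            for start in range(0, tr_idx.size, cfg.batch_size):
                idx = tr_idx[order[start: start + cfg.batch_size]]
                logits = self._forward(Xs[idx], training=True)
                prob = _sigmoid(logits)
                dlogits = (prob - y[idx]) / idx.size
                self._backward(dlogits)
                self._adam_step()
            if val_idx.size:
                vl = self._loss(Xs[val_idx], y[val_idx])
                if vl < best_val - 1e-6:
                    best_val, patience = vl, 0
                    best_state = self._snapshot()
                else:
                    patience += 1
                    if patience >= cfg.early_stopping_patience:
                        break
        if best_state is not None:
            self._restore(best_state)
        return self

    def _loss(self, Xs, y):
        p = _sigmoid(self._forward(Xs, training=False))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())

    def _snapshot(self):
        out = []
        for lay in self.layers + [self.fc1, self.fc2]:
            if hasattr(lay, "params"):
                out.append([p.copy() for p, _ in lay.params()])
            else:
                out.append(None)
        return out

    def _restore(self, state):
        for lay, saved in zip(self.layers + [self.fc1, self.fc2], state):
            if saved is not None:
                for (p, _), s in zip(lay.params(), saved):
                    p[...] = s

    # -- inference ---------------------------------------------------------
    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        Xs = (X - self._loc) / self._scl
        return _sigmoid(self._forward(Xs, training=False))

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)
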