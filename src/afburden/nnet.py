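"""A compact, dependency-free 1-D convolutional network with Adam training.

Implements exactly the layers the noise detector needs: 1-D convolution
(im2col matmul), ReLU, batch normalisation, max pooling (width 2, stride 2),
dense layers and a softmax cross-entropy head. Forward/backward passes are
float32 numpy; weight initialisation and minibatch order are driven by a
seeded generator, so training is deterministic.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-5


class Conv1D:
    """Valid-mode 1-D convolution, channels-first: (B, C_in, L) -> (B, C_out, L-k+1)."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * k))
        self.W = (rng.standard_normal((c_out, c_in, k)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        b, c, L = x.shape
        p = L - self.k + 1
        o = self.W.shape[0]
        if c * self.k <= 64:
            # few input channels: im2col is small, one GEMM beats the tap loop
            win = np.lib.stride_tricks.sliding_window_view(x, self.k, axis=2)
            col = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(
                b * p, c * self.k
            )
            y = (col @ self.W.reshape(o, -1).T).reshape(b, p, o)
            y = np.ascontiguousarray(y.transpose(0, 2, 1))
        else:
            # accumulate over kernel taps: y += W[:, :, j] @ x[:, :, j:j+P];
            # avoids the large im2col intermediate on long traces
            y = np.zeros((b, o, p), dtype=np.float32)
            for j in range(self.k):
                y += np.matmul(self.W[:, :, j], x[:, :, j : j + p])
        return y + self.b[None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        b, c, L = x.shape
        p = dy.shape[2]
        self.dW = np.empty_like(self.W)
        dx = np.zeros_like(x)
        for j in range(self.k):
            xs = x[:, :, j : j + p]
            self.dW[:, :, j] = np.tensordot(dy, xs, axes=([0, 2], [0, 2]))
            dx[:, :, j : j + p] += np.matmul(self.W[:, :, j].T, dy)
        self.db = dy.sum(axis=(0, 2)).astype(np.float32)
        return dx

    def params(self):
        return [("W", self), ("b", self)]


class ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask

    def params(self):
        return []


class BatchNorm1D:
    """Per-channel batch normalisation over batch and positions."""

    def __init__(self, c: int):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.run_mean = np.zeros(c, dtype=np.float32)
        self.run_var = np.ones(c, dtype=np.float32)
        self._n_updates = 0

    def forward(self, x, train: bool = True):
        axes = (0, 2) if x.ndim == 3 else (0,)
        shape = (1, -1, 1) if x.ndim == 3 else (1, -1)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            # cumulative average: robust for short training runs where an
            # exponential moving average would stay near its initial value
            self._n_updates += 1
            w = 1.0 / self._n_updates
            self.run_mean = (1 - w) * self.run_mean + w * mean
            self.run_var = (1 - w) * self.run_var + w * var
        else:
            scale = (self.gamma / np.sqrt(self.run_var + _EPS)).astype(np.float32)
            shift = (self.beta - self.run_mean * scale).astype(np.float32)
            return x * scale.reshape(shape) + shift.reshape(shape)
        self._shape = shape
        self._std = np.sqrt(var + _EPS).reshape(shape)
        self._xhat = (x - mean.reshape(shape)) / self._std
        self._n = x.size // x.shape[1]
        return self.gamma.reshape(shape) * self._xhat + self.beta.reshape(shape)

    def backward(self, dy):
        axes = (0, 2) if dy.ndim == 3 else (0,)
        shape = self._shape
        self.dgamma = (dy * self._xhat).sum(axis=axes).astype(np.float32)
        self.dbeta = dy.sum(axis=axes).astype(np.float32)
        g = self.gamma.reshape(shape)
        dxhat = dy * g
        n = self._n
        dx = (
            dxhat
            - dxhat.mean(axis=axes).reshape(shape)
            - self._xhat * (dxhat * self._xhat).mean(axis=axes).reshape(shape)
        ) / self._std
        return dx.astype(np.float32)

    def params(self):
        return [("gamma", self), ("beta", self)]


class MaxPool1D:
    """Width-2, stride-2 pooling; odd tails are truncated."""

    def forward(self, x):
        b, c, L = x.shape
        self._L = L
        L2 = L // 2
        xr = x[:, :, : 2 * L2].reshape(b, c, L2, 2)
        self._arg = xr.argmax(axis=3)
        return xr.max(axis=3)

    def backward(self, dy):
        b, c, L2 = dy.shape
        dx = np.zeros((b, c, self._L), dtype=np.float32)
        idx = 2 * np.arange(L2)[None, None, :] + self._arg
        bi = np.arange(b)[:, None, None]
        ci = np.arange(c)[None, :, None]
        np.add.at(dx, (bi, ci, idx), dy)
        return dx

    def params(self):
        return []


class Flatten:
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)

    def params(self):
        return []


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = (rng.standard_normal((n_in, n_out)) * scale).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW = (self._x.T @ dy).astype(np.float32)
        self.db = dy.sum(axis=0).astype(np.float32)
        return dy @ self.W.T

    def params(self):
        return [("W", self), ("b", self)]


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params  # list of (attr_name, layer)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(getattr(l, n)) for n, l in params]
        self.v = [np.zeros_like(getattr(l, n)) for n, l in params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, (name, layer) in enumerate(self.params):
            g = getattr(layer, "d" + name)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p = getattr(layer, name)
            setattr(layer, name, p - self.lr * mhat / (np.sqrt(vhat) + self.eps))


class SoftmaxClassifierNet:
    """A stack of layers ending in a linear logit layer + softmax."""

    def __init__(self, layers):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            if isinstance(layer, BatchNorm1D):
                x = layer.forward(x, train=train)
            else:
                x = layer.forward(x)
        return x  # logits

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def predict_proba(self, x: np.ndarray, batch: int = 64) -> np.ndarray:
        probs = []
        for i in range(0, len(x), batch):
            probs.append(softmax(self.forward(x[i : i + batch], train=False)))
        return np.concatenate(probs)

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        epochs: int,
        lr: float,
        batch_size: int,
        rng: np.random.Generator,
    ) -> list[float]:
        """Minimise softmax cross-entropy with Adam; returns per-epoch loss."""
        n = len(x)
        n_cls = int(y.max()) + 1
        opt = Adam(self.params(), lr=lr)
        losses = []
        for _ in range(epochs):
            order = rng.permutation(n)
            total = 0.0
            for i in range(0, n, batch_size):
                idx = order[i : i + batch_size]
                xb, yb = x[idx], y[idx]
                logits = self.forward(xb, train=True)
                p = softmax(logits)
                total += -float(
                    np.log(np.clip(p[np.arange(len(yb)), yb], 1e-12, None)).sum()
                )
                dlogits = p.copy()
                dlogits[np.arange(len(yb)), yb] -= 1.0
                dlogits /= len(yb)
                self.backward(dlogits.astype(np.float32))
                opt.step()
            losses.append(total / n)
        _ = n_cls
        return losses
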