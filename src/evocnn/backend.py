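"""Compact numpy CNN trainer.

Implements exactly the layer vocabulary of :class:`~evocnn.arch.ArchitectureSpec`
(conv with 'same' zero padding and stride 1, batch normalization, 2x2 max
pooling, flatten, dropout, dense, sigmoid output) with reverse-mode
gradients and Adam updates, in float32.  The convolution is computed as a
sum of k*k shifted matrix products, which is fast enough for the desk-scale
image sizes this package targets (tens of pixels per side).

Binary cross-entropy is optimized in logit form for numerical stability.
"""

from __future__ import annotations

import numpy as np

from .arch import ArchitectureSpec

__all__ = ["NumpyNet", "StandInBackbone", "BackendError"]


class BackendError(RuntimeError):
    """Shape mismatch or numerical failure during training."""


def _he_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class _Layer:
    params: dict
    grads: dict

    def __init__(self) -> None:
        self.params, self.grads = {}, {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class _Conv(_Layer):
    """Same-padded stride-1 convolution, kernel k, channels-last."""

    def __init__(self, c_in: int, filters: int, kernel: int, rng) -> None:
        super().__init__()
        self.k = kernel
        self.params = {
            "W": _he_init(rng, (kernel, kernel, c_in, filters), kernel * kernel * c_in),
            "b": np.zeros(filters, dtype=np.float32),
        }

    def forward(self, x, train):
        k = self.k
        pt, pb = (k - 1) // 2, k // 2
        xp = np.pad(x, ((0, 0), (pt, pb), (pt, pb), (0, 0)))
        self._xp, self._pt = xp, pt
        n, h, w, _ = x.shape
        W = self.params["W"]
        out = np.broadcast_to(self.params["b"], (n, h, w, W.shape[3])).copy()
        for i in range(k):
            for j in range(k):
                out += xp[:, i : i + h, j : j + w, :] @ W[i, j]
        return out

    def backward(self, dout):
        k, pt = self.k, self._pt
        xp = self._xp
        n, h, w, f = dout.shape
        W = self.params["W"]
        dW = np.empty_like(W)
        dxp = np.zeros_like(xp)
        dflat = dout.reshape(-1, f)
        for i in range(k):
            for j in range(k):
                patch = xp[:, i : i + h, j : j + w, :].reshape(-1, W.shape[2])
                dW[i, j] = patch.T @ dflat
                dxp[:, i : i + h, j : j + w, :] += dout @ W[i, j].T
        self.grads = {"W": dW, "b": dout.sum(axis=(0, 1, 2))}
        self._xp = None
        return dxp[:, pt : pt + h, pt : pt + w, :]


class _BatchNorm(_Layer):
    """Per-channel normalization over (N, H, W) with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params = {
            "gamma": np.ones(channels, dtype=np.float32),
            "beta": np.zeros(channels, dtype=np.float32),
        }
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x, train):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(np.float32)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * ivar
        if train:
            self._cache = (xhat, ivar, x.shape, axes)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dout):
        xhat, ivar, shape, axes = self._cache
        m = np.prod([shape[a] for a in axes])
        dgamma = (dout * xhat).sum(axis=axes)
        dbeta = dout.sum(axis=axes)
        self.grads = {"gamma": dgamma, "beta": dbeta}
        g = self.params["gamma"] * ivar / m
        dx = g * (m * dout - dbeta - xhat * dgamma)
        self._cache = None
        return dx.astype(np.float32)


class _ReLU(_Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class _MaxPool(_Layer):
    """2x2, stride 2; odd trailing rows/columns are dropped."""

    def forward(self, x, train):
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        xr = (
            x[:, : 2 * h2, : 2 * w2, :]
            .reshape(n, h2, 2, w2, 2, c)
            .transpose(0, 1, 3, 5, 2, 4)
            .reshape(n, h2, w2, c, 4)
        )
        self._idx = xr.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        n, h, w, c = self._in_shape
        h2, w2 = h // 2, w // 2
        dxr = np.zeros((n, h2, w2, c, 4), dtype=dout.dtype)
        np.put_along_axis(dxr, self._idx[..., None], dout[..., None], axis=-1)
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        dx[:, : 2 * h2, : 2 * w2, :] = (
            dxr.reshape(n, h2, w2, c, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(n, 2 * h2, 2 * w2, c)
        )
        return dx


class _Flatten(_Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class _Dropout(_Layer):
    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        self.rate, self.rng = rate, rng

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate).astype(np.float32) / (
            1.0 - self.rate
        )
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class _Dense(_Layer):
    def __init__(self, d_in: int, units: int, rng) -> None:
        super().__init__()
        self.params = {
            "W": _he_init(rng, (d_in, units), d_in),
            "b": np.zeros(units, dtype=np.float32),
        }

    def forward(self, x, train):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads = {"W": self._x.T @ dout, "b": dout.sum(axis=0)}
        dx = dout @ self.params["W"].T
        self._x = None
        return dx


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class NumpyNet:
    """A trainable network instantiated from an :class:`ArchitectureSpec`."""

    def __init__(self, spec: ArchitectureSpec, seed: int = 0) -> None:
        self.spec = spec
        self.rng = np.random.default_rng(seed)
        self.layers: list[_Layer] = []
        if spec.frozen_backbone:
            c = int(spec.feature_dim)
            h = w = 1
        else:
            h, w, c = spec.input_shape
        flat = None
        for layer in spec.layers:
            kind, p = layer.kind, layer.params
            if kind == "conv":
                self.layers.append(_Conv(c, p["filters"], p["kernel"], self.rng))
                c = p["filters"]
                if p.get("activation") == "relu":
                    pass  # relu applied after batch_norm; see below
            elif kind == "batch_norm":
                self.layers.append(_BatchNorm(c))
                self.layers.append(_ReLU())
            elif kind == "max_pool":
                self.layers.append(_MaxPool())
                h, w = h // 2, w // 2
                if h < 1 or w < 1:
                    raise BackendError("pooling drove a spatial dimension below 1")
            elif kind == "flatten":
                self.layers.append(_Flatten())
                flat = h * w * c
            elif kind == "dropout":
                self.layers.append(_Dropout(p["rate"], self.rng))
            elif kind == "dense":
                if flat is None:
                    raise BackendError("dense before flatten")
                self.layers.append(_Dense(flat, p["units"], self.rng))
                self.layers.append(_ReLU())
                flat = p["units"]
            elif kind == "output":
                if flat is None:
                    raise BackendError("output before flatten")
                self.layers.append(_Dense(flat, p["units"], self.rng))
                flat = p["units"]
            else:
                raise BackendError(f"unknown layer kind {kind!r}")
        # Adam state
        self._adam_m: list[dict] = [
            {k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers
        ]
        self._adam_v: list[dict] = [
            {k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers
        ]
        self._adam_t = 0

    # -- inference ---------------------------------------------------------

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if self.spec.frozen_backbone:
            if X.ndim != 2 or X.shape[1] != self.spec.feature_dim:
                raise BackendError(
                    f"expected (N, {self.spec.feature_dim}) features, got {X.shape}"
                )
            return X.reshape(X.shape[0], 1, 1, -1)
        if X.ndim == 3:
            X = X[..., None]
        if X.ndim != 4 or X.shape[1:] != tuple(self.spec.input_shape):
            raise BackendError(
                f"expected input shape {self.spec.input_shape}, got {X.shape[1:]}"
            )
        return X

    def forward_logits(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        out = self._prepare(X)
        for layer in self.layers:
            out = layer.forward(out, train)
        return out.reshape(-1)

    def predict_proba(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        probs = []
        for start in range(0, len(X), batch_size):
            z = self.forward_logits(X[start : start + batch_size], train=False)
            probs.append(_sigmoid(z))
        return np.concatenate(probs) if probs else np.empty(0)

    # -- training ----------------------------------------------------------

    def _adam_step(self, lr: float, b1=0.9, b2=0.999, eps=1e-8) -> None:
        self._adam_t += 1
        t = self._adam_t
        for layer, m, v in zip(self.layers, self._adam_m, self._adam_v):
            for key, param in layer.params.items():
                g = layer.grads[key].astype(np.float32)
                m[key] = b1 * m[key] + (1 - b1) * g
                v[key] = b2 * v[key] + (1 - b2) * g * g
                mhat = m[key] / (1 - b1**t)
                vhat = v[key] / (1 - b2**t)
                param -= lr * mhat / (np.sqrt(vhat) + eps)

    def train_batch(self, X: np.ndarray, y: np.ndarray, lr: float) -> float:
        z = self.forward_logits(X, train=True)
        y = np.asarray(y, dtype=np.float32)
        # stable BCE-with-logits: softplus(z) - y*z
        loss = float(np.mean(np.logaddexp(0.0, z) - y * z))
        if not np.isfinite(loss):
            raise BackendError("non-finite training loss")
        dz = ((_sigmoid(z) - y) / len(y)).astype(np.float32).reshape(-1, 1)
        dout = dz
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        self._adam_step(lr)
        return loss

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        epochs: int,
        batch_size: int,
        learning_rate: float,
        shuffle_rng: np.random.Generator | None = None,
    ) -> list[float]:
        """Minimize BCE for the budget; returns mean loss per epoch."""
        rng = shuffle_rng if shuffle_rng is not None else self.rng
        n = len(X)
        if n == 0:
            raise BackendError("empty training set")
        losses = []
        for _ in range(epochs):
            order = rng.permutation(n)
            batch_losses = []
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                batch_losses.append(self.train_batch(X[idx], y[idx], learning_rate))
            losses.append(float(np.mean(batch_losses)))
        return losses


class StandInBackbone:
    """Synthetic frozen feature extractor (stand-in for a pretrained
    convolutional backbone).

    A fixed, seeded two-stage random convolutional network: conv(8, 3x3) ->
    relu -> 2x2 pool -> conv(16, 3x3) -> relu -> 2x2 pool -> flatten.  Its
    weights are never trained; it exists so the dense-head search can run
    without downloading pretrained weights.
    """

    def __init__(self, input_shape: tuple[int, int, int], seed: int = 7) -> None:
        rng = np.random.default_rng(seed)
        h, w, c = input_shape
        if min(h, w) < 4:
            raise BackendError("backbone needs at least 4 pixels per side")
        self.input_shape = input_shape
        self._layers = [
            _Conv(c, 8, 3, rng), _ReLU(), _MaxPool(),
            _Conv(8, 16, 3, rng), _ReLU(), _MaxPool(),
            _Flatten(),
        ]
        self.feature_dim = (h // 4) * (w // 4) * 16

    def transform(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 3:
            X = X[..., None]
        feats = []
        for start in range(0, len(X), batch_size):
            out = X[start : start + batch_size]
            for layer in self._layers:
                out = layer.forward(out, train=False)
            feats.append(out)
        return np.concatenate(feats) if feats else np.empty((0, self.feature_dim))
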