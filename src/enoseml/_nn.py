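"""Minimal numpy neural-network layers with explicit backpropagation.

Implements exactly the pieces the residual backbone needs — im2col
convolution, batch normalization, ReLU, max pooling, global average pooling,
a linear head, softmax cross-entropy and Adam — in float32, CPU-only,
fully deterministic given a seeded ``numpy.random.Generator``.

Every layer follows the same protocol: ``forward(x, train)`` caches what the
backward pass needs, ``backward(dout)`` returns the gradient with respect to
the input and fills the layer's ``grads`` dict (keyed like ``params``).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "GlobalAvgPool",
    "Linear",
    "softmax_cross_entropy",
    "Adam",
]

DTYPE = np.float32


def _out_size(n: int, k: int, s: int, p: int) -> int:
    return (n + 2 * p - k) // s + 1


def _window_view(xp: np.ndarray, kh: int, kw: int, s: int) -> np.ndarray:
    """Strided (N, C, OH, OW, kh, kw) view of a padded (N, C, H, W) array."""
    n, c, h, w = xp.shape
    oh = (h - kh) // s + 1
    ow = (w - kw) // s + 1
    sn, sc, sh, sw = xp.strides
    return np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, c, oh, ow, kh, kw),
        strides=(sn, sc, sh * s, sw * s, sh, sw),
        writeable=False,
    )


class Conv2d:
    """2-D convolution (cross-correlation), no bias — batch norm follows."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        stride: int,
        padding: int,
        rng: np.random.Generator,
    ) -> None:
        self.cin, self.cout = in_channels, out_channels
        self.k, self.s, self.p = kernel, stride, padding
        fan_in = in_channels * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_channels, fan_in))
        self.params = {"W": w.astype(DTYPE)}
        self.grads = {"W": np.zeros_like(self.params["W"])}
        self._cache: tuple | None = None

    def out_shape(self, h: int, w: int) -> tuple[int, int]:
        return _out_size(h, self.k, self.s, self.p), _out_size(w, self.k, self.s, self.p)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        p, k, s = self.p, self.k, self.s
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        view = _window_view(xp, k, k, s)
        n_, _, oh, ow, _, _ = view.shape
        cols = np.ascontiguousarray(view.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * oh * ow, c * k * k
        )
        out = cols @ self.params["W"].T  # (N*OH*OW, Cout)
        out = out.reshape(n, oh, ow, self.cout).transpose(0, 3, 1, 2)
        if train:
            self._cache = (cols, x.shape, oh, ow)
        return np.ascontiguousarray(out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, xshape, oh, ow = self._cache
        n, c, h, w = xshape
        k, s, p = self.k, self.s, self.p
        dcols_flat = dout.transpose(0, 2, 3, 1).reshape(-1, self.cout)
        self.grads["W"][...] = dcols_flat.T @ cols
        dcols = (dcols_flat @ self.params["W"]).reshape(n, oh, ow, c, k, k)
        hp, wp = h + 2 * p, w + 2 * p
        dxp = np.zeros((n, c, hp, wp), dtype=DTYPE)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * oh : s, j : j + s * ow : s] += dcols[
                    :, :, :, :, i, j
                ].transpose(0, 3, 1, 2)
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class BatchNorm2d:
    """Per-channel batch normalization with running statistics for eval."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        self.eps = eps
        self.momentum = momentum
        self.params = {
            "gamma": np.ones(channels, dtype=DTYPE),
            "beta": np.zeros(channels, dtype=DTYPE),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self._cache: tuple | None = None
        self._collect: list | None = None

    def start_stat_collection(self) -> None:
        """Begin accumulating exact population statistics (see ``finalize``)."""
        self._collect = []

    def finalize_stat_collection(self) -> None:
        """Replace running stats with the population statistics of the
        collected batches (law of total variance across batches)."""
        if not self._collect:
            self._collect = None
            return
        w = np.array([m for _, _, m in self._collect], dtype=np.float64)
        mus = np.stack([mu for mu, _, _ in self._collect]).astype(np.float64)
        vars_ = np.stack([v for _, v, _ in self._collect]).astype(np.float64)
        wn = w[:, None] / w.sum()
        mean = (wn * mus).sum(axis=0)
        var = (wn * (vars_ + mus**2)).sum(axis=0) - mean**2
        self.running_mean = mean.astype(DTYPE)
        self.running_var = np.maximum(var, 0.0).astype(DTYPE)
        self._collect = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        g = self.params["gamma"][None, :, None, None]
        b = self.params["beta"][None, :, None, None]
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            if self._collect is not None:
                self._collect.append((mu, var, x.shape[0] * x.shape[2] * x.shape[3]))
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mu[None, :, None, None]) * inv[None, :, None, None]
            self._cache = (xhat, inv)
            return (g * xhat + b).astype(DTYPE)
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        xhat = (x - self.running_mean[None, :, None, None]) * inv[None, :, None, None]
        return (g * xhat + b).astype(DTYPE)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.grads["gamma"][...] = (dout * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"][...] = dout.sum(axis=(0, 2, 3))
        g = self.params["gamma"][None, :, None, None]
        dxhat = dout * g
        sum_dxhat = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = (inv[None, :, None, None] / m) * (
            m * dxhat - sum_dxhat - xhat * sum_dxhat_xhat
        )
        return dx.astype(DTYPE)


class ReLU:
    params: dict = {}
    grads: dict = {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2d:
    params: dict = {}
    grads: dict = {}

    def __init__(self, kernel: int, stride: int, padding: int) -> None:
        self.k, self.s, self.p = kernel, stride, padding

    def out_shape(self, h: int, w: int) -> tuple[int, int]:
        return _out_size(h, self.k, self.s, self.p), _out_size(w, self.k, self.s, self.p)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        k, s, p = self.k, self.s, self.p
        xp = (
            np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
            if p
            else x
        )
        view = _window_view(xp, k, k, s)  # (N, C, OH, OW, k, k)
        n, c, oh, ow, _, _ = view.shape
        flat = view.reshape(n, c, oh, ow, k * k)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, x.shape, oh, ow)
        return np.ascontiguousarray(out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        idx, xshape, oh, ow = self._cache
        n, c, h, w = xshape
        k, s, p = self.k, self.s, self.p
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=DTYPE)
        for i in range(k):
            for j in range(k):
                mask = idx == (i * k + j)
                dxp[:, :, i : i + s * oh : s, j : j + s * ow : s] += dout * mask
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class GlobalAvgPool:
    params: dict = {}
    grads: dict = {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(
            (dout / (h * w))[:, :, None, None], self._shape
        ).astype(DTYPE)


class Linear:
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator) -> None:
        w = rng.normal(0.0, np.sqrt(2.0 / in_dim), size=(out_dim, in_dim))
        self.params = {"W": w.astype(DTYPE), "b": np.zeros(out_dim, dtype=DTYPE)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"][...] = dout.T @ self._x
        self.grads["b"][...] = dout.sum(axis=0)
        return dout @ self.params["W"]


def softmax_cross_entropy(
    logits: np.ndarray, targets: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over a batch and its gradient w.r.t. the logits.

    ``targets`` are integer class indices.
    """
    z = logits - logits.max(axis=1, keepdims=True)
    expz = np.exp(z)
    probs = expz / expz.sum(axis=1, keepdims=True)
    n = len(targets)
    loss = float(-np.log(probs[np.arange(n), targets] + 1e-12).mean())
    dlogits = probs.copy()
    dlogits[np.arange(n), targets] -= 1.0
    return loss, (dlogits / n).astype(DTYPE)


class Adam:
    """Adam over the parameters of a list of layers."""

    def __init__(
        self,
        layers: list,
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        self.layers = [l for l in layers if l.params]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [
            {k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers
        ]
        self._v = [
            {k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers
        ]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for layer, m, v in zip(self.layers, self._m, self._v):
            for key, param in layer.params.items():
                g = layer.grads[key]
                m[key] += (1.0 - self.b1) * (g - m[key])
                v[key] += (1.0 - self.b2) * (g * g - v[key])
                mhat = m[key] / bc1
                vhat = v[key] / bc2
                param -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                    param.dtype
                )
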