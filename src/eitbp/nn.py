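"""A small, fully seeded numpy neural-network engine.

Implements exactly the pieces the pressure regressor needs — strided 2-D
convolution (im2col + GEMM), batch normalization, ReLU, flatten, a dense
head, mean-squared-error loss and Adam — with explicit backprop.  Arrays
are float32 by default (float64 available for gradient checking).  All
randomness comes from a caller-supplied generator, so training runs are
bit-reproducible on a given machine.

Layout convention: activations are (N, H, W, C).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2D",
    "BatchNorm",
    "ReLU",
    "Flatten",
    "Dense",
    "Network",
    "Adam",
    "mse_loss",
]


def _same_pad(n: int, k: int, s: int) -> tuple[int, int, int]:
    """TensorFlow-style 'same' padding: output ceil(n/s)."""
    out = -(-n // s)
    total = max((out - 1) * s + k - n, 0)
    return out, total // 2, total - total // 2


class Layer:
    trainable: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]

    def __init__(self) -> None:
        self.trainable = {}
        self.grads = {}

    #: set by Network on its first layer: the input gradient is never
    #: consumed there, so conv layers may skip the costly col2im scatter
    is_first = False

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_params(self) -> tuple[int, int]:
        """(trainable, non-trainable) parameter counts."""
        return sum(v.size for v in self.trainable.values()), 0


class Conv2D(Layer):
    """Strided 2-D convolution with 'same' or 'valid' padding."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: tuple[int, int],
        stride: tuple[int, int] = (1, 1),
        padding: str = "same",
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        kh, kw = kernel
        fan_in = kh * kw * c_in
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(kh, kw, c_in, c_out))
        self.trainable = {
            "w": w.astype(dtype),
            "b": np.zeros(c_out, dtype=dtype),
        }
        self.kernel = kernel
        self.stride = stride
        self.padding = padding
        self.dtype = dtype

    def _im2col(self, x: np.ndarray):
        kh, kw = self.kernel
        sh, sw = self.stride
        n, h, w_, c = x.shape
        if self.padding == "same":
            ho, pt, pb = _same_pad(h, kh, sh)
            wo, pl, pr = _same_pad(w_, kw, sw)
            xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        elif self.padding == "valid":
            ho = (h - kh) // sh + 1
            wo = (w_ - kw) // sw + 1
            pt = pl = 0
            xp = x
        else:
            raise ValueError(f"unknown padding {self.padding!r}")
        if kw == 1 and xp.shape[2] == 1:
            # frames-only convolution: fill per kernel offset, contiguous
            # channel runs (much faster than the generic gather)
            cols = np.empty((n, ho, kh, c), dtype=xp.dtype)
            for a in range(kh):
                cols[:, :, a, :] = xp[:, a : a + sh * ho : sh, 0, :]
            return cols.reshape(n * ho, kh * c), (n, ho, 1, xp.shape), (pt, pl)
        win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
        win = win[:, ::sh, ::sw]  # (n, ho, wo, c, kh, kw)
        cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
            n * ho * wo, kh * kw * c
        )
        return cols, (n, ho, wo, xp.shape), (pt, pl)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        x = x.astype(self.dtype, copy=False)
        cols, (n, ho, wo, xp_shape), pads = self._im2col(x)
        w = self.trainable["w"]
        c_out = w.shape[-1]
        y = cols @ w.reshape(-1, c_out) + self.trainable["b"]
        self._cache = (cols, x.shape, xp_shape, pads, (n, ho, wo))
        return y.reshape(n, ho, wo, c_out)

    def out_spatial(self, h: int, w_: int) -> tuple[int, int]:
        kh, kw = self.kernel
        sh, sw = self.stride
        if self.padding == "same":
            return -(-h // sh), -(-w_ // sw)
        return (h - kh) // sh + 1, (w_ - kw) // sw + 1

    def precompute_cols(self, x: np.ndarray, chunk: int = 256) -> np.ndarray:
        """im2col of a fixed input set, shape (n, patches, k*k*c).

        Useful for a first layer whose input never changes across epochs:
        the column matrix is built once and :meth:`forward_from_cols`
        replaces the per-step gather with a plain GEMM.
        """
        x = x.astype(self.dtype, copy=False)
        out = None
        for i in range(0, len(x), chunk):
            cols, (n, ho, wo, _), _ = self._im2col(x[i : i + chunk])
            if out is None:
                out = np.empty(
                    (len(x), ho * wo, cols.shape[1]), dtype=self.dtype
                )
            out[i : i + chunk] = cols.reshape(n, ho * wo, -1)
        return out

    def forward_from_cols(
        self, cols: np.ndarray, out_spatial: tuple[int, int]
    ) -> np.ndarray:
        """Forward from precomputed per-sample columns (n, patches, k)."""
        n = len(cols)
        ho, wo = out_spatial
        flat = cols.reshape(n * ho * wo, -1)
        w = self.trainable["w"]
        c_out = w.shape[-1]
        y = flat @ w.reshape(-1, c_out) + self.trainable["b"]
        self._cache = (flat, None, None, (0, 0), (n, ho, wo))
        return y.reshape(n, ho, wo, c_out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, x_shape, xp_shape, (pt, pl), (n, ho, wo) = self._cache
        kh, kw = self.kernel
        sh, sw = self.stride
        w = self.trainable["w"]
        c_in, c_out = w.shape[2], w.shape[3]
        dy_flat = dy.reshape(n * ho * wo, c_out).astype(self.dtype, copy=False)
        self.grads["w"] = (cols.T @ dy_flat).reshape(w.shape)
        self.grads["b"] = dy_flat.sum(axis=0)
        if self.is_first or xp_shape is None:
            return None  # input gradient unused at the first layer
        dcols = (dy_flat @ w.reshape(-1, c_out).T).reshape(
            n, ho, wo, kh, kw, c_in
        )
        dxp = np.zeros(xp_shape, dtype=self.dtype)
        for i in range(kh):
            for j in range(kw):
                dxp[:, i : i + sh * ho : sh, j : j + sw * wo : sw, :] += dcols[
                    :, :, :, i, j, :
                ]
        h, w_ = x_shape[1], x_shape[2]
        return dxp[:, pt : pt + h, pl : pl + w_, :]


class BatchNorm(Layer):
    """Per-channel batch normalization over (N, H, W)."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        self.trainable = {
            "gamma": np.ones(c, dtype=dtype),
            "beta": np.zeros(c, dtype=dtype),
        }
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(self.running_mean.dtype)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(self.running_var.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv, x.shape, axes, train)
        return self.trainable["gamma"] * xhat + self.trainable["beta"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, shape, axes, train = self._cache
        m = np.prod([shape[a] for a in axes])
        self.grads["gamma"] = (dy * xhat).sum(axis=axes)
        self.grads["beta"] = dy.sum(axis=axes)
        g = self.trainable["gamma"]
        if not train:
            return dy * g * inv
        dxhat = dy * g
        return (
            inv
            / m
            * (
                m * dxhat
                - dxhat.sum(axis=axes)
                - xhat * (dxhat * xhat).sum(axis=axes)
            )
        )

    def n_params(self) -> tuple[int, int]:
        t = sum(v.size for v in self.trainable.values())
        return t, self.running_mean.size + self.running_var.size


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(
        self,
        n_in: int,
        n_out: int,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        lim = np.sqrt(6.0 / (n_in + n_out))
        self.trainable = {
            "w": rng.uniform(-lim, lim, size=(n_in, n_out)).astype(dtype),
            "b": np.zeros(n_out, dtype=dtype),
        }

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.trainable["w"] + self.trainable["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["w"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.trainable["w"].T


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over all entries and its gradient."""
    diff = pred - target
    loss = float(np.mean(diff**2))
    return loss, (2.0 / diff.size) * diff


class Network:
    """A plain sequential network."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers
        if layers:
            layers[0].is_first = True

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def parameters(self):
        """Yield (layer_index, name, array) for all trainable parameters."""
        for i, layer in enumerate(self.layers):
            for name, value in layer.trainable.items():
                yield i, name, value

    def n_params(self) -> tuple[int, int]:
        """(total, trainable) parameter counts including BN statistics."""
        trainable = nontrainable = 0
        for layer in self.layers:
            t, nt = layer.n_params()
            trainable += t
            nontrainable += nt
        return trainable + nontrainable, trainable

    def get_state(self) -> list[dict]:
        state = []
        for layer in self.layers:
            d = {k: v.copy() for k, v in layer.trainable.items()}
            if isinstance(layer, BatchNorm):
                d["_running_mean"] = layer.running_mean.copy()
                d["_running_var"] = layer.running_var.copy()
            state.append(d)
        return state

    def set_state(self, state: list[dict]) -> None:
        for layer, d in zip(self.layers, state):
            for k in layer.trainable:
                layer.trainable[k][...] = d[k]
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = d["_running_mean"]
                layer.running_var[...] = d["_running_var"]


class Adam:
    """Adam optimizer over a network's trainable parameters."""

    def __init__(
        self,
        net: Network,
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.net = net
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {
            (i, n): np.zeros_like(v, dtype=np.float64)
            for i, n, v in net.parameters()
        }
        self.v = {
            (i, n): np.zeros_like(v, dtype=np.float64)
            for i, n, v in net.parameters()
        }

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, name, value in self.net.parameters():
            g = self.net.layers[i].grads[name].astype(np.float64)
            key = (i, name)
            self.m[key] = b1 * self.m[key] + (1 - b1) * g
            self.v[key] = b2 * self.v[key] + (1 - b2) * g * g
            mhat = self.m[key] / (1 - b1**self.t)
            vhat = self.v[key] / (1 - b2**self.t)
            value -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                value.dtype
            )
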