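"""Minimal CNN building blocks on numpy arrays.

All layers operate on float32 NHWC tensors. Convolutions run as one im2col
matrix product per pass so the heavy lifting is a single BLAS GEMM call.

Every layer owns persistent workspace buffers, reused across steps and keyed
by input shape: on a single-CPU box the first-touch page faults of fresh
multi-hundred-MB temporaries otherwise dominate the arithmetic.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base class: parameters and gradients live in parallel dicts."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self._bufs: dict[tuple, np.ndarray] = {}

    def _buf(self, name: str, shape: tuple, dtype=np.float32) -> np.ndarray:
        """Persistent workspace view: one growable flat array per name, so
        batches of different sizes share the same memory."""
        key = (name, np.dtype(dtype).str)
        size = int(np.prod(shape))
        flat = self._bufs.get(key)
        if flat is None or flat.size < size:
            flat = np.empty(size, dtype=dtype)
            self._bufs[key] = flat
        return flat[:size].reshape(shape)

    def release_buffers(self) -> None:
        self._bufs.clear()

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    @property
    def weight_decay_keys(self) -> tuple[str, ...]:
        """Parameter names subject to L2 regularization."""
        return ()


class Conv2D(Layer):
    """Same-padded 2-D convolution with an odd square kernel, stride 1.

    Weights are stored (k, k, c_in, c_out); He-normal initialised. Set
    ``first_layer=True`` to skip the (unused) input-gradient computation.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        rng: np.random.Generator,
        first_layer: bool = False,
    ):
        super().__init__()
        if kernel % 2 != 1 or kernel < 1:
            raise ValueError(f"kernel size must be odd and positive, got {kernel}")
        self.k = kernel
        self.c_in = c_in
        self.c_out = c_out
        self.first_layer = first_layer
        fan_in = kernel * kernel * c_in
        scale = np.sqrt(2.0 / fan_in)
        self.params["W"] = rng.normal(0.0, scale, (kernel, kernel, c_in, c_out)).astype(
            np.float32
        )
        self.params["b"] = np.zeros(c_out, dtype=np.float32)
        self._cache: tuple | None = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        """(n, h, w, c) -> (n*h*w, k*k*c) window matrix, same padding."""
        k, p = self.k, self.k // 2
        n, h, w, c = x.shape
        xpad = self._buf("xpad", (n, h + 2 * p, w + 2 * p, c))
        if p:
            xpad[:, :p, :, :] = 0
            xpad[:, -p:, :, :] = 0
            xpad[:, :, :p, :] = 0
            xpad[:, :, -p:, :] = 0
        xpad[:, p : p + h, p : p + w, :] = x
        xcol = self._buf("xcol", (n, h, w, k * k, c))
        for di in range(k):
            for dj in range(k):
                xcol[:, :, :, di * k + dj, :] = xpad[:, di : di + h, dj : dj + w, :]
        return xcol.reshape(n * h * w, k * k * c)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, _ = x.shape
        xcol = self._im2col(x)
        Wmat = self.params["W"].reshape(-1, self.c_out)
        y = self._buf("y", (n * h * w, self.c_out))
        np.matmul(xcol, Wmat, out=y)
        y += self.params["b"]
        self._cache = (xcol, (n, h, w)) if train else None
        return y.reshape(n, h, w, self.c_out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._cache is not None, "backward before training-mode forward"
        xcol, (n, h, w) = self._cache
        k, p = self.k, self.k // 2
        c_in, c_out = self.c_in, self.c_out
        dy2 = np.ascontiguousarray(dy).reshape(-1, c_out)
        self.grads["W"] = (xcol.T @ dy2).reshape(self.params["W"].shape)
        self.grads["b"] = dy2.sum(axis=0)
        self._cache = None
        if self.first_layer:
            return dy  # upstream gradient unused
        # input gradient via k*k thin GEMMs into a small reused temp: avoids
        # materialising a second (n*h*w, k*k*c_in) matrix alongside xcol
        W = self.params["W"]
        dtmp = self._buf("dtmp", (n * h * w, c_in))
        dxpad = self._buf("dxpad", (n, h + 2 * p, w + 2 * p, c_in))
        dxpad[:] = 0
        for di in range(k):
            for dj in range(k):
                np.matmul(dy2, W[di, dj].T, out=dtmp)
                dxpad[:, di : di + h, dj : dj + w, :] += dtmp.reshape(n, h, w, c_in)
        dx = self._buf("dx", (n, h, w, c_in))
        np.copyto(dx, dxpad[:, p : p + h, p : p + w, :])
        return dx

    @property
    def weight_decay_keys(self) -> tuple[str, ...]:
        return ("W",)


class BatchNorm(Layer):
    """Per-channel batch normalization over (N, H, W) with running statistics.

    The running-statistics momentum is deliberately low (0.6): corpora here
    are small enough that an epoch is only a handful of mini-batches, and a
    slower-moving average would leave inference statistics stale for many
    epochs. For a final model, population statistics should be recomputed
    over the training set (``SequentialCNN.finalize_batchnorm``).
    """

    def __init__(self, c: int, momentum: float = 0.6, eps: float = 1e-5):
        super().__init__()
        self.params["gamma"] = np.ones(c, dtype=np.float32)
        self.params["beta"] = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._cache: tuple | None = None
        self._accum: list | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        c = x.shape[-1]
        x2 = x.reshape(-1, c)
        m = x2.shape[0]
        if train:
            mean = x2.sum(axis=0)
            mean /= m
            var = np.einsum("ij,ij->j", x2, x2) / np.float32(m) - mean * mean
            np.maximum(var, 0, out=var)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            )
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            )
            if self._accum is not None:
                self._accum.append((m, mean.copy(), var.copy()))
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + np.float32(self.eps))).astype(np.float32)
        xhat = self._buf("xhat", x.shape)
        np.subtract(x, mean, out=xhat)
        xhat *= inv
        y = self._buf("y", x.shape)
        np.multiply(xhat, self.params["gamma"], out=y)
        y += self.params["beta"]
        if train:
            self._cache = (xhat.reshape(-1, c), inv)
        return y

    def start_stat_accumulation(self) -> None:
        self._accum = []

    def finish_stat_accumulation(self) -> None:
        """Replace running statistics with population statistics pooled over
        the accumulated batches (law of total variance across batches)."""
        assert self._accum is not None and self._accum, "no batches accumulated"
        ns = np.array([a[0] for a in self._accum], dtype=np.float64)
        means = np.stack([a[1] for a in self._accum]).astype(np.float64)
        vars_ = np.stack([a[2] for a in self._accum]).astype(np.float64)
        total = ns.sum()
        mean = (ns[:, None] * means).sum(axis=0) / total
        ex2 = (ns[:, None] * (vars_ + means**2)).sum(axis=0) / total
        self.running_mean = mean.astype(np.float32)
        self.running_var = np.maximum(ex2 - mean**2, 0).astype(np.float32)
        self._accum = None

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._cache is not None
        xhat, inv = self._cache
        c = dy.shape[-1]
        dy2 = dy.reshape(-1, c)
        m = dy2.shape[0]
        self.grads["gamma"] = np.einsum("ij,ij->j", dy2, xhat)
        self.grads["beta"] = dy2.sum(axis=0)
        g = self.params["gamma"]
        # dx = gamma*inv * (dy - mean(dy) - xhat*mean(dy*xhat)), in place on dy
        dy2 -= self.grads["beta"] / np.float32(m)
        tmp = self._buf("tmp", dy2.shape)
        np.multiply(xhat, self.grads["gamma"] / np.float32(m), out=tmp)
        dy2 -= tmp
        dy2 *= g * inv
        self._cache = None
        return dy


class ReLU(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        y = np.maximum(x, 0, out=x)
        if train:
            mask = self._buf("mask", x.shape, dtype=bool)
            np.greater(y, 0, out=mask)
            self._mask = mask
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._mask is not None
        dy *= self._mask
        self._mask = None
        return dy


class MaxPool2(Layer):
    """2x2 max pooling with stride 2; odd trailing rows/cols are dropped (floor).

    Backward routes each pooled gradient to every window entry equal to the
    window maximum; exact float ties are vanishingly rare after batch norm,
    and tied zeros are masked out by the preceding ReLU's backward pass.
    """

    def __init__(self) -> None:
        super().__init__()
        self._cache: tuple | None = None

    @staticmethod
    def _views(x: np.ndarray):
        return (
            x[:, 0::2, 0::2, :],
            x[:, 0::2, 1::2, :],
            x[:, 1::2, 0::2, :],
            x[:, 1::2, 1::2, :],
        )

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c = x.shape
        xt = x[:, : 2 * (h // 2), : 2 * (w // 2), :]
        v = self._views(xt)
        y = self._buf("y", v[0].shape)
        np.maximum(v[0], v[1], out=y)
        np.maximum(y, v[2], out=y)
        np.maximum(y, v[3], out=y)
        if train:
            self._cache = (x, y)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._cache is not None
        x, y = self._cache
        n, h, w, c = x.shape
        dx = self._buf("dx", x.shape)
        dx[:] = 0
        xt = x[:, : 2 * (h // 2), : 2 * (w // 2), :]
        dxt = dx[:, : 2 * (h // 2), : 2 * (w // 2), :]
        eq = self._buf("eq", y.shape, dtype=bool)
        for xv, dv in zip(self._views(xt), self._views(dxt)):
            np.equal(xv, y, out=eq)
            np.copyto(dv, dy, where=eq)
        self._cache = None
        return dx


class Dense(Layer):
    """Fully connected layer over the flattened feature map."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.params["W"] = rng.normal(0.0, scale, (n_in, n_out)).astype(np.float32)
        self.params["b"] = np.zeros(n_out, dtype=np.float32)
        self._x: np.ndarray | None = None
        self._shape: tuple | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        x2 = x.reshape(x.shape[0], -1)
        if train:
            self._x = x2
            self._shape = x.shape
        return x2 @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._x is not None
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        dx = self._buf("dx", self._shape)
        np.copyto(dx, (dy @ self.params["W"].T).reshape(self._shape))
        self._x = None
        return dx

    @property
    def weight_decay_keys(self) -> tuple[str, ...]:
        return ("W",)


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, numerically stabilised."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log-likelihood of integer labels under `probs`."""
    n = probs.shape[0]
    p = np.clip(probs[np.arange(n), labels], 1e-12, None)
    return float(-np.log(p).mean())
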