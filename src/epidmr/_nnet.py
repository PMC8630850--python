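"""Minimal NumPy neural-network engine for 1-D convolutional sequence models.

Implements exactly the layer vocabulary the DMR network needs — 1-D
convolution (valid/same padding, stride 1), batch normalization over
channels, ReLU, max pooling, dropout, flatten, dense — with hand-written
backprop and an Adam optimizer. Convolutions are lowered to GEMM via an
im2col built from k slice views, so the heavy lifting happens in BLAS;
everything is float32 and fully deterministic for a fixed RNG on a single
thread.

This engine is intentionally small: no autograd graph, just layers with
``forward``/``backward`` and flat parameter/gradient lists.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Layer:
    """Base layer: parameters and their gradients are parallel lists."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def out_length(self, L: int) -> int:
        """Spatial length after this layer (-1 marks 'invalid')."""
        return L


class Conv1D(Layer):
    """1-D convolution, channels-first (N, C, L), stride 1.

    ``padding='valid'`` shrinks the length to L - k + 1; ``'same'``
    zero-pads (left (k-1)//2, remainder right) to preserve L.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel_size: int,
                 padding: str, rng: np.random.Generator):
        if padding not in ("valid", "same"):
            raise ValueError(f"unknown padding {padding!r}")
        self.in_ch, self.out_ch, self.k, self.padding = in_ch, out_ch, kernel_size, padding
        # He-style variance scaling for ReLU networks
        scale = np.sqrt(2.0 / (in_ch * kernel_size))
        self.W = (rng.standard_normal((out_ch, in_ch * kernel_size)) * scale).astype(F32)
        self.b = np.zeros(out_ch, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    @property
    def kernels(self) -> np.ndarray:
        """Kernel weights as (out_ch, in_ch, k)."""
        return self.W.reshape(self.out_ch, self.in_ch, self.k)

    def set_kernels(self, kernels: np.ndarray, bias: np.ndarray | None = None) -> None:
        self.W = np.asarray(kernels, dtype=F32).reshape(self.out_ch, -1).copy()
        if bias is not None:
            self.b = np.asarray(bias, dtype=F32).copy()

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def _pad(self, x: np.ndarray) -> np.ndarray:
        if self.padding == "valid":
            return x
        left = (self.k - 1) // 2
        right = self.k - 1 - left
        return np.pad(x, ((0, 0), (0, 0), (left, right)))

    def out_length(self, L: int) -> int:
        return L - self.k + 1 if self.padding == "valid" else L

    def forward(self, x, train):
        xp = self._pad(np.ascontiguousarray(x, dtype=F32))
        N, C, Lp = xp.shape
        L_out = Lp - self.k + 1
        if L_out < 1:
            raise ValueError(
                f"input length {x.shape[2]} too short for kernel size {self.k}"
            )
        self._xp = xp
        self._L_out = L_out
        # one batched GEMM per kernel tap keeps memory flat and BLAS busy
        Wk = self.W.reshape(self.out_ch, self.in_ch, self.k)
        out = np.matmul(Wk[None, :, :, 0], xp[:, :, :L_out])
        for j in range(1, self.k):
            out += np.matmul(Wk[None, :, :, j], xp[:, :, j : j + L_out])
        out += self.b[:, None]
        return out

    def backward(self, dout):
        xp, L_out = self._xp, self._L_out
        N, C, Lp = xp.shape
        dout = np.ascontiguousarray(dout, dtype=F32)
        Wk = self.W.reshape(self.out_ch, self.in_ch, self.k)
        dWk = self.dW.reshape(self.out_ch, self.in_ch, self.k)
        # flatten (batch, position) into one GEMM axis per tap
        d2t = np.ascontiguousarray(dout.transpose(0, 2, 1)).reshape(
            N * L_out, self.out_ch
        )
        dxp_t = np.zeros((N, Lp, C), dtype=F32)
        for j in range(self.k):
            xs_t = np.ascontiguousarray(
                xp[:, :, j : j + L_out].transpose(0, 2, 1)
            ).reshape(N * L_out, C)
            dWk[:, :, j] = d2t.T @ xs_t
            dxp_t[:, j : j + L_out, :] += (d2t @ Wk[:, :, j]).reshape(N, L_out, C)
        self.db[...] = dout.sum(axis=(0, 2))
        del self._xp
        dxp = np.ascontiguousarray(dxp_t.transpose(0, 2, 1))
        if self.padding == "same":
            left = (self.k - 1) // 2
            return dxp[:, :, left : left + (Lp - self.k + 1)]
        return dxp


class BatchNorm1D(Layer):
    """Per-channel batch normalization over the (batch, position) axes."""

    def __init__(self, channels: int, momentum: float = 0.99, eps: float = 1e-3):
        self.gamma = np.ones(channels, dtype=F32)
        self.beta = np.zeros(channels, dtype=F32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=F32)
        self.running_var = np.ones(channels, dtype=F32)
        self.momentum, self.eps = momentum, eps
        self.calibrating = False
        self._acc = None

    def start_calibration(self) -> None:
        self.calibrating = True
        self._acc = [0, np.zeros_like(self.running_mean, dtype=np.float64),
                     np.zeros_like(self.running_var, dtype=np.float64)]

    def finish_calibration(self) -> None:
        count, s, ss = self._acc
        mean = s / count
        self.running_mean[...] = mean
        self.running_var[...] = np.maximum(ss / count - mean ** 2, 0.0)
        self.calibrating = False
        self._acc = None

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def forward(self, x, train):
        g = self.gamma[:, None]
        b = self.beta[:, None]
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean[...] = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            )
            self.running_var[...] = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            )
            self._inv_std = 1.0 / np.sqrt(var + self.eps)
            self._xhat = (x - mean[:, None]) * self._inv_std[:, None]
            return g * self._xhat + b
        if self.calibrating:
            # exact population moments of this layer's inference-path input;
            # normalize with batch stats so downstream layers see live data
            self._acc[0] += x.shape[0] * x.shape[2]
            self._acc[1] += x.sum(axis=(0, 2), dtype=np.float64)
            self._acc[2] += (x.astype(np.float64) ** 2).sum(axis=(0, 2))
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            inv = 1.0 / np.sqrt(var + self.eps)
            return g * ((x - mean[:, None]) * inv[:, None]) + b
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        return g * ((x - self.running_mean[:, None]) * inv[:, None]) + b

    def backward(self, dout):
        m = dout.shape[0] * dout.shape[2]
        self.dgamma[...] = (dout * self._xhat).sum(axis=(0, 2))
        self.dbeta[...] = dout.sum(axis=(0, 2))
        gi = (self.gamma * self._inv_std)[:, None]
        dx = gi * (
            dout
            - self.dbeta[:, None] / m
            - self._xhat * self.dgamma[:, None] / m
        )
        return dx.astype(F32)


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool1D(Layer):
    """Non-overlapping max pooling along the position axis; remainder dropped."""

    def __init__(self, pool_size: int = 2):
        self.p = pool_size

    def out_length(self, L: int) -> int:
        return L // self.p

    def forward(self, x, train):
        N, C, L = x.shape
        Lo = L // self.p
        xv = x[:, :, : Lo * self.p].reshape(N, C, Lo, self.p)
        self._argmax = xv.argmax(axis=3)
        self._in_shape = (N, C, L)
        return np.take_along_axis(xv, self._argmax[..., None], axis=3)[..., 0]

    def backward(self, dout):
        N, C, L = self._in_shape
        Lo = L // self.p
        dxv = np.zeros((N, C, Lo, self.p), dtype=F32)
        np.put_along_axis(dxv, self._argmax[..., None], dout[..., None], axis=3)
        dx = np.zeros((N, C, L), dtype=F32)
        dx[:, :, : Lo * self.p] = dxv.reshape(N, C, Lo * self.p)
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate, self.rng = rate, rng

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(F32) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = (rng.standard_normal((n_in, n_out)) * scale).astype(F32)
        self.b = np.zeros(n_out, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        return dout @ self.W.T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, y: np.ndarray, sample_weight: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Weighted softmax cross-entropy loss and gradient w.r.t. logits."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    if sample_weight is None:
        sample_weight = np.ones(n)
    wsum = sample_weight.sum()
    eps = 1e-12
    loss = -(sample_weight * np.log(p[np.arange(n), y] + eps)).sum() / wsum
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    dlogits *= (sample_weight / wsum)[:, None]
    return float(loss), dlogits.astype(F32)


class Sequential:
    """A plain layer stack with shared forward/backward traversal."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def forward_until(self, x: np.ndarray, n_layers: int) -> np.ndarray:
        """Inference-mode forward through the first ``n_layers`` layers."""
        for layer in self.layers[:n_layers]:
            x = layer.forward(x, train=False)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def n_params(self) -> int:
        return sum(p.size for p in self.params())

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params(), weights, strict=True):
            p[...] = w


class Adam:
    """Adam optimizer over a flat parameter list (in-place updates)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2 ** self.t) / (1 - self.b1 ** self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v, strict=True):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)
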