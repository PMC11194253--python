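"""Minimal seeded NumPy layers with reverse-mode gradients.

Supports exactly what the stage classifiers need: 2-D convolution
(im2col backed by BLAS matmul), batch normalization, ReLU, 2x2 max
pooling, global average pooling, dense layers, dropout, residual basic
blocks, and a softmax cross-entropy head.  Tensors are NCHW float32 (a
deliberate speed/precision trade-off for CPU training); all parameter
initialization draws from an explicit ``numpy.random.Generator``.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np

DTYPE = np.float32


class Param:
    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name


class Layer:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> List[Param]:
        return []


def _he_init(rng: np.random.Generator, shape: Tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(DTYPE)


class Conv2d(Layer):
    """k x k convolution, symmetric zero padding, optional stride."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int = 3,
        stride: int = 1,
        pad: Optional[int] = None,
        rng: Optional[np.random.Generator] = None,
    ) -> None:
        rng = rng or np.random.default_rng(0)
        self.k, self.stride = kernel, stride
        self.pad = pad if pad is not None else kernel // 2
        fan_in = in_ch * kernel * kernel
        self.w = Param(_he_init(rng, (out_ch, in_ch, kernel, kernel), fan_in), "conv_w")
        self.b = Param(np.zeros(out_ch, dtype=DTYPE), "conv_b")
        self._cache: Optional[tuple] = None

    def _im2col(self, xp: np.ndarray, Ho: int, Wo: int) -> np.ndarray:
        """Patch matrix in (N*Ho*Wo, C*k*k) layout for BLAS matmul."""
        N, C, _, _ = xp.shape
        k, s = self.k, self.stride
        cols = np.empty((N, Ho, Wo, C, k, k), dtype=xp.dtype)
        for ki in range(k):
            for kj in range(k):
                patch = xp[:, :, ki : ki + s * Ho : s, kj : kj + s * Wo : s]
                cols[:, :, :, :, ki, kj] = patch.transpose(0, 2, 3, 1)
        return cols.reshape(N * Ho * Wo, C * k * k)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        N, C, H, W = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        Ho = (H + 2 * p - k) // s + 1
        Wo = (W + 2 * p - k) // s + 1
        cols = self._im2col(xp, Ho, Wo)
        wmat = self.w.value.reshape(self.w.value.shape[0], -1)
        out = cols @ wmat.T + self.b.value  # (N*Ho*Wo, O)
        self._cache = (xp.shape, cols, Ho, Wo)
        O = wmat.shape[0]
        return np.ascontiguousarray(
            out.reshape(N, Ho, Wo, O).transpose(0, 3, 1, 2)
        )

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xp_shape, cols, Ho, Wo = self._cache  # type: ignore[misc]
        N, C = xp_shape[0], xp_shape[1]
        k, s, p = self.k, self.stride, self.pad
        O = grad.shape[1]
        gt = np.ascontiguousarray(grad.transpose(0, 2, 3, 1)).reshape(N * Ho * Wo, O)
        wmat = self.w.value.reshape(O, -1)
        self.w.grad[...] = (gt.T @ cols).reshape(self.w.value.shape)
        self.b.grad[...] = gt.sum(axis=0)
        dcols = (gt @ wmat).reshape(N, Ho, Wo, C, k, k)
        dxp = np.zeros(xp_shape, dtype=grad.dtype)
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki : ki + s * Ho : s, kj : kj + s * Wo : s] += dcols[
                    :, :, :, :, ki, kj
                ].transpose(0, 3, 1, 2)
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp

    def params(self) -> List[Param]:
        return [self.w, self.b]


class BatchNorm2d(Layer):
    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        self.gamma = Param(np.ones(ch, dtype=DTYPE), "bn_gamma")
        self.beta = Param(np.zeros(ch, dtype=DTYPE), "bn_beta")
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(ch, dtype=DTYPE)
        self.running_var = np.ones(ch, dtype=DTYPE)
        self._cache: Optional[tuple] = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std, train, x.shape)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std, train, shape = self._cache  # type: ignore[misc]
        N, C, H, W = shape
        m = N * H * W
        self.gamma.grad[...] = (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad[...] = grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma.value[None, :, None, None]
        if not train:
            return g * inv_std[None, :, None, None]
        # batch statistics participate in the graph during training
        term = (
            g
            - g.mean(axis=(0, 2, 3))[None, :, None, None]
            - xhat * (g * xhat).mean(axis=(0, 2, 3))[None, :, None, None]
        )
        return term * inv_std[None, :, None, None]

    def params(self) -> List[Param]:
        return [self.gamma, self.beta]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, 0.0)


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2 (ties route the gradient to the first max)."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        N, C, H, W = x.shape
        self._in_shape = x.shape
        xr = x.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = xr.reshape(N, C, H // 2, W // 2, 4)
        self._arg = flat.argmax(axis=-1)
        return flat.max(axis=-1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        N, C, H, W = self._in_shape
        out = np.zeros((N, C, H // 2, W // 2, 4), dtype=grad.dtype)
        np.put_along_axis(out, self._arg[..., None], grad[..., None], axis=-1)
        out = out.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return out.reshape(N, C, H, W)


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        N, C, H, W = self._shape
        return np.broadcast_to(grad[:, :, None, None], self._shape) / (H * W)


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: Optional[np.random.Generator] = None) -> None:
        rng = rng or np.random.default_rng(0)
        self.w = Param(_he_init(rng, (n_in, n_out), n_in), "dense_w")
        self.b = Param(np.zeros(n_out, dtype=DTYPE), "dense_b")

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.w.grad[...] = self._x.T @ grad
        self.b.grad[...] = grad.sum(axis=0)
        return grad @ self.w.value.T

    def params(self) -> List[Param]:
        return [self.w, self.b]


class Dropout(Layer):
    def __init__(self, rate: float, rng: Optional[np.random.Generator] = None) -> None:
        if not (0 <= rate < 1):
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0:
            self._mask = None
            return x
        self._mask = ((self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)).astype(DTYPE)
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        return grad * self._mask


class BasicBlock(Layer):
    """Two 3x3 conv/BN stages with an identity (or 1x1 projection) skip."""

    def __init__(
        self, in_ch: int, out_ch: int, stride: int = 1,
        rng: Optional[np.random.Generator] = None,
    ) -> None:
        self.conv1 = Conv2d(in_ch, out_ch, 3, stride=stride, rng=rng)
        self.bn1 = BatchNorm2d(out_ch)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(out_ch, out_ch, 3, rng=rng)
        self.bn2 = BatchNorm2d(out_ch)
        self.relu_out = ReLU()
        self.proj: Optional[Conv2d] = None
        self.proj_bn: Optional[BatchNorm2d] = None
        if stride != 1 or in_ch != out_ch:
            self.proj = Conv2d(in_ch, out_ch, 1, stride=stride, pad=0, rng=rng)
            self.proj_bn = BatchNorm2d(out_ch)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = self.conv1.forward(x, train)
        out = self.bn1.forward(out, train)
        out = self.relu1.forward(out, train)
        out = self.conv2.forward(out, train)
        out = self.bn2.forward(out, train)
        if self.proj is not None:
            skip = self.proj_bn.forward(self.proj.forward(x, train), train)  # type: ignore[union-attr]
        else:
            skip = x
        return self.relu_out.forward(out + skip, train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.relu_out.backward(grad)
        g_main = self.bn2.backward(g)
        g_main = self.conv2.backward(g_main)
        g_main = self.relu1.backward(g_main)
        g_main = self.bn1.backward(g_main)
        g_main = self.conv1.backward(g_main)
        if self.proj is not None:
            g_skip = self.proj.backward(self.proj_bn.backward(g))  # type: ignore[union-attr]
        else:
            g_skip = g
        return g_main + g_skip

    def params(self) -> List[Param]:
        out = self.conv1.params() + self.bn1.params() + self.conv2.params() + self.bn2.params()
        if self.proj is not None:
            out += self.proj.params() + self.proj_bn.params()  # type: ignore[union-attr]
        return out


class Sequential:
    """Layer pipeline with full activation caching (needed by Grad-CAM)."""

    def __init__(self, layers: List[Layer]) -> None:
        self.layers = layers
        self.outputs: List[np.ndarray] = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self.outputs = []
        for layer in self.layers:
            x = layer.forward(x, train)
            self.outputs.append(x)
        return x

    def backward(self, grad: np.ndarray, stop_after: int = -1) -> np.ndarray:
        """Backpropagate; if ``stop_after >= 0`` stop once the gradient with
        respect to layer ``stop_after``'s output has been computed."""
        for i in range(len(self.layers) - 1, -1, -1):
            if i == stop_after:
                return grad
            grad = self.layers[i].backward(grad)
        return grad

    def params(self) -> List[Param]:
        out: List[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray) -> Tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. logits."""
    n = logits.shape[0]
    p = softmax(logits)
    eps = 1e-12
    loss = -np.log(p[np.arange(n), y] + eps).mean()
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return float(loss), grad / n


class Adam:
    """Adaptive-moment optimizer (the ecosystem-default first-order choice)."""

    def __init__(self, params: List[Param], lr: float = 1e-3,
                 betas: Tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        if self.lr == 0:
            return
        for i, p in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
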