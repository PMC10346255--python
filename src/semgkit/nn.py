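"""A compact seeded 1-D convolutional network engine on numpy.

Implements exactly the layer set the gesture classifier needs — 1-D
convolution (with stride and dilation, 'same' padding), max pooling, dense,
dropout, Leaky ReLU, flatten, branch/residual composition — with manual
backpropagation and an Adam optimizer. Convolutions are lowered to batched
GEMMs via an im2col gather, which keeps a full training run on the default
synthetic dataset within minutes on one CPU core.

All parameters are float32 by default (float64 available for gradient
checks). Weight initialization is Glorot-uniform from a caller-supplied
``numpy.random.Generator``; dropout draws from a shared generator box so a
whole network can be reseeded for reproducible training runs.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter", "RngBox", "Layer", "Conv1D", "Dense", "LeakyReLU", "MaxPool1D",
    "Dropout", "Flatten", "Sequential", "InceptionResBlock", "Network",
    "Adam", "softmax", "softmax_cross_entropy",
]


class Parameter:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name


class RngBox:
    """Mutable holder for the generator used by stochastic layers."""

    def __init__(self, seed: int = 0) -> None:
        self.gen = np.random.default_rng(seed)

    def reseed(self, seed: int) -> None:
        self.gen = np.random.default_rng(seed)


class Layer:
    name: str = ""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> list[Parameter]:
        return []


class Conv1D(Layer):
    """1-D convolution over (batch, channels, length) with 'same' padding.

    Output length is ``ceil(L / stride)``; the kernel's effective reach is
    ``dilation * (kernel - 1) + 1``.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        *,
        stride: int = 1,
        dilation: int = 1,
        bias: bool = True,
        rng: np.random.Generator,
        dtype=np.float32,
        name: str = "conv",
    ) -> None:
        if min(in_channels, out_channels, kernel, stride, dilation) < 1:
            raise ValueError("conv hyper-parameters must be >= 1")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        self.dilation = dilation
        self.use_bias = bias
        self.name = name
        fan_in = in_channels * kernel
        fan_out = out_channels * kernel
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        w = rng.uniform(-limit, limit, size=(out_channels, in_channels, kernel))
        self.w = Parameter(w.astype(dtype), f"{name}.w")
        self.b = Parameter(np.zeros(out_channels, dtype=dtype), f"{name}.b") if bias else None

    def _geometry(self, length: int) -> tuple[int, int, int]:
        l_out = -(-length // self.stride)
        k_eff = self.dilation * (self.kernel - 1) + 1
        pad = max((l_out - 1) * self.stride + k_eff - length, 0)
        return l_out, pad // 2, pad - pad // 2

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        batch, c_in, length = x.shape
        l_out, pl, pr = self._geometry(length)
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        cols = np.empty((batch, c_in, self.kernel, l_out), dtype=x.dtype)
        for k in range(self.kernel):
            s0 = k * self.dilation
            cols[:, :, k, :] = xp[:, :, s0 : s0 + self.stride * l_out : self.stride]
        cols = cols.reshape(batch, c_in * self.kernel, l_out)
        self._cache = (cols, length, pl, pr, xp.shape[-1])
        w2 = self.w.value.reshape(self.out_channels, -1)
        y = np.matmul(w2, cols)  # (B, C_out, L_out)
        if self.b is not None:
            y += self.b.value[:, None]
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols, length, pl, _pr, lp = self._cache
        batch = grad.shape[0]
        w2 = self.w.value.reshape(self.out_channels, -1)
        dw2 = np.matmul(grad, cols.transpose(0, 2, 1)).sum(axis=0)
        self.w.grad += dw2.reshape(self.w.value.shape)
        if self.b is not None:
            self.b.grad += grad.sum(axis=(0, 2))
        dcols = np.matmul(w2.T, grad)  # (B, C_in*K, L_out)
        dcols = dcols.reshape(batch, self.in_channels, self.kernel, -1)
        dxp = np.zeros((batch, self.in_channels, lp), dtype=grad.dtype)
        l_out = dcols.shape[-1]
        for k in range(self.kernel):
            s0 = k * self.dilation
            dxp[:, :, s0 : s0 + self.stride * l_out : self.stride] += dcols[:, :, k, :]
        return dxp[:, :, pl : pl + length]

    def parameters(self) -> list[Parameter]:
        return [self.w] + ([self.b] if self.b is not None else [])


class Dense(Layer):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        *,
        bias: bool = True,
        rng: np.random.Generator,
        dtype=np.float32,
        name: str = "dense",
    ) -> None:
        self.in_features = in_features
        self.out_features = out_features
        self.name = name
        limit = np.sqrt(6.0 / (in_features + out_features))
        w = rng.uniform(-limit, limit, size=(in_features, out_features))
        self.w = Parameter(w.astype(dtype), f"{name}.w")
        self.b = Parameter(np.zeros(out_features, dtype=dtype), f"{name}.b") if bias else None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        y = x @ self.w.value
        if self.b is not None:
            y += self.b.value
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ grad
        if self.b is not None:
            self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value.T

    def parameters(self) -> list[Parameter]:
        return [self.w] + ([self.b] if self.b is not None else [])


class LeakyReLU(Layer):
    """x for x >= 0, slope * x otherwise."""

    def __init__(self, slope: float = 0.3, name: str = "leaky_relu") -> None:
        self.slope = slope
        self.name = name

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        scale = np.where(x < 0, x.dtype.type(self.slope), x.dtype.type(1.0))
        self._scale = scale
        return x * scale

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._scale


class MaxPool1D(Layer):
    """Non-overlapping max pooling; a trailing remainder is dropped."""

    def __init__(self, size: int = 2, name: str = "maxpool") -> None:
        if size < 1:
            raise ValueError("pool size must be >= 1")
        self.size = size
        self.stride = size
        self.name = name

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        b, c, length = x.shape
        l_out = length // self.size
        xt = x[:, :, : l_out * self.size].reshape(b, c, l_out, self.size)
        self._argmax = xt.argmax(axis=3)
        self._shape = x.shape
        return np.take_along_axis(xt, self._argmax[..., None], axis=3)[..., 0]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b, c, length = self._shape
        l_out = grad.shape[-1]
        gp = np.zeros((b, c, l_out, self.size), dtype=grad.dtype)
        np.put_along_axis(gp, self._argmax[..., None], grad[..., None], axis=3)
        out = np.zeros((b, c, length), dtype=grad.dtype)
        out[:, :, : l_out * self.size] = gp.reshape(b, c, l_out * self.size)
        return out


class Dropout(Layer):
    """Inverted dropout; ``rate`` is the probability of dropping a unit."""

    def __init__(self, rate: float, rng_box: RngBox, name: str = "dropout") -> None:
        if not 0 <= rate < 1:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng_box = rng_box
        self.name = name

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        mask = (self.rng_box.gen.random(x.shape) < keep).astype(x.dtype) / keep
        self._mask = mask
        return x * mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def __init__(self, name: str = "flatten") -> None:
        self.name = name

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, layers: list[Layer], name: str = "sequential") -> None:
        self.layers = layers
        self.name = name

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.parameters()]


class InceptionResBlock(Layer):
    """Parallel branches merged by element-wise summation, plus an optional
    residual shortcut (identity, or a 1x1 projection when channel counts
    differ), followed by a Leaky ReLU on the merged map.

    All branches must produce equal shapes ('same' padding, stride 1, equal
    filter counts), which the summation merge requires.
    """

    def __init__(
        self,
        branches: list[Sequential],
        shortcut: Conv1D | None,
        use_residual: bool,
        activation: LeakyReLU,
        name: str = "inception_res",
    ) -> None:
        self.branches = branches
        self.shortcut = shortcut  # None means identity when use_residual
        self.use_residual = use_residual
        self.activation = activation
        self.name = name

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        outs = [br.forward(x, training) for br in self.branches]
        merged = outs[0]
        for o in outs[1:]:
            merged = merged + o
        if self.use_residual:
            merged = merged + (x if self.shortcut is None else self.shortcut.forward(x, training))
        return self.activation.forward(merged, training)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = self.activation.backward(grad)
        gx = self.branches[0].backward(grad)
        for br in self.branches[1:]:
            gx = gx + br.backward(grad)
        if self.use_residual:
            gx = gx + (grad if self.shortcut is None else self.shortcut.backward(grad))
        return gx

    def parameters(self) -> list[Parameter]:
        params = [p for br in self.branches for p in br.parameters()]
        if self.use_residual and self.shortcut is not None:
            params += self.shortcut.parameters()
        return params


class Network:
    """A sequential stack ending in a dense classifier head.

    ``logits`` returns pre-softmax scores (used with the fused
    softmax/cross-entropy loss during training); ``forward`` returns class
    probabilities.
    """

    def __init__(self, layers: list[Layer], rng_box: RngBox) -> None:
        self.stack = Sequential(layers, name="network")
        self.rng_box = rng_box

    def logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.stack.forward(x, training)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return softmax(self.logits(x, training))

    def backward(self, grad: np.ndarray) -> None:
        self.stack.backward(grad)

    def parameters(self) -> list[Parameter]:
        return self.stack.parameters()

    def n_trainable(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0

    def reseed_dropout(self, seed: int) -> None:
        self.rng_box.reseed(seed)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. logits.

    ``labels`` are integer class indices.
    """
    batch = logits.shape[0]
    probs = softmax(logits.astype(np.float64))
    eps = 1e-12
    loss = -np.log(probs[np.arange(batch), labels] + eps).mean()
    grad = probs
    grad[np.arange(batch), labels] -= 1.0
    grad /= batch
    return float(loss), grad.astype(logits.dtype)


class Adam:
    """Adam optimizer (beta1=0.9, beta2=0.999, eps=1e-7)."""

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-7,
    ) -> None:
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
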