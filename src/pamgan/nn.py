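"""Minimal tensor-network core: layers, tape-based backprop, Adam.

The translation networks here are small single-channel image-to-image
CNNs, so the package carries its own compact engine rather than a full
framework: each layer exposes ``forward(x) -> (y, cache)`` and
``backward(cache, dy) -> dx`` (accumulating parameter gradients), and a
network forward returns an explicit tape so one network can appear several
times in a composite objective (as in cycle-consistent training, where
each generator runs twice per step).  Compute is float32 numpy (BLAS
matmuls via im2col); all randomness comes from explicitly passed
generators, so training is a pure function of (data, specs, seed).

Convolutions are im2col + BLAS matmul; the decoder upsamples by
nearest-neighbour resize followed by convolution.
"""

from __future__ import annotations

import numpy as np

EPS = 1e-5
DTYPE = np.float32


class Param:
    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name


class Layer:
    """Base layer: stateless apart from parameters."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray):  # -> (y, cache)
        raise NotImplementedError

    def backward(self, cache, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


# ---------------------------------------------------------------------------
# padding helpers (zero / reflect), with exact gradient folding

def _pad(x: np.ndarray, p: int, mode: str) -> np.ndarray:
    if p == 0:
        return x
    width = ((0, 0), (0, 0), (p, p), (p, p))
    if mode == "zero":
        return np.pad(x, width)
    if mode == "reflect":
        return np.pad(x, width, mode="reflect")
    raise ValueError(f"unknown pad mode {mode!r}")


def _unpad_grad(dxp: np.ndarray, p: int, mode: str) -> np.ndarray:
    if p == 0:
        return dxp
    dx = dxp[:, :, p:-p, p:-p].copy()
    if mode == "reflect":
        # padded row i (i<p) mirrors interior row p-i; fold gradients back
        dx[:, :, 1 : p + 1, :] += dxp[:, :, :p, p:-p][:, :, ::-1, :]
        dx[:, :, -p - 1 : -1, :] += dxp[:, :, -p:, p:-p][:, :, ::-1, :]
        dx[:, :, :, 1 : p + 1] += dxp[:, :, p:-p, :p][:, :, :, ::-1]
        dx[:, :, :, -p - 1 : -1] += dxp[:, :, p:-p, -p:][:, :, :, ::-1]
        # corners mirror both axes
        dx[:, :, 1 : p + 1, 1 : p + 1] += dxp[:, :, :p, :p][:, :, ::-1, ::-1]
        dx[:, :, 1 : p + 1, -p - 1 : -1] += dxp[:, :, :p, -p:][:, :, ::-1, ::-1]
        dx[:, :, -p - 1 : -1, 1 : p + 1] += dxp[:, :, -p:, :p][:, :, ::-1, ::-1]
        dx[:, :, -p - 1 : -1, -p - 1 : -1] += dxp[:, :, -p:, -p:][:, :, ::-1, ::-1]
    return dx


def _im2col(xp: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(N, C, Hp, Wp) -> (N, C*k*k, Ho*Wo) patches."""
    n, c, hp, wp = xp.shape
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]          # (N, C, Ho, Wo, k, k)
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, ho * wo)
    return np.ascontiguousarray(cols)


class Conv2d(Layer):
    """2D convolution (cross-correlation) with 'same'-style padding."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        stride: int = 1,
        pad: int | None = None,
        pad_mode: str = "zero",
        rng: np.random.Generator | None = None,
        init_std: float = 0.02,
    ) -> None:
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch, self.k, self.stride = in_ch, out_ch, kernel, stride
        self.pad = (kernel - 1) // 2 if pad is None else pad
        self.pad_mode = pad_mode
        self.w = Param(
            rng.normal(0.0, init_std, size=(out_ch, in_ch * kernel * kernel)).astype(DTYPE),
            "w",
        )
        self.b = Param(np.zeros(out_ch, dtype=DTYPE), "b")

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray):
        n = x.shape[0]
        xp = _pad(x, self.pad, self.pad_mode)
        hp, wp = xp.shape[2], xp.shape[3]
        if hp < self.k or wp < self.k:
            raise ValueError(f"input {x.shape[2:]} smaller than kernel {self.k}")
        ho = (hp - self.k) // self.stride + 1
        wo = (wp - self.k) // self.stride + 1
        cols = _im2col(xp, self.k, self.stride)
        y = np.matmul(self.w.value, cols) + self.b.value[None, :, None]
        y = y.reshape(n, self.out_ch, ho, wo)
        return y, (cols, x.shape, (hp, wp))

    def backward(self, cache, dy: np.ndarray) -> np.ndarray:
        cols, x_shape, (hp, wp) = cache
        n, _, ho, wo = dy.shape
        k, s = self.k, self.stride
        dyf = dy.reshape(n, self.out_ch, ho * wo)
        self.w.grad += np.matmul(dyf, cols.transpose(0, 2, 1)).sum(axis=0)
        self.b.grad += dyf.sum(axis=(0, 2))
        # input gradient = correlation of the zero-stuffed output gradient
        # with spatially flipped, channel-transposed kernels (one GEMM)
        hs, ws = (ho - 1) * s + 1, (wo - 1) * s + 1
        ry, rx = hp - ((ho - 1) * s + k), wp - ((wo - 1) * s + k)
        dys = np.zeros((n, self.out_ch, hs + 2 * (k - 1) + ry, ws + 2 * (k - 1) + rx),
                       dtype=dy.dtype)
        dys[:, :, k - 1 : k - 1 + hs : s, k - 1 : k - 1 + ws : s] = dy
        w_flip = (self.w.value.reshape(self.out_ch, self.in_ch, k, k)[:, :, ::-1, ::-1]
                  .transpose(1, 0, 2, 3).reshape(self.in_ch, self.out_ch * k * k))
        dxp = np.matmul(np.ascontiguousarray(w_flip), _im2col(dys, k, 1))
        return _unpad_grad(dxp.reshape(n, self.in_ch, hp, wp), self.pad, self.pad_mode)


class InstanceNorm2d(Layer):
    """Per-sample, per-channel normalization over the spatial axes."""

    def __init__(self, channels: int) -> None:
        self.gamma = Param(np.ones(channels, dtype=DTYPE), "gamma")
        self.beta = Param(np.zeros(channels, dtype=DTYPE), "beta")

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray):
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        std = np.sqrt(var + EPS)
        xhat = (x - mu) / std
        y = self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]
        return y, (xhat, std)

    def backward(self, cache, dy: np.ndarray) -> np.ndarray:
        xhat, std = cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.value[None, :, None, None]
        m1 = dxhat.mean(axis=(2, 3), keepdims=True)
        m2 = (dxhat * xhat).mean(axis=(2, 3), keepdims=True)
        return (dxhat - m1 - xhat * m2) / std


class ReLU(Layer):
    def forward(self, x):
        mask = x > 0
        return x * mask, mask

    def backward(self, cache, dy):
        return dy * cache


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2) -> None:
        self.slope = slope

    def forward(self, x):
        mask = x > 0
        return np.where(mask, x, self.slope * x), mask

    def backward(self, cache, dy):
        return np.where(cache, dy, self.slope * dy)


class TanhUnit(Layer):
    """tanh rescaled to [0, 1]: y = (tanh(x) + 1) / 2."""

    def forward(self, x):
        t = np.tanh(x)
        return (t + 1.0) / 2.0, t

    def backward(self, cache, dy):
        return dy * (1.0 - cache**2) / 2.0


class Sigmoid(Layer):
    def forward(self, x):
        y = 1.0 / (1.0 + np.exp(-x))
        return y, y

    def backward(self, cache, dy):
        return dy * cache * (1.0 - cache)


class UpsampleNearest2(Layer):
    def forward(self, x):
        y = x.repeat(2, axis=2).repeat(2, axis=3)
        return y, x.shape

    def backward(self, cache, dy):
        n, c, h, w = cache
        return dy.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray):
        tape = []
        for layer in self.layers:
            x, cache = layer.forward(x)
            tape.append(cache)
        return x, tape

    def backward(self, tape, dy: np.ndarray) -> np.ndarray:
        for layer, cache in zip(reversed(self.layers), reversed(tape)):
            dy = layer.backward(cache, dy)
        return dy


class ResidualBlock(Layer):
    """conv-norm-relu-conv-norm with an identity skip connection."""

    def __init__(self, channels: int, rng: np.random.Generator, pad_mode: str = "reflect",
                 norm: str = "instance") -> None:
        self.body = Sequential([
            Conv2d(channels, channels, 3, pad_mode=pad_mode, rng=rng),
            _make_norm(norm, channels),
            ReLU(),
            Conv2d(channels, channels, 3, pad_mode=pad_mode, rng=rng),
            _make_norm(norm, channels),
        ])

    def params(self) -> list[Param]:
        return self.body.params()

    def forward(self, x):
        y, tape = self.body.forward(x)
        return x + y, tape

    def backward(self, tape, dy):
        return dy + self.body.backward(tape, dy)


class Identity(Layer):
    def params(self):
        return []

    def forward(self, x):
        return x, None

    def backward(self, cache, dy):
        return dy


class BatchNorm2d(Layer):
    """Per-channel normalization over batch and spatial axes (train-mode only)."""

    def __init__(self, channels: int) -> None:
        self.gamma = Param(np.ones(channels, dtype=DTYPE), "gamma")
        self.beta = Param(np.zeros(channels, dtype=DTYPE), "beta")

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x):
        mu = x.mean(axis=(0, 2, 3), keepdims=True)
        var = x.var(axis=(0, 2, 3), keepdims=True)
        std = np.sqrt(var + EPS)
        xhat = (x - mu) / std
        y = self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]
        return y, (xhat, std)

    def backward(self, cache, dy):
        xhat, std = cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.value[None, :, None, None]
        m1 = dxhat.mean(axis=(0, 2, 3), keepdims=True)
        m2 = (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        return (dxhat - m1 - xhat * m2) / std


def _make_norm(kind: str, channels: int) -> Layer:
    if kind == "instance":
        return InstanceNorm2d(channels)
    if kind == "batch":
        return BatchNorm2d(channels)
    if kind == "none":
        return Identity()
    raise ValueError(f"unknown norm {kind!r}")


class GlobalMeanPool(Layer):
    """Reduce a decision map to a single value per sample (keeps 4D shape)."""

    def forward(self, x):
        n, c, h, w = x.shape
        return x.mean(axis=(2, 3), keepdims=True), (h, w)

    def backward(self, cache, dy):
        h, w = cache
        return np.broadcast_to(dy, (*dy.shape[:2], h, w)) / (h * w)


# ---------------------------------------------------------------------------
# losses (value + gradient wrt prediction)

def bce_loss(p: np.ndarray, target: float) -> tuple[float, np.ndarray]:
    """Binary cross-entropy of sigmoid outputs against a constant label."""
    pc = np.clip(p, 1e-7, 1.0 - 1e-7)
    loss = float(-np.mean(target * np.log(pc) + (1.0 - target) * np.log(1.0 - pc)))
    grad = (pc - target) / (pc * (1.0 - pc)) / p.size
    return loss, grad


def lsgan_loss(p: np.ndarray, target: float) -> tuple[float, np.ndarray]:
    """Least-squares adversarial loss variant."""
    diff = p - target
    return float(np.mean(diff**2)), 2.0 * diff / p.size


def l1_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    diff = pred - target
    return float(np.mean(np.abs(diff))), np.sign(diff) / diff.size


class Adam:
    """Adam optimizer over an explicit parameter list."""

    def __init__(self, params: list[Param], lr: float = 2e-4,
                 betas: tuple[float, float] = (0.5, 0.999), eps: float = 1e-8) -> None:
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad**2
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def count_parameters(net: Layer) -> int:
    """Exact number of trainable scalars in a network."""
    return int(sum(p.value.size for p in net.params()))


def get_state(net: Layer) -> list[np.ndarray]:
    return [p.value.copy() for p in net.params()]


def set_state(net: Layer, state: list[np.ndarray]) -> None:
    params = net.params()
    if len(params) != len(state):
        raise ValueError(f"state has {len(state)} arrays, network expects {len(params)}")
    for p, arr in zip(params, state):
        if p.value.shape != arr.shape:
            raise ValueError(f"shape mismatch {p.value.shape} vs {arr.shape}")
        p.value[...] = arr
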