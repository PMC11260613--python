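"""Minimal numpy convolutional-network engine for slice-wise dose prediction.

Implements exactly the pieces the residual encoder–decoder needs — same-size
2-D convolution via im2col, ReLU, 2x average pooling / nearest upsampling,
residual blocks and an Adam optimizer — with explicit backpropagation.
Arrays are ``(batch, channels, height, width)`` float64 throughout; all
weight initialisation draws from a caller-supplied seeded generator, so a
network build is a pure function of its seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ShapeError

__all__ = ["Conv2d", "ReLU", "AvgPool2", "Upsample2", "ResidualBlock", "ResEncDec", "Adam"]


class Conv2d:
    """Same-size 2-D convolution (odd kernel, stride 1, zero padding).

    Forward and backward are each a single GEMM over an im2col matrix with
    the batch folded into the columns, which is what keeps CPU training of
    the reduced preset tractable.
    """

    def __init__(self, cin: int, cout: int, kernel: int, rng: np.random.Generator,
                 dtype=np.float32):
        if kernel % 2 != 1:
            raise ShapeError(f"kernel size must be odd, got {kernel}")
        self.cin, self.cout, self.kernel = cin, cout, kernel
        self.dtype = dtype
        fan_in = cin * kernel * kernel
        # He initialisation, suited to the ReLU nonlinearity
        self.weight = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, fan_in)).astype(dtype)
        self.bias = np.zeros(cout, dtype=dtype)
        self.d_weight = np.zeros_like(self.weight)
        self.d_bias = np.zeros_like(self.bias)
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k, p = self.kernel, self.kernel // 2
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (n, c, h, w, k, k)
        return np.ascontiguousarray(win.transpose(1, 4, 5, 0, 2, 3)).reshape(
            c * k * k, n * h * w
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.cin:
            raise ShapeError(f"expected {self.cin} input channels, got {x.shape[1]}")
        x = np.asarray(x, dtype=self.dtype)
        self._shape = x.shape
        self._cols = self._im2col(x)
        n, _, h, w = x.shape
        y = (self.weight @ self._cols).reshape(self.cout, n, h, w)
        return np.ascontiguousarray(y.transpose(1, 0, 2, 3)) + self.bias[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, _, h, w = self._shape
        k, p = self.kernel, self.kernel // 2
        dyf = np.ascontiguousarray(
            np.asarray(dy, dtype=self.dtype).transpose(1, 0, 2, 3)
        ).reshape(self.cout, n * h * w)
        self.d_weight = dyf @ self._cols.T
        self.d_bias = dyf.sum(axis=1)
        dcols = (self.weight.T @ dyf).reshape(self.cin, k, k, n, h, w)
        # accumulate in (c, n, H, W) so every slice-add is contiguous, then
        # transpose once
        dxp = np.zeros((self.cin, n, h + 2 * p, w + 2 * p), dtype=self.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, i, j]
        self._cols = None
        return np.ascontiguousarray(
            dxp[:, :, p : p + h, p : p + w].transpose(1, 0, 2, 3)
        )

    def parameters(self):
        return [self.weight, self.bias]

    def gradients(self):
        return [self.d_weight, self.d_bias]


class ReLU:
    def __init__(self):
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask

    def parameters(self):
        return []

    def gradients(self):
        return []


class AvgPool2:
    """2x2 average pooling with stride 2."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ShapeError(f"in-plane size {(h, w)} not divisible by 2")
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(dy, 2, axis=2), 2, axis=3) / 4.0

    def parameters(self):
        return []

    def gradients(self):
        return []


class Upsample2:
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))

    def parameters(self):
        return []

    def gradients(self):
        return []


class ResidualBlock:
    """conv-ReLU-conv with identity shortcut, ReLU after the add."""

    def __init__(self, channels: int, rng: np.random.Generator, dtype=np.float32):
        self.conv1 = Conv2d(channels, channels, 3, rng, dtype)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(channels, channels, 3, rng, dtype)
        self.relu2 = ReLU()

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.relu1.forward(self.conv1.forward(x))
        return self.relu2.forward(self.conv2.forward(h) + x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        g = self.relu2.backward(dy)
        dx = self.conv1.backward(self.relu1.backward(self.conv2.backward(g)))
        return dx + g

    def parameters(self):
        return self.conv1.parameters() + self.conv2.parameters()

    def gradients(self):
        return self.conv1.gradients() + self.conv2.gradients()


class ResEncDec:
    """Residual encoder–decoder mapping 3-channel slices to 1-channel dose.

    ``widths`` sets the channel count per resolution level; each level below
    the first halves the in-plane resolution, so inputs must be divisible by
    ``2 ** (len(widths) - 1)``.  Long skip connections add encoder features
    back in at every decoder level.  Fully convolutional: any compliant
    in-plane size works.
    """

    def __init__(self, widths: tuple[int, ...], seed: int, in_channels: int = 3,
                 dtype=np.float32):
        rng = np.random.default_rng(seed)
        self.widths = tuple(widths)
        self.in_channels = in_channels
        self.dtype = dtype
        L = len(widths)
        self.stem = Conv2d(in_channels, widths[0], 3, rng, dtype)
        self.stem_relu = ReLU()
        self.enc_blocks = [ResidualBlock(widths[i], rng, dtype) for i in range(L - 1)]
        self.pools = [AvgPool2() for _ in range(L - 1)]
        self.down_convs = [Conv2d(widths[i], widths[i + 1], 3, rng, dtype) for i in range(L - 1)]
        self.down_relus = [ReLU() for _ in range(L - 1)]
        self.mid_block = ResidualBlock(widths[-1], rng, dtype)
        self.ups = [Upsample2() for _ in range(L - 1)]
        self.dec_convs = [Conv2d(widths[i + 1], widths[i], 3, rng, dtype) for i in range(L - 1)]
        self.dec_relus = [ReLU() for _ in range(L - 1)]
        self.dec_blocks = [ResidualBlock(widths[i], rng, dtype) for i in range(L - 1)]
        self.head = Conv2d(widths[0], 1, 1, rng, dtype)

    @property
    def downsample_factor(self) -> int:
        return 2 ** (len(self.widths) - 1)

    def _check_inplane(self, x: np.ndarray) -> None:
        f = self.downsample_factor
        if x.ndim != 4 or x.shape[1] != self.in_channels:
            raise ShapeError(f"expected (n, {self.in_channels}, h, w), got {x.shape}")
        if x.shape[2] % f or x.shape[3] % f:
            raise ShapeError(
                f"in-plane size {x.shape[2:]} not divisible by the downsampling factor {f}"
            )

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._check_inplane(x)
        x = np.asarray(x, dtype=self.dtype)
        s = self.stem_relu.forward(self.stem.forward(x))
        skips: list[np.ndarray] = []
        for i in range(len(self.enc_blocks)):
            s = self.enc_blocks[i].forward(s)
            skips.append(s)
            s = self.down_relus[i].forward(self.down_convs[i].forward(self.pools[i].forward(s)))
        s = self.mid_block.forward(s)
        for i in reversed(range(len(self.dec_blocks))):
            s = self.dec_relus[i].forward(self.dec_convs[i].forward(self.ups[i].forward(s)))
            s = self.dec_blocks[i].forward(s + skips[i])
        return self.head.forward(s)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        g = self.head.backward(dy)
        skip_grads: list[np.ndarray | None] = [None] * len(self.dec_blocks)
        for i in range(len(self.dec_blocks)):
            g = self.dec_blocks[i].backward(g)
            skip_grads[i] = g  # the add routes the same gradient to the encoder branch
            g = self.ups[i].backward(self.dec_convs[i].backward(self.dec_relus[i].backward(g)))
        g = self.mid_block.backward(g)
        for i in reversed(range(len(self.enc_blocks))):
            g = self.pools[i].backward(self.down_convs[i].backward(self.down_relus[i].backward(g)))
            g = self.enc_blocks[i].backward(g + skip_grads[i])
        return self.stem.backward(self.stem_relu.backward(g))

    def _layers(self):
        yield self.stem
        yield from self.enc_blocks
        yield from self.down_convs
        yield self.mid_block
        yield from self.dec_convs
        yield from self.dec_blocks
        yield self.head

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self._layers() for p in layer.parameters()]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self._layers() for g in layer.gradients()]

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def state_arrays(self) -> list[np.ndarray]:
        """Parameter arrays in a stable order, for checkpointing."""
        return self.parameters()

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ShapeError(f"checkpoint has {len(arrays)} arrays, model needs {len(params)}")
        for p, a in zip(params, arrays):
            if p.shape != a.shape:
                raise ShapeError(f"checkpoint array shape {a.shape} != parameter shape {p.shape}")
            p[...] = a


class Adam:
    """Adam optimizer updating parameter arrays in place."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean-squared error and its gradient with respect to ``pred``."""
    diff = pred - np.asarray(target, dtype=pred.dtype)
    return float(np.mean(diff.astype(np.float64) ** 2)), 2.0 * diff / diff.size
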