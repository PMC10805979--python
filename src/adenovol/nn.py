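"""Minimal CPU neural-network engine: layers, U-Net topology, Adam, BCE.

Everything is plain float64 numpy, which makes predictions bit-reproducible
across runs and machines (BLAS reductions aside, the arithmetic is fixed:
convolutions go through `tensordot`, so a given numpy build is
deterministic). The engine implements exactly what slice-wise tumor
segmentation needs and nothing more: 3x3 same-padding convolutions, ReLU,
2x2 max pooling, nearest-neighbor upsampling, channel concatenation, a 1x1
output head, sigmoid/binary-cross-entropy with logits, and Adam.

Shapes follow the (N, C, H, W) convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _he_init(
    rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, dtype: np.dtype
) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(dtype)


class Conv2D:
    """Same-padding 2D convolution, kernel 3x3 or 1x1."""

    def __init__(self, cin: int, cout: int, ksize: int, rng: np.random.Generator,
                 dtype: np.dtype = np.float32):
        if ksize not in (1, 3):
            raise ValueError("only 1x1 and 3x3 kernels are supported")
        self.ksize = ksize
        self.W = _he_init(rng, (cout, cin, ksize, ksize), fan_in=cin * ksize * ksize, dtype=dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        if self.ksize == 1:
            y = np.tensordot(x, self.W[:, :, 0, 0], axes=([1], [1]))  # (N,H,W,O)
            return np.moveaxis(y, 3, 1) + self.b[None, :, None, None]
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (N,C,H,W,3,3)
        y = np.tensordot(win, self.W, axes=([1, 4, 5], [1, 2, 3]))  # (N,H,W,O)
        return np.moveaxis(y, 3, 1) + self.b[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        assert x is not None, "backward before forward(train=True)"
        self.db[...] = dy.sum(axis=(0, 2, 3))
        if self.ksize == 1:
            self.dW[:, :, 0, 0] = np.tensordot(dy, x, axes=([0, 2, 3], [0, 2, 3]))
            dx = np.tensordot(np.moveaxis(dy, 1, 3), self.W[:, :, 0, 0], axes=([3], [0]))
            self._x = None
            return np.moveaxis(dx, 3, 1)
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = sliding_window_view(xp, (3, 3), axis=(2, 3))
        self.dW[...] = np.tensordot(dy, win, axes=([0, 2, 3], [0, 2, 3]))
        dyp = np.pad(dy, ((0, 0), (0, 0), (1, 1), (1, 1)))
        wind = sliding_window_view(dyp, (3, 3), axis=(2, 3))  # (N,O,H,W,3,3)
        w_flip = self.W[:, :, ::-1, ::-1]
        dx = np.tensordot(wind, w_flip, axes=([1, 4, 5], [0, 2, 3]))  # (N,H,W,C)
        self._x = None
        return np.moveaxis(dx, 3, 1)


class ReLU:
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        mask = self._mask
        assert mask is not None
        self._mask = None
        return dy * mask


class MaxPool2:
    """2x2 max pooling, stride 2; ties route the gradient to the first max."""

    def __init__(self) -> None:
        self._argmax: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"pooling needs even spatial dims, got {h}x{w}")
        xr = (
            x.reshape(n, c, h // 2, 2, w // 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h // 2, w // 2, 4)
        )
        if train:
            self._argmax = xr.argmax(axis=4)
            self._shape = x.shape
        return xr.max(axis=4)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        am, shape = self._argmax, self._shape
        assert am is not None and shape is not None
        n, c, h, w = shape
        grad = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(grad, am[..., None], dy[..., None], axis=4)
        dx = (
            grad.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )
        self._argmax = None
        return dx


class UpNearest2:
    """Nearest-neighbor 2x upsampling."""

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class UNet2D:
    """Small encoder-decoder with skip connections and a 1x1 logit head.

    `depth` resolution levels (depth-1 poolings); level ``i`` carries
    ``base_filters * 2**i`` channels. Input spatial dims must be divisible
    by ``2**(depth-1)``. `forward` returns logits; apply `sigmoid` for
    probabilities.
    """

    def __init__(self, depth: int = 3, base_filters: int = 8, in_channels: int = 1,
                 seed: int = 0, dtype: np.dtype = np.float32):
        if depth < 2:
            raise ValueError("depth must be >= 2")
        self.depth = depth
        self.base_filters = base_filters
        self.in_channels = in_channels
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7070]))

        f = base_filters
        dt = self.dtype
        self.enc: list[tuple[Conv2D, ReLU, Conv2D, ReLU]] = []
        cin = in_channels
        for lv in range(depth):
            cout = f * 2**lv
            self.enc.append((Conv2D(cin, cout, 3, rng, dt), ReLU(),
                             Conv2D(cout, cout, 3, rng, dt), ReLU()))
            cin = cout
        self.pools = [MaxPool2() for _ in range(depth - 1)]
        self.ups = [UpNearest2() for _ in range(depth - 1)]
        self.dec: list[tuple[Conv2D, ReLU, Conv2D, ReLU]] = []
        for lv in range(depth - 2, -1, -1):
            skip = f * 2**lv
            cin_dec = skip * 2 + skip  # upsampled coarser level + skip
            self.dec.append((Conv2D(cin_dec, skip, 3, rng, dt), ReLU(),
                             Conv2D(skip, skip, 3, rng, dt), ReLU()))
        self.head = Conv2D(f, 1, 1, rng, dt)

    # -- parameter plumbing -------------------------------------------------
    def _conv_layers(self) -> list[tuple[str, Conv2D]]:
        out = []
        for i, (c1, _, c2, _) in enumerate(self.enc):
            out += [(f"enc{i}_c1", c1), (f"enc{i}_c2", c2)]
        for i, (c1, _, c2, _) in enumerate(self.dec):
            out += [(f"dec{i}_c1", c1), (f"dec{i}_c2", c2)]
        out.append(("head", self.head))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, conv in self._conv_layers():
            state[f"{name}.W"] = conv.W.copy()
            state[f"{name}.b"] = conv.b.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, conv in self._conv_layers():
            W, b = state[f"{name}.W"], state[f"{name}.b"]
            if W.shape != conv.W.shape or b.shape != conv.b.shape:
                raise ValueError(
                    f"architecture mismatch at {name}: expected {conv.W.shape}, got {W.shape}"
                )
            conv.W[...] = W
            conv.b[...] = b

    def params(self):
        out = []
        for _, conv in self._conv_layers():
            out.extend(conv.params())
        return out

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.in_channels:
            raise ValueError(f"expected (N,{self.in_channels},H,W), got {x.shape}")
        div = 2 ** (self.depth - 1)
        if x.shape[2] % div or x.shape[3] % div:
            raise ValueError(
                f"spatial dims {x.shape[2:]} must be divisible by {div} for depth {self.depth}"
            )
        x = np.ascontiguousarray(x, dtype=self.dtype)
        skips = []
        h = x
        for lv in range(self.depth):
            c1, r1, c2, r2 = self.enc[lv]
            h = r2.forward(c2.forward(r1.forward(c1.forward(h, train), train), train), train)
            if lv < self.depth - 1:
                skips.append(h)
                h = self.pools[lv].forward(h, train)
        self._skip_channels = []
        for j, lv in enumerate(range(self.depth - 2, -1, -1)):
            up = self.ups[j].forward(h, train)
            skip = skips[lv]
            self._skip_channels.append((up.shape[1], skip.shape[1]))
            h = np.concatenate([up, skip], axis=1)
            c1, r1, c2, r2 = self.dec[j]
            h = r2.forward(c2.forward(r1.forward(c1.forward(h, train), train), train), train)
        return self.head.forward(h, train)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        dskips: dict[int, np.ndarray] = {}
        for j in range(len(self.dec) - 1, -1, -1):
            lv = self.depth - 2 - j
            c1, r1, c2, r2 = self.dec[j]
            d = c1.backward(r1.backward(c2.backward(r2.backward(d))))
            n_up, _ = self._skip_channels[j]
            d_up, d_skip = d[:, :n_up], d[:, n_up:]
            dskips[lv] = d_skip
            d = self.ups[j].backward(d_up)
        for lv in range(self.depth - 1, -1, -1):
            if lv < self.depth - 1:
                d = self.pools[lv].backward(d)
                d = d + dskips[lv]
            c1, r1, c2, r2 = self.enc[lv]
            d = c1.backward(r1.backward(c2.backward(r2.backward(d))))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return sigmoid(self.forward(x, train=False))


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.result_type(z.dtype, np.float32))
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Numerically stable mean binary cross-entropy and its logit gradient."""
    z, y = logits, targets
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    grad = (sigmoid(z) - y) / z.size
    return float(loss.mean()), grad


class Adam:
    """Adam optimizer over a model's (param, grad) pairs."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
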