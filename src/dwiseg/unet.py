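"""A small 3D encoder–decoder segmentation network in NumPy.

This is a plain U-Net-style fully convolutional network: per resolution
level two (3×3×3 conv → instance norm → ReLU) blocks, 2× max-pool
downsampling, nearest-neighbour upsampling with skip concatenation, and a
1×1×1 convolution head with a per-channel sigmoid (labels may overlap
where tracts cross, so the head is multi-label, not softmax).

Forward and reverse passes are written explicitly: convolutions run as a
single GEMM over an im2col view, and each layer caches exactly what its
backward pass needs (inputs are kept; the im2col matrix is recomputed in
backward to bound memory).  Parameters are updated with Adam.  All
arithmetic is float32 and channel-first (C, D, H, W); initialization and
every stochastic choice are driven by a caller-supplied seed, so runs are
exactly reproducible.

The network is intentionally small — it is sized for desk-scale patches
(32³–96³) on a CPU, which is all the subset-augmentation training scheme
needs to be exercised end to end.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["UNet3D", "Adam"]

F32 = np.float32


class _Layer:
    """Minimal layer protocol: forward caches, backward consumes."""

    params: list  # list of [array, grad] pairs

    def __init__(self) -> None:
        self.params = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv3d(_Layer):
    """3D convolution, kernel k, 'same' padding (k odd) or 1×1×1."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        super().__init__()
        self.cin, self.cout, self.k = cin, cout, k
        fan_in = cin * k**3
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, fan_in))
        self.W = [w.astype(F32), np.zeros((cout, fan_in), F32)]
        self.b = [np.zeros(cout, F32), np.zeros(cout, F32)]
        self.params = [self.W, self.b]
        self._x: np.ndarray | None = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        if p:
            x = np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))
        win = sliding_window_view(x, (k, k, k), axis=(1, 2, 3))
        # (cin, D, H, W, k, k, k) -> (cin*k^3, D*H*W)
        cols = win.transpose(0, 4, 5, 6, 1, 2, 3)
        return np.ascontiguousarray(cols).reshape(self.cin * k**3, -1)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        self._shape = x.shape[1:]
        out = self.W[0] @ self._im2col(x) + self.b[0][:, None]
        return out.reshape((self.cout,) + self._shape)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        g = grad.reshape(self.cout, -1)
        cols = self._im2col(self._x)
        self.W[1] += g @ cols.T
        self.b[1] += g.sum(axis=1)
        dcols = (self.W[0].T @ g).reshape((self.cin, k, k, k) + self._shape)
        D, H, Wd = self._shape
        dxp = np.zeros((self.cin, D + 2 * p, H + 2 * p, Wd + 2 * p), F32)
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    dxp[:, i:i + D, j:j + H, l:l + Wd] += dcols[:, i, j, l]
        return dxp[:, p:p + D, p:p + H, p:p + Wd] if p else dxp


class InstanceNorm(_Layer):
    """Per-channel normalization over the spatial axes, with affine."""

    def __init__(self, c: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = [np.ones(c, F32), np.zeros(c, F32)]
        self.beta = [np.zeros(c, F32), np.zeros(c, F32)]
        self.params = [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        ax = (1, 2, 3)
        mu = x.mean(axis=ax, keepdims=True)
        var = x.var(axis=ax, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return self.gamma[0][:, None, None, None] * self._xhat + \
            self.beta[0][:, None, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        ax = (1, 2, 3)
        xhat, inv = self._xhat, self._inv
        self.gamma[1] += (grad * xhat).sum(axis=ax)
        self.beta[1] += grad.sum(axis=ax)
        g = grad * self.gamma[0][:, None, None, None]
        gm = g.mean(axis=ax, keepdims=True)
        gxm = (g * xhat).mean(axis=ax, keepdims=True)
        return (g - gm - xhat * gxm) * inv


class ReLU(_Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool2(_Layer):
    """2×2×2 max pooling; spatial dims must be even."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, D, H, W = x.shape
        r = x.reshape(c, D // 2, 2, H // 2, 2, W // 2, 2)
        out = r.max(axis=(2, 4, 6))
        self._r, self._out = r, out
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        mask = self._r == self._out[:, :, None, :, None, :, None]
        # split gradient equally over tied maxima (ties are rare)
        cnt = mask.sum(axis=(2, 4, 6), keepdims=True)
        g = (mask / cnt) * grad[:, :, None, :, None, :, None]
        c, d2, _, h2, _, w2, _ = g.shape
        return g.reshape(c, d2 * 2, h2 * 2, w2 * 2).astype(F32)


class Upsample2(_Layer):
    """Nearest-neighbour ×2 upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, 1).repeat(2, 2).repeat(2, 3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        c, D, H, W = grad.shape
        r = grad.reshape(c, D // 2, 2, H // 2, 2, W // 2, 2)
        return r.sum(axis=(2, 4, 6))


class _ConvBlock(_Layer):
    """conv → norm → relu, twice."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        self.layers = [
            Conv3d(cin, cout, 3, rng), InstanceNorm(cout), ReLU(),
            Conv3d(cout, cout, 3, rng), InstanceNorm(cout), ReLU(),
        ]
        for lyr in self.layers:
            self.params.extend(lyr.params)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for lyr in self.layers:
            x = lyr.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for lyr in reversed(self.layers):
            grad = lyr.backward(grad)
        return grad


class UNet3D:
    """Encoder–decoder FCN mapping (in_ch, D, H, W) → per-voxel label
    probabilities (out_ch, D, H, W); spatial dims must be divisible by
    2**depth."""

    def __init__(self, in_ch: int, out_ch: int, depth: int = 2,
                 base_width: int = 8, seed: int = 0):
        if depth < 1:
            raise ValueError("depth must be ≥ 1")
        rng = np.random.default_rng(seed)
        self.in_ch, self.out_ch = in_ch, out_ch
        self.depth, self.base_width, self.seed = depth, base_width, seed
        widths = [base_width * 2**i for i in range(depth + 1)]
        self.enc = [_ConvBlock(in_ch if i == 0 else widths[i - 1], widths[i], rng)
                    for i in range(depth)]
        self.pools = [MaxPool2() for _ in range(depth)]
        self.bottleneck = _ConvBlock(widths[depth - 1], widths[depth], rng)
        self.ups = [Upsample2() for _ in range(depth)]
        self.dec = [_ConvBlock(widths[i] + widths[i + 1], widths[i], rng)
                    for i in reversed(range(depth))]
        self.head = Conv3d(widths[0], out_ch, 1, rng)
        self.params: list = []
        for block in (*self.enc, self.bottleneck, *self.dec, self.head):
            self.params.extend(block.params)

    def _check(self, x: np.ndarray) -> None:
        if x.shape[0] != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {x.shape[0]}")
        for s in x.shape[1:]:
            if s % 2**self.depth:
                raise ValueError(
                    f"spatial size {s} not divisible by 2^{self.depth}"
                )

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Sigmoid probabilities; caches activations for backward."""
        x = np.ascontiguousarray(x, dtype=F32)
        self._check(x)
        skips = []
        h = x
        for enc, pool in zip(self.enc, self.pools):
            h = enc.forward(h)
            skips.append(h)
            h = pool.forward(h)
        h = self.bottleneck.forward(h)
        self._skip_ch = []
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips)):
            h = up.forward(h)
            self._skip_ch.append(skip.shape[0])
            h = dec.forward(np.concatenate([skip, h], axis=0))
        logits = self.head.forward(h)
        self._prob = 1.0 / (1.0 + np.exp(-logits))
        return self._prob

    def backward(self, dprob: np.ndarray) -> None:
        """Accumulate parameter gradients given dLoss/dprob."""
        grad = (dprob * self._prob * (1.0 - self._prob)).astype(F32)
        grad = self.head.backward(grad)
        skip_grads = []
        for dec, up, c_skip in zip(reversed(self.dec), reversed(self.ups),
                                   reversed(self._skip_ch)):
            g = dec.backward(grad)
            skip_grads.append(g[:c_skip])
            grad = up.backward(g[c_skip:])
        grad = self.bottleneck.backward(grad)
        # skip_grads was collected shallow-first; the encoder unwinds
        # deepest-first
        for enc, pool, sg in zip(reversed(self.enc), reversed(self.pools),
                                 reversed(skip_grads)):
            grad = pool.backward(grad) + sg
            grad = enc.backward(grad)

    def zero_grad(self) -> None:
        for p in self.params:
            p[1][...] = 0.0

    def n_parameters(self) -> int:
        return int(sum(p[0].size for p in self.params))

    # -- checkpointing ----------------------------------------------------
    def state_dict(self) -> dict:
        return {f"p{i}": p[0] for i, p in enumerate(self.params)}

    def load_state_dict(self, state: dict) -> None:
        for i, p in enumerate(self.params):
            arr = np.asarray(state[f"p{i}"], dtype=F32)
            if arr.shape != p[0].shape:
                raise ValueError("checkpoint shape mismatch")
            p[0][...] = arr

    def save(self, path, extra: dict | None = None) -> None:
        meta = {
            "in_ch": self.in_ch, "out_ch": self.out_ch, "depth": self.depth,
            "base_width": self.base_width, "seed": self.seed,
        }
        np.savez(path, __meta__=np.array([repr(meta)]), **self.state_dict())

    @classmethod
    def load(cls, path) -> "UNet3D":
        with np.load(path, allow_pickle=False) as f:
            meta = eval(str(f["__meta__"][0]), {"__builtins__": {}})
            net = cls(**meta)
            net.load_state_dict({k: f[k] for k in f.files if k != "__meta__"})
        return net


class Adam:
    """Adam over a network's [param, grad] pairs."""

    def __init__(self, params: list, lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p[0]) for p in params]
        self.v = [np.zeros_like(p[0]) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
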