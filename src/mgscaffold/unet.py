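"""A small, dependency-free 2D U-Net in NumPy.

Encoder-decoder with skip connections: ``n_stages`` encoding stages of
``convs_per_stage`` 3x3 same-padded convolutions + ReLU, 2x2 max-pooling
between stages, feature maps doubling per stage; a mirrored decoder
using 2x2 up-convolutions and channel concatenation; a final 1x1
convolution head. Forward and backward passes are implemented with
im2col/col2im over BLAS matmuls, trained with Adam on a weighted
softmax (or sigmoid) cross-entropy.

Everything is float32, seeded and single-threaded deterministic: two
runs from the same seed produce bit-identical parameter states.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

# ---------------------------------------------------------------------------
# layers


class Conv2D:
    """k x k same-padded convolution with bias."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = c_in * k * k
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.W = (rng.standard_normal((c_out, fan_in)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k, self.c_in, self.c_out = k, c_in, c_out
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    @property
    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def n_params(self) -> int:
        return self.W.size + self.b.size

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        B, C, H, W = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        cols = np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5)).reshape(
            B, H * W, C * self.k * self.k
        )
        out = cols @ self.W.T + self.b
        if train:
            self._cache = (cols, (B, C, H, W))
        return np.ascontiguousarray(
            out.reshape(B, H, W, self.c_out).transpose(0, 3, 1, 2)
        )

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, (B, C, H, W) = self._cache
        p, k = self.k // 2, self.k
        d = dout.transpose(0, 2, 3, 1).reshape(B, H * W, self.c_out)
        self.dW += np.einsum("bpc,bpk->ck", d, cols, optimize=True)
        self.db += d.sum(axis=(0, 1))
        dcols = (d @ self.W).reshape(B, H, W, C, k, k)
        dxp = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + H, j : j + W] += dcols[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2
                )
        return dxp[:, :, p : p + H, p : p + W] if p else dxp


class ReLU:
    def __init__(self):
        self._mask = None

    params: list = []

    def n_params(self) -> int:
        return 0

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2:
    """2x2 max pooling, stride 2; input height/width must be even."""

    def __init__(self):
        self._cache = None

    params: list = []

    def n_params(self) -> int:
        return 0

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        B, C, H, W = x.shape
        xf = x.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xf = xf.reshape(B, C, H // 2, W // 2, 4)
        idx = xf.argmax(axis=-1)
        out = np.take_along_axis(xf, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, (B, C, H, W))
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        idx, (B, C, H, W) = self._cache
        dxf = np.zeros((B, C, H // 2, W // 2, 4), dtype=np.float32)
        np.put_along_axis(dxf, idx[..., None], dout[..., None], axis=-1)
        dx = dxf.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dx.reshape(B, C, H, W)


class UpConv2:
    """2x2 stride-2 transposed convolution (exact x2 upsampling)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * 4))
        self.W = (rng.standard_normal((c_in, c_out, 2, 2)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    @property
    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def n_params(self) -> int:
        return self.W.size + self.b.size

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        B, C, H, W = x.shape
        t = np.einsum("bcij,codq->boidjq", x, self.W, optimize=True)
        out = t.reshape(B, self.W.shape[1], 2 * H, 2 * W) + self.b[None, :, None, None]
        if train:
            self._x = x
        return out.astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        B, C, H, W = x.shape
        dt = dout.reshape(B, self.W.shape[1], H, 2, W, 2)
        self.dW += np.einsum("bcij,boidjq->codq", x, dt, optimize=True)
        self.db += dout.sum(axis=(0, 2, 3))
        return np.einsum("boidjq,codq->bcij", dt, self.W, optimize=True).astype(
            np.float32
        )


# ---------------------------------------------------------------------------
# network


class UNet2D:
    """2D U-Net; see module docstring for the architecture."""

    def __init__(
        self,
        n_stages: int = 3,
        convs_per_stage: int = 2,
        base_features: int = 16,
        kernel_size: int = 3,
        in_channels: int = 1,
        out_channels: int = 4,
        seed: int = 0,
    ):
        if n_stages < 1 or base_features < 1:
            raise ValueError("need n_stages >= 1 and base_features >= 1")
        if kernel_size % 2 == 0:
            raise ValueError("kernel size must be odd")
        rng = np.random.default_rng(seed)
        self.n_stages = n_stages
        self.convs_per_stage = convs_per_stage
        self.out_channels = out_channels
        feats = [base_features * 2**i for i in range(n_stages)]
        self.feats = feats

        self.enc_blocks: list[list] = []
        c_in = in_channels
        for f in feats:
            block = []
            for _ in range(convs_per_stage):
                block += [Conv2D(c_in, f, kernel_size, rng), ReLU()]
                c_in = f
            self.enc_blocks.append(block)
        self.pools = [MaxPool2() for _ in range(n_stages - 1)]

        self.upconvs: list[UpConv2] = []
        self.dec_blocks: list[list] = []
        for i in range(n_stages - 2, -1, -1):
            f = feats[i]
            self.upconvs.append(UpConv2(c_in, f, rng))
            c_in = 2 * f  # concat with skip
            block = []
            for _ in range(convs_per_stage):
                block += [Conv2D(c_in, f, kernel_size, rng), ReLU()]
                c_in = f
            self.dec_blocks.append(block)
        self.head = Conv2D(c_in, out_channels, 1, rng)
        self._skip_channels = feats[:-1]

    # -- plumbing ----------------------------------------------------------
    def _layers(self):
        for b in self.enc_blocks:
            yield from b
        yield from self.pools
        for u, b in zip(self.upconvs, self.dec_blocks):
            yield u
            yield from b
        yield self.head

    def parameters(self):
        for layer in self._layers():
            yield from layer.params

    def n_params(self) -> int:
        return sum(layer.n_params() for layer in self._layers())

    def zero_grad(self) -> None:
        for _, g in self.parameters():
            g[...] = 0.0

    @property
    def min_tile(self) -> int:
        return 2 ** (self.n_stages - 1)

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if x.shape[2] % self.min_tile or x.shape[3] % self.min_tile:
            raise ValueError(
                f"input height/width must be multiples of {self.min_tile}"
            )
        skips = []
        for i, block in enumerate(self.enc_blocks):
            for layer in block:
                x = layer.forward(x, train)
            if i < self.n_stages - 1:
                skips.append(x)
                x = self.pools[i].forward(x, train)
        for u, block in zip(self.upconvs, self.dec_blocks):
            x = u.forward(x, train)
            skip = skips.pop()
            x = np.concatenate([skip, x], axis=1)
            for layer in block:
                x = layer.forward(x, train)
        return self.head.forward(x, train)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        skip_grads: list[np.ndarray] = []
        for u, block in zip(reversed(self.upconvs), reversed(self.dec_blocks)):
            for layer in reversed(block):
                d = layer.backward(d)
            f = d.shape[1] // 2
            skip_grads.append(d[:, :f])
            d = u.backward(d[:, f:])
        for i in range(self.n_stages - 1, -1, -1):
            if i < self.n_stages - 1:
                d = self.pools[i].backward(d)
                d = d + skip_grads[i]
            for layer in reversed(self.enc_blocks[i]):
                d = layer.backward(d)

    # -- persistence -------------------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        return [p for p, _ in self.parameters()]

    def load_state(self, arrays: list[np.ndarray]) -> None:
        own = list(self.parameters())
        if len(own) != len(arrays):
            raise ValueError("checkpoint does not match architecture")
        for (p, _), a in zip(own, arrays):
            if p.shape != a.shape:
                raise ValueError("checkpoint shape mismatch")
            p[...] = a


# ---------------------------------------------------------------------------
# losses and optimizer


def softmax_cross_entropy(
    logits: np.ndarray, targets: np.ndarray, class_weights: np.ndarray
) -> tuple[float, np.ndarray]:
    """Weighted multi-class cross-entropy over (B, C, H, W) logits.

    Returns (mean loss, dloss/dlogits).
    """
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    probs = e / e.sum(axis=1, keepdims=True)
    B, C, H, W = logits.shape
    onehot = np.eye(C, dtype=np.float32)[targets].transpose(0, 3, 1, 2)
    w = class_weights[targets]  # (B, H, W)
    wsum = w.sum()
    logp = np.log(np.take_along_axis(probs, targets[:, None], axis=1)[:, 0] + 1e-12)
    loss = float(-(w * logp).sum() / wsum)
    dlogits = (probs - onehot) * w[:, None] / wsum
    return loss, dlogits.astype(np.float32)


def sigmoid_bce(
    logits: np.ndarray, targets: np.ndarray, pos_weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """Binary cross-entropy on (B, 1, H, W) logits vs {0,1} targets."""
    t = targets[:, None].astype(np.float32)
    p = 1.0 / (1.0 + np.exp(-logits))
    w = 1.0 + (pos_weight - 1.0) * t
    wsum = w.sum()
    loss = float(
        -(w * (t * np.log(p + 1e-12) + (1 - t) * np.log(1 - p + 1e-12))).sum() / wsum
    )
    return loss, (w * (p - t) / wsum).astype(np.float32)


class Adam:
    """Adam optimizer over a network's (param, grad) pairs."""

    def __init__(self, net: UNet2D, lr: float = 1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.net = net
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in net.parameters()]
        self.v = [np.zeros_like(p) for p, _ in net.parameters()]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for (p, g), m, v in zip(self.net.parameters(), self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
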