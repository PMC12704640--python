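"""Minimal CPU neural-network primitives for the 2D sulcal segmenter.

Small, explicit numpy implementations of 3x3/1x1 convolutions (im2col +
GEMM), ReLU, 2x2 average pooling, nearest-neighbour upsampling and the
AdamW optimizer, each with a hand-written backward pass.  Everything runs
in float32 and is deterministic given the initialization RNG.  This is
deliberately tiny: the segmentation task it serves is a 4-channel
encoder-decoder at 224x224, trained at desk scale on one CPU.
"""

from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("value", "grad", "decay")

    def __init__(self, value: np.ndarray, decay: bool = True):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.decay = decay  # weight decay applies to weights, not biases

    @property
    def size(self) -> int:
        return self.value.size


def _he(rng, shape, fan_in):
    return rng.standard_normal(shape).astype(np.float32) * np.sqrt(2.0 / fan_in)


def _im2col3(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N, C*9, H*W) patches for a padded 3x3 convolution.

    Built with nine strided copies straight into the target buffer; this is
    the training hot path.
    """
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    cols = np.empty((n, c, 9, h, w), dtype=x.dtype)
    for di in range(3):
        for dj in range(3):
            cols[:, :, di * 3 + dj] = xp[:, :, di:di + h, dj:dj + w]
    return cols.reshape(n, c * 9, h * w)


def _col2im3(gcols: np.ndarray, shape) -> np.ndarray:
    """Adjoint of :func:`_im2col3` (scatter-add of patch gradients)."""
    n, c, h, w = shape
    g = gcols.reshape(n, c, 9, h, w)
    padded = np.zeros((n, c, h + 2, w + 2), dtype=gcols.dtype)
    for di in range(3):
        for dj in range(3):
            padded[:, :, di:di + h, dj:dj + w] += g[:, :, di * 3 + dj]
    return padded[:, :, 1:-1, 1:-1]


class Conv3x3:
    """3x3 convolution, stride 1, zero padding 1."""

    def __init__(self, c_in: int, c_out: int, rng):
        self.c_in, self.c_out = c_in, c_out
        self.w = Param(_he(rng, (c_out, c_in * 9), c_in * 9))
        self.b = Param(np.zeros(c_out), decay=False)
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        cols = _im2col3(x)
        y = np.matmul(self.w.value, cols)  # (o,c9) @ (n,c9,l) -> (n,o,l)
        y += self.b.value[None, :, None]
        self._cache = (cols, (n, c, h, w))
        return y.reshape(n, self.c_out, h, w)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        cols, shape = self._cache
        n, c, h, w = shape
        g = np.ascontiguousarray(gy).reshape(n, self.c_out, h * w)
        self.w.grad += np.tensordot(g, cols, axes=([0, 2], [0, 2]))
        self.b.grad += g.sum(axis=(0, 2))
        gcols = np.matmul(self.w.value.T, g)
        return _col2im3(gcols, shape)


class Conv1x1:
    def __init__(self, c_in: int, c_out: int, rng):
        self.c_in, self.c_out = c_in, c_out
        self.w = Param(_he(rng, (c_out, c_in), c_in))
        self.b = Param(np.zeros(c_out), decay=False)
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        self._cache = x
        y = np.matmul(self.w.value, x.reshape(n, c, h * w))
        return y.reshape(n, self.c_out, h, w) + self.b.value[None, :, None, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x = self._cache
        n, c, h, w = x.shape
        g = np.ascontiguousarray(gy).reshape(n, self.c_out, h * w)
        xf = x.reshape(n, c, h * w)
        self.w.grad += np.tensordot(g, xf, axes=([0, 2], [0, 2]))
        self.b.grad += g.sum(axis=(0, 2))
        return np.matmul(self.w.value.T, g).reshape(n, c, h, w)


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy):
        return gy * self._mask


class AvgPool2:
    """2x2 average pooling, stride 2 (even spatial dims required)."""

    def params(self):
        return []

    def forward(self, x):
        n, c, h, w = x.shape
        self._shape = x.shape
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, gy):
        n, c, h, w = self._shape
        g = np.repeat(np.repeat(gy, 2, axis=2), 2, axis=3) * 0.25
        return g


class Upsample2:
    """Nearest-neighbour 2x upsampling."""

    def params(self):
        return []

    def forward(self, x):
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, gy):
        n, c, h, w = gy.shape
        return gy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class InstanceNorm:
    """Per-(sample, channel) spatial normalization with learnable affine.

    Keeps feature scales bounded through training: without normalization the
    activations of a plain conv stack grow without limit under region losses
    (which only constrain orderings, not scales), the logits saturate the
    sigmoids, and any channel that is wrong at saturation time freezes with
    vanishing gradients.
    """

    EPS = 1e-5

    def __init__(self, c):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c), decay=False)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x):
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.EPS)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return self.gamma.value[None, :, None, None] * xhat \
            + self.beta.value[None, :, None, None]

    def backward(self, gy):
        xhat, inv = self._cache
        self.gamma.grad += (gy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += gy.sum(axis=(0, 2, 3))
        g = gy * self.gamma.value[None, :, None, None]
        gm = g.mean(axis=(2, 3), keepdims=True)
        gxm = (g * xhat).mean(axis=(2, 3), keepdims=True)
        return inv * (g - gm - xhat * gxm)


class _ConvBlock:
    """(conv3x3 -> instance norm -> ReLU) x n_convs."""

    def __init__(self, c_in, c_out, rng, n_convs=2):
        self.layers = []
        for i in range(n_convs):
            self.layers.append(Conv3x3(c_in if i == 0 else c_out, c_out, rng))
            self.layers.append(InstanceNorm(c_out))
            self.layers.append(ReLU())

    def params(self):
        out = []
        for layer in self.layers:
            out += layer.params()
        return out

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, gy):
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy


class UNet2D:
    """Three-level encoder-decoder with skip connections.

    Channel widths (base, 2*base, 4*base); skips are concatenated before
    each decoder block; a final 1x1 projection yields one logit per label.
    Inference applies a per-channel sigmoid (multi-label, channels
    independent).
    """

    def __init__(self, in_channels=1, out_channels=4, base_width=6, seed=0,
                 slim_level1=False):
        rng = np.random.default_rng(seed)
        b = int(base_width)
        self.in_channels, self.out_channels, self.base_width = in_channels, out_channels, b
        self.slim_level1 = bool(slim_level1)
        # full-resolution blocks dominate CPU cost; the slim variant uses a
        # single conv in the full-resolution decoder block (the small preset
        # does this); the encoder keeps two convs for feature extraction
        n1 = 1 if slim_level1 else 2
        self.enc1 = _ConvBlock(in_channels, b, rng)
        self.pool1 = AvgPool2()
        self.enc2 = _ConvBlock(b, 2 * b, rng)
        self.pool2 = AvgPool2()
        self.bott = _ConvBlock(2 * b, 4 * b, rng)
        self.up2 = Upsample2()
        self.dec2 = _ConvBlock(4 * b + 2 * b, 2 * b, rng)
        self.up1 = Upsample2()
        self.dec1 = _ConvBlock(2 * b + b, b, rng, n_convs=n1)
        # the head also sees the raw input planes (identity skip): absolute
        # position and intensity stay linearly available at the output, which
        # a narrow trunk would otherwise have to carry through every block
        self.head = Conv1x1(b + in_channels, out_channels, rng)
        # start every channel near-empty (p ~ 0.27): the thin sulcal labels
        # cover a tiny pixel fraction, and an all-foreground start is a slow
        # local trap for the Dice loss
        self.head.b.value[...] = -1.0

    def params(self):
        out = []
        for blk in (self.enc1, self.enc2, self.bott, self.dec2, self.dec1, self.head):
            out += blk.params()
        return out

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.params())

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Logits of shape (N, out_channels, H, W); H, W divisible by 4."""
        x = np.ascontiguousarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[1] != self.in_channels:
            raise ValueError("expected input of shape (N, C_in, H, W)")
        if x.shape[2] % 4 or x.shape[3] % 4:
            raise ValueError("spatial dimensions must be divisible by 4")
        e1 = self.enc1.forward(x)
        e2 = self.enc2.forward(self.pool1.forward(e1))
        bt = self.bott.forward(self.pool2.forward(e2))
        d2_in = np.concatenate([self.up2.forward(bt), e2], axis=1)
        d2 = self.dec2.forward(d2_in)
        d1_in = np.concatenate([self.up1.forward(d2), e1], axis=1)
        d1 = self.dec1.forward(d1_in)
        return self.head.forward(np.concatenate([d1, x], axis=1))

    def backward(self, glogits: np.ndarray) -> np.ndarray:
        """Accumulate parameter gradients; returns the input gradient.

        Encoder outputs feed both the pooling path and a skip, so each
        encoder block receives the sum of both gradient contributions.
        """
        b = self.base_width
        g = self.head.backward(np.ascontiguousarray(glogits, dtype=np.float32))
        g, g_x_skip = g[:, :b], g[:, b:]  # input identity skip needs no grad
        g_cat1 = self.dec1.backward(g)
        g_up1, g_e1_skip = g_cat1[:, :2 * b], g_cat1[:, 2 * b:]
        g_cat2 = self.dec2.backward(self.up1.backward(g_up1))
        g_up2, g_e2_skip = g_cat2[:, :4 * b], g_cat2[:, 4 * b:]
        g_p2 = self.bott.backward(self.up2.backward(g_up2))
        g_e2 = self.pool2.backward(g_p2) + g_e2_skip
        g_p1 = self.enc2.backward(g_e2)
        g_e1 = self.pool1.backward(g_p1) + g_e1_skip
        return self.enc1.backward(g_e1) + g_x_skip

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0.0

    # --- weight state -------------------------------------------------------
    def get_weights(self):
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights):
        for p, w in zip(self.params(), weights):
            if p.value.shape != w.shape:
                raise ValueError("weight shape mismatch")
            p.value[...] = np.asarray(w, dtype=np.float32)


class AdamW:
    """Adam with decoupled weight decay (applied to weights, not biases)."""

    def __init__(self, params, lr=5e-3, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.02):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            if p.decay and self.weight_decay:
                p.value *= 1.0 - self.lr * self.weight_decay
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
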