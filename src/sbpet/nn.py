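"""Minimal 3-D convolutional network stack with explicit backpropagation.

Pure numpy: convolutions are im2col + GEMM, gradients are hand-derived and
checked against finite differences in the test suite.  The stack provides
exactly what the sketcher/refiner generators and PatchGAN discriminators
need — 3-D convolution (stride 1 or 2, 'same' zero padding), nearest
upsampling, leaky ReLU, sigmoid, channel concatenation, and Adam.

Layers cache their forward activations; ``backward`` must be called while
the caches from the matching ``forward`` are alive.  Networks are small
enough (desk preset) that this single-tape discipline is all the training
loop requires.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv3d",
    "LeakyReLU",
    "Upsample2",
    "UNet3D",
    "PatchGAN3d",
    "Adam",
    "sigmoid",
    "unet_param_shapes",
    "patchgan_param_shapes",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Conv3d:
    """3-D convolution, kernel k^3, stride s, zero padding k//2 ('same')."""

    def __init__(self, in_ch, out_ch, k=3, stride=1, rng=None, dtype=np.float32):
        self.in_ch, self.out_ch, self.k, self.stride = in_ch, out_ch, k, stride
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * k**3
        self.W = (rng.standard_normal((out_ch, in_ch, k, k, k)) * np.sqrt(2.0 / fan_in)).astype(dtype)
        self.b = np.zeros(out_ch, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    @property
    def params(self):
        return {"W": self.W, "b": self.b}

    @property
    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s, p = self.k, self.stride, self.k // 2
        n, c = x.shape[:2]
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else x
        win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
        win = win[:, :, ::s, ::s, ::s]  # (n, c, Do, Ho, Wo, k, k, k)
        do, ho, wo = win.shape[2:5]
        col = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(n * do * ho * wo, c * k**3)
        wmat = self.W.reshape(self.out_ch, -1).T
        out = col @ wmat + self.b
        out = out.reshape(n, do, ho, wo, self.out_ch).transpose(0, 4, 1, 2, 3)
        self._cache = (col, x.shape, (do, ho, wo))
        return np.ascontiguousarray(out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        col, x_shape, (do, ho, wo) = self._cache
        k, s, p = self.k, self.stride, self.k // 2
        n, c = x_shape[:2]
        dmat = dout.transpose(0, 2, 3, 4, 1).reshape(-1, self.out_ch)
        self.dW += (col.T @ dmat).T.reshape(self.W.shape)
        self.db += dmat.sum(axis=0)
        dcol = dmat @ self.W.reshape(self.out_ch, -1)
        dcol = dcol.reshape(n, do, ho, wo, c, k, k, k).transpose(0, 4, 5, 6, 7, 1, 2, 3)
        padded = (x_shape[2] + 2 * p, x_shape[3] + 2 * p, x_shape[4] + 2 * p)
        dxp = np.zeros((n, c) + padded, dtype=dout.dtype)
        for a in range(k):
            for bb in range(k):
                for cc in range(k):
                    dxp[:, :, a : a + s * do : s, bb : bb + s * ho : s, cc : cc + s * wo : s] += dcol[:, :, a, bb, cc]
        self._cache = None
        if p:
            return dxp[:, :, p:-p, p:-p, p:-p]
        return dxp


class LeakyReLU:
    def __init__(self, alpha=0.2):
        self.alpha = alpha
        self._mask = None
        self.params = {}
        self.grads = {}

    def forward(self, x):
        self._mask = x >= 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, dout):
        return np.where(self._mask, dout, self.alpha * dout)


class Upsample2:
    """Nearest-neighbor x2 upsampling along all spatial axes."""

    params: dict = {}
    grads: dict = {}

    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)

    def backward(self, dout):
        n, c, d, h, w = dout.shape
        return dout.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2).sum(axis=(3, 5, 7))


# ---------------------------------------------------------------------------
# architecture shape bookkeeping (shared by the builders and the counter)
# ---------------------------------------------------------------------------

def unet_param_shapes(in_ch: int, base: int, depth: int, out_ch: int = 1):
    """Ordered (name, W-shape) pairs for the U-Net generator; biases implied."""
    ch = [base * 2**i for i in range(depth)]
    shapes = []
    prev = in_ch
    for i in range(depth):
        shapes.append((f"enc{i}_a", (ch[i], prev, 3, 3, 3)))
        shapes.append((f"enc{i}_b", (ch[i], ch[i], 3, 3, 3)))
        prev = ch[i]
        if i < depth - 1:
            shapes.append((f"down{i}", (ch[i + 1], ch[i], 3, 3, 3)))
            prev = ch[i + 1]
    for i in reversed(range(depth - 1)):
        shapes.append((f"up{i}", (ch[i], ch[i + 1], 3, 3, 3)))
        shapes.append((f"merge{i}", (ch[i], 2 * ch[i], 3, 3, 3)))
    shapes.append(("final", (out_ch, ch[0], 1, 1, 1)))
    return shapes


def patchgan_param_shapes(in_ch: int, base: int, n_layers: int):
    shapes = []
    prev = in_ch
    c = base
    for i in range(n_layers):
        shapes.append((f"d{i}", (c, prev, 3, 3, 3)))
        prev = c
        c *= 2
    shapes.append(("out", (1, prev, 3, 3, 3)))
    return shapes


def count_shapes(shapes) -> int:
    """Trainable parameters (weights + one bias per output channel)."""
    return int(sum(np.prod(s) + s[0] for _, s in shapes))


class UNet3D:
    """Symmetric 3-D U-Net: conv-conv encoder levels joined by stride-2
    downsampling, nearest-upsample decoder with skip concatenation, linear
    1x1x1 output head.  Spatial extents must be divisible by 2**(depth-1)."""

    def __init__(self, in_ch, base, depth, out_ch=1, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.depth = depth
        self.dtype = dtype
        ch = [base * 2**i for i in range(depth)]
        conv = lambda i, o, **kw: Conv3d(i, o, rng=rng, dtype=dtype, **kw)
        self.enc = []
        prev = in_ch
        for i in range(depth):
            self.enc.append((conv(prev, ch[i]), LeakyReLU(), conv(ch[i], ch[i]), LeakyReLU()))
            prev = ch[i]
            if i < depth - 1:
                self.enc[-1] = self.enc[-1] + (conv(ch[i], ch[i + 1], stride=2), LeakyReLU())
                prev = ch[i + 1]
        self.dec = []
        for i in reversed(range(depth - 1)):
            self.dec.append((Upsample2(), conv(ch[i + 1], ch[i]), LeakyReLU(), conv(2 * ch[i], ch[i]), LeakyReLU()))
        self.final = conv(ch[0], out_ch, k=1)
        self._skip_ch = ch

    def layers(self):
        for block in self.enc:
            yield from block
        for block in self.dec:
            yield from block
        yield self.final

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim != 5:
            raise ValueError("expected (batch, channel, D, H, W) input")
        stride_div = 2 ** (self.depth - 1)
        if any(s % stride_div for s in x.shape[2:]):
            raise ValueError(f"spatial extents must be divisible by {stride_div}")
        skips = []
        h = x
        for i, block in enumerate(self.enc):
            h = block[1].forward(block[0].forward(h))
            h = block[3].forward(block[2].forward(h))
            if i < self.depth - 1:
                skips.append(h)
                h = block[5].forward(block[4].forward(h))
        for block, skip in zip(self.dec, reversed(skips)):
            h = block[2].forward(block[1].forward(block[0].forward(h)))
            h = np.concatenate([h, skip], axis=1)
            h = block[4].forward(block[3].forward(h))
        return self.final.forward(h)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.final.backward(dout)
        dskips = []  # collected shallowest-first -> indexed by encoder level
        for block in reversed(self.dec):
            d = block[3].backward(block[4].backward(d))
            # concat split: first half went through the up path, second is the skip
            half = d.shape[1] // 2
            d_up, d_skip = d[:, :half], d[:, half:]
            dskips.append(d_skip)
            d = block[0].backward(block[1].backward(block[2].backward(d_up)))
        for i in range(self.depth - 1, -1, -1):
            block = self.enc[i]
            if i < self.depth - 1:
                d = block[4].backward(block[5].backward(d))
                d = d + dskips[i]
            d = block[2].backward(block[3].backward(d))
            d = block[0].backward(block[1].backward(d))
        return d

    def zero_grad(self):
        for layer in self.layers():
            for g in layer.grads.values():
                g[...] = 0


class PatchGAN3d:
    """Patch discriminator: stride-2 conv stack ending in per-patch
    probabilities (sigmoid).  Conditioned by channel-concatenated inputs."""

    def __init__(self, in_ch, base, n_layers, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.dtype = dtype
        self.blocks = []
        prev = in_ch
        c = base
        for _ in range(n_layers):
            self.blocks.append((Conv3d(prev, c, stride=2, rng=rng, dtype=dtype), LeakyReLU()))
            prev = c
            c *= 2
        self.out = Conv3d(prev, 1, rng=rng, dtype=dtype)
        self._sig = None

    def layers(self):
        for conv, act in self.blocks:
            yield conv
            yield act
        yield self.out

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = np.asarray(x, dtype=self.dtype)
        for conv, act in self.blocks:
            h = act.forward(conv.forward(h))
        logits = self.out.forward(h)
        self._sig = sigmoid(logits)
        return self._sig

    def backward(self, dprob: np.ndarray) -> np.ndarray:
        d = dprob * self._sig * (1.0 - self._sig)
        d = self.out.backward(d)
        for conv, act in reversed(self.blocks):
            d = conv.backward(act.backward(d))
        return d

    def zero_grad(self):
        for layer in self.layers():
            for g in layer.grads.values():
                g[...] = 0


def clear_caches(net) -> None:
    """Drop forward-pass caches (large im2col buffers) from a network."""
    for layer in net.layers():
        for attr in ("_cache", "_mask"):
            if hasattr(layer, attr):
                setattr(layer, attr, None)
    if hasattr(net, "_sig"):
        net._sig = None


class Adam:
    """Adam over the parameters of one or more networks."""

    def __init__(self, nets, beta1=0.9, beta2=0.999, eps=1e-8):
        self.slots = []
        for net in nets if isinstance(nets, (list, tuple)) else [nets]:
            for layer in net.layers():
                for name in layer.params:
                    p, g = layer.params[name], layer.grads[name]
                    self.slots.append([p, g, np.zeros_like(p), np.zeros_like(p)])
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1**self.t
        corr2 = 1.0 - b2**self.t
        for p, g, m, v in self.slots:
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)
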