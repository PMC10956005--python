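"""Reverse-mode automatic differentiation over numpy arrays.

The dual-domain losses chain image-domain networks through acquisition-domain
transforms (Radon / Fourier) and back, so every building block here records a
closed-form vector-Jacobian product on a tape.  The op set is deliberately
small: dense/sparse linear maps, 3x3 convolutions, leaky ReLU, 2x2 pooling and
upsampling, channel concatenation, and mean-absolute-error reductions — enough
to express the generators and every consistency loss while staying on one CPU.

All arithmetic is float64 and single-threaded numpy, which makes repeated runs
bit-identical for a fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "param",
    "const",
    "add",
    "sub",
    "scale",
    "mul_const",
    "conv2d",
    "instance_norm",
    "leaky_relu",
    "avg_pool2",
    "upsample2",
    "concat_channels",
    "linear",
    "linop",
    "l1_mean",
    "weighted_sum",
    "Adam",
    "numeric_grad",
]


class Tensor:
    """A numpy array plus the tape bookkeeping needed for backprop."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self):
        self.grad = None

    def backward(self):
        """Seed a scalar output with gradient 1 and sweep the tape."""
        if self.data.ndim != 0 and self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _accum(t: Tensor, g: np.ndarray) -> None:
    if t.grad is None:
        t.grad = np.array(g, dtype=np.float64, copy=True)
    else:
        t.grad += g


def param(data) -> Tensor:
    return Tensor(data, requires_grad=True)


def const(data) -> Tensor:
    return Tensor(data)


def add(a: Tensor, b: Tensor) -> Tensor:
    if a.data.shape != b.data.shape:
        raise ValueError("add requires matching shapes")

    def backward(g):
        _accum(a, g)
        _accum(b, g)

    return Tensor(a.data + b.data, (a, b), backward)


def sub(a: Tensor, b: Tensor) -> Tensor:
    if a.data.shape != b.data.shape:
        raise ValueError("sub requires matching shapes")

    def backward(g):
        _accum(a, g)
        _accum(b, -g)

    return Tensor(a.data - b.data, (a, b), backward)


def scale(a: Tensor, s: float) -> Tensor:
    s = float(s)

    def backward(g):
        _accum(a, s * g)

    return Tensor(s * a.data, (a,), backward)


def mul_const(a: Tensor, c) -> Tensor:
    """Elementwise product with a fixed array (e.g. a sampling mask)."""
    c = np.asarray(c, dtype=np.float64)

    def backward(g):
        _accum(a, c * g)

    return Tensor(a.data * c, (a,), backward)


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padded stride-1 2-D convolution; x (C,H,W), w (F,C,kh,kw), b (F,)."""
    C, H, W = x.data.shape
    F, Cw, kh, kw = w.data.shape
    if Cw != C:
        raise ValueError("channel mismatch in conv2d")
    ph, pw = kh // 2, kw // 2
    xpad = np.pad(x.data, ((0, 0), (ph, ph), (pw, pw)))
    patches = np.empty((C, kh, kw, H, W))
    for i in range(kh):
        for j in range(kw):
            patches[:, i, j] = xpad[:, i : i + H, j : j + W]
    out = np.tensordot(w.data, patches, axes=([1, 2, 3], [0, 1, 2]))
    out += b.data[:, None, None]

    def backward(g):
        _accum(b, g.sum(axis=(1, 2)))
        _accum(w, np.tensordot(g, patches, axes=([1, 2], [3, 4])))
        gxpad = np.zeros_like(xpad)
        for i in range(kh):
            for j in range(kw):
                gxpad[:, i : i + H, j : j + W] += np.tensordot(
                    w.data[:, :, i, j], g, axes=([0], [0])
                )
        _accum(x, gxpad[:, ph : ph + H, pw : pw + W])

    return Tensor(out, (x, w, b), backward)


def leaky_relu(x: Tensor, alpha: float = 0.1) -> Tensor:
    mask = x.data > 0
    out = np.where(mask, x.data, alpha * x.data)

    def backward(g):
        _accum(x, np.where(mask, g, alpha * g))

    return Tensor(out, (x,), backward)


def avg_pool2(x: Tensor) -> Tensor:
    C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError("avg_pool2 requires even spatial dims")
    out = x.data.reshape(C, H // 2, 2, W // 2, 2).mean(axis=(2, 4))

    def backward(g):
        gx = np.repeat(np.repeat(g, 2, axis=1), 2, axis=2) / 4.0
        _accum(x, gx)

    return Tensor(out, (x,), backward)


def upsample2(x: Tensor) -> Tensor:
    out = np.repeat(np.repeat(x.data, 2, axis=1), 2, axis=2)

    def backward(g):
        C, H2, W2 = g.shape
        _accum(x, g.reshape(C, H2 // 2, 2, W2 // 2, 2).sum(axis=(2, 4)))

    return Tensor(out, (x,), backward)


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-channel normalization of a (C,H,W) tensor with affine parameters.

    Keeps activation scale — and hence the network Jacobian — of order one,
    which matters when losses chain several networks together.
    """
    C = x.data.shape[0]
    flat = x.data.reshape(C, -1)
    mu = flat.mean(axis=1)
    var = flat.var(axis=1)
    inv = 1.0 / np.sqrt(var + eps)
    y = (flat - mu[:, None]) * inv[:, None]
    out = (gamma.data[:, None] * y + beta.data[:, None]).reshape(x.data.shape)

    def backward(g):
        g2 = g.reshape(C, -1)
        _accum(beta, g2.sum(axis=1))
        _accum(gamma, (g2 * y).sum(axis=1))
        gy = g2 * gamma.data[:, None]
        n = y.shape[1]
        gx = inv[:, None] * (
            gy - gy.mean(axis=1, keepdims=True) - y * (gy * y).mean(axis=1, keepdims=True)
        )
        _accum(x, gx.reshape(x.data.shape))

    return Tensor(out, (x, gamma, beta), backward)


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    ca = a.data.shape[0]

    def backward(g):
        _accum(a, g[:ca])
        _accum(b, g[ca:])

    return Tensor(np.concatenate([a.data, b.data], axis=0), (a, b), backward)


def linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Affine map along the last axis: y[..., e] = sum_d x[..., d] w[d, e] + b[e]."""
    out = x.data @ w.data + b.data

    def backward(g):
        _accum(x, g @ w.data.T)
        x2 = x.data.reshape(-1, x.data.shape[-1])
        g2 = g.reshape(-1, g.shape[-1])
        _accum(w, x2.T @ g2)
        _accum(b, g2.sum(axis=0))

    return Tensor(out, (x, w, b), backward)


def linop(x: Tensor, forward_fn, adjoint_fn) -> Tensor:
    """Wrap an arbitrary linear operator given its forward and exact adjoint.

    Used for the Radon projector, filtered back projection and the centered
    DFT, whose vector-Jacobian products are their adjoints.
    """
    out = forward_fn(x.data)

    def backward(g):
        _accum(x, adjoint_fn(g))

    return Tensor(out, (x,), backward)


def l1_mean(x: Tensor, weight: float = 1.0) -> Tensor:
    """weight * mean(|x|); the empirical L1 expectation used by every loss term."""
    weight = float(weight)
    out = weight * np.mean(np.abs(x.data))

    def backward(g):
        _accum(x, g * weight * np.sign(x.data) / x.data.size)

    return Tensor(out, (x,), backward)


def weighted_sum(terms, weights=None) -> Tensor:
    """Scalar combination sum_i w_i * terms_i of 0-d tensors."""
    terms = list(terms)
    if weights is None:
        weights = [1.0] * len(terms)
    weights = [float(w) for w in weights]
    out = sum(w * t.data for w, t in zip(weights, terms))

    def backward(g):
        for w, t in zip(weights, terms):
            _accum(t, g * w)

    return Tensor(out, tuple(terms), backward)


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def numeric_grad(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite differences of a scalar function; test utility."""
    g = np.zeros_like(x, dtype=np.float64)
    flat = x.reshape(-1)
    gflat = g.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        fp = f(x)
        flat[i] = orig - eps
        fm = f(x)
        flat[i] = orig
        gflat[i] = (fp - fm) / (2 * eps)
    return g
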