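"""Minimal reverse-mode autodiff engine for small convolutional networks.

Supports exactly the operations the segmentation models need — same-pad
2-D convolution (im2col), ReLU, 2x2 max pooling, nearest-neighbour
upsampling, channel concatenation and sparse softmax cross-entropy — plus
an Adam optimizer.  Arrays are NCHW float64.  The engine is intentionally
small: it exists to make the reduced-width segmentation model trainable
and testable on synthetic data, not to compete with a general framework.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Var",
    "Param",
    "backward",
    "conv2d",
    "relu",
    "maxpool2",
    "upsample2",
    "concat",
    "softmax",
    "softmax_cross_entropy",
    "Adam",
    "he_init",
]


class Var:
    """Node in the computation graph."""

    __slots__ = ("value", "grad", "_parents", "_backward")

    def __init__(self, value, parents=(), backward_fn=None):
        self.value = np.asarray(value, dtype=float)
        self.grad = None
        self._parents = parents
        self._backward = backward_fn

    @property
    def shape(self):
        return self.value.shape

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.value)
        self.grad += g


class Param(Var):
    """Leaf variable with persistent value, updated by the optimizer."""

    __slots__ = ("trainable",)

    def __init__(self, value, trainable: bool = True):
        self.value = np.asarray(value, dtype=float)
        self.grad = None
        self._parents = ()
        self._backward = None
        self.trainable = trainable


def backward(loss: Var) -> None:
    """Reverse-mode sweep from a scalar loss."""
    topo: list[Var] = []
    seen: set[int] = set()
    stack = [(loss, False)]
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
    loss.grad = np.ones_like(loss.value)
    for node in reversed(topo):
        if node._backward is not None and node.grad is not None:
            node._backward(node.grad)


def he_init(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in = int(np.prod(shape[1:])) if len(shape) > 1 else shape[0]
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*k*k) with same padding."""
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # win: (N, C, H, W, k, k) -> (N, H, W, C, k, k)
    n, c, h, w = x.shape
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
    return np.ascontiguousarray(cols)


def conv2d(x: Var, weight: Param, bias: Param) -> Var:
    """Same-padding stride-1 convolution; weight (Cout, Cin, k, k)."""
    cout, cin, k, _ = weight.value.shape
    n, c, h, w = x.value.shape
    if c != cin:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight {cin}")
    cols = _im2col(x.value, k)
    wmat = weight.value.reshape(cout, cin * k * k).T
    out = (cols @ wmat + bias.value).reshape(n, h, w, cout).transpose(0, 3, 1, 2)

    def _bw(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(n * h * w, cout)
        if weight.trainable:
            weight._accumulate((cols.T @ gmat).T.reshape(weight.value.shape))
            bias._accumulate(gmat.sum(axis=0))
        # dX = conv(g, W flipped and transposed)
        w_flip = weight.value[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (Cin, Cout, k, k)
        gcols = _im2col(g, k)
        dx = (gcols @ w_flip.reshape(cin, cout * k * k).T).reshape(n, h, w, cin)
        x._accumulate(dx.transpose(0, 3, 1, 2))

    return Var(out, parents=(x, weight, bias), backward_fn=_bw)


def relu(x: Var) -> Var:
    mask = x.value > 0
    out = x.value * mask

    def _bw(g):
        x._accumulate(g * mask)

    return Var(out, parents=(x,), backward_fn=_bw)


def maxpool2(x: Var) -> Var:
    n, c, h, w = x.value.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2 requires even spatial dims")
    win = x.value.reshape(n, c, h // 2, 2, w // 2, 2)
    out = win.max(axis=(3, 5))

    def _bw(g):
        m = win == out[:, :, :, None, :, None]
        m = m / m.sum(axis=(3, 5), keepdims=True)
        dx = (m * g[:, :, :, None, :, None]).reshape(n, c, h, w)
        x._accumulate(dx)

    return Var(out, parents=(x,), backward_fn=_bw)


def upsample2(x: Var, factor: int = 2) -> Var:
    out = x.value.repeat(factor, axis=2).repeat(factor, axis=3)
    n, c, h, w = x.value.shape

    def _bw(g):
        dx = g.reshape(n, c, h, factor, w, factor).sum(axis=(3, 5))
        x._accumulate(dx)

    return Var(out, parents=(x,), backward_fn=_bw)


def concat(xs: list[Var]) -> Var:
    out = np.concatenate([v.value for v in xs], axis=1)
    splits = np.cumsum([v.value.shape[1] for v in xs])[:-1]

    def _bw(g):
        for v, piece in zip(xs, np.split(g, splits, axis=1)):
            v._accumulate(piece)

    return Var(out, parents=tuple(xs), backward_fn=_bw)


def softmax(logits: np.ndarray) -> np.ndarray:
    """Channel-wise softmax of an (N, K, H, W) array (plain numpy helper)."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: Var, labels: np.ndarray) -> Var:
    """Mean per-pixel sparse categorical cross-entropy.

    ``labels`` is an (N, H, W) integer array of class indices.
    """
    n, k, h, w = logits.value.shape
    p = softmax(logits.value)
    idx = (np.arange(n)[:, None, None], labels, np.arange(h)[None, :, None], np.arange(w)[None, None, :])
    picked = p[idx[0], labels, idx[2], idx[3]]
    loss = -np.log(np.clip(picked, 1e-12, None)).mean()

    def _bw(g):
        grad = p.copy()
        onehot = np.zeros_like(grad)
        onehot[idx[0], labels, idx[2], idx[3]] = 1.0
        grad = (grad - onehot) * (g / (n * h * w))
        logits._accumulate(grad)

    return Var(np.asarray(loss), parents=(logits,), backward_fn=_bw)


class Adam:
    """Adam optimizer over a list of Params (non-trainable ones are skipped)."""

    def __init__(self, params: list[Param], lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = [p for p in params if p.trainable]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
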