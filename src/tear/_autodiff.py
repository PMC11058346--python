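"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the numerical core behind the TEAR network and its composite loss.
It implements a tape-based ``Tensor`` supporting the operations the model
needs (broadcasting arithmetic, matmul, reductions, reshapes, slicing,
softmax/layer-norm building blocks, strided "same" convolution and nearest
up-sampling) plus Adam/AdamW optimizers.  Everything is float64 and
single-threaded, so results are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "Adam", "AdamW", "conv2d_same", "upsample_nearest"]

_INV_SQRT2 = 1.0 / math.sqrt(2.0)
_INV_SQRT2PI = 1.0 / math.sqrt(2.0 * math.pi)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an attached gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    # keep numpy from elementwise-dispatching `ndarray <op> Tensor`; Python
    # then falls back to the reflected Tensor operators
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()
        self.name = name

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor{self.shape}(requires_grad={self.requires_grad})"

    # -- autograd plumbing ----------------------------------------------------
    def _make(self, data: np.ndarray, parents: tuple["Tensor", ...],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        for node in topo:
            node.grad = None if node._backward is not None else node.grad
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad = self.grad + grad

    # -- arithmetic -----------------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data ** 2,
                                          other.shape))

        return self._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        def backward(g):
            self._accum(g * p * self.data ** (p - 1))

        return self._make(self.data ** p, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                gs = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(gs, self.shape))
            if other.requires_grad:
                go = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(go, other.shape))

        return self._make(self.data @ other.data, (self, other), backward)

    def __getitem__(self, idx):
        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return self._make(self.data[idx], (self,), backward)

    # -- reductions / reshapes ------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy()
                            if np.ndim(g) else np.full_like(self.data, g))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims),
                          (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else (
            np.prod([self.shape[a] for a in np.atleast_1d(axis)]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def backward(g):
            self._accum(g.reshape(self.shape))

        return self._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            self._accum(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            self._accum(g * 0.5 / out_data)

        return self._make(out_data, (self,), backward)

    def abs(self):
        def backward(g):
            self._accum(g * np.sign(self.data))

        return self._make(np.abs(self.data), (self,), backward)

    def clip(self, lo: float, hi: float):
        """Clamp; gradient is passed through strictly inside [lo, hi]."""
        inside = (self.data > lo) & (self.data < hi)

        def backward(g):
            self._accum(g * inside)

        return self._make(np.clip(self.data, lo, hi), (self,), backward)

    def clip_through(self, lo: float, hi: float):
        """Clamp with a straight-through gradient (backward acts as the
        identity).  Used as the decoder's output squashing: bounded values
        without the dead gradient zones of a saturating sigmoid."""

        def backward(g):
            self._accum(g)

        return self._make(np.clip(self.data, lo, hi), (self,), backward)

    def maximum(self, floor: float):
        mask = self.data > floor

        def backward(g):
            self._accum(g * mask)

        return self._make(np.maximum(self.data, floor), (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def gelu(self):
        """Exact GELU x*Phi(x) with the erf form."""
        x = self.data
        phi = 0.5 * (1.0 + erf(x * _INV_SQRT2))

        def backward(g):
            self._accum(g * (phi + x * np.exp(-0.5 * x * x) * _INV_SQRT2PI))

        return self._make(x * phi, (self,), backward)

    # -- composite building blocks --------------------------------------------
    def softmax(self, axis: int = -1):
        z = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = z.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def layer_norm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-6):
        """Normalize over the last axis, then scale/shift."""
        mu = self.mean(axis=-1, keepdims=True)
        xc = self - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xhat = xc / (var + eps).sqrt()
        return xhat * gamma + beta


# -- convolution -----------------------------------------------------------


def _same_pad(n: int, k: int, s: int) -> tuple[int, int, int]:
    """'same' padding with ceil-mode output length: out = ceil(n/s)."""
    out = -(-n // s)
    total = max((out - 1) * s + k - n, 0)
    return out, total // 2, total - total // 2


def conv2d_same(x: Tensor, w: Tensor, b: Tensor, stride: int = 1) -> Tensor:
    """2-D convolution, NCHW layout, zero 'same' padding, ceil-mode output.

    x: (B, C, H, W); w: (F, C, k, k); b: (F,).  Output (B, F, H', W') with
    H' = ceil(H/stride).
    """
    B, C, H, W = x.shape
    F, Cw, k, _ = w.shape
    if Cw != C:
        raise ValueError(f"channel mismatch: input {C}, weight {Cw}")
    oh, ph0, ph1 = _same_pad(H, k, stride)
    ow, pw0, pw1 = _same_pad(W, k, stride)
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph0, ph1), (pw0, pw1)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]          # (B, C, oh, ow, k, k)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B * oh * ow, C * k * k)
    wmat = w.data.reshape(F, C * k * k)
    out_data = (cols @ wmat.T).reshape(B, oh, ow, F).transpose(0, 3, 1, 2)
    out_data = out_data + b.data.reshape(1, F, 1, 1)

    def backward(g):
        gcols = g.transpose(0, 2, 3, 1).reshape(B * oh * ow, F)
        if w.requires_grad:
            w._accum((gcols.T @ cols).reshape(w.shape))
        if b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            if stride == 1 and oh == H and ow == W:
                # dX is the correlation of the output gradient with the
                # spatially flipped, channel-transposed kernel — one matmul
                wflip = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
                gp = np.pad(g, ((0, 0), (0, 0),
                                (k - 1 - ph0, k - 1 - ph1),
                                (k - 1 - pw0, k - 1 - pw1)))
                gwin = np.lib.stride_tricks.sliding_window_view(
                    gp, (k, k), axis=(2, 3))
                gc = gwin.transpose(0, 2, 3, 1, 4, 5).reshape(
                    B * H * W, F * k * k)
                gx = (gc @ wflip.reshape(C, F * k * k).T).reshape(
                    B, H, W, C).transpose(0, 3, 1, 2)
                x._accum(gx)
            else:
                gx_cols = (gcols @ wmat).reshape(B, oh, ow, C, k, k)
                gxp = np.zeros_like(xp)
                for di in range(k):
                    for dj in range(k):
                        gxp[:, :, di:di + oh * stride:stride,
                            dj:dj + ow * stride:stride] += \
                            gx_cols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
                x._accum(gxp[:, :, ph0:ph0 + H, pw0:pw0 + W])

    out = Tensor(out_data)
    parents = tuple(t for t in (x, w, b) if t.requires_grad)
    if parents:
        out.requires_grad = True
        out._parents = parents
        out._backward = backward
    return out


def upsample_nearest(x: Tensor, factor: int) -> Tensor:
    """Nearest-neighbour up-sampling of an NCHW tensor by an integer factor."""
    if factor == 1:
        return x
    B, C, H, W = x.shape
    out_data = x.data.repeat(factor, axis=2).repeat(factor, axis=3)

    def backward(g):
        gsum = g.reshape(B, C, H, factor, W, factor).sum(axis=(3, 5))
        x._accum(gsum)

    out = Tensor(out_data)
    if x.requires_grad:
        out.requires_grad = True
        out._parents = (x,)
        out._backward = backward
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    """Stack tensors along a new axis (used to batch per-image scalars)."""
    data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        slices = np.moveaxis(g, axis, 0)
        for t, gs in zip(tensors, slices):
            if t.requires_grad:
                t._accum(np.asarray(gs))

    out = Tensor(data)
    parents = tuple(t for t in tensors if t.requires_grad)
    if parents:
        out.requires_grad = True
        out._parents = parents
        out._backward = backward
    return out


# -- optimizers -------------------------------------------------------------


class Adam:
    """Adam with optional decoupled weight decay (AdamW when decay > 0)."""

    def __init__(self, params: Iterable[Tensor], lr: float = 5e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def clip_grad_norm(self, max_norm: float) -> float:
        """Scale all gradients so their global L2 norm is <= max_norm."""
        total = math.sqrt(sum(float(np.sum(p.grad * p.grad))
                              for p in self.params if p.grad is not None))
        if total > max_norm:
            scale = max_norm / total
            for p in self.params:
                if p.grad is not None:
                    p.grad = p.grad * scale
        return total

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            update = (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            if self.weight_decay:
                update = update + self.weight_decay * p.data
            p.data -= self.lr * update

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class AdamW(Adam):
    def __init__(self, params, lr: float = 5e-4, weight_decay: float = 1e-2,
                 **kw):
        super().__init__(params, lr=lr, weight_decay=weight_decay, **kw)
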