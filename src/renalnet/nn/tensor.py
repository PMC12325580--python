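"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small engine: just the operations the network needs
(broadcast arithmetic, matmul, 2-D convolution with stride/dilation/groups,
max pooling, batch normalisation, reductions, concatenation and the usual
activations), each with an exact analytic backward.  Convolutions are
evaluated by an im2col lowering onto BLAS matmuls.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Tensor:
    """An array node in the autodiff graph.

    ``data`` is an ``np.ndarray``; ``grad`` (same shape) is populated by
    :meth:`backward`.  Non-leaf tensors keep references to their parents so
    the graph can be walked in reverse topological order.
    """

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "name")

    def __init__(self, data, requires_grad: bool = False, _prev=(), name: str = ""):
        self.data = np.asarray(data)
        if self.data.dtype.kind != "f":
            self.data = self.data.astype(np.float32)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._backward = None
        self._prev = _prev
        self.name = name

    # ------------------------------------------------------------------ utils
    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad=None):
        """Backpropagate from this tensor. ``grad`` defaults to ones."""
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=self.data.dtype)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward()

    def zero_grad(self):
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # ------------------------------------------------------- basic arithmetic
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.dtype))
        out = Tensor(self.data + other.data, _prev=(self, other))

        def _bwd():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.shape))

        out._backward = _bwd
        return out

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.dtype))
        out = Tensor(self.data * other.data, _prev=(self, other))

        def _bwd():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.shape))

        out._backward = _bwd
        return out

    def __neg__(self):
        return self * Tensor(np.asarray(-1.0, dtype=self.dtype))

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.dtype))
        return self + (-other)

    __radd__ = __add__
    __rmul__ = __mul__

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def _bwd():
            if self.requires_grad:
                self._accum(out.grad @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ out.grad)

        out._backward = _bwd
        return out

    # ----------------------------------------------------------- activations
    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0), _prev=(self,))

        def _bwd():
            if self.requires_grad:
                self._accum(out.grad * (self.data > 0))

        out._backward = _bwd
        return out

    def sigmoid(self) -> "Tensor":
        x = self.data
        s = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                     np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
        out = Tensor(s, _prev=(self,))

        def _bwd():
            if self.requires_grad:
                self._accum(out.grad * s * (1.0 - s))

        out._backward = _bwd
        return out

    # ------------------------------------------------------------ reductions
    def sum(self) -> "Tensor":
        out = Tensor(np.asarray(self.data.sum(), dtype=self.dtype), _prev=(self,))

        def _bwd():
            if self.requires_grad:
                self._accum(np.broadcast_to(out.grad, self.shape).copy())

        out._backward = _bwd
        return out

    def mean(self, axes, keepdims: bool = False) -> "Tensor":
        axes = tuple(axes) if isinstance(axes, (tuple, list)) else (axes,)
        out = Tensor(self.data.mean(axis=axes, keepdims=keepdims), _prev=(self,))
        n = int(np.prod([self.shape[a] for a in axes]))

        def _bwd():
            if self.requires_grad:
                g = out.grad
                if not keepdims:
                    g = np.expand_dims(g, axes)
                self._accum(np.broadcast_to(g, self.shape) / n)

        out._backward = _bwd
        return out

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), _prev=(self,))

        def _bwd():
            if self.requires_grad:
                self._accum(out.grad.reshape(self.shape))

        out._backward = _bwd
        return out


def _unbroadcast(grad: np.ndarray, shape) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == tuple(shape):
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bwd():
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * out.grad.ndim
                idx[axis] = slice(a, b)
                t._accum(out.grad[tuple(idx)])

    out._backward = _bwd
    return out


# --------------------------------------------------------------- convolution
def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int, dilation: int):
    """(N,C,Hp,Wp) -> windows (N,C,Ho,Wo,kh,kw) as a strided view."""
    ekh = (kh - 1) * dilation + 1
    ekw = (kw - 1) * dilation + 1
    win = sliding_window_view(xp, (ekh, ekw), axis=(2, 3))
    return win[:, :, ::stride, ::stride, ::dilation, ::dilation]


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding: int = 0, dilation: int = 1, groups: int = 1) -> Tensor:
    """2-D cross-correlation, NCHW input, OIHW weights.

    ``groups == C_in`` with one filter per channel gives a depthwise
    convolution (weights shaped ``(C, 1, kh, kw)``).
    """
    N, C, H, W = x.shape
    O, Cg, kh, kw = w.shape
    if C != Cg * groups:
        raise ValueError(f"channel mismatch: input has {C} channels, kernel expects {Cg * groups}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) if padding else x.data
    cols = _im2col(xp, kh, kw, stride, dilation)   # (N,C,Ho,Wo,kh,kw)
    N_, C_, Ho, Wo, _, _ = cols.shape

    if groups == 1:
        mat = cols.transpose(0, 2, 3, 1, 4, 5).reshape(N * Ho * Wo, C * kh * kw)
        wmat = w.data.reshape(O, C * kh * kw)
        y = (mat @ wmat.T).reshape(N, Ho, Wo, O).transpose(0, 3, 1, 2)
    elif groups == C and Cg == 1:
        y = np.einsum("nchwij,cij->nchw", cols, w.data[:, 0], optimize=True)
    else:  # general grouped conv (unused hot path; kept for completeness)
        y = np.empty((N, O, Ho, Wo), dtype=x.dtype)
        og = O // groups
        for g in range(groups):
            cs, ce = g * Cg, (g + 1) * Cg
            osl = slice(g * og, (g + 1) * og)
            mat = cols[:, cs:ce].transpose(0, 2, 3, 1, 4, 5).reshape(N * Ho * Wo, Cg * kh * kw)
            wmat = w.data[osl].reshape(og, Cg * kh * kw)
            y[:, osl] = (mat @ wmat.T).reshape(N, Ho, Wo, og).transpose(0, 3, 1, 2)

    if b is not None:
        y = y + b.data.reshape(1, O, 1, 1)
    prev = (x, w) if b is None else (x, w, b)
    out = Tensor(y, _prev=prev)

    def _bwd():
        dy = out.grad  # (N,O,Ho,Wo)
        if b is not None and b.requires_grad:
            b._accum(dy.sum(axis=(0, 2, 3)))
        need_x = x.requires_grad
        if groups == 1:
            dymat = dy.transpose(0, 2, 3, 1).reshape(N * Ho * Wo, O)
            if w.requires_grad:
                mat = cols.transpose(0, 2, 3, 1, 4, 5).reshape(N * Ho * Wo, C * kh * kw)
                w._accum((dymat.T @ mat).reshape(O, C, kh, kw))
            if need_x:
                dcols = (dymat @ w.data.reshape(O, C * kh * kw)).reshape(
                    N, Ho, Wo, C, kh, kw).transpose(0, 3, 1, 2, 4, 5)
        elif groups == C and Cg == 1:
            if w.requires_grad:
                w._accum(np.einsum("nchw,nchwij->cij", dy, cols, optimize=True)[:, None])
            if need_x:
                dcols = dy[:, :, :, :, None, None] * w.data[:, 0][None, :, None, None]
        else:
            if w.requires_grad:
                dwg = np.empty_like(w.data)
                og = O // groups
                for g in range(groups):
                    cs, ce = g * Cg, (g + 1) * Cg
                    osl = slice(g * og, (g + 1) * og)
                    dwg[osl] = np.einsum("nohw,nchwij->ocij", dy[:, osl], cols[:, cs:ce], optimize=True)
                w._accum(dwg)
            if need_x:
                dcols = np.zeros(cols.shape, dtype=x.dtype)
                og = O // groups
                for g in range(groups):
                    cs, ce = g * Cg, (g + 1) * Cg
                    osl = slice(g * og, (g + 1) * og)
                    dcols[:, cs:ce] = np.einsum("nohw,ocij->nchwij", dy[:, osl], w.data[osl], optimize=True)
        if need_x:
            Hp, Wp = H + 2 * padding, W + 2 * padding
            dxp = np.zeros((N, C, Hp, Wp), dtype=x.dtype)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i * dilation: i * dilation + stride * Ho: stride,
                        j * dilation: j * dilation + stride * Wo: stride] += dcols[..., i, j]
            x._accum(dxp[:, :, padding: padding + H, padding: padding + W] if padding else dxp)

    out._backward = _bwd
    return out


def maxpool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2 (even spatial dims required)."""
    N, C, H, W = x.shape
    if H % 2 or W % 2:
        raise ValueError(f"maxpool2x2 needs even spatial dims, got {H}x{W}")
    win = x.data.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
        N, C, H // 2, W // 2, 4)
    idx = win.argmax(axis=-1)
    out = Tensor(np.take_along_axis(win, idx[..., None], axis=-1)[..., 0], _prev=(x,))

    def _bwd():
        if x.requires_grad:
            dwin = np.zeros(win.shape, dtype=x.dtype)
            np.put_along_axis(dwin, idx[..., None], out.grad[..., None], axis=-1)
            dx = dwin.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H, W)
            x._accum(dx)

    out._backward = _bwd
    return out


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, running_mean, running_var,
               training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Batch normalisation over (N,H,W) per channel for 4-D input, over N for 2-D.

    In training mode batch statistics are used (and the running buffers are
    updated in place); in eval mode the running statistics are used, making
    the layer an affine map.
    """
    axes = (0, 2, 3) if x.data.ndim == 4 else (0,)
    cshape = [1] * x.data.ndim
    cshape[1] = -1  # channel axis is 1 for both NCHW and (N,C)

    if training:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= (1 - momentum)
        running_mean += momentum * mu
        running_var *= (1 - momentum)
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var

    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(cshape)) * inv.reshape(cshape)
    y = gamma.data.reshape(cshape) * xhat + beta.data.reshape(cshape)
    out = Tensor(y, _prev=(x, gamma, beta))

    def _bwd():
        dy = out.grad
        if gamma.requires_grad:
            gamma._accum((dy * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta._accum(dy.sum(axis=axes))
        if x.requires_grad:
            g = gamma.data.reshape(cshape) * inv.reshape(cshape)
            if training:
                dmean = dy.mean(axis=axes, keepdims=True)
                dproj = (dy * xhat).mean(axis=axes, keepdims=True)
                x._accum(g * (dy - dmean - xhat * dproj))
            else:
                x._accum(g * dy)

    out._backward = _bwd
    return out


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy of ``logits`` (N,K) against int labels."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    out = Tensor(np.asarray(loss, dtype=logits.dtype), _prev=(logits,))

    def _bwd():
        if logits.requires_grad:
            g = p.copy()
            g[np.arange(n), labels] -= 1.0
            logits._accum(out.grad * g / n)

    out._backward = _bwd
    return out


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)
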