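"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the operator set needed by the agent's networks:
elementwise arithmetic with broadcasting, matmul, the usual nonlinearities,
reductions, reshaping/concatenation, 2-D convolution and transposed
convolution (im2col based), plus an Adam optimizer.  Tensors build a dynamic
graph; ``backward()`` runs a topological sweep.  A module-level switch
(``no_grad``) disables graph construction on rollout/acting paths where
gradients are never needed.
"""

from __future__ import annotations

import contextlib

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager that disables graph construction."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad and _GRAD_ENABLED
        self._backward = None
        self._parents = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph machinery ------------------------------------------------------
    def _make(self, data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, visited = [], set()

        def visit(t):
            if id(t) in visited:
                return
            visited.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.requires_grad and t._backward is None:
                # leaf
                t.grad = g if t.grad is None else t.grad + g
                continue
            if t._backward is None:
                continue
            for p, pg in zip(t._parents, t._backward(g)):
                if pg is None or not p.requires_grad:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self._make(
            self.data + other.data,
            (self, other),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self._make(
            self.data - other.data,
            (self, other),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(-g, other.shape)),
        )

    def __rsub__(self, other):
        return Tensor(other) - self

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self._make(
            self.data * other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self._make(
            self.data / other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            ),
        )

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, exponent: float):
        return self._make(
            self.data**exponent,
            (self,),
            lambda g: (g * exponent * self.data ** (exponent - 1),),
        )

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return _unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape)

        return self._make(self.data @ other.data, (self, other), backward)

    def __getitem__(self, idx):
        def backward(g):
            out = np.zeros_like(self.data)
            np.add.at(out, idx, g)
            return (out,)

        return self._make(self.data[idx], (self,), backward)

    # -- elementwise functions ------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return self._make(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return self._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return self._make(out_data, (self,), lambda g: (g * 0.5 / out_data,))

    def tanh(self):
        out_data = np.tanh(self.data)
        return self._make(out_data, (self,), lambda g: (g * (1.0 - out_data**2),))

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        return self._make(out_data, (self,), lambda g: (g * out_data * (1.0 - out_data),))

    def relu(self):
        mask = self.data > 0
        return self._make(self.data * mask, (self,), lambda g: (g * mask,))

    def softplus(self):
        # ln(1 + e^x), computed stably
        out_data = np.logaddexp(0.0, self.data)
        sig = 1.0 / (1.0 + np.exp(-self.data))
        return self._make(out_data, (self,), lambda g: (g * sig,))

    def clip(self, lo: float, hi: float):
        mask = (self.data > lo) & (self.data < hi)
        return self._make(np.clip(self.data, lo, hi), (self,), lambda g: (g * mask,))

    # -- reductions / shape ---------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, self.shape).copy(),)

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.size if axis is None else self.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        return self._make(
            self.data.reshape(*shape), (self,), lambda g: (g.reshape(self.shape),)
        )

    def transpose(self, *axes):
        inv = np.argsort(axes)
        return self._make(
            self.data.transpose(*axes), (self,), lambda g: (g.transpose(*inv),)
        )


def concat(tensors, axis=0):
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    if _GRAD_ENABLED and any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def maximum(a: Tensor, b: Tensor):
    """Elementwise maximum; ties route gradient to the first argument."""
    mask = a.data >= b.data
    out = Tensor(np.where(mask, a.data, b.data))
    if _GRAD_ENABLED and (a.requires_grad or b.requires_grad):
        out.requires_grad = True
        out._parents = (a, b)
        out._backward = lambda g: (g * mask, g * (~mask))
    return out


def minimum(a: Tensor, b: Tensor):
    mask = a.data <= b.data
    out = Tensor(np.where(mask, a.data, b.data))
    if _GRAD_ENABLED and (a.requires_grad or b.requires_grad):
        out.requires_grad = True
        out._parents = (a, b)
        out._backward = lambda g: (g * mask, g * (~mask))
    return out


# -- convolution primitives ---------------------------------------------------

def _im2col(x, kh, kw, sh, sw, ph, pw):
    n, c, h, w = x.shape
    ho = (h + 2 * ph - kh) // sh + 1
    wo = (w + 2 * pw - kw) // sw + 1
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    cols = np.empty((n, c, kh, kw, ho, wo), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i : i + sh * ho : sh, j : j + sw * wo : sw]
    return cols.reshape(n, c * kh * kw, ho * wo), ho, wo


def _col2im(cols, xshape, kh, kw, sh, sw, ph, pw):
    n, c, h, w = xshape
    ho = (h + 2 * ph - kh) // sh + 1
    wo = (w + 2 * pw - kw) // sw + 1
    cols = cols.reshape(n, c, kh, kw, ho, wo)
    xp = np.zeros((n, c, h + 2 * ph, w + 2 * pw), dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            xp[:, :, i : i + sh * ho : sh, j : j + sw * wo : sw] += cols[:, :, i, j]
    return xp[:, :, ph : h + ph, pw : w + pw]


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride, padding):
    """2-D convolution, NCHW layout; w has shape (out_ch, in_ch, kh, kw)."""
    sh, sw = stride
    ph, pw = padding
    oc, ic, kh, kw = w.shape
    n = x.shape[0]
    cols, ho, wo = _im2col(x.data, kh, kw, sh, sw, ph, pw)
    out_data = (w.data.reshape(oc, -1) @ cols).reshape(n, oc, ho, wo)
    out_data += b.data.reshape(1, oc, 1, 1)

    def backward(g):
        gflat = g.reshape(n, oc, ho * wo)
        dw = np.tensordot(gflat, cols, axes=([0, 2], [0, 2])).reshape(w.shape)
        db = g.sum(axis=(0, 2, 3))
        dcols = w.data.reshape(oc, -1).T @ gflat
        dx = _col2im(dcols, x.shape, kh, kw, sh, sw, ph, pw)
        return dx, dw, db

    out = Tensor(out_data)
    if _GRAD_ENABLED and (x.requires_grad or w.requires_grad or b.requires_grad):
        out.requires_grad = True
        out._parents = (x, w, b)
        out._backward = backward
    return out


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor, stride, padding, output_padding=(0, 0)):
    """Transposed 2-D convolution; w has shape (in_ch, out_ch, kh, kw)."""
    sh, sw = stride
    ph, pw = padding
    oph, opw = output_padding
    ic, oc, kh, kw = w.shape
    n, _, h, win = x.shape
    ho = (h - 1) * sh - 2 * ph + kh + oph
    wo = (win - 1) * sw - 2 * pw + kw + opw
    # forward = col2im of (w^T x)
    xflat = x.data.reshape(n, ic, h * win)
    cols = np.einsum("ck,nch->nkh", w.data.reshape(ic, -1), xflat)
    buf_h = max((h - 1) * sh + kh, ho + 2 * ph)
    buf_w = max((win - 1) * sw + kw, wo + 2 * pw)
    colsr = cols.reshape(n, oc, kh, kw, h, win)
    buf = np.zeros((n, oc, buf_h, buf_w))
    for i in range(kh):
        for j in range(kw):
            buf[:, :, i : i + sh * h : sh, j : j + sw * win : sw] += colsr[:, :, i, j]
    out_data = buf[:, :, ph : ph + ho, pw : pw + wo] + b.data.reshape(1, oc, 1, 1)

    def backward(g):
        db = g.sum(axis=(0, 2, 3))
        gp = np.zeros((n, oc, buf_h, buf_w))
        gp[:, :, ph : ph + ho, pw : pw + wo] = g
        gcols = np.empty((n, oc, kh, kw, h, win))
        for i in range(kh):
            for j in range(kw):
                gcols[:, :, i, j] = gp[:, :, i : i + sh * h : sh, j : j + sw * win : sw]
        gcols = gcols.reshape(n, oc * kh * kw, h * win)
        dx = np.einsum("ck,nkh->nch", w.data.reshape(ic, -1), gcols).reshape(x.shape)
        dw = np.einsum("nch,nkh->ck", xflat, gcols).reshape(w.shape)
        return dx, dw, db

    out = Tensor(out_data)
    if _GRAD_ENABLED and (x.requires_grad or w.requires_grad or b.requires_grad):
        out.requires_grad = True
        out._parents = (x, w, b)
        out._backward = backward
    return out


# -- optimizer -----------------------------------------------------------------

class Adam:
    """Adam with the standard bias correction (β1=0.9, β2=0.999)."""

    def __init__(self, params, lr=3e-4, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
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
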