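"""Reverse-mode automatic differentiation on NumPy arrays.

A small tape-based engine providing exactly the operations the phase-estimation
models need: elementwise arithmetic, matrix products, strided/dilated
convolutions in 1-D and 2-D, pooling, separable bilinear resampling, softmax
and the usual reductions.  Gradients are accumulated into ``Tensor.grad`` by
:meth:`Tensor.backward`, which walks the recorded graph in reverse topological
order.

All arrays are kept in float64 by default so that finite-difference gradient
checks and bit-exact reproducibility are straightforward.
"""

from __future__ import annotations

import numpy as np

DEFAULT_DTYPE = np.float64


def _as_array(x, dtype=None) -> np.ndarray:
    arr = np.asarray(x, dtype=dtype if dtype is not None else None)
    if arr.dtype.kind in "iub":
        arr = arr.astype(DEFAULT_DTYPE)
    return arr


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, inverting NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")
    __array_priority__ = 100  # our operators win over ndarray's

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- basic protocol -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __len__(self):
        return len(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    # -- graph mechanics ----------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        else:
            grad = _as_array(grad)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = grad
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accumulate(self, g):
        if not (self.requires_grad or self._parents):
            return  # constant: no gradient needed
        if self.grad is None:
            self.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g)
        else:
            self.grad = self.grad + g

    # -- operators ----------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        if isinstance(other, Tensor):
            return add(self, mul(other, -1.0))
        return add(self, -other if np.isscalar(other) else -_as_array(other))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, power(other, -1.0))
        return mul(self, 1.0 / _as_array(other))

    def __rtruediv__(self, other):
        return mul(power(self, -1.0), other)

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 or isinstance(shape[0], int) else shape[0])

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis=axis, keepdims=keepdims)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward, requires_grad=None) -> Tensor:
    out = Tensor(data)
    parents = tuple(p for p in parents if isinstance(p, Tensor))
    needs = any(p.requires_grad or p._parents for p in parents)
    out.requires_grad = needs if requires_grad is None else requires_grad
    if needs:
        out._parents = parents
        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# elementwise & structural ops
# ---------------------------------------------------------------------------

def add(a, b):
    a = astensor(a)
    if not isinstance(b, Tensor) and np.isscalar(b):
        # keep python scalars "weak" so float32 graphs stay float32
        data = a.data + b

        def backward(g):
            a._accumulate(_unbroadcast(g, a.data.shape))

        return _make(data, (a,), backward)
    b = astensor(b)
    data = a.data + b.data

    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(data, (a, b), backward)


def mul(a, b):
    a = astensor(a)
    if isinstance(b, Tensor):
        data = a.data * b.data

        def backward(g):
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

        return _make(data, (a, b), backward)
    barr = b if np.isscalar(b) else _as_array(b)  # scalars stay "weak"
    data = a.data * barr

    def backward(g):
        a._accumulate(_unbroadcast(g * barr, a.data.shape))

    return _make(data, (a,), backward)


def power(a, p: float):
    a = astensor(a)
    data = a.data ** p

    def backward(g):
        a._accumulate(g * p * a.data ** (p - 1.0))

    return _make(data, (a,), backward)


def relu(a):
    a = astensor(a)
    mask = a.data > 0
    data = a.data * mask

    def backward(g):
        a._accumulate(g * mask)

    return _make(data, (a,), backward)


def sigmoid(a):
    a = astensor(a)
    data = 1.0 / (1.0 + np.exp(-np.clip(a.data, -500, 500)))

    def backward(g):
        a._accumulate(g * data * (1.0 - data))

    return _make(data, (a,), backward)


def log(a, eps: float = 0.0):
    """Natural log; `eps` is added to the argument for numerical safety."""
    a = astensor(a)
    shifted = a.data + eps
    data = np.log(shifted)

    def backward(g):
        a._accumulate(g / shifted)

    return _make(data, (a,), backward)


def exp(a):
    a = astensor(a)
    data = np.exp(a.data)

    def backward(g):
        a._accumulate(g * data)

    return _make(data, (a,), backward)


def sqrt(a):
    a = astensor(a)
    data = np.sqrt(a.data)

    def backward(g):
        a._accumulate(g * 0.5 / data)

    return _make(data, (a,), backward)


def clamp(a, lo: float, hi: float):
    """Elementwise clip to [lo, hi]; gradient passes only strictly inside."""
    a = astensor(a)
    data = np.clip(a.data, lo, hi)
    mask = (a.data > lo) & (a.data < hi)

    def backward(g):
        a._accumulate(g * mask)

    return _make(data, (a,), backward)


def reshape(a, shape):
    a = astensor(a)
    data = a.data.reshape(shape)

    def backward(g):
        a._accumulate(g.reshape(a.data.shape))

    return _make(data, (a,), backward)


def transpose(a, axes):
    a = astensor(a)
    data = a.data.transpose(axes)
    inv = np.argsort(axes)

    def backward(g):
        a._accumulate(g.transpose(inv))

    return _make(data, (a,), backward)


def concat(tensors, axis=0):
    tensors = [astensor(t) for t in tensors]
    if not tensors:
        raise ValueError("concat of an empty list")
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    return _make(data, tuple(tensors), backward)


def take(a, indices, axis=0):
    """Select rows along `axis`; gradient scatters back (duplicates accumulate)."""
    a = astensor(a)
    indices = np.asarray(indices)
    data = np.take(a.data, indices, axis=axis)

    def backward(g):
        ga = np.zeros_like(a.data)
        if axis == 0:
            np.add.at(ga, indices, g)
        else:
            gm = np.moveaxis(ga, axis, 0)
            np.add.at(gm, indices, np.moveaxis(g, axis, 0))
        a._accumulate(ga)

    return _make(data, (a,), backward)


def sum_(a, axis=None, keepdims=False):
    a = astensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.data.shape))

    return _make(data, (a,), backward)


def mean(a, axis=None, keepdims=False):
    a = astensor(a)
    data = a.data.mean(axis=axis, keepdims=keepdims)
    n = a.data.size / data.size

    def backward(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.data.shape) / n)

    return _make(data, (a,), backward)


def matmul(a, b):
    a, b = astensor(a), astensor(b)
    data = a.data @ b.data

    def backward(g):
        a._accumulate(g @ b.data.swapaxes(-1, -2))
        b._accumulate(a.data.swapaxes(-1, -2) @ g)

    return _make(data, (a, b), backward)


def softmax(a, axis=-1):
    a = astensor(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * data).sum(axis=axis, keepdims=True)
        a._accumulate(data * (g - dot))

    return _make(data, (a,), backward)


# ---------------------------------------------------------------------------
# convolution / pooling / resampling
# ---------------------------------------------------------------------------

def _im2col(xp: np.ndarray, kh, kw, sh, sw, oh, ow) -> np.ndarray:
    n, c = xp.shape[:2]
    cols = np.empty((n, c, kh, kw, oh, ow), dtype=xp.dtype)
    for u in range(kh):
        for v in range(kw):
            cols[:, :, u, v] = xp[:, :, u:u + sh * oh:sh, v:v + sw * ow:sw]
    return cols


def conv2d(x, w, b=None, stride=1, padding=0):
    """2-D cross-correlation. x: (N,C,H,W); w: (O,C,kh,kw); b: (O,) or None."""
    x, w = astensor(x), astensor(w)
    if b is not None:
        b = astensor(b)
    sh, sw = (stride, stride) if isinstance(stride, int) else stride
    ph, pw = (padding, padding) if isinstance(padding, int) else padding
    n, c, h, wd = x.data.shape
    o, cw, kh, kw = w.data.shape
    if cw != c:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight {cw}")
    oh = (h + 2 * ph - kh) // sh + 1
    ow = (wd + 2 * pw - kw) // sw + 1
    if oh < 1 or ow < 1:
        raise ValueError(f"conv2d: spatial input {h}x{wd} too small for kernel {kh}x{kw}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else x.data
    cols = _im2col(xp, kh, kw, sh, sw, oh, ow)
    ckk = c * kh * kw
    cols_mat = cols.reshape(n, ckk, oh * ow)       # views, no copies: the whole
    wmat = w.data.reshape(o, ckk)                  # conv is batched GEMMs
    out = (wmat @ cols_mat).reshape(n, o, oh, ow)
    if b is not None:
        out = out + b.data.reshape(1, -1, 1, 1)

    def backward(g):
        g3 = np.ascontiguousarray(g).reshape(n, o, oh * ow)
        gw = np.matmul(g3, cols_mat.transpose(0, 2, 1)).sum(axis=0)
        w._accumulate(gw.reshape(w.data.shape))
        if b is not None:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        gcols = (wmat.T @ g3).reshape(n, c, kh, kw, oh, ow)
        gxp = np.zeros_like(xp)
        for u in range(kh):
            for v in range(kw):
                gxp[:, :, u:u + sh * oh:sh, v:v + sw * ow:sw] += gcols[:, :, u, v]
        if ph or pw:
            gxp = gxp[:, :, ph:ph + h, pw:pw + wd]
        x._accumulate(gxp)

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, backward)


def conv1d_causal(x, w, b=None, dilation=1):
    """Causal dilated 1-D convolution via left padding.

    x: (N,C,T); w: (O,C,k).  Output row t depends on input rows <= t only.
    """
    x, w = astensor(x), astensor(w)
    if b is not None:
        b = astensor(b)
    n, c, t = x.data.shape
    o, cw, k = w.data.shape
    if cw != c:
        raise ValueError(f"conv1d channel mismatch: input {c}, weight {cw}")
    lpad = (k - 1) * dilation
    xp = np.pad(x.data, ((0, 0), (0, 0), (lpad, 0)))
    out = np.zeros((n, o, t), dtype=x.data.dtype)
    for u in range(k):
        out += np.einsum("oc,nct->not", w.data[:, :, u], xp[:, :, u * dilation:u * dilation + t],
                         optimize=True)
    if b is not None:
        out = out + b.data.reshape(1, -1, 1)

    def backward(g):
        gw = np.empty_like(w.data)
        for u in range(k):
            gw[:, :, u] = np.einsum("not,nct->oc", g, xp[:, :, u * dilation:u * dilation + t],
                                    optimize=True)
        w._accumulate(gw)
        if b is not None:
            b._accumulate(g.sum(axis=(0, 2)))
        gxp = np.zeros_like(xp)
        for u in range(k):
            gxp[:, :, u * dilation:u * dilation + t] += np.einsum(
                "oc,not->nct", w.data[:, :, u], g, optimize=True)
        x._accumulate(gxp[:, :, lpad:])

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, backward)


def maxpool2d(x, kernel=3, stride=2, padding=1):
    x = astensor(x)
    n, c, h, wd = x.data.shape
    kh = kw = kernel
    sh = sw = stride
    ph = pw = padding
    oh = (h + 2 * ph - kh) // sh + 1
    ow = (wd + 2 * pw - kw) // sw + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)), constant_values=-np.inf)
    cols = _im2col(xp, kh, kw, sh, sw, oh, ow).reshape(n, c, kh * kw, oh, ow)
    idx = cols.argmax(axis=2)
    out = np.take_along_axis(cols, idx[:, :, None], axis=2)[:, :, 0]

    def backward(g):
        gcols = np.zeros((n, c, kh * kw, oh, ow), dtype=g.dtype)
        np.put_along_axis(gcols, idx[:, :, None], g[:, :, None], axis=2)
        gcols = gcols.reshape(n, c, kh, kw, oh, ow)
        gxp = np.zeros_like(xp, dtype=g.dtype)
        for u in range(kh):
            for v in range(kw):
                gxp[:, :, u:u + sh * oh:sh, v:v + sw * ow:sw] += gcols[:, :, u, v]
        x._accumulate(gxp[:, :, ph:ph + h, pw:pw + wd])

    return _make(out, (x,), backward)


def _interp_matrix(n_out: int, n_in: int, dtype=DEFAULT_DTYPE) -> np.ndarray:
    """Row-stochastic bilinear-resampling matrix, non-corner-aligned convention."""
    a = np.zeros((n_out, n_in), dtype=dtype)
    scale = n_in / n_out
    for i in range(n_out):
        src = (i + 0.5) * scale - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        i0 = int(np.floor(src))
        i1 = min(i0 + 1, n_in - 1)
        w1 = src - i0
        a[i, i0] += 1.0 - w1
        a[i, i1] += w1
    return a


def interpolate_bilinear(x, size):
    """Resize (N,C,H,W) to (N,C,size[0],size[1]) with separable bilinear sampling."""
    x = astensor(x)
    h2, w2 = size
    n, c, h, wd = x.data.shape
    ah = _interp_matrix(h2, h, x.data.dtype)
    aw = _interp_matrix(w2, wd, x.data.dtype)
    data = np.einsum("ij,ncjl,ml->ncim", ah, x.data, aw, optimize=True)

    def backward(g):
        x._accumulate(np.einsum("ij,ncim,ml->ncjl", ah, g, aw, optimize=True))

    return _make(data, (x,), backward)


def global_avg_pool(x):
    """(N,C,H,W) -> (N,C): spatial mean."""
    return mean(x, axis=(2, 3))


def numerical_gradient(fn, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite differences of a scalar-valued fn for gradient checks."""
    g = np.zeros_like(x, dtype=np.float64)
    flat = x.reshape(-1)
    gf = g.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        hi = fn()
        flat[i] = orig - eps
        lo = fn()
        flat[i] = orig
        gf[i] = (hi - lo) / (2 * eps)
    return g
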