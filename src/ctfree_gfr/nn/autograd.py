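"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for small volumetric encoder-decoder networks: dense 3D
convolution (im2col + BLAS matmul), instance normalization, pooling/upsampling,
pointwise nonlinearities and the reductions the losses need.  Arrays are
float32 and laid out ``(N, C, D, H, W)``.

Each op returns a :class:`Tensor` holding a closure that maps the output
gradient to parent gradients; ``Tensor.backward()`` runs the closures in
reverse topological order.  Convolution recomputes its im2col matrix in the
backward pass instead of caching it, trading a little compute for a lot of
memory on full-resolution feature maps.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv3d", "instance_norm", "avg_pool3d",
           "upsample_nearest3d", "softmax_channels", "edge_magnitude"]

_F32 = np.float32


class Tensor:
    """A node in the computation graph wrapping a float32 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward_fn")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward_fn=None):
        self.data = np.asarray(data, dtype=_F32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in _parents
        )
        self._parents = _parents
        self._backward_fn = _backward_fn

    # -- graph -------------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can be deeper than the recursion limit
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
        self.grad = np.asarray(grad, dtype=_F32)
        for node in reversed(topo):
            if node._backward_fn is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._backward_fn(node.grad)):
                if not parent.requires_grad or g is None:
                    continue
                g = g.astype(_F32, copy=False)
                parent.grad = g if parent.grad is None else parent.grad + g

    # -- basic arithmetic ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def __add__(self, other):
        other = _as_tensor(other)
        return Tensor(
            self.data + other.data,
            _parents=(self, other),
            _backward_fn=lambda g: (_unbroadcast(g, self.data.shape),
                                    _unbroadcast(g, other.data.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, _parents=(self,), _backward_fn=lambda g: (-g,))

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        return Tensor(
            self.data * other.data,
            _parents=(self, other),
            _backward_fn=lambda g: (_unbroadcast(g * other.data, self.data.shape),
                                    _unbroadcast(g * self.data, other.data.shape)),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        return Tensor(
            self.data / other.data,
            _parents=(self, other),
            _backward_fn=lambda g: (
                _unbroadcast(g / other.data, self.data.shape),
                _unbroadcast(-g * self.data / other.data**2, other.data.shape),
            ),
        )

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    # -- reductions and pointwise functions ----------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            return (np.broadcast_to(gg, self.data.shape),)

        return Tensor(out, _parents=(self,), _backward_fn=bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def log(self):
        return Tensor(np.log(self.data), _parents=(self,),
                      _backward_fn=lambda g: (g / self.data,))

    def log1p_neg(self):
        """log(1 - x), used by cross-entropy."""
        return Tensor(np.log1p(-self.data), _parents=(self,),
                      _backward_fn=lambda g: (-g / (1.0 - self.data),))

    def abs(self):
        return Tensor(np.abs(self.data), _parents=(self,),
                      _backward_fn=lambda g: (g * np.sign(self.data),))

    def clip(self, lo: float, hi: float):
        mask = (self.data > lo) & (self.data < hi)
        return Tensor(np.clip(self.data, lo, hi), _parents=(self,),
                      _backward_fn=lambda g: (g * mask,))

    def relu(self):
        mask = self.data > 0
        return Tensor(self.data * mask, _parents=(self,),
                      _backward_fn=lambda g: (g * mask,))

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor(s, _parents=(self,),
                      _backward_fn=lambda g: (g * s * (1.0 - s),))

    def softplus(self):
        # numerically stable: log(1 + e^x) = max(x, 0) + log1p(e^-|x|)
        out = np.maximum(self.data, 0) + np.log1p(np.exp(-np.abs(self.data)))
        sig = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor(out, _parents=(self,), _backward_fn=lambda g: (g * sig,))


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, (gs, s) in enumerate(zip(g.shape, shape)):
        if s == 1 and gs > 1:
            g = g.sum(axis=i, keepdims=True)
    return g


# -- structural ops ----------------------------------------------------------


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        return tuple(
            np.take(g, np.arange(offsets[i], offsets[i + 1]), axis=axis)
            for i in range(len(tensors))
        )

    return Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                  _parents=tuple(tensors), _backward_fn=bwd)


def _offset_slices(offsets, dims):
    """(out_slice, in_slice) per axis so out[out_sl] += z[in_sl] realizes a
    shift by ``offset`` with zero padding."""
    out_sl, in_sl = [], []
    for o, dim in zip(offsets, dims):
        out_sl.append(slice(max(0, -o), dim - max(0, o)))
        in_sl.append(slice(max(0, o), dim - max(0, -o)))
    return tuple(out_sl), tuple(in_sl)


def _corr3d(x: np.ndarray, w: np.ndarray, b: np.ndarray | None) -> np.ndarray:
    """Same-padding cross-correlation; x (N,C,D,H,W), w (Cout,Cin,k,k,k).

    Decomposed as one channels-last transpose, k^3 BLAS matmuls (one per
    kernel offset) and shifted accumulations — avoids materializing the
    im2col matrix.
    """
    n, cin, d, h, wd = x.shape
    cout, k = w.shape[0], w.shape[2]
    p = k // 2
    xt = np.ascontiguousarray(x.transpose(0, 2, 3, 4, 1))  # (N,D,H,W,Cin)
    xm = xt.reshape(-1, cin)
    if k == 1:
        out = (xm @ w.reshape(cout, cin).T.astype(_F32, copy=False)
               ).reshape(n, d, h, wd, cout)
    else:
        out = np.zeros((n, d, h, wd, cout), dtype=_F32)
        for dz in range(k):
            for dy in range(k):
                for dx in range(k):
                    z = xm @ w[:, :, dz, dy, dx].T
                    zv = z.reshape(n, d, h, wd, cout)
                    osl, isl = _offset_slices((dz - p, dy - p, dx - p), (d, h, wd))
                    out[:, osl[0], osl[1], osl[2], :] += zv[:, isl[0], isl[1], isl[2], :]
    if b is not None:
        out += b
    return np.ascontiguousarray(out.transpose(0, 4, 1, 2, 3))


def _corr3d_weight_grad(x: np.ndarray, g: np.ndarray, k: int) -> np.ndarray:
    """Kernel gradient: correlate input with the output gradient at each lag."""
    n, cin, d, h, wd = x.shape
    cout = g.shape[1]
    p = k // 2
    xt = np.ascontiguousarray(x.transpose(0, 2, 3, 4, 1))
    gt = np.ascontiguousarray(g.transpose(0, 2, 3, 4, 1))
    if k == 1:
        return (gt.reshape(-1, cout).T @ xt.reshape(-1, cin)).reshape(
            cout, cin, 1, 1, 1)
    dw = np.empty((cout, cin, k, k, k), dtype=_F32)
    for dz in range(k):
        for dy in range(k):
            for dx in range(k):
                osl, isl = _offset_slices((dz - p, dy - p, dx - p), (d, h, wd))
                gs = gt[:, osl[0], osl[1], osl[2], :].reshape(-1, cout)
                xs = xt[:, isl[0], isl[1], isl[2], :].reshape(-1, cin)
                dw[:, :, dz, dy, dx] = gs.T @ xs
    return dw


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """3D convolution, stride 1, same (zero) padding, odd kernel."""
    k = w.data.shape[2]
    parents = (x, w) if b is None else (x, w, b)
    out = _corr3d(x.data, w.data, None if b is None else b.data)

    def bwd(g):
        grads = []
        if x.requires_grad:
            w_flip = w.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
            grads.append(_corr3d(g, np.ascontiguousarray(w_flip), None))
        else:
            grads.append(None)
        if w.requires_grad:
            grads.append(_corr3d_weight_grad(x.data, g, k))
        else:
            grads.append(None)
        if b is not None:
            grads.append(g.sum(axis=(0, 2, 3, 4)) if b.requires_grad else None)
        return tuple(grads)

    return Tensor(out, _parents=parents, _backward_fn=bwd)


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize each (sample, channel) over its spatial extent."""
    ax = (2, 3, 4)
    mu = x.data.mean(axis=ax, keepdims=True)
    var = x.data.var(axis=ax, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    gshape = (1, -1, 1, 1, 1)
    out = gamma.data.reshape(gshape) * xhat + beta.data.reshape(gshape)
    m = float(np.prod([x.data.shape[a] for a in ax]))

    def bwd(g):
        dxhat = g * gamma.data.reshape(gshape)
        gx = None
        if x.requires_grad:
            gx = inv * (
                dxhat
                - dxhat.mean(axis=ax, keepdims=True)
                - xhat * (dxhat * xhat).mean(axis=ax, keepdims=True)
            )
        dgamma = (g * xhat).sum(axis=(0, 2, 3, 4)) if gamma.requires_grad else None
        dbeta = g.sum(axis=(0, 2, 3, 4)) if beta.requires_grad else None
        return gx, dgamma, dbeta

    del m
    return Tensor(out, _parents=(x, gamma, beta), _backward_fn=bwd)


def avg_pool3d(x: Tensor) -> Tensor:
    """Factor-2 average pooling on all spatial axes."""
    n, c, d, h, w = x.data.shape
    if d % 2 or h % 2 or w % 2:
        raise ValueError(f"spatial shape {(d, h, w)} not divisible by 2")
    r = x.data.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
    out = r.mean(axis=(3, 5, 7))

    def bwd(g):
        gg = g[:, :, :, None, :, None, :, None] / 8.0
        return (np.broadcast_to(gg, (n, c, d // 2, 2, h // 2, 2, w // 2, 2))
                .reshape(n, c, d, h, w),)

    return Tensor(out, _parents=(x,), _backward_fn=bwd)


def upsample_nearest3d(x: Tensor) -> Tensor:
    """Factor-2 nearest-neighbor upsampling on all spatial axes."""
    n, c, d, h, w = x.data.shape
    out = (x.data[:, :, :, None, :, None, :, None]
           * np.ones((1, 1, 1, 2, 1, 2, 1, 2), dtype=_F32)
           ).reshape(n, c, 2 * d, 2 * h, 2 * w)

    def bwd(g):
        return (g.reshape(n, c, d, 2, h, 2, w, 2).sum(axis=(3, 5, 7)),)

    return Tensor(out, _parents=(x,), _backward_fn=bwd)


def softmax_channels(x: Tensor) -> Tensor:
    """Per-voxel softmax over the channel axis (axis 1)."""
    z = x.data - x.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)

    def bwd(g):
        return (p * (g - (g * p).sum(axis=1, keepdims=True)),)

    return Tensor(p, _parents=(x,), _backward_fn=bwd)


def _cdiff(a: np.ndarray, axis: int) -> np.ndarray:
    """Zero-padded central difference along a spatial axis."""
    out = np.zeros_like(a)
    sl_mid = [slice(None)] * a.ndim
    sl_fwd = [slice(None)] * a.ndim
    sl_bwd = [slice(None)] * a.ndim
    sl_mid[axis] = slice(1, -1)
    sl_fwd[axis] = slice(2, None)
    sl_bwd[axis] = slice(None, -2)
    out[tuple(sl_mid)] = (a[tuple(sl_fwd)] - a[tuple(sl_bwd)]) * 0.5
    return out


def edge_magnitude(x: Tensor, eps: float = 1e-6) -> Tensor:
    """Spatial gradient magnitude per channel — a cheap edge feature."""
    diffs = [_cdiff(x.data, ax) for ax in (2, 3, 4)]
    mag = np.sqrt(sum(d * d for d in diffs) + eps)

    def bwd(g):
        gx = np.zeros_like(x.data)
        for ax, dv in zip((2, 3, 4), diffs):
            # adjoint of the zero-padded central difference is its negation
            gx += -_cdiff(g * dv / mag, ax)
        return (gx,)

    return Tensor(mag, _parents=(x,), _backward_fn=bwd)
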