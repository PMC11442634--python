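"""Minimal reverse-mode autodiff on numpy arrays.

Implements exactly the tensor operations the segmentation network needs:
elementwise arithmetic, activations, reductions, reshapes, channel
concatenation/slicing, 2-D (grouped/strided) convolution, stride-matched
transposed convolution, channel layer norm and batch norm.  Gradients are
accumulated by closures on a dynamically built tape; ``Tensor.backward``
walks the tape in reverse topological order.

Convolution backward supports the two regimes the architecture uses:
stride == kernel with no padding (patchify / downsample, non-overlapping
windows) and stride == 1 with symmetric padding (all other convs).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf

__all__ = [
    "Tensor",
    "Parameter",
    "concat",
    "conv2d",
    "conv_transpose2d",
    "layer_norm_cf",
    "batch_norm2d",
]


class Tensor:
    """An n-d array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = requires_grad
        self.grad = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- bookkeeping -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g):
        if self.requires_grad or self._parents:
            self.grad = g if self.grad is None else self.grad + g

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        # iterative topological sort (graphs can be deep: LSTM unrolls)
        topo, seen, stack = [], set(), [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                g = node.grad
                if g.dtype != node.data.dtype:  # avoid float64 creep
                    g = g.astype(node.data.dtype)
                node._backward(g)

    # -- elementwise arithmetic -------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = _node(self.data + other.data, (self, other))

        def bw(g):
            self._accum(_unbroadcast(g, self.shape))
            other._accum(_unbroadcast(g, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _node(-self.data, (self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = _node(self.data * other.data, (self, other))

        def bw(g):
            self._accum(_unbroadcast(g * other.data, self.shape))
            other._accum(_unbroadcast(g * self.data, other.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        other = _as_tensor(other)
        out = _node(self.data / other.data, (self, other))

        def bw(g):
            self._accum(_unbroadcast(g / other.data, self.shape))
            other._accum(
                _unbroadcast(-g * self.data / other.data**2, other.shape)
            )

        out._backward = bw
        return out

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        out = _node(self.data.reshape(shape), (self,))
        out._backward = lambda g: self._accum(g.reshape(old))
        return out

    def narrow(self, axis: int, start: int, length: int):
        """Slice ``length`` entries along ``axis`` starting at ``start``."""
        idx = [slice(None)] * self.ndim
        idx[axis] = slice(start, start + length)
        idx = tuple(idx)
        out = _node(self.data[idx], (self,))

        def bw(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            self._accum(full)

        out._backward = bw
        return out

    # -- reductions --------------------------------------------------------
    def sum(self):
        out = _node(self.data.sum(), (self,))
        out._backward = lambda g: self._accum(
            np.broadcast_to(g, self.shape).astype(self.data.dtype)
        )
        return out

    def mean(self):
        n = self.data.size
        out = _node(self.data.mean(), (self,))
        out._backward = lambda g: self._accum(
            np.broadcast_to(g / n, self.shape).astype(self.data.dtype)
        )
        return out

    # -- activations -------------------------------------------------------
    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = _node(s, (self,))
        out._backward = lambda g: self._accum(g * s * (1.0 - s))
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = _node(t, (self,))
        out._backward = lambda g: self._accum(g * (1.0 - t * t))
        return out

    def relu(self):
        out = _node(np.maximum(self.data, 0.0), (self,))
        out._backward = lambda g: self._accum(g * (self.data > 0))
        return out

    def gelu(self):
        x = self.data
        cdf = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        out = _node(x * cdf, (self,))
        pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
        out._backward = lambda g: self._accum(g * (cdf + x * pdf))
        return out

    def log(self):
        out = _node(np.log(self.data), (self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def clip(self, lo: float, hi: float):
        out = _node(np.clip(self.data, lo, hi), (self,))
        mask = (self.data >= lo) & (self.data <= hi)
        out._backward = lambda g: self._accum(g * mask)
        return out

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _node(data, parents) -> Tensor:
    out = Tensor(data)
    out._parents = tuple(
        p for p in parents if p.requires_grad or p._parents or p._backward
    )
    return out


def _unbroadcast(g, shape):
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = list(tensors)
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), tensors)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    out._backward = bw
    return out


# -- convolution primitives -----------------------------------------------


def _im2col(x, kh, kw, stride, pad, groups):
    """Unfold an NCHW array into (N, groups, C/g*kh*kw, OH*OW) columns."""
    n, cin, h, wid = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    if kh == 1 and kw == 1 and stride == 1:
        oh, ow = h, wid
        cols = x.reshape(n, groups, cin // groups, oh * ow)
        return cols, oh, ow
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    oh, ow = win.shape[2], win.shape[3]
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(
        n, groups, (cin // groups) * kh * kw, oh * ow
    )
    return np.ascontiguousarray(cols), oh, ow


def _dw_corr(x, w, pad):
    """Depthwise stride-1 correlation by shift-and-add over kernel taps."""
    kh, kw = w.shape[2], w.shape[3]
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    n, c, hp, wp = x.shape
    oh, ow = hp - kh + 1, wp - kw + 1
    y = np.zeros((n, c, oh, ow), dtype=x.dtype)
    for di in range(kh):
        for dj in range(kw):
            y += w[None, :, 0, di, dj, None, None] * \
                x[:, :, di:di + oh, dj:dj + ow]
    return y, None


def _corr_raw(x, w, stride, pad, groups):
    """Plain (non-autodiff) grouped cross-correlation via im2col + matmul."""
    n, cin = x.shape[:2]
    cout, cg, kh, kw = w.shape
    if cg == 1 and groups == cin == cout and stride == 1:
        y, _ = _dw_corr(x, w, pad)
        return y, None
    cols, oh, ow = _im2col(x, kh, kw, stride, pad, groups)
    wg = w.reshape(groups, cout // groups, cg * kh * kw)
    y = np.matmul(wg, cols)  # (n, g, cout/g, L)
    return y.reshape(n, cout, oh, ow), cols


def conv2d(x: Tensor, w: Tensor, b: Tensor | None,
           stride: int = 1, padding: int = 0, groups: int = 1) -> Tensor:
    """Grouped 2-D cross-correlation, NCHW layout.

    Backward is implemented for stride == kernel with zero padding
    (non-overlapping windows) and for stride == 1.
    """
    n, cin, h, wid = x.shape
    cout, cg, kh, kw = w.shape
    if cg * groups != cin:
        raise ValueError(
            f"channel mismatch: input has {cin} channels, weight expects "
            f"{cg * groups} (groups={groups})"
        )
    if stride > 1:
        if stride != kh or padding != 0:
            raise NotImplementedError("strided conv requires stride == kernel")
        if h % stride or wid % stride:
            bad = "height" if h % stride else "width"
            raise ValueError(
                f"spatial {bad} {h if h % stride else wid} not divisible by "
                f"stride {stride}"
            )
    y, cols = _corr_raw(x.data, w.data, stride, padding, groups)
    if b is not None:
        y = y + b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)
    out = _node(y, parents)
    oh, ow = y.shape[2], y.shape[3]

    def bw(g):
        if cols is None:  # depthwise stride-1 path
            if w.requires_grad or w._parents:
                xp = x.data
                if padding:
                    xp = np.pad(xp, ((0, 0), (0, 0), (padding, padding),
                                     (padding, padding)))
                dw = np.empty((cin, 1, kh, kw), dtype=g.dtype)
                for di in range(kh):
                    for dj in range(kw):
                        dw[:, 0, di, dj] = np.einsum(
                            "nchw,nchw->c",
                            xp[:, :, di:di + oh, dj:dj + ow], g,
                        )
                w._accum(dw)
            if b is not None and (b.requires_grad or b._parents):
                b._accum(g.sum(axis=(0, 2, 3)))
            if x.requires_grad or x._parents:
                dxp, _ = _dw_corr(g, w.data[:, :, ::-1, ::-1], kh - 1)
                x._accum(dxp[:, :, padding:padding + h, padding:padding + wid])
            return
        gg = g.reshape(n, groups, cout // groups, oh * ow)
        if w.requires_grad or w._parents:
            dw = np.matmul(gg, cols.transpose(0, 1, 3, 2)).sum(axis=0)
            w._accum(dw.reshape(w.shape))
        if b is not None and (b.requires_grad or b._parents):
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._parents:
            wg = w.data.reshape(groups, cout // groups, cg, kh, kw)
            if stride == 1:
                # full correlation of the output grad with flipped kernels
                wt = wg[:, :, :, ::-1, ::-1].transpose(0, 2, 1, 3, 4)
                wt = wt.reshape(cin, cout // groups, kh, kw)
                dxp, _ = _corr_raw(g.reshape(n, cout, oh, ow), wt,
                                   1, kh - 1, groups)
                x._accum(dxp[:, :, padding:padding + h, padding:padding + wid])
            else:  # stride == kernel, padding == 0: disjoint windows
                wmat = wg.reshape(groups, cout // groups, cg * kh * kw)
                dcols = np.matmul(wmat.transpose(0, 2, 1), gg)
                dxw = dcols.reshape(n, groups, cg, kh, kw, oh, ow)
                dxw = dxw.reshape(n, cin, kh, kw, oh, ow)
                dx = dxw.transpose(0, 1, 4, 2, 5, 3).reshape(n, cin, h, wid)
                x._accum(dx)

    out._backward = bw
    return out


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None,
                     stride: int = 2) -> Tensor:
    """Transposed conv with kernel == stride (exact 2x upsampling)."""
    n, cin, h, wid = x.shape
    cin_w, cout, kh, kw = w.shape
    if cin_w != cin:
        raise ValueError(
            f"channel mismatch: input has {cin} channels, weight expects {cin_w}"
        )
    if kh != stride or kw != stride:
        raise NotImplementedError("transposed conv requires kernel == stride")
    y = np.einsum("nchw,cokl->nohkwl", x.data, w.data, optimize=True)
    y = y.reshape(n, cout, h * kh, wid * kw)
    if b is not None:
        y = y + b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)
    out = _node(y, parents)

    def bw(g):
        g6 = g.reshape(n, cout, h, kh, wid, kw)
        if x.requires_grad or x._parents:
            x._accum(np.einsum("nohkwl,cokl->nchw", g6, w.data, optimize=True))
        if w.requires_grad or w._parents:
            w._accum(np.einsum("nchw,nohkwl->cokl", x.data, g6, optimize=True))
        if b is not None and (b.requires_grad or b._parents):
            b._accum(g.sum(axis=(0, 2, 3)))

    out._backward = bw
    return out


def layer_norm_cf(x: Tensor, gamma: Tensor, beta: Tensor,
                  eps: float = 1e-6) -> Tensor:
    """Layer norm over the channel axis of an NCHW map (channels-first)."""
    mu = x.data.mean(axis=1, keepdims=True)
    var = x.data.var(axis=1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    g4 = gamma.data[None, :, None, None]
    out = _node(g4 * xhat + beta.data[None, :, None, None], (x, gamma, beta))

    def bw(g):
        if gamma.requires_grad or gamma._parents:
            gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad or beta._parents:
            beta._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._parents:
            dxh = g * g4
            m1 = dxh.mean(axis=1, keepdims=True)
            m2 = (dxh * xhat).mean(axis=1, keepdims=True)
            x._accum(inv * (dxh - m1 - xhat * m2))

    out._backward = bw
    return out


def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                 running_mean, running_var, training: bool,
                 momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Batch norm over (N, H, W) per channel; updates running stats in place."""
    axes = (0, 2, 3)
    if training:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        m = x.data.size // x.shape[1]
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        # unbiased running variance, biased batch variance in the graph
        running_var += momentum * var * (m / max(m - 1, 1))
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * inv[None, :, None, None]
    g4 = gamma.data[None, :, None, None]
    out = _node(g4 * xhat + beta.data[None, :, None, None], (x, gamma, beta))

    def bw(g):
        if gamma.requires_grad or gamma._parents:
            gamma._accum((g * xhat).sum(axis=axes))
        if beta.requires_grad or beta._parents:
            beta._accum(g.sum(axis=axes))
        if x.requires_grad or x._parents:
            dxh = g * g4
            if training:
                m1 = dxh.mean(axis=axes, keepdims=True)
                m2 = (dxh * xhat).mean(axis=axes, keepdims=True)
                x._accum(inv[None, :, None, None] * (dxh - m1 - xhat * m2))
            else:
                x._accum(inv[None, :, None, None] * dxh)

    out._backward = bw
    return out
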