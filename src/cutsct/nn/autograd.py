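"""Tensor, the operation set, and reverse-mode backpropagation."""

from __future__ import annotations

import contextlib

import numpy as np

_GRAD_ENABLED = [True]


@contextlib.contextmanager
def no_grad():
    """Disable graph recording (inference / discriminator targets)."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


class Tensor:
    """float32 array node in a dynamically recorded computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED[-1]
        self.grad = None
        self._parents = tuple(parents) if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from a scalar tensor through the recorded graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        if isinstance(other, Tensor):
            out = Tensor(self.data + other.data,
                         self.requires_grad or other.requires_grad,
                         (self, other))
            if out.requires_grad:
                def bw(g, a=self, b=other):
                    if a.requires_grad:
                        a._accum(_unbroadcast(g, a.data.shape))
                    if b.requires_grad:
                        b._accum(_unbroadcast(g, b.data.shape))
                out._backward = bw
            return out
        out = Tensor(self.data + other, self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(g)
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-other if isinstance(other, Tensor) else -np.asarray(other))

    def __mul__(self, other):
        if isinstance(other, Tensor):
            out = Tensor(self.data * other.data,
                         self.requires_grad or other.requires_grad,
                         (self, other))
            if out.requires_grad:
                def bw(g, a=self, b=other):
                    if a.requires_grad:
                        a._accum(_unbroadcast(g * b.data, a.data.shape))
                    if b.requires_grad:
                        b._accum(_unbroadcast(g * a.data, b.data.shape))
                out._backward = bw
            return out
        out = Tensor(self.data * other, self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g, a=self, c=other: a._accum(g * c)
        return out

    __rmul__ = __mul__

    def mean(self) -> "Tensor":
        out = Tensor(self.data.mean(), self.requires_grad, (self,))
        if out.requires_grad:
            def bw(g, a=self):
                a._accum(np.full_like(a.data, g / a.data.size))
            out._backward = bw
        return out

    def sum(self) -> "Tensor":
        out = Tensor(self.data.sum(), self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(np.full_like(a.data, g))
        return out

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(g.reshape(a.data.shape))
        return out


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# -- activations ---------------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), x.requires_grad, (x,))
    if out.requires_grad:
        mask = x.data > 0
        out._backward = lambda g, a=x, m=mask: a._accum(g * m)
    return out


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    out = Tensor(np.where(x.data > 0, x.data, slope * x.data), x.requires_grad, (x,))
    if out.requires_grad:
        scale = np.where(x.data > 0, np.float32(1.0), np.float32(slope))
        out._backward = lambda g, a=x, s=scale: a._accum(g * s)
    return out


def tanh(x: Tensor) -> Tensor:
    y = np.tanh(x.data)
    out = Tensor(y, x.requires_grad, (x,))
    if out.requires_grad:
        out._backward = lambda g, a=x, yy=y: a._accum(g * (1.0 - yy * yy))
    return out


# -- padding -------------------------------------------------------------------

def pad2d(x: Tensor, pad: int, mode: str = "reflect") -> Tensor:
    """Pad the last two axes of an (N, C, H, W) tensor."""
    if pad == 0:
        return x
    widths = ((0, 0), (0, 0), (pad, pad), (pad, pad))
    y = np.pad(x.data, widths, mode="reflect" if mode == "reflect" else "constant")
    out = Tensor(y, x.requires_grad, (x,))
    if out.requires_grad:
        if mode == "reflect":
            H, W = x.data.shape[2], x.data.shape[3]
            ridx = np.pad(np.arange(H), pad, mode="reflect")
            cidx = np.pad(np.arange(W), pad, mode="reflect")

            def bw(g, a=x, ri=ridx, ci=cidx, h=H, w=W):
                gi = np.zeros_like(a.data)
                # accumulate along rows then columns; reflect indices repeat
                tmp = np.zeros(g.shape[:3] + (w,), dtype=g.dtype)
                np.add.at(tmp, (slice(None), slice(None), slice(None), ci), g)
                np.add.at(gi, (slice(None), slice(None), ri, slice(None)), tmp)
                a._accum(gi)
            out._backward = bw
        else:
            out._backward = lambda g, a=x, p=pad: a._accum(g[:, :, p:-p, p:-p])
    return out


# -- convolution via im2col/col2im ---------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    N, C, H, W = x.shape
    oh = (H - kh) // stride + 1
    ow = (W - kw) // stride + 1
    s0, s1, s2, s3 = x.strides
    view = np.lib.stride_tricks.as_strided(
        x, (N, C, kh, kw, oh, ow), (s0, s1, s2, s3, s2 * stride, s3 * stride)
    )
    return np.ascontiguousarray(view).reshape(N, C * kh * kw, oh * ow)


def _col2im(cols: np.ndarray, x_shape: tuple, kh: int, kw: int, stride: int) -> np.ndarray:
    N, C, H, W = x_shape
    oh = (H - kh) // stride + 1
    ow = (W - kw) // stride + 1
    g = np.zeros(x_shape, dtype=cols.dtype)
    cols = cols.reshape(N, C, kh, kw, oh, ow)
    for i in range(kh):
        for j in range(kw):
            g[:, :, i:i + oh * stride:stride, j:j + ow * stride:stride] += cols[:, :, i, j]
    return g


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, stride: int = 1) -> Tensor:
    """Cross-correlation of an (N, C, H, W) input with (O, C, kh, kw) weights.

    Padding is applied by the caller (reflection or zero via :func:`pad2d`).
    """
    O, C, kh, kw = weight.data.shape
    N = x.data.shape[0]
    if x.data.shape[2] < kh or x.data.shape[3] < kw:
        raise ValueError(
            f"spatial input {x.data.shape[2:]} smaller than kernel ({kh}, {kw})"
        )
    cols = _im2col(x.data, kh, kw, stride)  # (N, C*kh*kw, L)
    Wm = weight.data.reshape(O, C * kh * kw)
    y = np.matmul(Wm, cols) + bias.data[None, :, None]
    oh = (x.data.shape[2] - kh) // stride + 1
    ow = (x.data.shape[3] - kw) // stride + 1
    req = x.requires_grad or weight.requires_grad or bias.requires_grad
    out = Tensor(y.reshape(N, O, oh, ow), req, (x, weight, bias))
    if out.requires_grad:
        def bw(g, a=x, w=weight, b=bias, cc=cols, s=stride, k=(kh, kw), dims=(O, C)):
            O_, C_ = dims
            gy = g.reshape(g.shape[0], O_, -1)  # (N, O, L)
            if b.requires_grad:
                b._accum(gy.sum(axis=(0, 2)))
            if w.requires_grad:
                gw = np.matmul(gy, cc.transpose(0, 2, 1)).sum(axis=0)
                w._accum(gw.reshape(w.data.shape))
            if a.requires_grad:
                gcols = np.matmul(w.data.reshape(O_, -1).T, gy)
                a._accum(_col2im(gcols, a.data.shape, k[0], k[1], s))
        out._backward = bw
    return out


def conv_transpose2d(
    x: Tensor, weight: Tensor, bias: Tensor,
    stride: int = 2, padding: int = 1, output_padding: int = 1,
) -> Tensor:
    """Transposed convolution; weights shaped (C_in, O, kh, kw)."""
    C, O, kh, kw = weight.data.shape
    N, _, H, W = x.data.shape
    h_full = (H - 1) * stride + kh
    w_full = (W - 1) * stride + kw
    h_out = h_full - 2 * padding + output_padding
    w_out = w_full - 2 * padding + output_padding
    Wm = weight.data.reshape(C, O * kh * kw)
    cols = np.matmul(Wm.T, x.data.reshape(N, C, H * W))
    full = _col2im(cols, (N, O, h_full, w_full), kh, kw, stride)
    y = full[:, :, padding:padding + h_out, padding:padding + w_out].copy()
    y += bias.data[None, :, None, None]
    req = x.requires_grad or weight.requires_grad or bias.requires_grad
    out = Tensor(y, req, (x, weight, bias))
    if out.requires_grad:
        def bw(g, a=x, w=weight, b=bias, geom=(h_full, w_full, padding, kh, kw, stride)):
            hf, wf, p, kh_, kw_, s = geom
            if b.requires_grad:
                b._accum(g.sum(axis=(0, 2, 3)))
            gfull = np.zeros((g.shape[0], g.shape[1], hf, wf), dtype=g.dtype)
            gfull[:, :, p:p + g.shape[2], p:p + g.shape[3]] = g
            gcols = _im2col(gfull, kh_, kw_, s)  # (N, O*kh*kw, H*W)
            if w.requires_grad:
                xr = a.data.reshape(a.shape[0], a.shape[1], -1)
                gw = np.matmul(xr, gcols.transpose(0, 2, 1)).sum(axis=0)
                w._accum(gw.reshape(w.data.shape))
            if a.requires_grad:
                gx = np.matmul(w.data.reshape(w.data.shape[0], -1), gcols)
                a._accum(gx.reshape(a.data.shape))
        out._backward = bw
    return out


# -- normalization -------------------------------------------------------------

def instance_norm2d(x: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel standardization over the spatial axes (no affine)."""
    mu = x.data.mean(axis=(2, 3), keepdims=True)
    var = x.data.var(axis=(2, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = Tensor(xhat, x.requires_grad, (x,))
    if out.requires_grad:
        def bw(g, a=x, xh=xhat, iv=inv):
            m = a.data.shape[2] * a.data.shape[3]
            gm = g.mean(axis=(2, 3), keepdims=True)
            gx = iv * (g - gm - xh * (g * xh).mean(axis=(2, 3), keepdims=True))
            a._accum(gx)
        out._backward = bw
    return out


# -- linear algebra for projection heads ---------------------------------------

def linear(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Affine map of row vectors: (P, D) @ (D, O) + (O,)."""
    y = x.data @ weight.data + bias.data
    req = x.requires_grad or weight.requires_grad or bias.requires_grad
    out = Tensor(y, req, (x, weight, bias))
    if out.requires_grad:
        def bw(g, a=x, w=weight, b=bias):
            if b.requires_grad:
                b._accum(g.sum(axis=0))
            if w.requires_grad:
                w._accum(a.data.T @ g)
            if a.requires_grad:
                a._accum(g @ w.data.T)
        out._backward = bw
    return out


def l2_normalize_rows(x: Tensor, eps: float = 1e-10) -> Tensor:
    """Scale each row of a (P, D) tensor to unit Euclidean length."""
    n = np.sqrt((x.data ** 2).sum(axis=1, keepdims=True) + eps)
    y = x.data / n
    out = Tensor(y, x.requires_grad, (x,))
    if out.requires_grad:
        def bw(g, a=x, yy=y, nn=n):
            dot = (g * yy).sum(axis=1, keepdims=True)
            a._accum((g - yy * dot) / nn)
        out._backward = bw
    return out


def sample_spatial(x: Tensor, flat_idx: np.ndarray) -> Tensor:
    """Gather patch vectors from a (1, C, H, W) feature map.

    Returns a (P, C) tensor of the feature vectors at the given flattened
    spatial locations.
    """
    N, C, H, W = x.data.shape
    if N != 1:
        raise ValueError("sample_spatial expects batch size 1")
    flat = x.data.reshape(C, H * W)
    out = Tensor(flat[:, flat_idx].T, x.requires_grad, (x,))
    if out.requires_grad:
        def bw(g, a=x, idx=flat_idx, dims=(C, H, W)):
            gi = np.zeros((dims[0], dims[1] * dims[2]), dtype=g.dtype)
            np.add.at(gi, (slice(None), idx), g.T)
            a._accum(gi.reshape(a.data.shape))
        out._backward = bw
    return out


# -- losses --------------------------------------------------------------------

def mse_to_constant(x: Tensor, target: float) -> Tensor:
    """Mean squared deviation of every element from a constant label."""
    d = x.data - np.float32(target)
    out = Tensor(np.mean(d * d), x.requires_grad, (x,))
    if out.requires_grad:
        out._backward = lambda g, a=x, dd=d: a._accum(g * 2.0 * dd / dd.size)
    return out


def cross_entropy_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy of (P, K) logits against integer labels."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    sm = ez / ez.sum(axis=1, keepdims=True)
    P = z.shape[0]
    nll = -np.log(sm[np.arange(P), labels] + 1e-12)
    out = Tensor(nll.mean(), logits.requires_grad, (logits,))
    if out.requires_grad:
        def bw(g, a=logits, s=sm, lab=labels, p=P):
            gs = s.copy()
            gs[np.arange(p), lab] -= 1.0
            a._accum(g * gs / p)
        out._backward = bw
    return out
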