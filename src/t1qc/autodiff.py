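"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A small tape-based engine, sized for this package: float32 tensors, the
operations the motion classifier needs (elementwise arithmetic, matmul,
convolution, pooling, batch normalisation, bilinear upsampling), and a
:func:`backward` that can stop at designated tensors so feature-map
gradients (Grad-CAM) are cheap to extract without touching the layers
below them.

Gradients are first order: the engine differentiates scalars with respect
to tensors, not gradients with respect to gradients.
"""

from __future__ import annotations

import contextlib

import numpy as np

__all__ = ["Tensor", "backward", "default_dtype", "use_dtype"]

_F32 = np.float32
_DTYPE = np.float32  # module default; float64 available for oracle checks


def default_dtype():
    return _DTYPE


@contextlib.contextmanager
def use_dtype(dtype):
    """Temporarily switch the dtype newly created tensors are stored in.

    Float32 is the working precision; float64 exists so that gradient
    implementations can be validated against finite differences without
    single-precision cancellation dominating the comparison.
    """
    global _DTYPE
    previous = _DTYPE
    _DTYPE = np.dtype(dtype).type
    try:
        yield
    finally:
        _DTYPE = previous


def _as_f32(x) -> np.ndarray:
    a = np.asarray(x)
    return a.astype(_DTYPE) if a.dtype != _DTYPE else a


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_bwd")

    def __init__(self, data, requires_grad=False, parents=(), bwd=None):
        self.data = _as_f32(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = parents
        self._bwd = bwd  # callable(g) -> tuple of parent grads (None allowed)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def zero_grad(self):
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    # -- elementwise arithmetic ------------------------------------------
    def __add__(self, other):
        other = _wrap(other)
        out_data = self.data + other.data

        def bwd(g):
            return _unbroadcast(g, self.shape), _unbroadcast(g, other.shape)

        return Tensor(out_data, parents=(self, other), bwd=bwd)

    __radd__ = __add__

    def __mul__(self, other):
        other = _wrap(other)
        out_data = self.data * other.data
        a, b = self, other

        def bwd(g):
            return (
                _unbroadcast(g * b.data, a.shape),
                _unbroadcast(g * a.data, b.shape),
            )

        return Tensor(out_data, parents=(a, b), bwd=bwd)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-_wrap(other))

    def __rsub__(self, other):
        return _wrap(other) + (-self)

    def __matmul__(self, other):
        other = _wrap(other)
        a, b = self, other
        out = a.data @ b.data

        def bwd(g):
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

        return Tensor(out, parents=(a, b), bwd=bwd)

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        src = self

        def bwd(g):
            return (g.reshape(src.shape),)

        return Tensor(self.data.reshape(shape), parents=(self,), bwd=bwd)

    def sum(self, axis=None, keepdims=False):
        src = self

        def bwd(g):
            if axis is None:
                return (np.ascontiguousarray(np.broadcast_to(g, src.shape)),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.ascontiguousarray(np.broadcast_to(gg, src.shape)),)

        return Tensor(
            self.data.sum(axis=axis, keepdims=keepdims), parents=(self,), bwd=bwd
        )

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=_F32))


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# -- nonlinearities -------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def bwd(g):
        return (g * mask,)

    return Tensor(np.where(mask, x.data, 0.0), parents=(x,), bwd=bwd)


def sigmoid(x: Tensor) -> Tensor:
    # numerically stable form; clipped away from {0, 1} so scores stay in the
    # open interval and cross-entropy gradients remain finite in float32
    z = np.exp(-np.abs(x.data))
    s = np.where(x.data >= 0, 1.0 / (1.0 + z), z / (1.0 + z))
    s = np.clip(s, 1e-7, 1.0 - 1e-7).astype(x.data.dtype)

    def bwd(g):
        return (g * s * (1.0 - s),)

    return Tensor(s, parents=(x,), bwd=bwd)


def log(x: Tensor) -> Tensor:
    def bwd(g):
        return (g / x.data,)

    return Tensor(np.log(x.data), parents=(x,), bwd=bwd)


def clamp(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp with straight-through gradient inside the interval."""
    inside = (x.data > lo) & (x.data < hi)

    def bwd(g):
        return (g * inside,)

    return Tensor(np.clip(x.data, lo, hi), parents=(x,), bwd=bwd)


def concat(tensors: list[Tensor], axis: int) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        return tuple(np.ascontiguousarray(p) for p in np.split(g, splits, axis=axis))

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        parents=tuple(tensors),
        bwd=bwd,
    )


# -- convolution ----------------------------------------------------------

def conv3d(x: Tensor, w: Tensor, stride=(1, 1, 1), pad=(1, 1, 1)) -> Tensor:
    """3D cross-correlation, NCDHW layout; 2D convolution is the kd=1 case.

    im2col in a (batch, C·k³, positions) layout — filled by one strided-slice
    copy per kernel offset, which NumPy handles fast — followed by a single
    batched BLAS matmul.  The column matrix is kept for the weight-gradient
    GEMM in backward.
    """
    B, C, D, H, W = x.shape
    O, Cw, kd, kh, kw = w.shape
    assert C == Cw, f"channel mismatch {C} vs {Cw}"
    sd, sh, sw = stride
    pd, ph, pw = pad
    xp = np.zeros((B, C, D + 2 * pd, H + 2 * ph, W + 2 * pw), dtype=x.data.dtype)
    xp[:, :, pd : pd + D, ph : ph + H, pw : pw + W] = x.data
    Do = (D + 2 * pd - kd) // sd + 1
    Ho = (H + 2 * ph - kh) // sh + 1
    Wo = (W + 2 * pw - kw) // sw + 1
    P = Do * Ho * Wo
    ck = C * kd * kh * kw
    col = np.empty((B, ck, P), dtype=x.data.dtype)
    colv = col.reshape(B, C, kd, kh, kw, Do, Ho, Wo)
    for i in range(kd):
        for j in range(kh):
            for k in range(kw):
                colv[:, :, i, j, k] = xp[
                    :, :, i : i + sd * Do : sd, j : j + sh * Ho : sh, k : k + sw * Wo : sw
                ]
    wmat = w.data.reshape(O, ck)
    out = np.matmul(wmat, col).reshape(B, O, Do, Ho, Wo)

    def bwd(g):
        gmat = g.reshape(B, O, P)
        gw = np.matmul(gmat, col.transpose(0, 2, 1)).sum(axis=0).reshape(w.shape)
        gcol = np.matmul(wmat.T, gmat).reshape(B, C, kd, kh, kw, Do, Ho, Wo)
        gxp = np.zeros_like(xp)
        for i in range(kd):
            for j in range(kh):
                for k in range(kw):
                    gxp[
                        :, :, i : i + sd * Do : sd, j : j + sh * Ho : sh, k : k + sw * Wo : sw
                    ] += gcol[:, :, i, j, k]
        gx = gxp[:, :, pd : pd + D, ph : ph + H, pw : pw + W]
        return np.ascontiguousarray(gx), gw

    return Tensor(out, parents=(x, w), bwd=bwd)


def maxpool3d(x: Tensor, k=3, s=2, p=1) -> Tensor:
    B, C, D, H, W = x.shape
    xp = np.pad(
        x.data,
        ((0, 0), (0, 0), (p, p), (p, p), (p, p)),
        constant_values=-np.inf,
    )
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
    win = win[:, :, ::s, ::s, ::s]
    Do, Ho, Wo = win.shape[2:5]
    wf = win.reshape(B, C, Do, Ho, Wo, k * k * k)
    idx = wf.argmax(axis=-1)
    out = np.take_along_axis(wf, idx[..., None], axis=-1)[..., 0]

    def bwd(g):
        di, hi, wi = np.unravel_index(idx, (k, k, k))
        dd = np.arange(Do)[:, None, None] * s + di
        hh = np.arange(Ho)[None, :, None] * s + hi
        ww = np.arange(Wo)[None, None, :] * s + wi
        Dp, Hp, Wp = xp.shape[2:]
        bb = np.arange(B)[:, None, None, None, None]
        cc = np.arange(C)[None, :, None, None, None]
        flat = (((bb * C + cc) * Dp + dd) * Hp + hh) * Wp + ww
        gxp = np.zeros(xp.size, dtype=xp.dtype)
        np.add.at(gxp, flat.ravel(), g.ravel())
        gxp = gxp.reshape(xp.shape)
        return (np.ascontiguousarray(gxp[:, :, p : p + D, p : p + H, p : p + W]),)

    return Tensor(np.ascontiguousarray(out), parents=(x,), bwd=bwd)


# -- bilinear upsampling --------------------------------------------------

def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Dense (n_out, n_in) linear-interpolation matrix (align_corners)."""
    m = np.zeros((n_out, n_in), dtype=_F32)
    if n_in == 1:
        m[:, 0] = 1.0
        return m
    pos = np.linspace(0.0, n_in - 1, n_out)
    lo = np.floor(pos).astype(int)
    lo = np.minimum(lo, n_in - 2)
    frac = (pos - lo).astype(_F32)
    m[np.arange(n_out), lo] = 1.0 - frac
    m[np.arange(n_out), lo + 1] = frac
    return m


def upsample_bilinear(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Bilinear resize of the last two axes (align-corners convention)."""
    h, w = x.shape[-2:]
    my = _interp_matrix(h, out_hw[0]).astype(x.data.dtype)
    mx = _interp_matrix(w, out_hw[1]).astype(x.data.dtype)
    out = np.einsum("ph,...hw,qw->...pq", my, x.data, mx, optimize=True)

    def bwd(g):
        return (np.einsum("ph,...pq,qw->...hw", my, g, mx, optimize=True),)

    return Tensor(out.astype(x.data.dtype), parents=(x,), bwd=bwd)


# -- backward pass --------------------------------------------------------

def backward(root: Tensor, stop: tuple[Tensor, ...] = ()) -> None:
    """Backpropagate from scalar ``root``.

    Gradients accumulate into ``.grad`` of (a) leaf tensors created with
    ``requires_grad=True`` and (b) any tensor listed in ``stop``, which is
    treated as a leaf: its own gradient is recorded but nothing propagates
    past it.  Repeated calls accumulate, as in standard frameworks.
    """
    if root.data.size != 1:
        raise ValueError("backward requires a scalar root")
    stop_ids = {id(t) for t in stop}

    topo: list[Tensor] = []
    seen = {id(root)}
    stack: list[tuple[Tensor, bool]] = [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        stack.append((node, True))
        if id(node) in stop_ids:
            continue
        for p in node._parents:
            if id(p) not in seen:
                seen.add(id(p))
                stack.append((p, False))

    grads: dict[int, np.ndarray] = {id(root): np.ones_like(root.data)}
    for node in reversed(topo):
        g = grads.pop(id(node), None)
        if g is None:
            continue
        is_stop = id(node) in stop_ids
        if node._bwd is not None and not is_stop:
            for p, pg in zip(node._parents, node._bwd(g)):
                if pg is None:
                    continue
                acc = grads.get(id(p))
                grads[id(p)] = pg if acc is None else acc + pg
        if node.requires_grad or is_stop:
            node.grad = g.copy() if node.grad is None else node.grad + g
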