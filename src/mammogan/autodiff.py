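"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the translation networks need: 2-D
convolution, padding (constant / reflect / replicate), 2x2 average pooling,
nearest-neighbour upsampling, channel concatenation, pointwise
nonlinearities, and the mean-squared / mean-absolute reductions used by the
losses.  The graph is rebuilt on every forward pass; ``Tensor.backward()``
runs a topological sweep accumulating gradients into ``Tensor.grad``.

All data is float64 ``(N, C, H, W)`` unless an op documents otherwise.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "constant", "add", "sub", "mul", "scale", "conv2d", "pad2d",
    "avg_pool2", "upsample_nearest2", "concat_channels", "concat_batch",
    "split_batch", "relu",
    "leaky_relu", "tanh", "sigmoid", "sqrt_safe", "mean_all", "sum_all",
    "mse", "l1", "bce",
]


class Tensor:
    """A node in the computation graph wrapping a numpy array."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        data = np.asarray(data)
        if not np.issubdtype(data.dtype, np.floating):
            data = data.astype(np.float64)
        self.data = data
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self):
        self.grad = None

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype)
        else:
            self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def constant(data) -> Tensor:
    return Tensor(data)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unary(x, fwd, bwd):
    x = _as_tensor(x)
    y_data = fwd(x.data)
    if not x.requires_grad:
        return Tensor(y_data)

    def backward(g):
        x._accum(bwd(g, x.data, y_data))

    return Tensor(y_data, True, (x,), backward)


# ---------------------------------------------------------------------------
# arithmetic

def add(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out_req = a.requires_grad or b.requires_grad
    y = Tensor(a.data + b.data, out_req, (a, b))

    def backward(g):
        if a.requires_grad:
            a._accum(g)
        if b.requires_grad:
            b._accum(g)

    y._backward = backward
    return y


def sub(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    y = Tensor(a.data - b.data, a.requires_grad or b.requires_grad, (a, b))

    def backward(g):
        if a.requires_grad:
            a._accum(g)
        if b.requires_grad:
            b._accum(-g)

    y._backward = backward
    return y


def mul(a, b):
    """Elementwise product of two same-shape tensors."""
    a, b = _as_tensor(a), _as_tensor(b)
    y = Tensor(a.data * b.data, a.requires_grad or b.requires_grad, (a, b))

    def backward(g):
        if a.requires_grad:
            a._accum(g * b.data)
        if b.requires_grad:
            b._accum(g * a.data)

    y._backward = backward
    return y


def scale(x, s: float):
    return _unary(x, lambda d: d * s, lambda g, xd, yd: g * s)


# ---------------------------------------------------------------------------
# nonlinearities

def relu(x):
    return _unary(x, lambda d: np.maximum(d, 0.0),
                  lambda g, xd, yd: g * (xd > 0))


def leaky_relu(x, slope=0.2):
    return _unary(x, lambda d: np.where(d > 0, d, slope * d),
                  lambda g, xd, yd: g * np.where(xd > 0, 1.0, slope))


def tanh(x):
    return _unary(x, np.tanh, lambda g, xd, yd: g * (1.0 - yd * yd))


def sigmoid(x):
    def fwd(d):
        out = np.empty_like(d)
        pos = d >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-d[pos]))
        e = np.exp(d[~pos])
        out[~pos] = e / (1.0 + e)
        return out

    return _unary(x, fwd, lambda g, xd, yd: g * yd * (1.0 - yd))


def sqrt_safe(x, eps=1e-12):
    """sqrt with a zero subgradient at 0 (used for gradient magnitudes)."""
    def bwd(g, xd, yd):
        return g * np.where(yd > eps, 0.5 / np.maximum(yd, eps), 0.0)

    return _unary(x, lambda d: np.sqrt(np.maximum(d, 0.0)), bwd)


# ---------------------------------------------------------------------------
# shape ops

_PAD_MODES = {"constant": "constant", "reflect": "reflect", "replicate": "edge"}


def _fast_pad(data, pad, np_mode):
    """np.pad replacement for the trailing two axes (hot path)."""
    pt, pb, pl, pr = pad
    *lead, H, W = data.shape
    out = np.empty((*lead, H + pt + pb, W + pl + pr), dtype=data.dtype)
    out[..., pt:pt + H, pl:pl + W] = data
    if np_mode == "constant":
        if pt:
            out[..., :pt, :] = 0
        if pb:
            out[..., pt + H:, :] = 0
        if pl:
            out[..., :, :pl] = 0
        if pr:
            out[..., :, pl + W:] = 0
        return out
    # fill rows then columns (corners follow automatically)
    for k in range(pt):
        src = pt + (pt - k) if np_mode == "reflect" else pt
        out[..., k, pl:pl + W] = out[..., src, pl:pl + W]
    for k in range(pb):
        base = pt + H - 1
        src = base - (k + 1) if np_mode == "reflect" else base
        out[..., pt + H + k, pl:pl + W] = out[..., src, pl:pl + W]
    for k in range(pl):
        src = pl + (pl - k) if np_mode == "reflect" else pl
        out[..., :, k] = out[..., :, src]
    for k in range(pr):
        base = pl + W - 1
        src = base - (k + 1) if np_mode == "reflect" else base
        out[..., :, pl + W + k] = out[..., :, src]
    return out


_PAD_CACHE: dict = {}


def _pad_frame_map(H, W, pad, np_mode):
    """Frame positions of a padded array and their source pixels.

    The interior of the padded array maps one-to-one onto the input (a
    crop); only the frame needs scatter-accumulation.  Cached per
    (shape, pad, mode).
    """
    key = (H, W, pad, np_mode)
    hit = _PAD_CACHE.get(key)
    if hit is not None:
        return hit
    pt, pb, pl, pr = pad
    idx = np.pad(np.arange(H * W).reshape(H, W), [(pt, pb), (pl, pr)],
                 mode=np_mode)
    Hp, Wp = H + pt + pb, W + pl + pr
    frame = np.ones((Hp, Wp), dtype=bool)
    frame[pt:pt + H, pl:pl + W] = False
    frame_pos = np.flatnonzero(frame.ravel())
    src = idx.ravel()[frame_pos]
    _PAD_CACHE[key] = (frame_pos, src)
    return frame_pos, src


def pad2d(x, pad, mode="constant"):
    """Pad the two trailing axes.  ``pad`` = (top, bottom, left, right).

    Backward scatters gradients onto the source pixels, which for reflect /
    replicate modes accumulates contributions from every padded copy.
    """
    x = _as_tensor(x)
    pt, pb, pl, pr = pad
    np_mode = _PAD_MODES[mode]
    y_data = _fast_pad(x.data, pad, np_mode)
    if not x.requires_grad:
        return Tensor(y_data)

    H, W = x.data.shape[-2:]

    def backward(g):
        gx = np.ascontiguousarray(g[..., pt:pt + H, pl:pl + W])
        if np_mode != "constant":
            frame_pos, src = _pad_frame_map(H, W, (pt, pb, pl, pr), np_mode)
            lead = x.data.shape[:-2]
            n_lead = int(np.prod(lead)) if lead else 1
            g2 = g.reshape(n_lead, -1)
            gx2 = gx.reshape(n_lead, H * W)
            np.add.at(gx2, (np.arange(n_lead)[:, None], src[None, :]),
                      g2[:, frame_pos])
        x._accum(gx)

    return Tensor(y_data, True, (x,), backward)


def conv2d(x, w, b=None, stride=1):
    """Cross-correlation of (N,C,H,W) with (F,C,kh,kw); no implicit padding."""
    x, w = _as_tensor(x), _as_tensor(w)
    N, C, H, W = x.data.shape
    F, C2, kh, kw = w.data.shape
    if C != C2:
        raise ValueError(f"channel mismatch: input {C}, kernel {C2}")
    s = stride
    Ho, Wo = (H - kh) // s + 1, (W - kw) // s + 1
    if Ho < 1 or Wo < 1:
        raise ValueError("convolution output would be empty")

    # im2col in (N, C*kh*kw, Ho*Wo) layout; per-tap strided copies are much
    # cheaper than one 6-D transpose copy
    cols6 = np.empty((N, C, kh, kw, Ho, Wo), dtype=x.data.dtype)
    for a in range(kh):
        for bb in range(kw):
            cols6[:, :, a, bb] = x.data[:, :, a:a + s * Ho:s, bb:bb + s * Wo:s]
    cols = cols6.reshape(N, C * kh * kw, Ho * Wo)
    w_m = w.data.reshape(F, -1)
    y_data = (w_m @ cols).reshape(N, F, Ho, Wo)
    if b is not None:
        b = _as_tensor(b)
        y_data = y_data + b.data[None, :, None, None]

    parents = (x, w) if b is None else (x, w, b)
    req = any(p.requires_grad for p in parents)
    if not req:
        return Tensor(y_data)

    def backward(g):
        g_m = g.reshape(N, F, Ho * Wo)
        if b is not None and b.requires_grad:
            b._accum(g_m.sum(axis=(0, 2)))
        if w.requires_grad:
            gw = np.matmul(g_m, cols.transpose(0, 2, 1)).sum(axis=0)
            w._accum(gw.reshape(w.data.shape))
        if x.requires_grad:
            gcols = np.matmul(w_m.T, g_m).reshape(N, C, kh, kw, Ho, Wo)
            gx = np.zeros_like(x.data)
            for a in range(kh):
                for bb in range(kw):
                    gx[:, :, a:a + s * Ho:s, bb:bb + s * Wo:s] += gcols[:, :, a, bb]
            x._accum(gx)

    return Tensor(y_data, True, parents, backward)


def avg_pool2(x):
    """2x2 average pooling, stride 2; trailing sides must be even."""
    x = _as_tensor(x)
    *lead, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError("avg_pool2 requires even spatial sides")
    y_data = x.data.reshape(*lead, H // 2, 2, W // 2, 2).mean(axis=(-3, -1))
    if not x.requires_grad:
        return Tensor(y_data)

    def backward(g):
        gx = np.repeat(np.repeat(g, 2, axis=-2), 2, axis=-1) / 4.0
        x._accum(gx)

    return Tensor(y_data, True, (x,), backward)


def upsample_nearest2(x):
    x = _as_tensor(x)
    y_data = np.repeat(np.repeat(x.data, 2, axis=-2), 2, axis=-1)
    if not x.requires_grad:
        return Tensor(y_data)

    def backward(g):
        *lead, H, W = g.shape
        gx = g.reshape(*lead, H // 2, 2, W // 2, 2).sum(axis=(-3, -1))
        x._accum(gx)

    return Tensor(y_data, True, (x,), backward)


def concat_batch(tensors):
    """Concatenate along the leading (batch) axis."""
    tensors = [_as_tensor(t) for t in tensors]
    y_data = np.concatenate([t.data for t in tensors], axis=0)
    req = any(t.requires_grad for t in tensors)
    if not req:
        return Tensor(y_data)
    sizes = [t.data.shape[0] for t in tensors]

    def backward(g):
        off = 0
        for t, n in zip(tensors, sizes):
            if t.requires_grad:
                t._accum(g[off:off + n])
            off += n

    return Tensor(y_data, True, tuple(tensors), backward)


def split_batch(x, n: int):
    """Split into (first n, rest) along the batch axis."""
    x = _as_tensor(x)
    a = Tensor(x.data[:n], x.requires_grad, (x,))
    b = Tensor(x.data[n:], x.requires_grad, (x,))
    if x.requires_grad:
        def bw_a(g):
            full = np.zeros_like(x.data)
            full[:n] = g
            x._accum(full)

        def bw_b(g):
            full = np.zeros_like(x.data)
            full[n:] = g
            x._accum(full)

        a._backward, b._backward = bw_a, bw_b
    return a, b


def concat_channels(tensors):
    tensors = [_as_tensor(t) for t in tensors]
    y_data = np.concatenate([t.data for t in tensors], axis=1)
    req = any(t.requires_grad for t in tensors)
    if not req:
        return Tensor(y_data)
    sizes = [t.data.shape[1] for t in tensors]

    def backward(g):
        off = 0
        for t, c in zip(tensors, sizes):
            if t.requires_grad:
                t._accum(g[:, off:off + c])
            off += c

    return Tensor(y_data, True, tuple(tensors), backward)


# ---------------------------------------------------------------------------
# reductions

def sum_all(x):
    x = _as_tensor(x)
    y = Tensor(x.data.sum(keepdims=False).reshape(()), x.requires_grad, (x,))

    def backward(g):
        x._accum(np.broadcast_to(g, x.data.shape))

    y._backward = backward
    return y


def mean_all(x):
    x = _as_tensor(x)
    n = x.data.size
    y = Tensor(np.asarray(x.data.mean()), x.requires_grad, (x,))

    def backward(g):
        x._accum(np.broadcast_to(g / n, x.data.shape))

    y._backward = backward
    return y


def mse(pred, target):
    """Mean squared error over all elements; target may be a constant array."""
    d = sub(pred, _as_tensor(target))
    return mean_all(mul(d, d))


def l1(pred, target):
    """Mean absolute error; subgradient 0 at exact ties."""
    pred, target = _as_tensor(pred), _as_tensor(target)
    diff = pred.data - target.data
    y = Tensor(np.asarray(np.abs(diff).mean()),
               pred.requires_grad or target.requires_grad, (pred, target))
    n = diff.size

    def backward(g):
        s = np.sign(diff) * (g / n)
        if pred.requires_grad:
            pred._accum(s)
        if target.requires_grad:
            target._accum(-s)

    y._backward = backward
    return y


def soft_dice_loss(pred_prob, target, eps=1.0):
    """1 - 2*sum(p*t)/(sum(p)+sum(t)+eps) on probabilities.

    Robust to extreme foreground/background imbalance, where plain
    cross-entropy collapses to the empty prediction.
    """
    pred_prob = _as_tensor(pred_prob)
    t = np.asarray(_as_tensor(target).data)
    p = pred_prob.data
    inter = float((p * t).sum())
    union = float(p.sum() + t.sum() + eps)
    y = Tensor(np.asarray(1.0 - 2.0 * inter / union),
               pred_prob.requires_grad, (pred_prob,))

    def backward(g):
        pred_prob._accum(g * (-2.0) * (t * union - inter) / union ** 2)

    y._backward = backward
    return y


def bce(pred_prob, target, eps=1e-7):
    """Binary cross-entropy on probabilities in (0,1)."""
    pred_prob = _as_tensor(pred_prob)
    t = _as_tensor(target).data
    p = np.clip(pred_prob.data, eps, 1.0 - eps)
    y = Tensor(np.asarray(-(t * np.log(p) + (1 - t) * np.log(1 - p)).mean()),
               pred_prob.requires_grad, (pred_prob,))
    n = p.size

    def backward(g):
        pred_prob._accum(g * (p - t) / (p * (1 - p)) / n)

    y._backward = backward
    return y
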