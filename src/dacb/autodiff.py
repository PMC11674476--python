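"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The DACB network is small enough that a tape-based scalar-of-arrays engine
is all that is needed: every operation records its parents and a backward
closure; :meth:`Tensor.backward` runs the closures in reverse topological
order.  Only the primitives the network uses are provided (dense algebra,
pointwise activations, 1-D convolution/pooling, softmax cross-entropy).

Gradients are accumulated into ``Tensor.grad`` as plain ``ndarray``s.
Broadcasting in ``+``/``*`` is supported; the backward pass sums gradients
over broadcast axes.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "stack",
    "conv1d_same",
    "maxpool1d",
    "lstm_sequence",
    "softmax",
    "softmax_cross_entropy",
]


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_bwd")

    def __init__(self, data, requires_grad=False, _parents=(), _bwd=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in _parents
        )
        self._parents = _parents
        self._bwd = _bwd

    # -- introspection ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph mechanics -------------------------------------------------
    def _accum(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        """Backpropagate from this node (default seed: ones)."""
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        if grad is None:
            grad = np.ones_like(self.data)
        self._accum(grad)
        for t in reversed(topo):
            if t._bwd is not None:
                t._bwd(t.grad)

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other, self.data.dtype)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor(self.data + other.data, _parents=(self, other), _bwd=bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor(-self.data, _parents=(self,), _bwd=bwd)

    def __sub__(self, other):
        return self + (-_as_tensor(other, self.data.dtype))

    def __mul__(self, other):
        other = _as_tensor(other, self.data.dtype)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor(self.data * other.data, _parents=(self, other), _bwd=bwd)

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = _as_tensor(other, self.data.dtype)
        out = self.data @ other.data

        def bwd(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.shape))

        return Tensor(out, _parents=(self, other), _bwd=bwd)

    # -- shape ops -------------------------------------------------------
    def reshape(self, *shape):
        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(self.shape))

        return Tensor(self.data.reshape(*shape), _parents=(self,), _bwd=bwd)

    def narrow(self, axis, start, length):
        """Contiguous slice along ``axis``; backward scatters into zeros."""
        idx = [slice(None)] * self.data.ndim
        idx[axis] = slice(start, start + length)
        idx = tuple(idx)

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[idx] = g
                self._accum(full)

        return Tensor(self.data[idx], _parents=(self,), _bwd=bwd)

    def sum(self, axis=None, keepdims=False):
        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.shape))

        return Tensor(
            self.data.sum(axis=axis, keepdims=keepdims),
            _parents=(self,),
            _bwd=bwd,
        )

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    @property
    def T2(self):
        """Transpose of the last two axes."""

        def bwd(g):
            if self.requires_grad:
                self._accum(np.swapaxes(g, -1, -2))

        return Tensor(np.swapaxes(self.data, -1, -2), _parents=(self,), _bwd=bwd)

    # -- activations -----------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def bwd(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor(self.data * mask, _parents=(self,), _bwd=bwd)

    def sigmoid(self):
        out = _sigmoid(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * out * (1.0 - out))

        return Tensor(out, _parents=(self,), _bwd=bwd)

    def tanh(self):
        out = np.tanh(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out * out))

        return Tensor(out, _parents=(self,), _bwd=bwd)

    def elu(self, alpha=1.0):
        neg = self.data <= 0
        out = np.where(neg, alpha * np.expm1(self.data), self.data)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * np.where(neg, out + alpha, 1.0))

        return Tensor(out, _parents=(self,), _bwd=bwd)


def _as_tensor(x, dtype):
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=dtype))


def _sigmoid(x):
    # clipping keeps exp() in range; sigmoid saturates exactly beyond +-60
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


def _unbroadcast(grad, shape):
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


def concat(tensors, axis):
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(a, b)
                t._accum(g[tuple(idx)])

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        _parents=tuple(tensors),
        _bwd=bwd,
    )


def stack(tensors, axis):
    def bwd(g):
        parts = np.moveaxis(g, axis, 0)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accum(p)

    return Tensor(
        np.stack([t.data for t in tensors], axis=axis),
        _parents=tuple(tensors),
        _bwd=bwd,
    )


def conv1d_same(x, w, b):
    """Batched 1-D cross-correlation, stride 1, zero same-padding.

    x: (B, L, C_in);  w: (K, C_in, F);  b: (F,)  ->  (B, L, F)
    K must be odd so the padding is symmetric.
    """
    K, cin, F = w.data.shape
    if K % 2 != 1:
        raise ValueError("kernel size must be odd for symmetric same-padding")
    B, L, _ = x.data.shape
    pad = K // 2
    xp = np.pad(x.data, ((0, 0), (pad, pad), (0, 0)))
    # windows: (B, L, K, C_in) -> flat (B*L, K*C_in)
    win = np.lib.stride_tricks.sliding_window_view(xp, K, axis=1)
    win = np.ascontiguousarray(np.moveaxis(win, -1, 2))
    cols = win.reshape(B * L, K * cin)
    wmat = w.data.reshape(K * cin, F)
    out = (cols @ wmat + b.data).reshape(B, L, F)

    def bwd(g):
        gflat = g.reshape(B * L, F)
        if w.requires_grad:
            w._accum((cols.T @ gflat).reshape(K, cin, F))
        if b.requires_grad:
            b._accum(gflat.sum(axis=0))
        if x.requires_grad:
            dcols = (gflat @ wmat.T).reshape(B, L, K, cin)
            dxp = np.zeros_like(xp)
            for k in range(K):
                dxp[:, k : k + L, :] += dcols[:, :, k, :]
            x._accum(dxp[:, pad : pad + L, :])

    return Tensor(out, _parents=(x, w, b), _bwd=bwd)


def maxpool1d(x, pool):
    """Non-overlapping max pooling along axis 1; trailing remainder dropped."""
    if pool < 1:
        raise ValueError("pool size must be >= 1")
    B, L, C = x.data.shape
    Lo = L // pool
    xv = x.data[:, : Lo * pool, :].reshape(B, Lo, pool, C)
    out = xv.max(axis=2)

    def bwd(g):
        if not x.requires_grad:
            return
        # gradient is split evenly among tied maxima within a window
        mask = xv == out[:, :, None, :]
        dxv = mask * (g / mask.sum(axis=2))[:, :, None, :]
        full = np.zeros_like(x.data)
        full[:, : Lo * pool, :] = dxv.reshape(B, Lo * pool, C)
        x._accum(full.astype(x.data.dtype, copy=False))

    return Tensor(out, _parents=(x,), _bwd=bwd)


def lstm_sequence(x, w, b, reverse=False):
    """One LSTM direction over a batch of sequences, as a single fused op.

    x: (B, T, F);  w: (H+F, 4H) gate weights over [h_prev, x_t] with the
    four gate blocks ordered (forget, input, output, candidate);
    b: (4H,).  Returns the hidden-state sequence (B, T, H); position ``t``
    holds the state after consuming the sequence up to ``t`` (forward) or
    from the end down to ``t`` (``reverse=True``).

    The backward pass is hand-derived backpropagation through time; it is
    exercised against finite differences and against the step-by-step cell
    composition in the test suite.
    """
    B, T, F = x.data.shape
    H = w.data.shape[1] // 4
    if w.data.shape[0] != H + F:
        raise ValueError(f"gate weights {w.data.shape} incompatible with H={H}, F={F}")
    wh = w.data[:H]
    wx = w.data[H:]
    dt = w.data.dtype
    # time-major layout keeps every per-step slice contiguous
    xp = np.ascontiguousarray(
        np.moveaxis(x.data.astype(dt, copy=False) @ wx + b.data, 1, 0)
    )  # (T, B, 4H)

    order = range(T - 1, -1, -1) if reverse else range(T)
    h = np.zeros((B, H), dtype=dt)
    C = np.zeros((B, H), dtype=dt)
    out = np.empty((B, T, H), dtype=dt)
    # cached per-step activations for BPTT
    F_, I_, O_, G_ = {}, {}, {}, {}
    Cprev_, tanhC_, hprev_ = {}, {}, {}
    for t in order:
        a = h @ wh
        a += xp[t]
        sg = _sigmoid(a[:, : 3 * H])
        f = sg[:, :H]
        i = sg[:, H : 2 * H]
        o = sg[:, 2 * H :]
        g = np.tanh(a[:, 3 * H :])
        hprev_[t], Cprev_[t] = h, C
        C = f * C + i * g
        tc = np.tanh(C)
        h = o * tc
        F_[t], I_[t], O_[t], G_[t], tanhC_[t] = f, i, o, g, tc
        out[:, t] = h

    def bwd(grad):
        need_w = w.requires_grad
        need_b = b.requires_grad
        need_x = x.requires_grad
        dwh = np.zeros_like(wh) if need_w else None
        dxp = np.empty((T, B, 4 * H), dtype=dt)
        dh = np.zeros((B, H), dtype=dt)
        dC = np.zeros((B, H), dtype=dt)
        for t in reversed(list(order)):
            dh = dh + grad[:, t]
            f, i, o, g, tc = F_[t], I_[t], O_[t], G_[t], tanhC_[t]
            dC = dC + dh * o * (1.0 - tc * tc)
            da_o = dh * tc * o * (1.0 - o)
            da_f = dC * Cprev_[t] * f * (1.0 - f)
            da_i = dC * g * i * (1.0 - i)
            da_g = dC * i * (1.0 - g * g)
            da = np.concatenate([da_f, da_i, da_o, da_g], axis=1)
            dxp[t] = da
            if need_w:
                dwh += hprev_[t].T @ da
            dh = da @ wh.T
            dC = dC * f
        if need_w:
            xg = np.moveaxis(x.data, 1, 0).reshape(T * B, F)
            dwx = xg.T.astype(dt, copy=False) @ dxp.reshape(T * B, 4 * H)
            w._accum(np.concatenate([dwh, dwx], axis=0))
        if need_b:
            b._accum(dxp.sum(axis=(0, 1)))
        if need_x:
            x._accum(np.moveaxis(dxp @ wx.T, 0, 1))

    return Tensor(out, _parents=(x, w, b), _bwd=bwd)


def softmax(x, axis=-1):
    m = x.data.max(axis=axis, keepdims=True)
    e = np.exp(x.data - m)
    out = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        if x.requires_grad:
            dot = (g * out).sum(axis=axis, keepdims=True)
            x._accum(out * (g - dot))

    return Tensor(out, _parents=(x,), _bwd=bwd)


def softmax_cross_entropy(logits, y):
    """Mean categorical cross-entropy of integer labels ``y``; returns
    (scalar loss Tensor, class-probability ndarray)."""
    m = logits.data.max(axis=1, keepdims=True)
    e = np.exp(logits.data - m)
    p = e / e.sum(axis=1, keepdims=True)
    n = logits.data.shape[0]
    eps = np.finfo(p.dtype).tiny
    loss = -np.log(p[np.arange(n), y] + eps).mean()

    def bwd(g):
        if logits.requires_grad:
            d = p.copy()
            d[np.arange(n), y] -= 1.0
            logits._accum(g * d / n)

    return (
        Tensor(np.asarray(loss, dtype=logits.data.dtype), _parents=(logits,), _bwd=bwd),
        p,
    )
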