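"""Minimal reverse-mode autodiff on numpy arrays, NHWC layout.

Feature maps are ``(batch, height, width, channels)`` float arrays.  Every op
records its parents and a closure that accumulates gradients; ``Tensor.backward``
runs a topological sweep.  Ops preserve the dtype of their inputs, so the same
graph can be run in float32 for speed or float64 for numerical gradient checks.

Convolutions are evaluated as K*K shifted GEMMs (one matmul per kernel tap)
rather than im2col, which keeps peak memory at O(input) instead of O(K^2 input).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add",
    "mul",
    "relu",
    "sigmoid",
    "concat",
    "conv2d",
    "depthwise_conv2d",
    "linear",
    "max_pool2d",
    "upsample_nearest",
    "batch_norm",
    "global_avg_pool",
    "global_max_pool",
    "channel_mean",
    "channel_max",
    "softmax",
    "softmax_cross_entropy",
]


class Tensor:
    """A numpy array with an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "tag")

    def __init__(self, data, requires_grad=False, parents=(), backward=None, tag=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward
        self.tag = tag

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self):
        return Tensor(self.data)

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # Small conveniences used by the layers.
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad, shape):
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def add(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def mul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def relu(x):
    x = _as_tensor(x)
    mask = x.data > 0
    out = Tensor(np.where(mask, x.data, 0), parents=(x,))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    out._backward = backward
    return out


def sigmoid(x):
    x = _as_tensor(x)
    # Numerically stable in both tails: z = exp(-|x|) lies in (0, 1].
    z = np.exp(-np.abs(np.clip(x.data, -60, 60)))
    s = (np.where(x.data >= 0, 1.0, z) / (1.0 + z)).astype(x.dtype)
    out = Tensor(s, parents=(x,))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * s * (1 - s))

    out._backward = backward
    return out


def concat(tensors, axis=-1):
    tensors = [_as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(p)

    out._backward = backward
    return out


def conv2d(x, w, b=None):
    """Standard 2-D convolution, stride 1, 'same' padding.

    x: (N, H, W, C); w: (K, K, C, O); b: (O,) or None.
    """
    x, w = _as_tensor(x), _as_tensor(w)
    K = w.shape[0]
    p = K // 2
    N, H, W, C = x.shape
    O = w.shape[3]
    xp = np.pad(x.data, ((0, 0), (p, p), (p, p), (0, 0))) if p else x.data
    out_data = np.zeros((N, H, W, O), dtype=x.dtype)
    flat = out_data.reshape(-1, O)
    for k in range(K):
        for l in range(K):
            xs = xp[:, k:k + H, l:l + W, :].reshape(-1, C)
            flat += xs @ w.data[k, l]
    parents = (x, w)
    if b is not None:
        b = _as_tensor(b)
        out_data += b.data
        parents = (x, w, b)

    def backward(g):
        gf = g.reshape(-1, O)
        if b is not None and b.requires_grad:
            b._accumulate(gf.sum(axis=0))
        if w.requires_grad:
            dw = np.zeros_like(w.data)
            for k in range(K):
                for l in range(K):
                    xs = xp[:, k:k + H, l:l + W, :].reshape(-1, C)
                    dw[k, l] = xs.T @ gf
            w._accumulate(dw)
        if x.requires_grad:
            dxp = np.zeros((N, H + 2 * p, W + 2 * p, C), dtype=x.dtype)
            for k in range(K):
                for l in range(K):
                    dxp[:, k:k + H, l:l + W, :] += (gf @ w.data[k, l].T).reshape(N, H, W, C)
            x._accumulate(dxp[:, p:p + H, p:p + W, :] if p else dxp)

    return Tensor(out_data, parents=parents, backward=backward)


def depthwise_conv2d(x, w, b=None):
    """Depth-wise 2-D convolution, stride 1, 'same' padding.

    x: (N, H, W, C); w: (K, K, C); each channel is filtered independently.
    """
    x, w = _as_tensor(x), _as_tensor(w)
    K = w.shape[0]
    p = K // 2
    N, H, W, C = x.shape
    xp = np.pad(x.data, ((0, 0), (p, p), (p, p), (0, 0))) if p else x.data
    out_data = np.zeros((N, H, W, C), dtype=x.dtype)
    for k in range(K):
        for l in range(K):
            out_data += xp[:, k:k + H, l:l + W, :] * w.data[k, l]
    parents = (x, w)
    if b is not None:
        b = _as_tensor(b)
        out_data += b.data
        parents = (x, w, b)

    def backward(g):
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 1, 2)))
        if w.requires_grad:
            dw = np.zeros_like(w.data)
            for k in range(K):
                for l in range(K):
                    dw[k, l] = (xp[:, k:k + H, l:l + W, :] * g).sum(axis=(0, 1, 2))
            w._accumulate(dw)
        if x.requires_grad:
            dxp = np.zeros((N, H + 2 * p, W + 2 * p, C), dtype=x.dtype)
            for k in range(K):
                for l in range(K):
                    dxp[:, k:k + H, l:l + W, :] += g * w.data[k, l]
            x._accumulate(dxp[:, p:p + H, p:p + W, :] if p else dxp)

    return Tensor(out_data, parents=parents, backward=backward)


def linear(x, w, b=None):
    """x: (..., Cin) @ w: (Cin, Cout) + b."""
    x, w = _as_tensor(x), _as_tensor(w)
    out_data = x.data @ w.data
    parents = (x, w)
    if b is not None:
        b = _as_tensor(b)
        out_data = out_data + b.data
        parents = (x, w, b)

    def backward(g):
        if b is not None and b.requires_grad:
            b._accumulate(g.reshape(-1, g.shape[-1]).sum(axis=0))
        if w.requires_grad:
            w._accumulate(x.data.reshape(-1, x.shape[-1]).T @ g.reshape(-1, g.shape[-1]))
        if x.requires_grad:
            x._accumulate(g @ w.data.T)

    return Tensor(out_data, parents=parents, backward=backward)


def max_pool2d(x, size=2):
    """Non-overlapping max pooling; H and W must be divisible by ``size``."""
    x = _as_tensor(x)
    N, H, W, C = x.shape
    s = size
    if H % s or W % s:
        raise ValueError(f"spatial size ({H}x{W}) not divisible by pool size {s}")
    xr = x.data.reshape(N, H // s, s, W // s, s, C).transpose(0, 1, 3, 5, 2, 4)
    xr = xr.reshape(N, H // s, W // s, C, s * s)
    idx = xr.argmax(axis=-1)
    out_data = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    out = Tensor(out_data, parents=(x,))

    def backward(g):
        if not x.requires_grad:
            return
        dxr = np.zeros((N, H // s, W // s, C, s * s), dtype=x.dtype)
        np.put_along_axis(dxr, idx[..., None], g[..., None], axis=-1)
        dx = dxr.reshape(N, H // s, W // s, C, s, s).transpose(0, 1, 4, 2, 5, 3)
        x._accumulate(dx.reshape(N, H, W, C))

    out._backward = backward
    return out


def upsample_nearest(x, scale=2):
    x = _as_tensor(x)
    s = int(scale)
    out = Tensor(x.data.repeat(s, axis=1).repeat(s, axis=2), parents=(x,))
    N, H, W, C = x.shape

    def backward(g):
        if x.requires_grad:
            x._accumulate(g.reshape(N, H, s, W, s, C).sum(axis=(2, 4)))

    out._backward = backward
    return out


def batch_norm(x, gamma, beta, running_mean, running_var, training,
               momentum=0.9, eps=1e-3):
    """Channel-wise batch normalization (NHWC, stats over N, H, W).

    ``running_mean``/``running_var`` are plain numpy arrays updated in place
    during training (they are state, not differentiated).
    """
    x, gamma, beta = _as_tensor(x), _as_tensor(gamma), _as_tensor(beta)
    axes = tuple(range(x.data.ndim - 1))
    if training:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= momentum
        running_mean += (1 - momentum) * mu
        running_var *= momentum
        running_var += (1 - momentum) * var
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out_data = (gamma.data * xhat + beta.data).astype(x.dtype)

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=axes))
        if x.requires_grad:
            if training:
                m = np.prod([x.shape[a] for a in axes])
                gxh = g * gamma.data
                dx = (gxh - gxh.mean(axis=axes) - xhat * (gxh * xhat).mean(axis=axes)) * inv
            else:
                dx = g * gamma.data * inv
            x._accumulate(dx.astype(x.dtype))

    return Tensor(out_data, parents=(x, gamma, beta), backward=backward)


def global_avg_pool(x):
    """(N, H, W, C) -> (N, C) spatial mean."""
    x = _as_tensor(x)
    N, H, W, C = x.shape
    out = Tensor(x.data.mean(axis=(1, 2)), parents=(x,))

    def backward(g):
        if x.requires_grad:
            x._accumulate(np.broadcast_to(g[:, None, None, :] / (H * W), x.shape))

    out._backward = backward
    return out


def global_max_pool(x):
    """(N, H, W, C) -> (N, C) spatial max."""
    x = _as_tensor(x)
    N, H, W, C = x.shape
    flat = x.data.reshape(N, H * W, C)
    idx = flat.argmax(axis=1)
    out = Tensor(np.take_along_axis(flat, idx[:, None, :], axis=1)[:, 0, :], parents=(x,))

    def backward(g):
        if x.requires_grad:
            dflat = np.zeros_like(flat)
            np.put_along_axis(dflat, idx[:, None, :], g[:, None, :], axis=1)
            x._accumulate(dflat.reshape(x.shape))

    out._backward = backward
    return out


def channel_mean(x):
    """(N, H, W, C) -> (N, H, W, 1) mean over channels."""
    x = _as_tensor(x)
    C = x.shape[-1]
    out = Tensor(x.data.mean(axis=-1, keepdims=True), parents=(x,))

    def backward(g):
        if x.requires_grad:
            x._accumulate(np.broadcast_to(g / C, x.shape))

    out._backward = backward
    return out


def channel_max(x):
    """(N, H, W, C) -> (N, H, W, 1) max over channels."""
    x = _as_tensor(x)
    idx = x.data.argmax(axis=-1)
    out = Tensor(np.take_along_axis(x.data, idx[..., None], axis=-1), parents=(x,))

    def backward(g):
        if x.requires_grad:
            dx = np.zeros_like(x.data)
            np.put_along_axis(dx, idx[..., None], g, axis=-1)
            x._accumulate(dx)

    out._backward = backward
    return out


def softmax(x, axis=-1):
    x = _as_tensor(x)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(s.astype(x.dtype), parents=(x,))

    def backward(g):
        if x.requires_grad:
            dot = (g * s).sum(axis=axis, keepdims=True)
            x._accumulate((s * (g - dot)).astype(x.dtype))

    out._backward = backward
    return out


def softmax_cross_entropy(logits, onehot):
    """Mean per-pixel categorical cross-entropy with fused softmax gradient.

    logits: (N, H, W, M) or (N, M); onehot: same shape, rows summing to 1.
    Returns a scalar Tensor.
    """
    logits = _as_tensor(logits)
    y = np.asarray(onehot, dtype=logits.dtype)
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    logp = z - lse
    npix = int(np.prod(logits.shape[:-1]))
    loss = -(y * logp).sum() / npix
    out = Tensor(np.asarray(loss, dtype=np.float64), parents=(logits,))
    probs = np.exp(logp)

    def backward(g):
        if logits.requires_grad:
            logits._accumulate(((probs - y) * (float(g) / npix)).astype(logits.dtype))

    out._backward = backward
    return out
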