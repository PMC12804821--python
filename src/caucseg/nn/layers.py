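"""Layer/module abstractions over the autograd ops.

Parameters are tagged (kernel / bias / bn_scale / bn_shift) so that the
complexity module can count kernel weights only, while the headline model
summary counts everything a framework summary would (including the batch-norm
moving statistics, which are state rather than trainable parameters).
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor

DTYPE = np.float32


class Parameter(Tensor):
    __slots__ = ("kind",)

    def __init__(self, data, kind):
        super().__init__(np.asarray(data, dtype=DTYPE), requires_grad=True)
        self.kind = kind


class RngState:
    """Mutable RNG holder shared by all dropout layers of one model."""

    def __init__(self, seed=0):
        self.rng = np.random.default_rng(seed)

    def reseed(self, seed):
        self.rng = np.random.default_rng(seed)


class Module:
    def __init__(self):
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        yield f"{name}.{i}", v

    def modules(self):
        yield self
        for _, child in self.children():
            yield from child.modules()

    def named_parameters(self, prefix=""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield f"{prefix}{name}", value
        for name, child in self.children():
            yield from child.named_parameters(prefix=f"{prefix}{name}.")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def train(self, mode=True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def weight_count(self, include_bn=True, include_bias=True, include_stats=False):
        """Count parameters by tag.

        ``include_stats`` additionally counts batch-norm moving mean/variance,
        matching framework-style "total params" summaries.
        """
        total = 0
        for _, p in self.named_parameters():
            if p.kind == "kernel":
                total += p.data.size
            elif p.kind == "bias" and include_bias:
                total += p.data.size
            elif p.kind in ("bn_scale", "bn_shift") and include_bn:
                total += p.data.size
        if include_stats:
            for m in self.modules():
                if isinstance(m, BatchNorm):
                    total += m.running_mean.size + m.running_var.size
        return int(total)

    def state_dict(self):
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        i = 0
        for m in self.modules():
            if isinstance(m, BatchNorm):
                state[f"__bn{i}.running_mean"] = m.running_mean.copy()
                state[f"__bn{i}.running_var"] = m.running_var.copy()
                i += 1
        return state

    def load_state_dict(self, state):
        for name, p in self.named_parameters():
            p.data = np.asarray(state[name], dtype=DTYPE).reshape(p.data.shape)
        i = 0
        for m in self.modules():
            if isinstance(m, BatchNorm):
                m.running_mean[:] = state[f"__bn{i}.running_mean"]
                m.running_var[:] = state[f"__bn{i}.running_var"]
                i += 1


def he_normal(rng, shape, fan_in):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(DTYPE)


class Conv2d(Module):
    """Standard KxK conv, stride 1, same padding."""

    def __init__(self, in_ch, out_ch, kernel_size, rng, bias=True, zero_init=False):
        super().__init__()
        self.in_ch, self.out_ch, self.kernel_size = in_ch, out_ch, kernel_size
        fan_in = kernel_size * kernel_size * in_ch
        w = np.zeros((kernel_size, kernel_size, in_ch, out_ch), dtype=DTYPE) if zero_init \
            else he_normal(rng, (kernel_size, kernel_size, in_ch, out_ch), fan_in)
        self.weight = Parameter(w, "kernel")
        self.bias = Parameter(np.zeros(out_ch), "bias") if bias else None

    def forward(self, x):
        if x.shape[-1] != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {x.shape[-1]}")
        return ag.conv2d(x, self.weight, self.bias)


class DepthwiseConv2d(Module):
    def __init__(self, channels, kernel_size, rng, bias=False):
        super().__init__()
        self.channels, self.kernel_size = channels, kernel_size
        fan_in = kernel_size * kernel_size
        self.weight = Parameter(he_normal(rng, (kernel_size, kernel_size, channels), fan_in), "kernel")
        self.bias = Parameter(np.zeros(channels), "bias") if bias else None

    def forward(self, x):
        if x.shape[-1] != self.channels:
            raise ValueError(f"expected {self.channels} input channels, got {x.shape[-1]}")
        return ag.depthwise_conv2d(x, self.weight, self.bias)


class Linear(Module):
    def __init__(self, in_features, out_features, rng, bias=True):
        super().__init__()
        self.weight = Parameter(he_normal(rng, (in_features, out_features), in_features), "kernel")
        self.bias = Parameter(np.zeros(out_features), "bias") if bias else None

    def forward(self, x):
        return ag.linear(x, self.weight, self.bias)


class BatchNorm(Module):
    def __init__(self, channels, momentum=0.9, eps=1e-3):
        super().__init__()
        self.gamma = Parameter(np.ones(channels), "bn_scale")
        self.beta = Parameter(np.zeros(channels), "bn_shift")
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps

    def forward(self, x):
        return ag.batch_norm(x, self.gamma, self.beta, self.running_mean,
                             self.running_var, self.training, self.momentum, self.eps)


class Dropout(Module):
    """Element-wise ("drop-layer") or channel-wise ("drop-channel") dropout."""

    def __init__(self, rate, rng_state, channelwise=False):
        super().__init__()
        self.rate = rate
        self.channelwise = channelwise
        self.rng_state = rng_state

    def forward(self, x):
        if not self.training or self.rate <= 0:
            return x
        rng = self.rng_state.rng
        if self.channelwise:
            shape = (x.shape[0],) + (1,) * (len(x.shape) - 2) + (x.shape[-1],)
        else:
            shape = x.shape
        keep = (rng.random(shape) >= self.rate).astype(x.dtype) / (1.0 - self.rate)
        return ag.mul(x, keep)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.data.dtype)
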