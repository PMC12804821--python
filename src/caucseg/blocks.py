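"""Building blocks of the segmentation network.

* ``DepthwiseSeparableConv`` (DSC): a KxK per-channel spatial convolution
  followed by a 1x1 cross-channel (pointwise) convolution.  Kernel-weight cost
  is K^2*C + C*N versus K^2*C*N for a standard convolution.  Both stages are
  followed by batch normalization and ReLU (the canonical depthwise-separable
  arrangement).
* ``LCB`` (Linear Concatenated Block): DSC -> concat-with-input -> 1x1
  bottleneck at N/2 filters -> dropout, repeated, ending in a third DSC that
  sets the block's N output channels.
* ``AttentionGate``: additive soft attention that gates a skip feature X with a
  coarser, deeper feature Y, producing a refined map of X's shape.
* ``CBAM``: sequential channel-then-spatial attention.

All blocks map NHWC feature maps to NHWC feature maps and expose
``weight_count`` for the parameter-budget calculus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import autograd as ag
from .nn.layers import BatchNorm, Conv2d, DepthwiseConv2d, Dropout, Linear, Module


@dataclass(frozen=True)
class LCBSpec:
    """Per-block filter allocation.

    ``N`` is the block's filter allocation (all three DSCs emit N channels),
    ``Ni`` the block input's channel count, ``K`` the spatial kernel size; the
    two 1x1 bottlenecks always use N/2 filters.
    """

    N: int
    Ni: int
    K: int = 3
    dropout_rate: float = 0.1

    def __post_init__(self):
        if self.N % 2:
            raise ValueError("N must be even (bottleneck width is N/2)")
        if self.K % 2 == 0:
            raise ValueError("K must be odd")

    @property
    def bottleneck(self):
        return self.N // 2


@dataclass(frozen=True)
class AGSpec:
    """Shape contract of an attention gate: Y is one pooling level deeper than
    X (half spatial size, double channels); the refined output matches X."""

    x_channels: int
    inter_channels: int

    @property
    def y_channels(self):
        return 2 * self.x_channels


@dataclass(frozen=True)
class CBAMSpec:
    reduction_ratio: int = 8
    spatial_kernel: int = 7

    def __post_init__(self):
        if self.spatial_kernel % 2 == 0:
            raise ValueError("spatial_kernel must be odd")


class DepthwiseSeparableConv(Module):
    """KxK depthwise + 1x1 pointwise convolution, BN+ReLU after each stage."""

    def __init__(self, in_ch, out_ch, rng, kernel_size=3, activation=True):
        super().__init__()
        if out_ch < 1:
            raise ValueError("filter count must be >= 1")
        self.in_ch, self.out_ch, self.kernel_size = in_ch, out_ch, kernel_size
        self.depthwise = DepthwiseConv2d(in_ch, kernel_size, rng, bias=False)
        self.bn_dw = BatchNorm(in_ch)
        self.pointwise = Conv2d(in_ch, out_ch, 1, rng, bias=True)
        self.pointwise.census_exempt = True  # the 1x1 stage is part of the DSC
        self.bn_pw = BatchNorm(out_ch)
        self.activation = activation

    def forward(self, x):
        h = ag.relu(self.bn_dw(self.depthwise(x)))
        h = self.bn_pw(self.pointwise(h))
        return ag.relu(h) if self.activation else h

    def kernel_weight_count(self):
        """K^2*C + C*N: the depthwise-separable kernel-weight cost."""
        return self.weight_count(include_bn=False, include_bias=False)


class ConvBNReLU(Module):
    """Standard conv + BN + ReLU stage (stem, output head, plain baselines)."""

    def __init__(self, in_ch, out_ch, rng, kernel_size=3, activation=True,
                 batch_norm=True, zero_init=False):
        super().__init__()
        self.conv = Conv2d(in_ch, out_ch, kernel_size, rng, zero_init=zero_init)
        self.bn = BatchNorm(out_ch) if batch_norm else None
        self.activation = activation

    def forward(self, x):
        h = self.conv(x)
        if self.bn is not None:
            h = self.bn(h)
        return ag.relu(h) if self.activation else h


class LCB(Module):
    """Linear Concatenated Block.

    Dataflow (channel counts for allocation N, input Ni):

        C1 = DSC(input)                 # N
        CU1 = concat(input, C1)         # Ni + N
        P1 = 1x1(CU1), dropout          # N/2
        C2 = DSC(P1)                    # N
        CU2 = concat(P1, C2)            # 3N/2
        P2 = 1x1(CU2), dropout          # N/2
        out = DSC(P2)                   # N
    """

    def __init__(self, spec, rng, rng_state):
        super().__init__()
        self.spec = spec
        N, Ni, K, half = spec.N, spec.Ni, spec.K, spec.bottleneck
        self.dsc1 = DepthwiseSeparableConv(Ni, N, rng, K)
        self.proj1 = Conv2d(Ni + N, half, 1, rng)
        self.bn1 = BatchNorm(half)
        self.drop1 = Dropout(spec.dropout_rate, rng_state)
        self.dsc2 = DepthwiseSeparableConv(half, N, rng, K)
        self.proj2 = Conv2d(half + N, half, 1, rng)
        self.bn2 = BatchNorm(half)
        self.drop2 = Dropout(spec.dropout_rate, rng_state)
        self.dsc3 = DepthwiseSeparableConv(half, N, rng, K)

    def forward(self, x, record=None):
        if x.shape[-1] != self.spec.Ni:
            raise ValueError(
                f"LCB{self.spec.N} expects Ni={self.spec.Ni} input channels, got {x.shape[-1]}")
        c1 = self.dsc1(x)
        cu1 = ag.concat([x, c1])
        p1 = self.drop1(ag.relu(self.bn1(self.proj1(cu1))))
        c2 = self.dsc2(p1)
        cu2 = ag.concat([p1, c2])
        p2 = self.drop2(ag.relu(self.bn2(self.proj2(cu2))))
        c3 = self.dsc3(p2)
        if record is not None:
            record.extend(t.shape[-1] for t in (c1, cu1, p1, p1, c2, cu2, p2, p2, c3))
        return c3


class LCBWithoutBottleneck(Module):
    """The LCB with its two 1x1 bottlenecks removed (concatenations feed the
    next DSC directly).  Used as the denominator of the empirical bottleneck
    parameter-reduction ratio."""

    def __init__(self, spec, rng):
        super().__init__()
        N, Ni, K = spec.N, spec.Ni, spec.K
        self.dsc1 = DepthwiseSeparableConv(Ni, N, rng, K)
        self.dsc2 = DepthwiseSeparableConv(Ni + N, N, rng, K)
        self.dsc3 = DepthwiseSeparableConv(Ni + 2 * N, N, rng, K)

    def forward(self, x):
        c1 = self.dsc1(x)
        cu1 = ag.concat([x, c1])
        c2 = self.dsc2(cu1)
        cu2 = ag.concat([cu1, c2])
        return self.dsc3(cu2)


class AttentionGate(Module):
    """Additive attention gate.

    X (skip, N x N x M) and Y (deeper, N/2 x N/2 x 2M) are projected to
    ``inter_channels`` with 1x1 convolutions (BN after each); Y's projection is
    upsampled parameter-free to X's grid; the sum passes ReLU, a 1x1
    convolution to one channel and a sigmoid, giving a per-pixel gate in (0, 1)
    that multiplies X.
    """

    def __init__(self, spec, rng):
        super().__init__()
        self.spec = spec
        cx, ci = spec.x_channels, spec.inter_channels
        self.theta_x = Conv2d(cx, ci, 1, rng)
        self.bn_x = BatchNorm(ci)
        self.phi_y = Conv2d(spec.y_channels, ci, 1, rng)
        self.bn_y = BatchNorm(ci)
        self.psi = Conv2d(ci, 1, 1, rng)
        self.bn_psi = BatchNorm(1)

    def forward(self, x, y):
        if x.shape[-1] != self.spec.x_channels or y.shape[-1] != self.spec.y_channels:
            raise ValueError(
                f"attention gate expects X with {self.spec.x_channels} and Y with "
                f"{self.spec.y_channels} channels, got {x.shape[-1]} and {y.shape[-1]}")
        if x.shape[1] != 2 * y.shape[1] or x.shape[2] != 2 * y.shape[2]:
            raise ValueError("Y must be half of X's spatial extent")
        gx = self.bn_x(self.theta_x(x))
        gy = ag.upsample_nearest(self.bn_y(self.phi_y(y)), 2)
        alpha = ag.sigmoid(self.bn_psi(self.psi(ag.relu(ag.add(gx, gy)))))
        return ag.mul(x, alpha)

    def gate(self, x, y):
        """The attention coefficients alpha (N, H, W, 1), for inspection."""
        gx = self.bn_x(self.theta_x(x))
        gy = ag.upsample_nearest(self.bn_y(self.phi_y(y)), 2)
        return ag.sigmoid(self.bn_psi(self.psi(ag.relu(ag.add(gx, gy)))))


class CBAM(Module):
    """Convolutional Block Attention Module: channel attention from pooled
    descriptors through a shared two-layer MLP, then spatial attention from a
    7x7 convolution over the channel-pooled planes; both applied
    multiplicatively, in sequence."""

    def __init__(self, channels, rng, spec=CBAMSpec()):
        super().__init__()
        if channels % spec.reduction_ratio:
            raise ValueError(
                f"channels ({channels}) must be divisible by reduction ratio "
                f"({spec.reduction_ratio})")
        self.channels, self.spec = channels, spec
        hidden = channels // spec.reduction_ratio
        self.mlp1 = Linear(channels, hidden, rng)
        self.mlp2 = Linear(hidden, channels, rng)
        self.spatial_conv = Conv2d(2, 1, spec.spatial_kernel, rng)

    def _mlp(self, v):
        return self.mlp2(ag.relu(self.mlp1(v)))

    def channel_map(self, x):
        """M_CH(F): sigmoid(MLP(avgpool F) + MLP(maxpool F)), shape (N, C)."""
        return ag.sigmoid(ag.add(self._mlp(ag.global_avg_pool(x)),
                                 self._mlp(ag.global_max_pool(x))))

    def spatial_map(self, x):
        """M_SP(F'): sigmoid(7x7 conv over [channel-avg; channel-max])."""
        pooled = ag.concat([ag.channel_mean(x), ag.channel_max(x)])
        return ag.sigmoid(self.spatial_conv(pooled))

    def forward(self, x):
        if x.shape[-1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[-1]}")
        f1 = ag.mul(x, _expand_nc(self.channel_map(x)))
        msp = self.spatial_map(f1)
        return ag.mul(f1, msp)


def _expand_nc(t):
    """(N, C) -> (N, 1, 1, C) view with gradient flow."""
    out = ag.Tensor(t.data[:, None, None, :], parents=(t,))

    def backward(g):
        if t.requires_grad:
            t._accumulate(g[:, 0, 0, :])

    out._backward = backward
    return out


def dsc_forward(feature_map, n_filters, kernel_size=3, rng=None):
    """Functional DSC: apply a freshly-initialized depthwise separable
    convolution with ``n_filters`` output channels to an NHWC feature map."""
    rng = rng or np.random.default_rng(0)
    x = feature_map if isinstance(feature_map, ag.Tensor) else ag.Tensor(np.asarray(feature_map))
    block = DepthwiseSeparableConv(x.shape[-1], n_filters, rng, kernel_size)
    block.eval()
    return block(x)


def lcb_forward(feature_map, spec, rng=None):
    """Functional LCB forward with a fresh block."""
    from .nn.layers import RngState

    rng = rng or np.random.default_rng(0)
    x = feature_map if isinstance(feature_map, ag.Tensor) else ag.Tensor(np.asarray(feature_map))
    block = LCB(spec, rng, RngState(0))
    block.eval()
    return block(x)


def attention_gate(x, y, spec, rng=None):
    """Functional attention gate with a fresh block."""
    rng = rng or np.random.default_rng(0)
    xt = x if isinstance(x, ag.Tensor) else ag.Tensor(np.asarray(x))
    yt = y if isinstance(y, ag.Tensor) else ag.Tensor(np.asarray(y))
    block = AttentionGate(spec, rng)
    block.eval()
    return block(xt, yt)


def cbam(feature_map, spec=CBAMSpec(), rng=None):
    """Functional CBAM with a fresh module."""
    rng = rng or np.random.default_rng(0)
    x = feature_map if isinstance(feature_map, ag.Tensor) else ag.Tensor(np.asarray(feature_map))
    block = CBAM(x.shape[-1], rng, spec)
    block.eval()
    return block(x)
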