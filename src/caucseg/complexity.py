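"""Parameter-reduction calculus for the depthwise-separable / bottleneck design.

Two closed-form ratios quantify how the network stays under its parameter
budget, both expressed as (parameters of the cheap design) / (parameters of
the standard design), counting convolution kernel weights only:

* ``pr1(N, K)``: a single KxK depthwise-separable layer with N filters versus
  a standard KxK convolution — ``1/K^2 + 1/N`` (``1/9 + 1/N`` at K = 3),
  independent of the input channel count.
* ``pr2(N, Ni, K)``: a whole Linear Concatenated Block with its two 1x1
  bottlenecks versus the same block with the concatenations fed straight into
  the next depthwise-separable layer —
  ``(3 + N/2 + N^2/(4(N+Ni))) / (9 + N)`` at K = 3.

Under the block-allocation pattern (encoder blocks double their input width,
decoder blocks halve it), ``pr2`` specializes per side:

* encoder (Ni = x, N = 2x):  ``1/3 + 2x/(3(9+2x))``
* decoder (Ni = 2x, N = x):  ``1/3 + x/(4(9+x))``

``empirical_pr2`` validates the closed form by constructing both block
variants and counting their kernel weights by enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .blocks import LCB, LCBSpec, LCBWithoutBottleneck
from .nn.layers import RngState

#: filter allocations of the LCB stages on each side, shallow to deep
SIDE_FILTERS = (16, 32, 64, 128)
#: DSC layers per LCB
DSC_PER_LCB = 3
#: filter count of the middle depthwise-separable layer
MIDDLE_FILTERS = 256


def np_sc(K, IC, NF):
    """Kernel weights of a standard KxK convolution: K*K*IC*NF."""
    _check_positive(K=K, IC=IC, NF=NF)
    return K * K * IC * NF


def np_dsc(K, IC, N):
    """Kernel weights of a KxK depthwise-separable convolution: K*K*IC + IC*N."""
    _check_positive(K=K, IC=IC, N=N)
    return K * K * IC + IC * N


def pr1(N, K=3):
    """Per-layer parameter-reduction ratio of a DSC layer: 1/K^2 + 1/N."""
    _check_positive(N=N, K=K)
    return 1.0 / (K * K) + 1.0 / N


def apr1(dsc_layer_filter_list):
    """Mean of pr1 over the model's depthwise-separable layers."""
    filters = list(dsc_layer_filter_list)
    if not filters:
        raise ValueError("need at least one DSC layer")
    return float(np.mean([pr1(n) for n in filters]))


def model_dsc_filters():
    """Filter allocation of every DSC layer in the full model (m = 25):
    three per LCB at 16/32/64/128 on each side, plus the 256-filter middle."""
    per_side = [n for n in SIDE_FILTERS for _ in range(DSC_PER_LCB)]
    return per_side + per_side + [MIDDLE_FILTERS]


def pr2(N, Ni, K=3):
    """Per-block parameter-reduction ratio from the 1x1 bottlenecks."""
    _check_positive(N=N, Ni=Ni, K=K)
    k2 = K * K
    with_bottleneck = (k2 * Ni + N * Ni) + (N + Ni) * (N / 2) \
        + (k2 * N / 2 + N * N / 2) + (3 * N / 2) * (N / 2) + (k2 * N / 2 + N * N / 2)
    without = (k2 * Ni + N * Ni) + (k2 * (N + Ni) + (N + Ni) * N) \
        + (k2 * (2 * N + Ni) + (2 * N + Ni) * N)
    return with_bottleneck / without


def pr2_side(side, x):
    """Side-specialized pr2 under the width-doubling pattern.

    encoder: blocks double their input width (Ni = x, N = 2x);
    decoder: blocks halve it (Ni = 2x, N = x).
    """
    _check_positive(x=x)
    if side == "encoder":
        return 1.0 / 3.0 + 2.0 * x / (3.0 * (9.0 + 2.0 * x))
    if side == "decoder":
        return 1.0 / 3.0 + x / (4.0 * (9.0 + x))
    raise ValueError(f"side must be 'encoder' or 'decoder', got {side!r}")


def apr2(encoder_xs=SIDE_FILTERS, decoder_xs=SIDE_FILTERS):
    """Side means and pooled mean of pr2 over the blocks; returns
    (APR2E, APR2D, APR2)."""
    encoder_xs, decoder_xs = list(encoder_xs), list(decoder_xs)
    if not encoder_xs or not decoder_xs:
        raise ValueError("both sides need at least one block")
    e = [pr2_side("encoder", x) for x in encoder_xs]
    d = [pr2_side("decoder", x) for x in decoder_xs]
    return (float(np.mean(e)), float(np.mean(d)),
            float((sum(e) + sum(d)) / (len(e) + len(d))))


def empirical_pr2(spec):
    """Brute-force counterpart of pr2: build the block with and without its
    1x1 bottlenecks and count kernel weights only."""
    rng = np.random.default_rng(0)
    with_b = LCB(spec, rng, RngState(0)).weight_count(include_bn=False, include_bias=False)
    without = LCBWithoutBottleneck(spec, rng).weight_count(include_bn=False, include_bias=False)
    return with_b / without


@dataclass
class ComplexityReport:
    """Closed-form and empirical parameter-reduction figures for a model."""

    m: int
    NE: int
    ND: int
    pr1_per_layer: dict
    apr1: float
    pr2_encoder: dict
    pr2_decoder: dict
    apr2_encoder: float
    apr2_decoder: float
    apr2: float
    #: pr2 evaluated with each block's true graph input width (the first
    #: encoder block receives the 64-channel stem output, breaking the
    #: idealized width-doubling pattern)
    pr2_actual: dict = field(default_factory=dict)
    empirical_pr2: dict = field(default_factory=dict)
    np_per_dsc_layer: dict = field(default_factory=dict)

    def as_dict(self):
        return {k: v for k, v in self.__dict__.items()}


def full_model_report():
    """Complexity report for the full model's block plan."""
    filters = model_dsc_filters()
    e_mean, d_mean, pooled = apr2()
    # True graph input widths: stem -> 64, then the previous block's N.
    enc_ni = (64,) + SIDE_FILTERS[:-1]
    dec_ni = {128: 384, 64: 192, 32: 96, 16: 48}
    pr2_actual, empirical = {}, {}
    for n, ni in zip(SIDE_FILTERS, enc_ni):
        pr2_actual[f"encoder_LCB{n}"] = pr2(n, ni)
        empirical[f"encoder_LCB{n}"] = empirical_pr2(LCBSpec(N=n, Ni=ni))
    for n in reversed(SIDE_FILTERS):
        pr2_actual[f"decoder_LCB{n}"] = pr2(n, dec_ni[n])
        empirical[f"decoder_LCB{n}"] = empirical_pr2(LCBSpec(N=n, Ni=dec_ni[n]))
    return ComplexityReport(
        m=len(filters),
        NE=len(SIDE_FILTERS),
        ND=len(SIDE_FILTERS),
        pr1_per_layer={n: pr1(n) for n in sorted(set(filters))},
        apr1=apr1(filters),
        pr2_encoder={x: pr2_side("encoder", x) for x in SIDE_FILTERS},
        pr2_decoder={x: pr2_side("decoder", x) for x in SIDE_FILTERS},
        apr2_encoder=e_mean,
        apr2_decoder=d_mean,
        apr2=pooled,
        pr2_actual=pr2_actual,
        empirical_pr2=empirical,
        # pr1 = np_dsc/np_sc is independent of IC; tabulate at IC = N/2 (the
        # in-block input width of the second and third DSCs).
        np_per_dsc_layer={n: {"np_sc": np_sc(3, max(n // 2, 1), n),
                              "np_dsc": np_dsc(3, max(n // 2, 1), n)}
                          for n in sorted(set(filters))},
    )


def _check_positive(**kwargs):
    for name, value in kwargs.items():
        if value < 1:
            raise ValueError(f"{name} must be >= 1, got {value}")
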