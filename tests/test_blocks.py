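"""Building blocks: DSC weight costs, LCB dataflow, attention gate, CBAM."""

import numpy as np
import pytest

from caucseg.blocks import (
    AGSpec,
    AttentionGate,
    CBAM,
    CBAMSpec,
    DepthwiseSeparableConv,
    LCB,
    LCBSpec,
    attention_gate,
    cbam,
    dsc_forward,
)
from caucseg.nn import autograd as ag
from caucseg.nn.layers import RngState

rng = np.random.default_rng(0)


class TestDSC:
    def test_kernel_weight_count_is_k2c_plus_cn(self):
        block = DepthwiseSeparableConv(64, 128, np.random.default_rng(0))
        assert block.kernel_weight_count() == 9 * 64 + 64 * 128 == 8768

    def test_minimal_case(self):
        block = DepthwiseSeparableConv(1, 1, np.random.default_rng(0), kernel_size=1)
        assert block.kernel_weight_count() == 2

    def test_output_shape(self):
        out = dsc_forward(rng.normal(size=(1, 56, 56, 32)).astype(np.float32), 64)
        assert out.shape == (1, 56, 56, 64)

    def test_rejects_nonpositive_filters(self):
        with pytest.raises(ValueError):
            DepthwiseSeparableConv(8, 0, np.random.default_rng(0))


class TestLCB:
    def test_channel_trajectory_matches_block_contract(self):
        # 56x56x32 input at allocation N=64: the nine internal stages run
        # 64, 96, 32, 32, 64, 96, 32, 32, 64 channels.
        block = LCB(LCBSpec(N=64, Ni=32), np.random.default_rng(0), RngState(0))
        block.eval()
        record = []
        out = block(ag.Tensor(rng.normal(size=(1, 56, 56, 32)).astype(np.float32)),
                    record=record)
        assert record == [64, 96, 32, 32, 64, 96, 32, 32, 64]
        assert out.shape == (1, 56, 56, 64)

    @pytest.mark.parametrize("n,ni", [(16, 64), (32, 16), (128, 384)])
    def test_output_channels_equal_allocation(self, n, ni):
        block = LCB(LCBSpec(N=n, Ni=ni), np.random.default_rng(0), RngState(0))
        block.eval()
        out = block(ag.Tensor(rng.normal(size=(1, 8, 8, ni)).astype(np.float32)))
        assert out.shape == (1, 8, 8, n)

    def test_kernel_weight_count_matches_per_layer_hand_sum(self):
        n, ni = 64, 32
        block = LCB(LCBSpec(N=n, Ni=ni), np.random.default_rng(0), RngState(0))
        hand = ((9 * ni + ni * n)                 # DSC1
                + (ni + n) * (n // 2)             # 1x1 bottleneck 1
                + (9 * (n // 2) + (n // 2) * n)   # DSC2
                + (n // 2 + n) * (n // 2)         # 1x1 bottleneck 2
                + (9 * (n // 2) + (n // 2) * n))  # DSC3
        assert block.weight_count(include_bn=False, include_bias=False) == hand

    def test_channel_mismatch_names_expected_width(self):
        block = LCB(LCBSpec(N=16, Ni=8), np.random.default_rng(0), RngState(0))
        with pytest.raises(ValueError, match="Ni=8"):
            block(ag.Tensor(np.zeros((1, 4, 4, 5), dtype=np.float32)))

    def test_spec_invariants(self):
        with pytest.raises(ValueError):
            LCBSpec(N=15, Ni=8)
        assert LCBSpec(N=64, Ni=8).bottleneck == 32


class TestAttentionGate:
    def test_refined_map_has_skip_shape(self):
        x = rng.normal(size=(2, 28, 28, 128)).astype(np.float32)
        y = rng.normal(size=(2, 14, 14, 256)).astype(np.float32)
        out = attention_gate(x, y, AGSpec(x_channels=128, inter_channels=128))
        assert out.shape == x.shape

    def test_identity_gate_returns_skip_exactly(self):
        gate = AttentionGate(AGSpec(x_channels=8, inter_channels=4),
                             np.random.default_rng(0))
        gate.eval()
        gate.psi.weight.data[:] = 0.0
        gate.psi.bias.data[:] = 500.0  # sigmoid saturates to exactly 1.0
        x = ag.Tensor(rng.normal(size=(1, 8, 8, 8)).astype(np.float32))
        y = ag.Tensor(rng.normal(size=(1, 4, 4, 16)).astype(np.float32))
        out = gate(x, y)
        assert np.array_equal(out.data, x.data)

    def test_gate_values_lie_in_unit_interval(self):
        gate = AttentionGate(AGSpec(x_channels=16, inter_channels=8),
                             np.random.default_rng(3))
        gate.eval()
        for i in range(100):
            r = np.random.default_rng(i)
            x = ag.Tensor(r.normal(scale=3, size=(1, 8, 8, 16)).astype(np.float32))
            y = ag.Tensor(r.normal(scale=3, size=(1, 4, 4, 32)).astype(np.float32))
            alpha = gate.gate(x, y).data
            assert alpha.shape == (1, 8, 8, 1)
            assert (alpha >= 0).all() and (alpha <= 1).all()

    def test_shape_violations_rejected(self):
        gate = AttentionGate(AGSpec(x_channels=8, inter_channels=4),
                             np.random.default_rng(0))
        x = ag.Tensor(np.zeros((1, 8, 8, 8), dtype=np.float32))
        with pytest.raises(ValueError, match="channels"):
            gate(x, ag.Tensor(np.zeros((1, 4, 4, 8), dtype=np.float32)))
        with pytest.raises(ValueError, match="spatial"):
            gate(x, ag.Tensor(np.zeros((1, 8, 8, 16), dtype=np.float32)))


class TestCBAM:
    def test_shape_preserving(self):
        out = cbam(rng.normal(size=(1, 16, 16, 16)).astype(np.float32))
        assert out.shape == (1, 16, 16, 16)

    def test_constant_input_gives_constant_interior_spatial_map(self):
        # Away from the zero-padded border, a constant input is translation
        # symmetric, so the 7x7 spatial attention must be constant there.
        module = CBAM(8, np.random.default_rng(0))
        module.eval()
        x = ag.Tensor(np.full((1, 12, 12, 8), 0.7, dtype=np.float32))
        msp = module.spatial_map(x).data[0, 3:-3, 3:-3, 0]
        assert np.allclose(msp, msp[0, 0])

    def test_channel_map_matches_bruteforce_pooling_mlp(self):
        module = CBAM(8, np.random.default_rng(1))
        module.eval()
        x = rng.normal(size=(2, 4, 4, 8)).astype(np.float32)
        got = module.channel_map(ag.Tensor(x)).data

        # independent recomputation with plain numpy
        w1, b1 = module.mlp1.weight.data, module.mlp1.bias.data
        w2, b2 = module.mlp2.weight.data, module.mlp2.bias.data

        def mlp(v):
            return np.maximum(v @ w1 + b1, 0) @ w2 + b2

        raw = mlp(x.mean(axis=(1, 2))) + mlp(x.max(axis=(1, 2)))
        expected = 1.0 / (1.0 + np.exp(-raw))
        assert np.allclose(got, expected, atol=1e-6)

    def test_attention_values_in_open_unit_interval(self):
        module = CBAM(16, np.random.default_rng(2))
        module.eval()
        x = ag.Tensor(rng.normal(size=(1, 8, 8, 16)).astype(np.float32))
        mch = module.channel_map(x).data
        msp = module.spatial_map(x).data
        assert ((mch > 0) & (mch < 1)).all()
        assert ((msp > 0) & (msp < 1)).all()

    def test_indivisible_reduction_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            CBAM(12, np.random.default_rng(0), CBAMSpec(reduction_ratio=8))
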