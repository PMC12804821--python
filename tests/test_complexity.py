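"""Parameter-reduction calculus and its brute-force counting oracle."""

import numpy as np
import pytest

from caucseg.blocks import LCBSpec
from caucseg.complexity import (
    apr1,
    apr2,
    empirical_pr2,
    full_model_report,
    model_dsc_filters,
    np_dsc,
    np_sc,
    pr1,
    pr2,
    pr2_side,
)


class TestCounts:
    @pytest.mark.parametrize("args,expected", [
        ((3, 64, 128), 73728), ((1, 1, 1), 1), ((3, 3, 64), 1728)])
    def test_standard_conv_count(self, args, expected):
        assert np_sc(*args) == expected

    @pytest.mark.parametrize("args,expected", [
        ((3, 64, 128), 8768), ((3, 128, 256), 33920), ((1, 1, 1), 2)])
    def test_separable_conv_count(self, args, expected):
        assert np_dsc(*args) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            np_sc(0, 1, 1)
        with pytest.raises(ValueError):
            np_dsc(3, -1, 4)
        with pytest.raises(ValueError):
            pr1(0)


class TestPr1:
    def test_endpoint_values(self):
        assert pr1(16) == pytest.approx(1 / 9 + 1 / 16)
        assert pr1(256) == pytest.approx(1 / 9 + 1 / 256)

    def test_equals_count_ratio_for_any_input_width(self):
        for ic in (3, 16, 200):
            assert pr1(64) == pytest.approx(np_dsc(3, ic, 64) / np_sc(3, ic, 64))

    def test_strictly_decreasing_with_limit_one_ninth(self):
        values = [pr1(n) for n in range(1, 513)]
        assert all(a > b for a, b in zip(values, values[1:]))
        assert pr1(10 ** 9) == pytest.approx(1 / 9, abs=1e-8)

    def test_model_average(self):
        filters = model_dsc_filters()
        assert len(filters) == 25
        assert apr1(filters) == pytest.approx(0.1394, abs=5e-4)

    def test_single_and_uniform_lists(self):
        assert apr1([64]) == pytest.approx(pr1(64), rel=1e-12)
        assert apr1([32] * 7) == pytest.approx(pr1(32), rel=1e-12)
        with pytest.raises(ValueError):
            apr1([])


class TestPr2:
    def test_matches_empirical_on_grid(self):
        for n in (16, 32, 48, 64, 96, 128):
            for ni in (8, 16, 32, 64, 128, 256):
                assert abs(pr2(n, ni) - empirical_pr2(LCBSpec(N=n, Ni=ni))) < 1e-12

    def test_below_one_everywhere(self):
        ns = [2, 4, 16, 64, 256, 512]
        assert all(pr2(n, ni) < 1 for n in ns for ni in ns)

    def test_width_patterns_reduce_to_side_forms(self):
        for x in (8, 16, 64):
            assert pr2(2 * x, x) == pytest.approx(pr2_side("encoder", x), rel=1e-12)
            assert pr2(x, 2 * x) == pytest.approx(pr2_side("decoder", x), rel=1e-12)

    def test_ratio_decreases_as_input_width_grows(self):
        values = [empirical_pr2(LCBSpec(N=64, Ni=ni)) for ni in (8, 16, 32, 64, 128, 256)]
        assert all(a > b for a, b in zip(values, values[1:]))


class TestSideForms:
    def test_limit_at_small_x_is_one_third(self):
        # both closed forms tend to 1/3 as x -> 0+
        x = 1e-9
        assert 1 / 3 + 2 * x / (3 * (9 + 2 * x)) == pytest.approx(1 / 3, abs=1e-9)
        assert 1 / 3 + x / (4 * (9 + x)) == pytest.approx(1 / 3, abs=1e-9)
        # and both are already close to it at the smallest admissible width
        assert pr2_side("encoder", 1) == pytest.approx(1 / 3 + 2 / 33, rel=1e-12)
        assert pr2_side("decoder", 1) == pytest.approx(1 / 3 + 1 / 40, rel=1e-12)

    def test_reference_values(self):
        assert pr2_side("encoder", 64) == pytest.approx(1 / 3 + 128 / (3 * 137), rel=1e-12)
        assert pr2_side("decoder", 64) == pytest.approx(1 / 3 + 64 / (4 * 73), rel=1e-12)

    def test_increasing_in_x_and_below_one(self):
        for side in ("encoder", "decoder"):
            values = [pr2_side(side, x) for x in range(1, 300)]
            assert all(a < b for a, b in zip(values, values[1:]))
            assert values[-1] < 1

    def test_invalid_side(self):
        with pytest.raises(ValueError):
            pr2_side("sideways", 8)


class TestApr2:
    def test_model_blocks_pool_to_58_percent(self):
        e, d, pooled = apr2()
        assert pooled == pytest.approx(0.5825, abs=5e-4)
        assert e == pytest.approx(0.630, abs=5e-3)
        assert d == pytest.approx(0.535, abs=5e-3)

    def test_identical_single_element_lists(self):
        e, d, pooled = apr2([16], [16])
        assert e == pr2_side("encoder", 16)
        assert d == pr2_side("decoder", 16)
        assert pooled == pytest.approx((e + d) / 2)

    def test_pooled_mean_bounded_by_side_means(self):
        e, d, pooled = apr2((16, 128), (32, 64))
        assert min(e, d) <= pooled <= max(e, d)

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError):
            apr2([], [16])


def test_full_model_report_consistency():
    rep = full_model_report()
    assert rep.m == 25 and rep.NE == rep.ND == 4
    assert rep.apr1 == pytest.approx(apr1(model_dsc_filters()))
    assert rep.apr2 == pytest.approx(apr2()[2])
    for key, value in rep.pr2_actual.items():
        assert 0 < value < 1
        assert rep.empirical_pr2[key] == pytest.approx(value, abs=1e-12)
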