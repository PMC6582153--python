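"""Head-accounting arithmetic, clamping semantics, and the t-test."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from srxquant import accounting
from srxquant.datatypes import KcatRatio


class TestSequesteredFromRatio:
    def test_fully_open(self):
        assert accounting.sequestered_from_ratio(1.0).sequestered_fraction_pct == 0.0

    def test_wt_ratio(self):
        res = accounting.sequestered_from_ratio(KcatRatio(0.57))
        assert res.sequestered_fraction_pct == pytest.approx(43.0)
        assert not res.capped_flag

    def test_ratio_above_one_clamps_with_flag(self):
        res = accounting.sequestered_from_ratio(1.03)
        assert res.sequestered_fraction_pct == 0.0
        assert res.capped_flag
        assert res.raw_sequestered_pct == pytest.approx(-3.0)


class TestConversionFromRatios:
    def test_printed_ratios(self):
        res = accounting.conversion_from_ratios(0.96, 0.57)
        assert res.raw_conversion_pct == pytest.approx(100 * 0.39 / 0.43)
        assert accounting.round_half_up(res.conversion_pct) == 91.0

    def test_identity_is_zero(self):
        assert accounting.conversion_from_ratios(0.57, 0.57).conversion_pct == 0.0

    def test_above_pool_caps_at_100_with_flag(self):
        res = accounting.conversion_from_ratios(1.03, 0.57)
        assert res.conversion_pct == 100.0
        assert res.capped_flag
        assert res.raw_conversion_pct == pytest.approx(100 * 0.46 / 0.43)

    def test_no_wt_pool_rejected(self):
        with pytest.raises(ValueError, match="no WT sequestered pool"):
            accounting.conversion_from_ratios(0.9, 1.0)

    @given(st.floats(0.0, 0.99), st.floats(0.0, 2.0), st.floats(0.001, 1.0))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_strictly_increasing_in_mutant_ratio(self, r_wt, r_mut, delta):
        lo = accounting.conversion_from_ratios(r_mut, r_wt).raw_conversion_pct
        hi = accounting.conversion_from_ratios(r_mut + delta, r_wt).raw_conversion_pct
        assert hi > lo


class TestSrxDecrease:
    def test_h251n_fractions(self):
        res = accounting.srx_decrease_from_fractions(41.0, 65.0)
        assert res.raw_srx_decrease_pct == pytest.approx(100 * 24 / 59)
        assert accounting.round_half_up(res.srx_decrease_pct) == 41.0

    def test_equal_fractions_zero(self):
        assert accounting.srx_decrease_from_fractions(41.0, 41.0).srx_decrease_pct == 0.0

    def test_r719w_fractions(self):
        res = accounting.srx_decrease_from_fractions(41.0, 81.0)
        assert accounting.round_half_up(res.srx_decrease_pct) == 68.0

    def test_mutant_below_wt_floors_at_zero_with_flag(self):
        res = accounting.srx_decrease_from_fractions(41.0, 30.0)
        assert res.srx_decrease_pct == 0.0
        assert res.capped_flag
        assert res.raw_srx_decrease_pct < 0

    def test_no_wt_pool_rejected(self):
        with pytest.raises(ValueError, match="no SRX pool"):
            accounting.srx_decrease_from_fractions(100.0, 50.0)


@given(
    st.floats(1.0, 99.0),
    st.floats(0.0, 100.0),
)
@settings(max_examples=100, derandomize=True, deadline=None)
def test_two_routes_agree_on_shared_bookkeeping(fast_wt, fast_mut):
    """Ratio route and amplitude route are the same statistic when the kcat
    ratio equals the open-head fraction."""
    by_ratio = accounting.conversion_from_ratios(fast_mut / 100, fast_wt / 100)
    by_fraction = accounting.srx_decrease_from_fractions(fast_wt, fast_mut)
    assert by_ratio.raw_conversion_pct == pytest.approx(
        by_fraction.raw_srx_decrease_pct, rel=1e-12, abs=1e-9)


class TestCompareGroups:
    def test_identical_constant_samples(self):
        r = accounting.compare_groups([3.0, 3.0, 3.0], [3.0, 3.0, 3.0])
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_well_separated_groups(self):
        a = [1.0, 2.0, 3.0]
        b = [11.001, 12.0, 12.999]
        assert accounting.compare_groups(a, b).p_value < 0.001

    def test_matches_welch_textbook_formula(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 2, 12)
        res = accounting.compare_groups(a, b)
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        t = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va ** 2 / (a.size - 1) + vb ** 2 / (b.size - 1))
        from scipy.stats import t as tdist
        p = 2 * tdist.sf(abs(t), df)
        assert res.statistic == pytest.approx(t, rel=1e-10)
        assert res.df == pytest.approx(df, rel=1e-10)
        assert res.p_value == pytest.approx(p, rel=1e-10)

    def test_pooled_variant_matches_student_formula(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 6), rng.normal(1, 1, 9)
        res = accounting.compare_groups(a, b, equal_var=True)
        sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (a.size + b.size - 2)
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / a.size + 1 / b.size))
        assert res.statistic == pytest.approx(t, rel=1e-10)
        assert res.df == a.size + b.size - 2

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            accounting.compare_groups([1.0], [1.0, 2.0])


def test_round_half_up_ties_away_from_zero():
    assert accounting.round_half_up(90.5) == 91.0
    assert accounting.round_half_up(62.79) == 63.0
    assert accounting.round_half_up(0.125, 2) == 0.13
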