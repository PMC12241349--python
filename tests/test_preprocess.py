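"""Preprocessing chain: QA masking, EVI2, noise floor, gap filling, smoothing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from drypheno import (
    InsufficientDataError,
    ReflectanceSeries,
    SyntheticSeasonSpec,
    VISeries,
    apply_qa_mask,
    compute_evi2,
    gapfill_spline,
    mask_low_vi,
    preprocess,
    simulate_series,
    smooth_sg,
)
from drypheno.preprocess import reflectance_to_evi2


def _refl(n=10, qa=0):
    dates = pd.date_range("2010-01-01", periods=n, freq="D")
    return ReflectanceSeries(
        dates=dates,
        nir=np.full(n, 0.4),
        red=np.full(n, 0.1),
        qa_nir=np.full(n, qa),
        qa_red=np.full(n, qa),
    )


class TestQAMask:
    def test_all_accepted_is_identity(self):
        out = apply_qa_mask(_refl(qa=0), accepted_flag=0)
        assert out.valid.all()

    def test_all_rejected_leaves_nothing(self):
        out = apply_qa_mask(_refl(qa=1), accepted_flag=0)
        assert not out.valid.any()

    def test_mixed_flags_and_both_band_rule(self):
        dates = pd.date_range("2010-01-01", periods=3, freq="D")
        series = ReflectanceSeries(
            dates=dates,
            nir=np.full(3, 0.4),
            red=np.full(3, 0.1),
            qa_nir=np.array([0, 1, 0]),
            qa_red=np.array([0, 0, 0]),
        )
        out = apply_qa_mask(series, accepted_flag=0)
        assert out.valid.tolist() == [True, False, True]
        # values untouched
        np.testing.assert_array_equal(out.nir, series.nir)


class TestEVI2:
    @pytest.mark.parametrize(
        "nir,red,expected",
        [
            (0.4, 0.4, 0.0),
            (0.5, 0.1, 2.5 * 0.4 / 1.74),
            (0.3, 0.05, 0.625 / 1.42),
        ],
    )
    def test_hand_computed_values(self, nir, red, expected):
        assert compute_evi2(nir, red) == pytest.approx(expected, rel=1e-12)

    @given(st.floats(min_value=0.0, max_value=1.0))
    def test_equal_bands_give_zero(self, x):
        assert compute_evi2(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_nonfinite_propagates_as_nan(self):
        out = compute_evi2([0.4, np.nan], [0.1, 0.1])
        assert np.isfinite(out[0]) and np.isnan(out[1])

    def test_reflectance_to_evi2_grid(self):
        vi = reflectance_to_evi2(_refl(n=5))
        assert len(vi) == 5
        assert vi.valid.all()


class TestMaskLowVI:
    def test_above_floor_unchanged(self):
        s = VISeries(pd.date_range("2010-01-01", periods=5), np.full(5, 0.5))
        assert mask_low_vi(s).valid.all()

    def test_boundary_is_inclusive(self):
        s = VISeries(pd.date_range("2010-01-01", periods=3), [0.08, 0.0801, 0.5])
        out = mask_low_vi(s, floor=0.08)
        assert out.valid.tolist() == [False, True, True]

    def test_enumerated_counts(self):
        s = VISeries(pd.date_range("2010-01-01", periods=3), [0.05, 0.09, 0.20])
        assert mask_low_vi(s).n_valid == 2

    def test_idempotent(self):
        s = VISeries(pd.date_range("2010-01-01", periods=4), [0.05, 0.2, 0.08, 0.3])
        once = mask_low_vi(s)
        twice = mask_low_vi(once)
        np.testing.assert_array_equal(once.valid, twice.valid)


class TestGapfill:
    def test_no_gaps_is_identity(self):
        s = VISeries(pd.date_range("2010-01-01", periods=10), np.linspace(0.1, 0.5, 10))
        out = gapfill_spline(s)
        np.testing.assert_array_equal(out.values, s.values)

    def test_linear_ramp_gap_filled_linearly(self):
        vals = np.linspace(0.1, 0.5, 11)
        missing = vals.copy()
        missing[5] = np.nan
        s = VISeries(pd.date_range("2010-01-01", periods=11), missing)
        out = gapfill_spline(s)
        assert out.valid[5]
        assert out.values[5] == pytest.approx(vals[5], abs=1e-12)

    def test_long_gap_stays_invalid(self):
        n = 200
        vals = 0.3 + 0.1 * np.sin(np.arange(n) / 30)
        vals[50:140] = np.nan  # 90-day gap
        s = VISeries(pd.date_range("2010-01-01", periods=n), vals)
        out = gapfill_spline(s, max_gap_days=60)
        assert not out.valid[50:140].any()
        assert out.valid[:50].all() and out.valid[140:].all()

    def test_valid_values_bit_identical_on_noisy_series(self):
        rng = np.random.default_rng(0)
        vals = 0.3 + rng.normal(0, 0.02, 120)
        vals[40:50] = np.nan
        s = VISeries(pd.date_range("2010-01-01", periods=120), vals)
        out = gapfill_spline(s)
        np.testing.assert_array_equal(out.values[s.valid], s.values[s.valid])
        assert out.valid[40:50].all()

    def test_too_few_points_raises(self):
        s = VISeries(pd.date_range("2010-01-01", periods=3), [0.1, 0.2, 0.3])
        with pytest.raises(InsufficientDataError):
            gapfill_spline(s)


class TestSmoothSG:
    def test_quadratic_reproduced_exactly(self):
        t = np.arange(60, dtype=float)
        vals = 0.2 + 0.001 * t + 0.0001 * t**2
        s = VISeries(pd.date_range("2010-01-01", periods=60), vals)
        out = smooth_sg(s, window_days=31, polyorder=2)
        np.testing.assert_allclose(out.values, vals, atol=1e-12)

    def test_spike_attenuated(self):
        vals = np.full(60, 0.2)
        vals[30] = 0.6
        s = VISeries(pd.date_range("2010-01-01", periods=60), vals)
        out = smooth_sg(s)
        assert out.values[30] < 0.6
        assert out.values[30] > 0.2

    def test_linearity(self):
        rng = np.random.default_rng(1)
        a, b = 0.7, 1.3
        v1 = 0.3 + rng.normal(0, 0.05, 80)
        v2 = 0.2 + rng.normal(0, 0.05, 80)
        dates = pd.date_range("2010-01-01", periods=80)
        s1 = smooth_sg(VISeries(dates, v1)).values
        s2 = smooth_sg(VISeries(dates, v2)).values
        s12 = smooth_sg(VISeries(dates, a * v1 + b * v2)).values
        np.testing.assert_allclose(s12, a * s1 + b * s2, atol=1e-12)

    def test_window_exceeding_span_raises(self):
        s = VISeries(pd.date_range("2010-01-01", periods=10), np.full(10, 0.3))
        with pytest.raises(InsufficientDataError):
            smooth_sg(s, window_days=31)


def test_full_chain_distortion_below_noise_floor(noiseless_spec):
    """On noiseless synthetic data the whole chain is nearly a no-op."""
    series, _ = simulate_series(noiseless_spec, years=(2009, 2011))
    clean = preprocess(series)
    dev = np.abs(clean.values[clean.valid] - series.values[clean.valid])
    assert dev.max() < SyntheticSeasonSpec().noise_sd
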