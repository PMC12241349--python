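"""Season detection: retrieval window, peaks, threshold, delineation."""

import numpy as np
import pandas as pd
import pytest

from drypheno import (
    InsufficientDataError,
    SeasonConfig,
    SyntheticSeasonSpec,
    VISeries,
    build_retrieval_window,
    crossing_date,
    delineate_season,
    dynamic_threshold_filter,
    find_candidate_peaks,
    preprocess,
    retrieve_pheno,
    simulate_series,
    true_crossings,
)
from drypheno.seasons import FlatSeasonError, RetrievalWindow, records_to_table


def _const_series(value=0.3, start="2009-01-01", end="2011-12-31"):
    dates = pd.date_range(start, end, freq="D")
    return VISeries(dates=dates, values=np.full(len(dates), value))


def _bump_series(height, center_doy=180, width=60, base=0.15, year=2010):
    """Triangular bump of given height over a flat base, 3-year span."""
    dates = pd.date_range(f"{year - 1}-01-01", f"{year + 1}-12-31", freq="D")
    t = (dates - pd.Timestamp(f"{year}-01-01")) / pd.Timedelta(days=1) + 1.0
    tri = np.clip(1.0 - np.abs(np.asarray(t) - center_doy) / width, 0.0, None)
    return VISeries(dates=dates, values=base + height * tri)


class TestRetrievalWindow:
    def test_span_convention(self):
        w = build_retrieval_window(_const_series(), 2010)
        assert w.start_date == pd.Timestamp("2009-07-01")
        assert w.end_date == pd.Timestamp("2011-06-30")

    def test_constant_series_mean(self):
        w = build_retrieval_window(_const_series(0.3), 2010)
        assert w.window_mean == pytest.approx(0.3)

    def test_mean_ignores_invalid_flanks(self):
        dates = pd.date_range("2009-01-01", "2011-12-31", freq="D")
        values = np.full(len(dates), np.nan)
        in2010 = (dates >= "2010-01-01") & (dates <= "2010-12-31")
        values[in2010] = 0.3
        s = VISeries(dates=dates, values=values)
        w = build_retrieval_window(s, 2010)
        assert w.window_mean == pytest.approx(0.3)
        assert w.n_valid_days == int(in2010.sum())

    def test_insufficient_overlap_raises(self):
        s = _const_series(start="2010-06-01", end="2010-08-01")
        with pytest.raises(InsufficientDataError):
            build_retrieval_window(s, 2010)


class TestCandidatePeaks:
    def test_monotone_series_has_no_peaks(self):
        dates = pd.date_range("2009-01-01", "2011-12-31", freq="D")
        s = VISeries(dates=dates, values=np.linspace(0.1, 0.6, len(dates)))
        w = build_retrieval_window(s, 2010)
        assert find_candidate_peaks(s, w) == []

    def test_unimodal_peak_near_analytic_argmax(self, noiseless_spec):
        series, truth = simulate_series(noiseless_spec, years=(2009, 2011))
        clean = preprocess(series)
        w = build_retrieval_window(clean, 2010)
        peaks = find_candidate_peaks(clean, w)
        pos_2010 = [t.pos for t in truth if t.year == 2010][0]
        doys = [
            (p - pd.Timestamp("2010-01-01")) / pd.Timedelta(days=1) + 1 for p in peaks
        ]
        assert any(abs(d - pos_2010) <= 1.0 for d in doys)

    def test_bimodal_yields_two_peaks(self):
        s1 = SyntheticSeasonSpec(t1=60, t2=130, noise_sd=0, gap_fraction=0)
        s2 = SyntheticSeasonSpec(t1=230, t2=300, a=0.2, noise_sd=0, gap_fraction=0)
        series, _ = simulate_series([s1, s2], years=(2009, 2011))
        clean = preprocess(series)
        w = build_retrieval_window(clean, 2010)
        peaks = [p for p in find_candidate_peaks(clean, w) if p.year == 2010]
        assert len(peaks) == 2


class TestDynamicThreshold:
    def _window(self, mean):
        return RetrievalWindow(
            target_year=2010,
            start_date=pd.Timestamp("2009-07-01"),
            end_date=pd.Timestamp("2011-06-30"),
            window_mean=mean,
            n_valid_days=730,
        )

    def test_inclusive_gating(self):
        s = _bump_series(height=0.2)
        w0 = build_retrieval_window(s, 2010)
        peak = find_candidate_peaks(s, w0)[0]
        peak_value = s.values[s.dates.get_loc(peak)]
        kept = dynamic_threshold_filter([peak], s, self._window(peak_value))
        assert kept == [peak]  # equality retained
        kept = dynamic_threshold_filter([peak], s, self._window(peak_value + 1e-12))
        assert kept == []
        kept = dynamic_threshold_filter([peak], s, self._window(peak_value - 1e-12))
        assert kept == [peak]


class TestCrossingDate:
    def test_linear_ramp(self):
        dates = pd.date_range("2010-01-01", periods=41, freq="D")
        s = VISeries(dates=dates, values=np.linspace(0.1, 0.5, 41))
        c = crossing_date(s, 0.3, anchor=dates[-1], side="left")
        assert (c - dates[0]) / pd.Timedelta(days=1) == pytest.approx(20.0)

    def test_symmetric_triangle(self):
        s = _bump_series(height=0.3, center_doy=182, width=60)
        anchor = pd.Timestamp("2010-07-01")
        left = crossing_date(s, 0.3, anchor, "left")
        right = crossing_date(s, 0.3, anchor, "right")
        d_left = (anchor - left) / pd.Timedelta(days=1)
        d_right = (right - anchor) / pd.Timedelta(days=1)
        assert d_left == pytest.approx(d_right, abs=1e-9)

    def test_double_logistic_crossing_matches_analytic_root(self, noiseless_spec):
        series, _ = simulate_series(noiseless_spec, years=(2009, 2011))
        sos_true, _ = true_crossings(noiseless_spec, 0.5)
        level = noiseless_spec.b + 0.5 * noiseless_spec.a  # baseline flat, amp = a
        anchor = pd.Timestamp("2010-01-01") + pd.Timedelta(days=180)
        c = crossing_date(series, level, anchor, "left")
        doy = (c - pd.Timestamp("2010-01-01")) / pd.Timedelta(days=1) + 1
        assert abs(doy - sos_true) <= 1.0


class TestDelineate:
    def test_arithmetic_example(self):
        # construct a series hitting left_min 0.1, peak 0.5, right_min 0.2
        up = np.linspace(0.1, 0.5, 41)
        down = np.linspace(0.5, 0.2, 31)[1:]
        vals = np.concatenate([up, down])
        dates = pd.date_range("2010-03-01", periods=len(vals), freq="D")
        s = VISeries(dates=dates, values=vals)
        m = delineate_season(
            s, peak=dates[40], left_bound=dates[0], right_bound=dates[-1],
            threshold_fraction=0.5, target_year=2010,
        )
        assert m.baseline == pytest.approx(0.15)
        assert m.amplitude == pytest.approx(0.35)
        # SOS at level 0.30 on a 0.1->0.5 ramp over 40 days -> 20 days in
        sos_offset = m.sos - ((dates[0] - pd.Timestamp("2010-01-01")) / pd.Timedelta(days=1) + 1)
        assert sos_offset == pytest.approx(20.0, abs=1e-9)

    def test_constant_series_rejected(self):
        s = _const_series(0.3, "2010-01-01", "2010-12-31")
        with pytest.raises(FlatSeasonError):
            delineate_season(
                s, peak=s.dates[180], left_bound=s.dates[0], right_bound=s.dates[-1]
            )


class TestRetrievePheno:
    def test_noiseless_unimodal_within_one_day(self, noiseless_spec):
        series, truth = simulate_series(noiseless_spec, years=(2009, 2011))
        rec = retrieve_pheno(preprocess(series), 2010)
        t = [x for x in truth if x.year == 2010][0]
        assert rec.status == "retrieved" and len(rec.seasons) == 1
        assert abs(rec.seasons[0].sos - t.sos) <= 1.0
        assert abs(rec.seasons[0].eos - t.eos) <= 1.0

    def test_all_masked_series_is_insufficient(self):
        from drypheno import mask_low_vi

        rec = retrieve_pheno(mask_low_vi(_const_series(0.05)), 2010)
        assert rec.status == "insufficient_data"
        assert rec.seasons == ()

    def test_flat_series_status(self, flat_series):
        rec = retrieve_pheno(flat_series, 2010)
        assert rec.status == "flat_series"

    def test_shift_equivariance(self, noiseless_spec):
        """Adding a constant to the index leaves SOS/POS/EOS unchanged."""
        series, _ = simulate_series(noiseless_spec, years=(2009, 2011))
        rec0 = retrieve_pheno(preprocess(series), 2010)
        shifted = series.with_values(series.values + 0.2)
        rec1 = retrieve_pheno(preprocess(shifted), 2010)
        for a, b in zip(rec0.seasons, rec1.seasons):
            assert a.sos == pytest.approx(b.sos, abs=1e-6)
            assert a.pos == pytest.approx(b.pos, abs=1e-6)
            assert a.eos == pytest.approx(b.eos, abs=1e-6)
            assert b.baseline == pytest.approx(a.baseline + 0.2, abs=1e-6)

    def test_time_translation_equivariance(self, noiseless_spec):
        """Same spec anchored in different years gives the same DOYs."""
        s_a, _ = simulate_series(noiseless_spec, years=(2009, 2011))
        s_b, _ = simulate_series(noiseless_spec, years=(2013, 2015))
        rec_a = retrieve_pheno(preprocess(s_a), 2010)
        rec_b = retrieve_pheno(preprocess(s_b), 2014)
        assert len(rec_a.seasons) == len(rec_b.seasons) == 1
        assert rec_a.seasons[0].sos == pytest.approx(rec_b.seasons[0].sos, abs=1.0)
        assert rec_a.seasons[0].eos == pytest.approx(rec_b.seasons[0].eos, abs=1.0)

    def test_three_peaks_keep_two_largest_amplitudes(self):
        """Independent oracle: amplitudes are known by construction."""
        specs = [
            SyntheticSeasonSpec(t1=30, t2=80, a=0.10, r1=0.2, r2=0.2,
                                noise_sd=0, gap_fraction=0),
            SyntheticSeasonSpec(t1=150, t2=200, a=0.30, r1=0.2, r2=0.2,
                                noise_sd=0, gap_fraction=0),
            SyntheticSeasonSpec(t1=270, t2=320, a=0.20, r1=0.2, r2=0.2,
                                noise_sd=0, gap_fraction=0),
        ]
        series, _ = simulate_series(specs, years=(2009, 2011))
        rec = retrieve_pheno(preprocess(series), 2010)
        assert len(rec.seasons) == 2
        # chronological report with rank 1, 2; the a=0.10 season dropped
        assert rec.seasons[0].rank == 1 and rec.seasons[1].rank == 2
        assert rec.seasons[0].pos < rec.seasons[1].pos
        amps = sorted(s.amplitude for s in rec.seasons)
        assert amps[0] == pytest.approx(0.20, abs=0.03)
        assert amps[1] == pytest.approx(0.30, abs=0.03)

    def test_records_table_schema(self, noiseless_spec):
        series, _ = simulate_series(noiseless_spec, years=(2009, 2011))
        rec = retrieve_pheno(preprocess(series), 2010)
        df = records_to_table([rec], site="site_a")
        assert set(df.columns) >= {
            "site", "year", "season", "sos", "pos", "eos", "los",
            "baseline", "amplitude", "peak_value", "status",
        }
        assert (df["status"] == "retrieved").all()


def test_season_config_threshold_override(noiseless_spec):
    series, _ = simulate_series(noiseless_spec, years=(2009, 2011))
    clean = preprocess(series)
    rec_50 = retrieve_pheno(clean, 2010, threshold_fraction=0.5)
    rec_20 = retrieve_pheno(clean, 2010, threshold_fraction=0.2)
    assert rec_20.seasons[0].sos < rec_50.seasons[0].sos
    assert rec_20.seasons[0].eos > rec_50.seasons[0].eos
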