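"""Correlation, lag, coherence and Granger operations."""
import numpy as np
import pytest

from chronolfp.coupling import (CoherenceConfig, CountPlotConfig, band_pair_matrix,
                                correlation_count, cross_correlation, granger_test,
                                lag_bin_summary, matching_band_coefficients,
                                msc_coherence, pearson_xy)
from chronolfp.datatypes import BandPowerSeries, RecordingMeta
from chronolfp.synthetic import _ar1, _rng


class TestPearson:
    def test_affine_relation(self, rng):
        a = rng.standard_normal(100)
        out = pearson_xy(a, 2.0 * a + 1.0)
        assert out["r"] == pytest.approx(1.0)
        assert out["slope"] == pytest.approx(2.0)
        assert out["intercept"] == pytest.approx(1.0)

    def test_anticorrelation(self, rng):
        a = rng.standard_normal(100)
        assert pearson_xy(a, -a)["r"] == pytest.approx(-1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(50):
            r = pearson_xy(rng.standard_normal(21600), rng.standard_normal(21600))["r"]
            hits += abs(r) < 0.02
        assert hits >= 48

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_xy(np.ones(10), np.arange(10.0))


def _band_series(values, region="SCN", bin_s=4.0):
    n = values.shape[0]
    return BandPowerSeries(meta=RecordingMeta(region=region), bin_s=bin_s,
                           zt_hours=np.arange(n) * bin_s / 3600.0, values=values)


class TestBandPairMatrix:
    def test_identical_series_matched_cells_one(self, rng):
        v = np.abs(rng.standard_normal((21600, 10))) + 0.1
        m = band_pair_matrix(_band_series(v), _band_series(v, region="NAC"))
        match = matching_band_coefficients(m)
        assert np.allclose(match["day"], 1.0)
        assert np.allclose(match["night"], 1.0)

    def test_cells_equal_halfday_pearson_oracle(self, rng):
        va = np.abs(rng.standard_normal((21600, 10))) + 0.1
        vb = 0.5 * va + 0.5 * (np.abs(rng.standard_normal((21600, 10))) + 0.1)
        scn, nac = _band_series(va), _band_series(vb, region="NAC")
        m = band_pair_matrix(scn, nac)
        day = scn.zt_hours < 12.0
        # one within-region and one cross-region cell, both half-days
        r_day = pearson_xy(va[day, 0], vb[day, 3])["r"]
        assert m.loc["SCN:delta", "NAC:alpha1"] == pytest.approx(r_day, rel=1e-9)
        r_night = pearson_xy(vb[~day, 3], va[~day, 0])["r"]
        assert m.loc["NAC:alpha1", "SCN:delta"] == pytest.approx(r_night, rel=1e-9)

    def test_shuffled_time_matched_bands_near_zero(self, rng):
        va = np.abs(rng.standard_normal((21600, 10))) + 0.1
        vb = va[rng.permutation(21600)]
        m = band_pair_matrix(_band_series(va), _band_series(vb, region="NAC"))
        match = matching_band_coefficients(m)
        assert np.all(np.abs(match["day"]) < 0.05)

    def test_matching_vector_length_ten(self, rng):
        v = np.abs(rng.standard_normal((1800, 10))) + 0.1
        m = band_pair_matrix(_band_series(v), _band_series(v, region="NAC"))
        match = matching_band_coefficients(m)
        assert match["day"].size == match["night"].size == 10


class TestCorrelationCount:
    def test_identical_series_no_discordant(self, rng):
        z = rng.standard_normal(21600)
        zt = np.arange(21600) * 4.0 / 3600.0
        counts = correlation_count(z, z, zt)
        assert counts["high_low"].sum() == 0
        assert counts["low_high"].sum() == 0

    def test_negated_series_no_concordant(self, rng):
        z = rng.standard_normal(21600)
        z[z == 0] = 0.1
        zt = np.arange(21600) * 4.0 / 3600.0
        counts = correlation_count(z, -z, zt)
        assert counts["high_high"].sum() == 0
        assert counts["low_low"].sum() == 0

    def test_rows_partition_bins(self, rng):
        z1, z2 = rng.standard_normal((2, 21600))
        zt = np.arange(21600) * 4.0 / 3600.0
        counts = correlation_count(z1, z2, zt)
        assert counts.shape == (8, 4)
        assert np.all(counts.sum(axis=1) == 2700)

    def test_window_must_tile_day(self):
        with pytest.raises(ValueError):
            CountPlotConfig(window_h=5.0)


class TestCrossCorrelation:
    def test_delay_peaks_at_positive_lag(self, rng):
        a = rng.standard_normal(5000)
        b = np.roll(a, 5)  # b_t = a_{t-5}: a leads by 5
        lc = cross_correlation(a, b, max_lag_s=20.0)
        assert lc.lags_s[np.argmax(lc.coefficients)] == 5.0

    def test_autocorrelation_lag0_is_one(self, rng):
        a = rng.standard_normal(1000)
        assert cross_correlation(a, a, max_lag_s=10.0).at(0.0) == pytest.approx(1.0)

    def test_ar1_acf_matches_theory(self):
        a = _ar1(_rng(3, 7), 86400, 0.9, 1.0)
        lc = cross_correlation(a, a, max_lag_s=10.0)
        for k in range(1, 11):
            assert lc.at(float(k)) == pytest.approx(0.9 ** k, abs=0.05)

    def test_symmetry_under_argument_swap(self, rng):
        a, b = rng.standard_normal((2, 2000))
        ab = cross_correlation(a, b, max_lag_s=15.0)
        ba = cross_correlation(b, a, max_lag_s=15.0)
        assert np.allclose(ab.coefficients, ba.coefficients[::-1], atol=1e-12)

    def test_max_lag_too_long_rejected(self, rng):
        with pytest.raises(ValueError):
            cross_correlation(rng.standard_normal(50), rng.standard_normal(50),
                              max_lag_s=50.0)


class TestLagBins:
    def _profile(self, coeffs):
        from chronolfp.coupling import LagCorrelation
        return LagCorrelation(lags_s=np.arange(-60.0, 61.0), coefficients=coeffs)

    def test_constant_profile(self):
        out = lag_bin_summary(self._profile(np.full(121, 0.3)))
        assert all(v == pytest.approx(0.3) for v in out.values())

    def test_symmetric_profile_pairs_equal(self):
        lags = np.arange(-60.0, 61.0)
        out = lag_bin_summary(self._profile(np.exp(-np.abs(lags) / 10.0)))
        assert out["neg_far"] == pytest.approx(out["pos_far"])
        assert out["neg_near"] == pytest.approx(out["pos_near"])

    def test_matches_direct_mean_oracle(self, rng):
        c = rng.standard_normal(121)
        lags = np.arange(-60, 61)
        out = lag_bin_summary(self._profile(c))
        assert out["neg_far"] == pytest.approx(c[(lags >= -60) & (lags <= -30)].mean())
        assert out["pos_near"] == pytest.approx(c[(lags >= 1) & (lags <= 29)].mean())


class TestCoherence:
    def test_identical_signals_full_coherence(self, rng):
        x = rng.standard_normal(int(500 * 360))
        _, c = msc_coherence(x, x, fs=500.0)
        assert np.all(np.abs(c - 1.0) < 1e-6)

    def test_independent_noise_low_coherence(self, rng):
        a, b = rng.standard_normal((2, int(500 * 360)))
        _, c = msc_coherence(a, b, fs=500.0)
        assert c.mean() < 0.2

    def test_shared_tone_peaks_at_tone_frequency(self, rng):
        n = int(500 * 360)
        t = np.arange(n) / 500.0
        tone = np.sin(2 * np.pi * 10.0 * t)
        a = tone + rng.standard_normal(n)
        b = tone + rng.standard_normal(n)
        f, c = msc_coherence(a, b, fs=500.0)
        band = (f >= 5) & (f <= 15)
        assert c[np.argmin(np.abs(f - 10.0))] > np.median(c[band])

    def test_scale_invariance(self, rng):
        a, b = rng.standard_normal((2, int(500 * 250)))
        _, c1 = msc_coherence(a, b, fs=500.0)
        _, c2 = msc_coherence(5.0 * a, 0.2 * b, fs=500.0)
        assert np.allclose(c1, c2, atol=1e-10)

    def test_short_trace_rejected(self, rng):
        with pytest.raises(ValueError):
            msc_coherence(rng.standard_normal(100), rng.standard_normal(100), fs=500.0)


class TestGranger:
    def test_strong_unidirectional_coupling_detected(self):
        rng = np.random.default_rng(11)
        n = 5000
        a = rng.standard_normal(n)
        b = np.empty(n)
        b[0] = 0.0
        for t in range(1, n):
            b[t] = 0.8 * a[t - 1] + 0.1 * rng.standard_normal()
        res = granger_test(a, b, order=1)
        assert res["a->b"].p_value < 1e-6
        assert res["b->a"].p_value > 1e-4

    def test_time_reversal_flips_direction(self):
        rng = np.random.default_rng(12)
        n = 5000
        a = rng.standard_normal(n)
        b = np.r_[0.0, 0.8 * a[:-1]] + 0.1 * rng.standard_normal(n)
        fwd = granger_test(a, b, order=1)
        rev = granger_test(a[::-1], b[::-1], order=1)
        assert fwd["a->b"].p_value < 1e-6
        assert rev["b->a"].p_value < 1e-6
        assert rev["a->b"].p_value > fwd["a->b"].p_value

    def test_matches_statsmodels_reference(self):
        from statsmodels.tsa.stattools import grangercausalitytests
        rng = np.random.default_rng(13)
        n = 1000
        a = rng.standard_normal(n)
        b = np.r_[0.0, 0.4 * a[:-1]] + rng.standard_normal(n)
        ours = granger_test(a, b, order=1)["a->b"]
        ref = grangercausalitytests(np.column_stack([b, a]), maxlag=1, verbose=False)
        f_ref, p_ref, *_ = ref[1][0]["ssr_ftest"]
        assert ours.f_stat == pytest.approx(f_ref, rel=1e-6)
        assert ours.p_value == pytest.approx(p_ref, rel=1e-6)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            granger_test(np.ones(100), np.arange(100.0), order=1)
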