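"""Burg estimation, AIC order selection, PSD, confidence intervals and
band-power statistics."""

from collections import Counter

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from cortexdamage.fixtures import gen_ar_fixture
from cortexdamage.spectral_stats import (
    PSDEstimate, _ar_autocovariance, ar_psd, band_grid, band_power, burg_fit,
    compare_bands, default_freq_grid, power_ratio_db, psd_confidence,
    select_order_aic,
)

# well-separated AR(4): complex pole pairs at r=0.8, 0.3 rad and r=0.7, 1.2 rad
_POLES = [0.8 * np.exp(1j * 0.3), 0.8 * np.exp(-1j * 0.3),
          0.7 * np.exp(1j * 1.2), 0.7 * np.exp(-1j * 1.2)]
AR4_TRUE = np.real(np.poly(_POLES))[1:]


def _fit_estimate(a, s2, rate, n, order):
    f = default_freq_grid()
    return PSDEstimate(np.asarray(a), np.zeros(order), s2, order, rate, n,
                       freq_hz=f, psd=ar_psd(a, s2, rate, f))


def brute_force_burg(x, order):
    """Independent lattice oracle: numerically minimise the summed
    forward+backward prediction error over each reflection coefficient."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    ef, eb = x.copy(), x.copy()
    a = np.zeros(0)
    for m in range(order):
        efp, ebp = ef[m + 1:n], eb[m:n - 1]

        def cost(k):
            return np.sum((efp + k * ebp) ** 2) + np.sum((ebp + k * efp) ** 2)

        k = minimize_scalar(cost, bounds=(-1.0, 1.0), method="bounded",
                            options={"xatol": 1e-13}).x
        a = np.concatenate([a, [0.0]]) + k * np.concatenate([a[::-1], [1.0]])
        ef_new = efp + k * ebp
        eb_new = ebp + k * efp
        ef[m + 1:n] = ef_new
        eb[m + 1:n] = eb_new
    return a


class TestBurgFit:
    def test_recovers_ar1_coefficient(self):
        # x_t = 0.8 x_{t-1} + eps  →  denominator coefficient a1 = −0.8
        x = gen_ar_fixture([-0.8], 1.0, 10_000, seed=1)
        a, ks, s2 = burg_fit(x, 1)
        assert a[0] == pytest.approx(-0.8, abs=0.02)
        assert s2 == pytest.approx(1.0, rel=0.05)
        assert np.all(np.abs(ks) < 1.0)

    def test_white_noise_coefficients_are_small(self):
        x = gen_ar_fixture([], 1.0, 10_000, seed=2)
        a, _, _ = burg_fit(x, 4)
        assert np.all(np.abs(a) < 0.05)

    def test_matches_brute_force_lattice_oracle_on_small_series(self):
        for seed in range(5):
            x = gen_ar_fixture(AR4_TRUE, 1.0, 64, seed=seed)
            a, _, _ = burg_fit(x, 4)
            a_oracle = brute_force_burg(x, 4)
            np.testing.assert_allclose(a, a_oracle, atol=1e-8)

    def test_matches_statsmodels_burg(self):
        from statsmodels.regression.linear_model import burg as sm_burg
        x = gen_ar_fixture(AR4_TRUE, 1.0, 5000, seed=3)
        a, _, s2 = burg_fit(x - x.mean(), 4)
        phi, sm_s2 = sm_burg(x - x.mean(), 4)
        np.testing.assert_allclose(a, -phi, atol=1e-10)
        # noise-variance normalisations differ slightly between packages
        assert s2 == pytest.approx(sm_s2, rel=1e-3)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            burg_fit(np.ones(100), 2)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            burg_fit(np.arange(8.0), 4)


class TestOrderSelection:
    @pytest.mark.parametrize("coeffs,true_order",
                             [(list(AR4_TRUE), 4), ([-0.8], 1), ([], 0)])
    def test_aic_never_underfits_and_centres_on_true_order(self, coeffs, true_order):
        sel = Counter()
        for seed in range(20):
            x = gen_ar_fixture(coeffs, 1.0, 19_000 if true_order == 4 else 10_000,
                               seed=100 + seed)
            sel[select_order_aic(x, 20)] += 1
        assert min(sel) >= true_order          # AIC does not underfit
        assert sel.most_common(1)[0][0] == true_order
        assert sel[true_order] >= 12           # majority of seeds exact


class TestArPsd:
    def test_white_noise_psd_is_flat_and_integrates_to_variance(self):
        rate, s2 = 1000.0, 2.0
        f = np.linspace(0.0, rate / 2, 5001)
        S = ar_psd(np.zeros(0), s2, rate, f)
        assert np.allclose(S, S[0])
        assert S[0] == pytest.approx(s2 / (rate / 2))
        assert np.trapezoid(S, f) == pytest.approx(s2, rel=1e-9)

    def test_ar1_low_high_frequency_ratio_matches_closed_form(self):
        rate = 1000.0
        S = ar_psd(np.array([-0.9]), 1.0, rate, np.array([0.0, rate / 2]))
        assert S[0] / S[1] == pytest.approx(((1 + 0.9) / (1 - 0.9)) ** 2, rel=1e-9)

    def test_ar2_peak_at_pole_frequency(self):
        rate = 1000.0
        f_pole = 10.0
        th = 2 * np.pi * f_pole / rate
        # pole radius near 1 so the spectral peak sits at the pole angle
        a = np.real(np.poly([0.995 * np.exp(1j * th), 0.995 * np.exp(-1j * th)]))[1:]
        f = default_freq_grid()
        S = ar_psd(a, 1.0, rate, f)
        assert f[np.argmax(S)] == pytest.approx(f_pole, abs=0.2)

    def test_positivity_everywhere(self):
        S = ar_psd(AR4_TRUE, 1.0, 1000.0, default_freq_grid())
        assert np.all(S > 0)

    def test_unstable_model_rejected(self):
        with pytest.raises(ValueError):
            ar_psd(np.array([-1.2]), 1.0, 1000.0, np.array([1.0]))

    def test_one_sided_psd_integrates_to_model_variance(self):
        x = gen_ar_fixture(AR4_TRUE, 1.0, 8000, seed=3)
        a, _, s2 = burg_fit(x, 4)
        rate = 1000.0
        f = np.linspace(0.005, rate / 2, 20001)
        S = ar_psd(a, s2, rate, f)
        var_model = _ar_autocovariance(a, s2, 0)[0]
        assert np.trapezoid(S, f) == pytest.approx(var_model, rel=0.01)


class TestConfidence:
    def test_asymptotic_coverage_on_known_ar4(self):
        rate, n = 1000.0, 4000
        f = default_freq_grid()
        S_true = ar_psd(AR4_TRUE, 1.0, rate, f)
        covered = []
        for seed in range(100):
            x = gen_ar_fixture(AR4_TRUE, 1.0, n, seed=1000 + seed)
            a, ks, s2 = burg_fit(x, 4)
            est = PSDEstimate(a, ks, s2, 4, rate, n, freq_hz=f,
                              psd=ar_psd(a, s2, rate, f))
            lo, hi = psd_confidence(est)
            covered.append(np.mean((S_true >= lo) & (S_true <= hi)))
        assert np.mean(covered) >= 0.95

    def test_interval_width_shrinks_with_sample_size(self):
        rate = 1000.0
        widths = {}
        for n in (10_000, 40_000):
            x = gen_ar_fixture(AR4_TRUE, 1.0, n, seed=7)
            a, ks, s2 = burg_fit(x, 4)
            est = PSDEstimate(a, ks, s2, 4, rate, n, freq_hz=default_freq_grid(),
                              psd=ar_psd(a, s2, rate, default_freq_grid()))
            lo, hi = psd_confidence(est)
            widths[n] = np.mean(hi - lo)
        assert widths[40_000] < widths[10_000]

    def test_bootstrap_requires_replicates(self):
        est = _fit_estimate(AR4_TRUE, 1.0, 1000.0, 4000, 4)
        with pytest.raises(ValueError):
            psd_confidence(est, method="resample", n_boot=0)

    def test_bootstrap_agrees_with_asymptotic_scale(self):
        x = gen_ar_fixture(AR4_TRUE, 1.0, 8000, seed=3)
        a, ks, s2 = burg_fit(x, 4)
        f = default_freq_grid()
        e1 = PSDEstimate(a, ks, s2, 4, 1000.0, 8000, freq_hz=f,
                         psd=ar_psd(a, s2, 1000.0, f))
        lo_a, hi_a = psd_confidence(e1)
        e2 = PSDEstimate(a, ks, s2, 4, 1000.0, 8000, freq_hz=f,
                         psd=ar_psd(a, s2, 1000.0, f))
        lo_b, hi_b = psd_confidence(e2, method="resample", n_boot=100, seed=0)
        ratio = np.median((hi_a - lo_a) / (hi_b - lo_b))
        assert 0.5 < ratio < 2.0


class TestBandPower:
    def test_low_band_has_390_points(self):
        assert len(band_grid(1.0, 40.0)) == 390

    def test_high_band_has_600_points(self):
        assert len(band_grid(40.0, 100.0)) == 600

    def test_single_point_band(self):
        est = _fit_estimate(AR4_TRUE, 1.0, 1000.0, 4000, 4)
        psd_confidence(est)
        bp = band_power(est, (1.0, 1.1))
        assert bp.n_points == 1
        assert bp.power_sum == pytest.approx(
            float(ar_psd(AR4_TRUE, 1.0, 1000.0, np.array([1.0]))[0]))

    def test_empty_band_rejected(self):
        est = _fit_estimate(AR4_TRUE, 1.0, 1000.0, 4000, 4)
        with pytest.raises(ValueError):
            band_power(est, (40.0, 40.0))


class TestCompareBands:
    def _bp(self, power, var):
        from cortexdamage.spectral_stats import BandPower
        return BandPower(1.0, 40.0, 390, power, var)

    def test_identical_bands_give_t_zero_p_one(self):
        r = compare_bands(self._bp(5.0, 0.1), self._bp(5.0, 0.1))
        assert r.t_statistic == 0.0
        assert r.raw_p == pytest.approx(1.0)

    def test_five_sigma_difference_is_highly_significant(self):
        var = 0.02
        diff = 5.0 * np.sqrt(2 * var)
        r = compare_bands(self._bp(5.0 + diff, var), self._bp(5.0, var))
        assert r.raw_p < 1e-5

    def test_bonferroni_arithmetic(self):
        # a raw p of 0.03 over 10 comparisons is not significant at 0.01
        var = 1.0
        from scipy import stats
        t_for_p03 = stats.norm.ppf(1 - 0.015)
        r = compare_bands(self._bp(5.0 + t_for_p03 * np.sqrt(2 * var), var),
                          self._bp(5.0, var), n_comparisons=10,
                          df=np.inf)
        assert r.raw_p == pytest.approx(0.03, abs=0.001)
        assert r.bonferroni_adjusted_p == pytest.approx(0.30, abs=0.01)
        assert not r.significant
        assert r.bonferroni_adjusted_p == pytest.approx(
            min(1.0, r.raw_p * r.n_comparisons))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            compare_bands(self._bp(5.0, 0.0), self._bp(4.0, 0.0))

    def test_band_mismatch_rejected(self):
        from cortexdamage.spectral_stats import BandPower
        with pytest.raises(ValueError):
            compare_bands(self._bp(5.0, 0.1), BandPower(40.0, 100.0, 600, 5.0, 0.1))


class TestPowerRatioDb:
    def test_equal_spectra_give_zero_db(self):
        s = np.array([1.0, 2.0, 3.0])
        np.testing.assert_allclose(power_ratio_db(s, s), 0.0)

    def test_half_power_is_about_minus_three_db(self):
        s = np.array([2.0])
        assert power_ratio_db(s / 2, s)[0] == pytest.approx(-3.0103, abs=1e-4)

    def test_decade_is_minus_ten_db(self):
        s = np.array([5.0])
        assert power_ratio_db(s / 10, s)[0] == pytest.approx(-10.0)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            power_ratio_db(np.ones(3), np.ones(3),
                           freq_damaged=np.array([1.0, 2, 3]),
                           freq_baseline=np.array([1.0, 2, 4]))
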