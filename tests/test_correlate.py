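"""Correlators and bleach correction: oracle cases and estimator agreement."""

import numpy as np
import pytest

from corralfcs.correlate import (
    BleachCorrectionConfig,
    autocorrelate_direct,
    autocorrelate_multitau,
    average_curves,
    bleach_correct,
    sfcs_carpet,
)
from corralfcs.traces import IntensityTrace


def _trace(values, dt=1.0):
    values = np.asarray(values, dtype=float)
    return IntensityTrace(np.arange(values.size) * dt, values, dt)


class TestDirect:
    def test_constant_trace_is_zero(self):
        g = autocorrelate_direct(_trace(np.full(1000, 7.0)), max_lag=100.0)
        assert np.allclose(g.values, 0.0, atol=1e-25)

    def test_white_noise_within_sampling_bound(self):
        rng = np.random.default_rng(0)
        n = 20000
        g = autocorrelate_direct(_trace(rng.poisson(100, n)), max_lag=50.0)
        assert np.all(np.abs(g.values) < 3.0 / np.sqrt(n))

    def test_sinusoid_peaks_at_multiples_of_period(self):
        period = 50
        t = np.arange(8000)
        g = autocorrelate_direct(_trace(10 + np.sin(2 * np.pi * t / period)), max_lag=175.0)
        for k in (1, 2, 3):
            window = g.values[(g.lags > (k - 0.3) * period) & (g.lags < (k + 0.3) * period)]
            peak_lag = g.lags[np.argmax(np.where(
                (g.lags > (k - 0.3) * period) & (g.lags < (k + 0.3) * period),
                g.values, -np.inf))]
            assert peak_lag == pytest.approx(k * period, abs=1)
            assert window.max() > 0

    def test_time_reversal_symmetry(self):
        rng = np.random.default_rng(1)
        v = rng.gamma(2.0, 1.0, 5000)
        g1 = autocorrelate_direct(_trace(v), max_lag=500.0)
        g2 = autocorrelate_direct(_trace(v[::-1]), max_lag=500.0)
        assert np.allclose(g1.values, g2.values, atol=1e-10)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            autocorrelate_direct(_trace(np.array([1.0, -1.0] * 100)), max_lag=10.0)

    def test_max_lag_bounded_by_duration(self):
        with pytest.raises(ValueError):
            autocorrelate_direct(_trace(np.ones(100)), max_lag=60.0)


class TestMultitau:
    def test_constant_trace_is_zero(self):
        g = autocorrelate_multitau(_trace(np.full(4000, 3.0)), max_lag=400.0)
        assert np.allclose(g.values, 0.0, atol=1e-25)

    def test_agrees_with_direct_on_smooth_trace(self, free_suite):
        """Production multi-tau matches the direct oracle within 1% at
        shared lags below max_lag/4 on a diffusion trace."""
        trace = free_suite["example_trace"]
        d = autocorrelate_direct(trace, max_lag=200.0)
        m = autocorrelate_multitau(trace, max_lag=200.0)
        shared = m.lags[m.lags <= 50.0]
        gd = np.interp(shared, d.lags, d.values)
        gm = m.values[m.lags <= 50.0]
        assert np.all(np.abs(gm - gd) <= 0.01 * np.abs(gd))

    def test_fitted_tau_consistent_across_correlators(self, free_suite):
        """Transit times fitted from the direct and the multi-tau estimate
        of the same repetition-averaged measurement agree within 3%.

        The direct curve is evaluated on the multi-tau lag grid (its lags
        are exact multiples of the sampling step) so both fits see the same
        lag support and the comparison isolates the estimators."""
        from corralfcs.fcsfit import fit_fcs_2d
        from corralfcs.traces import CorrelationCurve

        d = free_suite["direct_avg_250"]
        m = average_curves(free_suite["curves"][250.0]).restrict(0.0, 200.0)
        idx = np.searchsorted(d.lags, m.lags)
        assert np.allclose(d.lags[idx], m.lags)
        d_on_m = CorrelationCurve(d.lags[idx], d.values[idx])
        tau_d = fit_fcs_2d(d_on_m, (0.5, 200.0)).tau_D
        tau_m = fit_fcs_2d(m, (0.5, 200.0)).tau_D
        assert tau_m == pytest.approx(tau_d, rel=0.03)

    def test_amplitude_matches_spot_occupancy(self, free_suite):
        """The fitted amplitude 1/N equals the mean Gaussian-weighted spot
        occupancy n_molecules * pi w^2 / arena area within 15%."""
        fit = free_suite["fits"][250.0]
        cfg = free_suite["config"]
        w2 = 250.0**2 / (2 * np.log(2))  # squared 1/e^2 radius from FWHM
        area = np.pi * (cfg.arena_diameter / 2.0) ** 2
        expected_N = cfg.n_molecules * np.pi * w2 / area
        assert fit.N == pytest.approx(expected_N, rel=0.15)

    def test_lag_spacing_quasi_logarithmic(self):
        g = autocorrelate_multitau(_trace(np.random.default_rng(2).poisson(50, 8000)))
        # far fewer points than a linear correlator, lags strictly increasing
        assert len(g) < 200
        assert np.all(np.diff(g.lags) > 0)

    def test_points_per_octave_validation(self):
        with pytest.raises(ValueError):
            autocorrelate_multitau(_trace(np.ones(100)), points_per_octave=3)


class TestBleachCorrection:
    def test_stationary_trace_mean_preserved(self):
        rng = np.random.default_rng(3)
        tr = _trace(rng.poisson(100, 40000), dt=1.0)  # 40 s at 1 ms
        out = bleach_correct(tr, BleachCorrectionConfig(crop_seconds=5.0))
        kept = tr.values[tr.times >= 5000.0]
        assert out.values.mean() == pytest.approx(kept.mean(), rel=1e-3)

    def test_crop_arithmetic(self):
        tr = _trace(np.ones(20000), dt=1.0)  # 20 s
        out = bleach_correct(tr, BleachCorrectionConfig(crop_seconds=5.0))
        assert out.duration == pytest.approx(15000.0, abs=2.0)

    def test_exponential_decay_flattened(self):
        """A 30-s half-life decay leaves essentially no linear trend after
        16-s local-mean normalisation."""
        rng = np.random.default_rng(4)
        t = np.arange(60000.0)  # 60 s at 1 ms
        decay = np.exp(-np.log(2) * t / 30000.0)
        tr = _trace(rng.poisson(200, t.size) * decay, dt=1.0)
        out = bleach_correct(tr, BleachCorrectionConfig(crop_seconds=5.0))
        slope = np.polyfit(out.times, out.values, 1)[0]
        assert abs(slope) * out.duration < 0.01 * out.values.mean()
        # uncorrected trend fails the same bound by a wide margin
        raw_slope = np.polyfit(tr.times, tr.values, 1)[0]
        assert abs(raw_slope) * tr.duration > 0.1 * tr.values.mean()

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            bleach_correct(_trace(np.ones(1000), dt=1.0), BleachCorrectionConfig())


class TestCarpet:
    def test_identical_pixels_identical_curves(self):
        rng = np.random.default_rng(5)
        v = rng.poisson(80, 4000).astype(float)
        pixels = [_trace(v), _trace(v), _trace(v)]
        curves = sfcs_carpet(pixels)
        assert np.array_equal(curves[0].values, curves[1].values)
        assert np.array_equal(curves[1].values, curves[2].values)
        assert [c.provenance["pixel"] for c in curves] == [0, 1, 2]

    def test_single_pixel_reduces_to_autocorrelate(self):
        rng = np.random.default_rng(6)
        tr = _trace(rng.poisson(80, 4000))
        (curve,) = sfcs_carpet([tr])
        ref = autocorrelate_multitau(tr)
        assert np.array_equal(curve.values, ref.values)

    def test_ragged_carpet_rejected(self):
        with pytest.raises(ValueError):
            sfcs_carpet([_trace(np.ones(100)), _trace(np.ones(50))])

    def test_free_diffusion_pixel_transit_times(self, free_suite):
        """Per-pixel transit times from a line carpet over simulated free
        diffusion cluster around the spot-geometry prediction (median
        within 10%)."""
        from corralfcs.fcsfit import fit_fcs_2d

        taus = []
        for curve in free_suite["pixel_curves"]:
            fit = fit_fcs_2d(curve, (0.5, float(curve.lags[-1])))
            taus.append(fit.tau_D)
        truth = 150.0**2 / (8 * np.log(2) * 0.4e3)  # ms, for 150-nm spot
        med = float(np.median(taus))
        assert med == pytest.approx(truth, rel=0.10)
        # unimodality proxy: no pixel wildly off the common scale
        assert np.max(taus) / np.min(taus) < 3.0


class TestAverage:
    def test_average_requires_common_grid(self):
        a = autocorrelate_multitau(_trace(np.random.default_rng(7).poisson(50, 4000)))
        b = autocorrelate_multitau(_trace(np.random.default_rng(8).poisson(50, 2000)))
        with pytest.raises(ValueError):
            average_curves([a, b])

    def test_average_is_lagwise_mean(self):
        t1 = _trace(np.random.default_rng(9).poisson(50, 4000))
        t2 = _trace(np.random.default_rng(10).poisson(50, 4000))
        c1, c2 = autocorrelate_multitau(t1), autocorrelate_multitau(t2)
        avg = average_curves([c1, c2])
        assert np.allclose(avg.values, (c1.values + c2.values) / 2.0)
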