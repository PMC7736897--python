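"""One-dimensional DMA: integration, SG smoothing, F(s), slopes."""

import numpy as np
import pytest

from ofsca import (
    AR2Spec,
    DMAConfig,
    FGnSpec,
    FluctuationResult,
    corrected_scale,
    default_scales,
    fit_slope,
    fluctuation_function,
    generate_ar2,
    generate_fgn,
    generate_sinusoid,
    integrate_profile,
    local_slopes,
    sg_smooth,
)
from oracles import brute_fluctuation, normal_equations_slope, windowed_polyfit_smooth


class TestIntegration:
    def test_constant_input(self):
        y = integrate_profile(np.full(10, 3.0)).values
        assert np.allclose(y, 3.0 * np.arange(1, 11))

    def test_differencing_inverts(self, rng):
        x = rng.normal(size=200)
        y = integrate_profile(x).values
        assert np.allclose(np.diff(y), x[1:], atol=1e-12)
        assert y[0] == x[0]

    def test_fgn_profile_variance_growth(self):
        """Integrated H=0.8 fGn has Var(y[i]) growing like i^1.6."""
        n, n_seeds, h = 4096, 50, 0.8
        idx = np.unique(np.logspace(np.log10(16), np.log10(n - 1), 12).astype(int))
        profiles = np.empty((n_seeds, idx.size))
        for s in range(n_seeds):
            y = np.cumsum(generate_fgn(FGnSpec(hurst=h, n=n, seed=4000 + s)).values)
            profiles[s] = y[idx]
        var = profiles.var(axis=0, ddof=1)
        slope, _ = np.polyfit(np.log(idx), np.log(var), 1)
        assert abs(slope - 2 * h) < 0.1


class TestSGSmooth:
    @pytest.mark.parametrize("degree", [0, 2, 4])
    def test_reproduces_polynomials_up_to_degree(self, degree):
        n, window = 120, 21
        t = np.linspace(-1, 1, n)
        coeffs = np.arange(1, degree + 2, dtype=float)
        y = np.polyval(coeffs, t)
        sm = sg_smooth(y, degree, window).values
        half = (window - 1) // 2
        assert np.allclose(sm, y[half : n - half], atol=1e-9)

    def test_degree_zero_is_moving_average(self, rng):
        y = rng.normal(size=100)
        window = 11
        sm = sg_smooth(y, 0, window).values
        expected = np.convolve(y, np.ones(window) / window, mode="valid")
        assert np.allclose(sm, expected, atol=1e-12)

    def test_matches_windowed_polyfit_oracle(self, rng):
        y = rng.normal(size=200)
        sm = sg_smooth(y, 2, 21).values
        assert np.allclose(sm, windowed_polyfit_smooth(y, 2, 21), atol=1e-10)

    def test_invalid_arguments_raise(self, rng):
        y = rng.normal(size=50)
        with pytest.raises(ValueError, match="odd"):
            sg_smooth(y, 2, 10)
        with pytest.raises(ValueError, match="degree"):
            sg_smooth(y, 11, 11)
        with pytest.raises(ValueError, match="length"):
            sg_smooth(y, 2, 51)


class TestFluctuationFunction:
    @pytest.mark.parametrize("degree", [0, 2, 4])
    def test_zero_on_polynomial_profile(self, degree):
        """SG detrending annihilates polynomial profiles of its own degree."""
        n = 400
        t = np.linspace(0, 1, n)
        profile = np.polyval(np.ones(degree + 1), t)
        cfg = DMAConfig(degree=degree, scales=[11, 31, 61], integrate=False)
        res = fluctuation_function(profile, cfg)
        assert np.all(res.F < 1e-9)

    @pytest.mark.parametrize("degree", [0, 2, 4])
    def test_matches_bruteforce_transcription(self, degree, rng):
        x = rng.normal(size=500)
        cfg = DMAConfig(degree=degree, scales=[11, 31], integrate=True)
        res = fluctuation_function(x, cfg)
        expected = brute_fluctuation(x, degree, [11, 31], integrate=True)
        assert np.allclose(res.F, expected, rtol=1e-10, atol=1e-12)

    def test_oracle_equivalence_random_cases(self):
        """The optimised path equals the loop transcription on 20 random cases."""
        rng = np.random.default_rng(99)
        for _ in range(20):
            n = int(rng.integers(120, 300))
            degree = int(rng.choice([0, 2, 4]))
            s = int(rng.choice([7, 11, 15, 21, 25]))
            integrate = bool(rng.integers(0, 2))
            x = rng.normal(size=n)
            cfg = DMAConfig(degree=degree, scales=[s], integrate=integrate)
            res = fluctuation_function(x, cfg)
            expected = brute_fluctuation(x, degree, [s], integrate=integrate)
            assert np.allclose(res.F, expected, rtol=1e-10, atol=1e-12)

    def test_scale_equivariance(self, rng):
        x = rng.normal(size=800)
        cfg = DMAConfig(degree=2, scales=[11, 31, 101])
        base = fluctuation_function(x, cfg).F
        scaled = fluctuation_function(-3.7 * x, cfg).F
        assert np.allclose(scaled, 3.7 * base, rtol=1e-12)

    def test_trend_insensitivity(self, rng):
        """Adding a polynomial of degree <= m to the profile leaves F unchanged."""
        n = 2000
        profile = np.cumsum(rng.normal(size=n))
        t = np.linspace(-1, 1, n)
        trend = 50.0 * t**2 - 20.0 * t + 7.0
        cfg = DMAConfig(degree=2, scales=[11, 51, 151], integrate=False)
        f0 = fluctuation_function(profile, cfg).F
        f1 = fluctuation_function(profile + trend, cfg).F
        assert np.allclose(f1, f0, rtol=1e-8)

    def test_oversized_scale_raises(self, rng):
        cfg = DMAConfig(degree=2, scales=[11, 101])
        with pytest.raises(ValueError, match="101"):
            fluctuation_function(rng.normal(size=60), cfg)

    def test_white_noise_slope_near_half(self):
        x = np.random.default_rng(17).standard_normal(2**14)
        cfg = DMAConfig(degree=2, scales=default_scales(2**14), fit_range=(1.0, 2.5))
        res = fluctuation_function(x, cfg)
        assert abs(fit_slope(res, 1.0, 2.5).alpha - 0.5) < 0.05


class TestCorrectedScale:
    @pytest.mark.parametrize(
        "s,degree,expected", [(193, 2, 100.0), (274, 4, 100.0), (101, 0, 101.0)]
    )
    def test_published_constants(self, s, degree, expected):
        assert corrected_scale(s, degree) == pytest.approx(expected)

    def test_unsupported_degree_raises(self):
        with pytest.raises(ValueError, match="degree"):
            corrected_scale(101, 3)


def _power_law_result(alpha, n_scales=10, prefactor=1.0):
    scales = np.arange(11, 11 + 2 * n_scales, 2)
    cs = scales / 1.93
    return FluctuationResult(
        scales=scales, corrected_scales=cs, F=prefactor * cs**alpha, n=10000
    )


class TestSlopeFits:
    def test_exact_power_law(self):
        res = _power_law_result(0.7)
        fit = fit_slope(res, np.log10(res.corrected_scales[0]) - 0.1,
                        np.log10(res.corrected_scales[-1]) + 0.1)
        assert fit.alpha == pytest.approx(0.7, abs=1e-12)

    def test_two_point_slope(self):
        res = FluctuationResult(
            scales=np.array([19, 193]),
            corrected_scales=np.array([10.0, 100.0]),
            F=np.array([10.0, 1000.0]),
            n=10000,
        )
        # (log10 1000 - log10 10) / (log10 100 - log10 10) = 2
        assert fit_slope(res, 0.5, 2.5).alpha == pytest.approx(2.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        res = _power_law_result(0.6)
        res.F = res.F * np.exp(0.1 * rng.normal(size=res.F.size))
        lo, hi = 0.5, 1.6
        fit = fit_slope(res, lo, hi)
        ls = np.log10(res.corrected_scales)
        mask = (ls > lo) & (ls < hi)
        slope, intercept = normal_equations_slope(ls[mask], np.log10(res.F[mask]))
        assert fit.alpha == pytest.approx(slope, abs=1e-12)
        assert fit.intercept == pytest.approx(intercept, abs=1e-12)

    def test_open_interval_and_errors(self):
        res = _power_law_result(0.7, n_scales=3)
        ls = np.log10(res.corrected_scales)
        with pytest.raises(ValueError, match="at least 2"):
            fit_slope(res, ls[0], ls[1])  # open interval excludes the endpoints
        res.F[1] = 0.0
        with pytest.raises(ValueError, match="undefined"):
            fit_slope(res, ls[0] - 0.1, ls[-1] + 0.1)

    def test_local_slopes_pure_power_law(self):
        mid, slopes = local_slopes(_power_law_result(0.42))
        assert np.allclose(slopes, 0.42, atol=1e-12)
        assert mid.size == slopes.size == 9

    def test_local_slopes_crossover(self):
        scales = np.array([11, 31, 101, 301, 1001, 3001])
        cs = scales.astype(float)
        F = np.where(cs < 100, cs, 100.0)
        res = FluctuationResult(scales=scales, corrected_scales=cs, F=F, n=10**5)
        _, slopes = local_slopes(res)
        assert slopes[0] == pytest.approx(1.0, abs=1e-12)
        assert slopes[-1] == pytest.approx(0.0, abs=1e-12)

    def test_local_slopes_zero_f_raises(self):
        res = _power_law_result(0.5)
        res.F[3] = 0.0
        with pytest.raises(ValueError):
            local_slopes(res)


class TestQualitativeRegimes:
    def test_sinusoid_plateau_beyond_period(self):
        """F(s) stops increasing once the window exceeds the oscillation period."""
        period = 10**2.1
        x = generate_sinusoid(period, n=2**14)
        cfg = DMAConfig(degree=2, scales=default_scales(2**14), fit_range=(1.0, 2.5))
        res = fluctuation_function(x, cfg)
        log_s = np.log10(res.corrected_scales)
        log_f = np.log10(res.F)
        plateau = log_s > np.log10(period) + 0.1
        # overall trend across the plateau is flat ...
        assert abs(fit_slope(res, np.log10(period) + 0.1, log_s[-1] + 0.1).alpha) < 0.05
        # ... and F never exceeds its level at the period crossover
        assert log_f[plateau].max() <= log_f[~plateau].max() + 0.01

    def test_detrending_order_ceiling_on_ar2(self):
        """Zeroth-order DMA saturates near slope 2; fourth order resolves more."""
        x = generate_ar2(AR2Spec(period=10**2.1, n=2**15, pole_radius=0.995, seed=5))
        lo, hi = 0.9, 1.4
        slopes = {}
        for degree in (0, 4):
            cfg = DMAConfig(
                degree=degree,
                scales=default_scales(2**15, degree=degree, s_max=1001),
                fit_range=(lo, hi),
            )
            slopes[degree] = fit_slope(fluctuation_function(x, cfg), lo, hi).alpha
        assert slopes[0] <= 2.05
        assert slopes[4] > 2.2


class TestDefaultScales:
    def test_grid_properties(self):
        scales = default_scales(2**14, degree=2)
        assert np.all(scales % 2 == 1)
        assert np.all(np.diff(scales) > 0)
        assert scales[0] >= 5
        assert scales[-1] <= 2**14 // 10

    def test_config_validation(self):
        with pytest.raises(ValueError, match="odd"):
            DMAConfig(degree=2, scales=[10, 21])
        with pytest.raises(ValueError, match="increasing"):
            DMAConfig(degree=2, scales=[21, 11])
        with pytest.raises(ValueError, match="degree"):
            DMAConfig(degree=3, scales=[11, 21])
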