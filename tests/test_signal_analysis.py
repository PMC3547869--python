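"""Detrending, correlation, autocorrelation, peaks and the stretch search."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dictyosc import (
    TimeSeries,
    autocorrelation,
    cross_correlation,
    descriptor_correlation_report,
    detect_peaks,
    detrend_moving_average,
    dominant_period,
    resample_align,
    stretch_factor_search,
)


def ts(values, dt=1.0):
    values = np.asarray(values, dtype=float)
    return TimeSeries(np.arange(len(values)) * dt, values)


class TestDetrend:
    def test_constant_gives_exact_zero(self):
        out = detrend_moving_average(ts(np.full(100, 7.3)), box=21)
        assert np.all(out.value == 0.0)

    def test_linear_ramp_zero_where_full_window_fits(self):
        n, box = 50, 11
        out = detrend_moving_average(ts(2.5 * np.arange(n) - 3), box=box)
        half = (box - 1) // 2
        interior = out.value[half : n - half]
        assert np.allclose(interior, 0.0, atol=1e-10)

    def test_small_example_by_hand(self):
        # center of [1, 2, 4] with box 3: 2 - 7/3 = -1/3
        out = detrend_moving_average(ts([1.0, 2.0, 4.0]), box=3)
        assert out.value[1] == pytest.approx(-1 / 3)

    def test_box_larger_than_series_rejected(self):
        with pytest.raises(ValueError):
            detrend_moving_average(ts([1.0, 2.0]), box=5)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-100, 100), min_size=10, max_size=60),
        st.lists(st.floats(-100, 100), min_size=10, max_size=60),
        st.floats(-3, 3),
        st.floats(-3, 3),
    )
    def test_linearity(self, xs, ys, alpha, beta):
        n = min(len(xs), len(ys))
        x, y = np.array(xs[:n]), np.array(ys[:n])
        box = max(3, n // 3) | 1
        d = lambda v: detrend_moving_average(ts(v), box).value
        combined = d(alpha * x + beta * y)
        separate = alpha * d(x) + beta * d(y)
        assert np.allclose(combined, separate, atol=1e-8)


class TestCrossCorrelation:
    def test_self_is_one(self, rng):
        x = ts(rng.normal(size=50))
        assert cross_correlation(x, x).rho == 1.0

    def test_negated_is_minus_one(self, rng):
        x = ts(rng.normal(size=50))
        y = x.with_values(-x.value)
        assert cross_correlation(x, y).rho == -1.0

    def test_hand_computed_example(self):
        # cov = 1/3, sigma^2 = 2/3 each -> rho = 0.5
        z, y = ts([1.0, 2.0, 3.0]), ts([1.0, 3.0, 2.0])
        assert cross_correlation(z, y).rho == pytest.approx(0.5)

    def test_symmetric(self, rng):
        a, b = ts(rng.normal(size=40)), ts(rng.normal(size=40))
        assert cross_correlation(a, b).rho == pytest.approx(
            cross_correlation(b, a).rho
        )

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.floats(0.01, 50), st.floats(-100, 100),
        st.booleans(),
    )
    def test_affine_invariance_and_sign_flip(self, slope, offset, flip):
        rg = np.random.default_rng(7)
        a, b = ts(rg.normal(size=60)), ts(rg.normal(size=60))
        base = cross_correlation(a, b).rho
        scale = -slope if flip else slope
        mapped = cross_correlation(a, b.with_values(scale * b.value + offset)).rho
        assert mapped == pytest.approx(-base if flip else base, abs=1e-9)

    def test_zero_variance_is_an_error_not_zero(self):
        with pytest.raises(ValueError, match="variance"):
            cross_correlation(ts([1.0, 1.0, 1.0]), ts([1.0, 2.0, 3.0]))

    def test_mismatched_grids_rejected(self):
        a = TimeSeries([0.0, 1.0, 2.0], [1.0, 2.0, 3.0])
        b = TimeSeries([0.0, 1.5, 2.5], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="time base"):
            cross_correlation(a, b)

    def test_nan_samples_dropped_pairwise(self, rng):
        x = rng.normal(size=30)
        a = ts(x)
        y = x.copy()
        y[5] = np.nan
        b = ts(y)
        res = cross_correlation(a, b)
        assert res.n_overlap == 29
        assert res.rho == pytest.approx(1.0)


class TestResampleAlign:
    def test_identical_grids_passthrough(self, rng):
        a = ts(rng.normal(size=20))
        ga, gb = resample_align(a, a, dt_s=1.0)
        assert np.allclose(ga.value, a.value)

    def test_linear_signal_interpolated_exactly(self):
        a = ts(np.arange(40.0))                       # dt 1
        b = TimeSeries(np.arange(20.0) * 2, np.arange(20.0) * 2 * 3.0 + 1)
        ga, gb = resample_align(a, b, dt_s=1.0)
        assert np.allclose(gb.value, 3.0 * ga.time_s + 1)

    def test_sinusoid_downsample_then_fine_grid(self):
        # linear interpolation of a sinusoid: worst-case error is
        # (dt^2 / 8) * (2 pi / T)^2 = 3.81e-3 for dt = 10 s, T = 360 s
        period = 360.0
        t = np.arange(0, 3600, 10.0)
        a = TimeSeries(t, np.sin(2 * np.pi * t / period))
        b = TimeSeries([0.0, 3600.0], [0.0, 0.0])
        ga, _ = resample_align(a, b, dt_s=1.0)
        exact = np.sin(2 * np.pi * ga.time_s / period)
        bound = (10.0**2 / 8) * (2 * np.pi / period) ** 2
        assert np.max(np.abs(ga.value - exact)) < 1.02 * bound

    def test_no_overlap_rejected(self):
        a = TimeSeries([0.0, 1.0], [0.0, 1.0])
        b = TimeSeries([5.0, 6.0], [0.0, 1.0])
        with pytest.raises(ValueError):
            resample_align(a, b)


class TestAutocorrelation:
    def test_lag_zero_is_one(self, rng):
        acf = autocorrelation(ts(rng.normal(size=200)), max_lag_s=50)
        assert acf.value[0] == pytest.approx(1.0)

    def test_sinusoid_side_peak_at_period(self):
        period = 40.0
        x = ts(np.sin(2 * np.pi * np.arange(400) / period))
        assert dominant_period(x, max_lag_s=100) == pytest.approx(period, abs=1.0)

    def test_white_noise_decorrelates(self):
        n = 10_000
        x = ts(np.random.default_rng(3).normal(size=n))
        acf = autocorrelation(x, max_lag_s=100)
        assert np.max(np.abs(acf.value[1:])) < 3 / np.sqrt(n)

    def test_max_lag_beyond_span_rejected(self):
        with pytest.raises(ValueError):
            autocorrelation(ts(np.arange(10.0)), max_lag_s=20)


class TestDetectPeaks:
    def test_clean_sinusoid_intervals(self):
        period, dt = 480.0, 1.0
        t = np.arange(0, 480 * 8, dt)
        x = TimeSeries(t, np.sin(2 * np.pi * t / period))
        # a pure sinusoid has MAD ~ 0.7 A, so the spiky-trace default k = 3
        # would sit above its own prominence; use an explicit threshold
        train = detect_peaks(x, min_separation_s=240, prominence_k=1.0)
        assert len(train) >= 6
        assert np.allclose(train.intervals_s, period, atol=dt)

    def test_constant_series_empty_train(self):
        train = detect_peaks(ts(np.ones(500)))
        assert len(train) == 0

    def test_peaks_ordered_and_positive_intervals(self, rng):
        t = np.arange(0, 4000, 2.0)
        x = TimeSeries(t, np.sin(2 * np.pi * t / 600) + 0.05 * rng.normal(size=t.size))
        train = detect_peaks(x, min_separation_s=300)
        assert np.all(train.intervals_s > 0)


class TestStretchSearch:
    def test_self_pair_returns_exactly_one(self, rng):
        t = np.arange(0, 4000, 5.0)
        a = TimeSeries(t, np.sin(2 * np.pi * t / 600))
        best, curve = stretch_factor_search(a, a)
        assert best == 1.0
        assert curve.loc[curve.factor == 1.0, "rho"].iloc[0] == pytest.approx(1.0)

    def test_constructed_factor_two_recovered(self):
        s0 = 2.0
        t_a = np.arange(0, 8000, 5.0)
        a = TimeSeries(t_a, np.sin(2 * np.pi * t_a / 600))
        t_b = np.arange(0, 8000 / s0, 5.0)
        b = TimeSeries(t_b, np.sin(2 * np.pi * t_b * s0 / 600))  # b(t) = a(s0 t)
        best, _ = stretch_factor_search(a, b)
        assert best == pytest.approx(s0, abs=0.011)

    def test_nonpositive_factor_rejected(self):
        a = ts(np.sin(np.arange(100.0)))
        with pytest.raises(ValueError):
            stretch_factor_search(a, a, factors=np.array([0.0, 1.0]))


class TestDescriptorReport:
    def test_impedance_against_itself_and_negation(self, rng):
        t = np.arange(0, 2000, 2.0)
        z = TimeSeries(t, np.sin(2 * np.pi * t / 300), label="impedance")
        table = descriptor_correlation_report(
            z, {"self": z, "neg": z.with_values(-z.value)}
        )
        by = table.set_index("descriptor")["rho"]
        assert by["self"] == pytest.approx(1.0)
        assert by["neg"] == pytest.approx(-1.0)

    def test_degenerate_descriptor_omitted_with_warning(self, rng):
        t = np.arange(0, 1000, 2.0)
        z = TimeSeries(t, np.sin(t / 50))
        flat = TimeSeries(t, np.zeros(t.size))
        with pytest.warns(UserWarning):
            table = descriptor_correlation_report(z, {"flat": flat, "ok": z})
        assert list(table["descriptor"]) == ["ok"]

    def test_window_restriction_applies(self):
        t = np.arange(0, 2000, 2.0)
        v = np.sin(2 * np.pi * t / 300)
        z = TimeSeries(t, v)
        # descriptor equals z in the window but is inverted outside it
        v2 = np.where((t >= 500) & (t <= 1500), v, -v)
        d = TimeSeries(t, v2)
        table = descriptor_correlation_report(z, {"d": d}, window_s=(500, 1500))
        assert table["rho"].iloc[0] == pytest.approx(1.0, abs=1e-6)

    def test_bootstrap_se_reported(self, rng):
        t = np.arange(0, 2000, 2.0)
        z = TimeSeries(t, np.sin(2 * np.pi * t / 300) + 0.1 * rng.normal(size=t.size))
        d = TimeSeries(t, np.sin(2 * np.pi * t / 300) + 0.1 * rng.normal(size=t.size))
        table = descriptor_correlation_report(
            z, {"d": d}, n_bootstrap=50, rng=np.random.default_rng(0)
        )
        assert 0 < table["rho_se"].iloc[0] < 0.2
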