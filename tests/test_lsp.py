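"""VI filtering and the six growing-season retrieval methods."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import fluxpheno as fp
from fluxpheno.errors import DegenerateAmplitudeError, InsufficientDataError
from fluxpheno.lsp import (
    FilteredVISeries,
    fit_double_logistic,
    lsp_delayed_moving_average,
    lsp_function_fit,
    lsp_threshold_global,
    lsp_threshold_local_fraction,
    lsp_threshold_local_midpoint,
    robust_extrema,
    sg_filter,
)
from fluxpheno.synthetic import vi_curve
from fluxpheno.types import COMPOSITE_DOYS, VISeries


def make_vi(values, valid=None):
    return VISeries(site_id="V", year=2001, composite_doy=COMPOSITE_DOYS,
                    vi=np.asarray(values, dtype=float), valid=valid)


def logistic_curve(params):
    return FilteredVISeries(
        daily=vi_curve(np.arange(1.0, 366.0), params), filter_id="analytic")


class TestSGFilter:
    def test_constant_series_preserved(self):
        out = sg_filter(make_vi(np.full(23, 0.5)))
        np.testing.assert_allclose(out.daily, 0.5, atol=1e-12)

    def test_cubic_composites_reproduced_exactly(self):
        """degree-4 fit reproduces any cubic at the composite points."""
        x = (COMPOSITE_DOYS - 177.0) / 200.0
        cubic = 0.5 + 0.2 * x - 0.3 * x ** 2 + 0.1 * x ** 3
        out = sg_filter(make_vi(cubic))
        np.testing.assert_allclose(out.daily[COMPOSITE_DOYS - 1], cubic, atol=1e-10)

    def test_too_few_valid_composites(self):
        vi = make_vi(np.full(23, 0.5), valid=np.arange(23) < 10)
        with pytest.raises(InsufficientDataError):
            sg_filter(vi)

    def test_filter_beats_raw_interpolation_under_contamination(self):
        """MSE to the noise-free daily curve drops after filtering in at
        least 95 of 100 noisy/dropout replicates."""
        params = fp.VIParams(noise_sd=0.03, dropout_prob=0.15)
        truth = vi_curve(np.arange(1.0, 366.0), params)
        wins = 0
        for seed in range(100):
            vi, _ = fp.generate_vi_series(params, seed=seed)
            raw = FilteredVISeries.from_interpolation(vi).daily
            filt = sg_filter(vi).daily
            if np.mean((filt - truth) ** 2) < np.mean((raw - truth) ** 2):
                wins += 1
        assert wins >= 95


class TestThresholdMethods:
    def test_global_threshold_at_inflection_value(self, noise_free_vi_params):
        p = noise_free_vi_params
        curve = logistic_curve(p)
        thr = float(vi_curve(p.t_up, p))
        m = lsp_threshold_global(curve, thr)
        assert m.sos == pytest.approx(p.t_up, abs=0.5)

    def test_threshold_above_maximum_yields_absent(self, noise_free_vi_params):
        m = lsp_threshold_global(logistic_curve(noise_free_vi_params), 0.95)
        assert m.sos is None and m.eos is None and m.reasons

    def test_step_curve_interpolated_crossing(self):
        daily = np.full(365, 0.2)
        daily[119:] = 0.8  # jump between DOY 119 and 120
        m = lsp_threshold_global(FilteredVISeries(daily=daily), 0.35)
        # two-point oracle: 0.2 -> 0.8 crossing 0.35 at fraction 0.25
        assert m.sos == pytest.approx(119 + 0.25, abs=1e-12)

    def test_midpoint_hits_logistic_inflection(self, noise_free_vi_params):
        m = lsp_threshold_local_midpoint(logistic_curve(noise_free_vi_params))
        assert m.sos == pytest.approx(noise_free_vi_params.t_up, abs=0.5)
        assert m.eos == pytest.approx(noise_free_vi_params.t_down, abs=0.5)

    def test_flat_curve_degenerate_amplitude(self):
        with pytest.raises(DegenerateAmplitudeError):
            lsp_threshold_local_midpoint(FilteredVISeries(daily=np.full(365, 0.4)))

    def test_midpoint_equals_half_fraction_everywhere(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            p = fp.VIParams(t_up=float(rng.uniform(90, 150)),
                            t_down=float(rng.uniform(230, 300)),
                            s_up=float(rng.uniform(5, 15)),
                            s_down=float(rng.uniform(5, 15)))
            curve = logistic_curve(p)
            a = lsp_threshold_local_midpoint(curve)
            b = lsp_threshold_local_fraction(curve, 0.5)
            assert a.sos == b.sos and a.eos == b.eos

    def test_midpoint_matches_exhaustive_daily_scan(self):
        """Asymmetric double logistics over a 5x5 grid: SOS/EOS equal the
        brute-force first/last crossing of the midpoint threshold."""
        for t_up in (95, 110, 125, 140, 155):
            for s in (5, 8, 11, 14, 17):
                p = fp.VIParams(t_up=float(t_up), s_up=float(s),
                                t_down=280.0, s_down=9.0)
                curve = logistic_curve(p)
                vmin, vmax = robust_extrema(curve.daily)
                thr = (vmin + vmax) / 2.0
                m = lsp_threshold_local_midpoint(curve)
                daily = curve.daily
                above = np.flatnonzero(daily >= thr)
                first, last = above[0], above[-1]
                assert first - 1 + 1 <= m.sos <= first + 1  # brackets the scan hit
                assert last <= m.eos <= last + 2

    def test_fraction_ordering_on_monotone_greenup(self, noise_free_vi_params):
        curve = logistic_curve(noise_free_vi_params)
        lo = lsp_threshold_local_fraction(curve, 0.2)
        hi = lsp_threshold_local_fraction(curve, 0.8)
        assert lo.sos < hi.sos

    def test_fraction_crossing_matches_logistic_inverse(self):
        """fraction 0.2 crossing equals the analytic logistic inverse."""
        p = fp.VIParams(vi_min=0.2, vi_max=0.8, t_up=115.0, s_up=9.0,
                        t_down=285.0, s_down=9.0)
        curve = logistic_curve(p)
        m = lsp_threshold_local_fraction(curve, 0.2)
        # analytic: vi_min + 0.2*amp crossed when up-logistic = 0.2 (down ~ 1)
        expect = p.t_up + p.s_up * np.log(0.2 / 0.8)
        assert m.sos == pytest.approx(expect, abs=0.6)

    @given(fraction=st.floats(min_value=0.1, max_value=0.9))
    def test_raising_fraction_never_decreases_sos(self, fraction):
        p = fp.VIParams()
        curve = logistic_curve(p)
        a = lsp_threshold_local_fraction(curve, fraction)
        b = lsp_threshold_local_fraction(curve, min(fraction + 0.05, 0.95))
        assert a.sos <= b.sos + 1e-9


class TestDelayedMovingAverage:
    def test_monotone_curve_matches_trailing_mean_oracle(self):
        daily = np.linspace(0.2, 0.8, 365)
        m = lsp_delayed_moving_average(FilteredVISeries(daily=daily), lag=5)
        # brute force: first day in the greenup half where value > trailing mean
        first = None
        for i in range(80, 182):
            pred = np.mean([daily[i - k * 16] for k in range(1, 6)])
            if daily[i] > pred:
                first = i + 1
                break
        assert m.sos is not None and abs(m.sos - first) <= 1.0

    def test_constant_curve_has_no_crossing(self):
        m = lsp_delayed_moving_average(FilteredVISeries(daily=np.full(365, 0.5)))
        assert m.sos is None and m.eos is None

    def test_dma_sos_precedes_midpoint_sos_on_logistic_grid(self):
        for t_up in (110, 125, 140):
            p = fp.VIParams(t_up=float(t_up))
            curve = logistic_curve(p)
            dma = lsp_delayed_moving_average(curve)
            mid = lsp_threshold_local_midpoint(curve)
            assert dma.sos < mid.sos


class TestFunctionFit:
    def test_parameter_recovery_on_self_generated_data(self, noise_free_vi_params):
        vi, _ = fp.generate_vi_series(noise_free_vi_params, seed=0)
        fitted = fit_double_logistic(vi.composite_doy, vi.vi)
        assert fitted["t1"] == pytest.approx(noise_free_vi_params.t_up, abs=0.1)
        assert fitted["t2"] == pytest.approx(noise_free_vi_params.t_down, abs=0.1)

    def test_midpoint_criterion_returns_inflections(self, noise_free_vi_params):
        vi, _ = fp.generate_vi_series(noise_free_vi_params, seed=0)
        m = lsp_function_fit(vi, "midpoint")
        assert m.sos == pytest.approx(noise_free_vi_params.t_up, abs=0.1)
        assert m.eos == pytest.approx(noise_free_vi_params.t_down, abs=0.1)

    def test_curvature_criterion_brackets_midpoint(self, noise_free_vi_params):
        vi, _ = fp.generate_vi_series(noise_free_vi_params, seed=0)
        mid = lsp_function_fit(vi, "midpoint")
        cur = lsp_function_fit(vi, "curvature")
        assert cur.sos < mid.sos       # greenup onset precedes the inflection
        assert cur.eos > mid.eos       # dormancy onset follows it

    def test_noisy_bias_within_two_days(self):
        """sigma=0.02, 40 seeds: mean SOS error within +/- 2 days of truth."""
        p = fp.VIParams(noise_sd=0.02, dropout_prob=0.0)
        errs = []
        for seed in range(40):
            vi, truth = fp.generate_vi_series(p, seed=seed)
            m = lsp_function_fit(vi, "midpoint")
            if m.sos is not None:
                errs.append(m.sos - truth.true_sos)
        assert len(errs) >= 35
        assert abs(np.mean(errs)) <= 2.0


class TestEvaluateMethods:
    def _metrics(self, values):
        return [fp.LSPMetrics(sos=v, eos=v + 140.0) for v in values]

    def _reference(self, values):
        return [fp.CFPMetrics(scu=v, ecu=v + 120.0) for v in values]

    def test_identical_dates_score_perfectly(self):
        vals = np.linspace(100, 140, 10)
        out = fp.evaluate_methods({"m": self._metrics(vals)}, self._reference(vals))
        assert out[0].r_squared == pytest.approx(1.0)
        assert out[0].rmse == pytest.approx(0.0, abs=1e-12)
        assert out[0].bias == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset_keeps_r2_but_shows_bias(self):
        vals = np.linspace(100, 140, 10)
        out = fp.evaluate_methods({"m": self._metrics(vals + 10.0)},
                                  self._reference(vals))
        assert out[0].r_squared == pytest.approx(1.0)
        assert out[0].rmse == pytest.approx(10.0)
        assert out[0].bias == pytest.approx(10.0)

    def test_ranking_by_r2_then_rmse(self):
        rng = np.random.default_rng(3)
        vals = np.linspace(100, 140, 20)
        good = self._metrics(vals + rng.normal(0, 1, 20))
        bad = self._metrics(vals + rng.normal(0, 15, 20))
        out = fp.evaluate_methods({"bad": bad, "good": good}, self._reference(vals))
        assert [m.method_id for m in out] == ["good", "bad"]
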