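"""Carbon-uptake date retrieval: smoothing, windows, zero intersections."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import fluxpheno as fp
from fluxpheno.cfp import (
    AUTUMN,
    SPRING,
    TransitionWindow,
    find_transition_window,
    smooth_nee,
    zero_intersection,
)
from fluxpheno.errors import (
    DegenerateFitError,
    EmptySeriesError,
    NoTransitionError,
    WrongSlopeError,
)
from conftest import make_flux


def brute_force_smooth(values, valid, width):
    """Independent window-sum oracle for the masked moving average."""
    n = len(values)
    half = width // 2
    out = np.full(n, np.nan)
    ok = np.zeros(n, dtype=bool)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        sel = valid[lo:hi]
        if sel.sum() >= np.ceil(width / 2.0):
            out[i] = values[lo:hi][sel].mean()
            ok[i] = True
    return out, ok


class TestSmoothNEE:
    def test_constant_series_unchanged(self):
        s, ok = smooth_nee(np.full(60, 2.0))
        assert ok.all()
        np.testing.assert_allclose(s, 2.0)

    def test_linear_series_exact_in_interior(self):
        d = np.arange(1.0, 101.0)
        s, _ = smooth_nee(d, width=15)
        np.testing.assert_allclose(s[7:-7], d[7:-7], atol=1e-12)

    def test_missing_days_match_brute_force(self):
        rng = np.random.default_rng(2)
        values = rng.normal(0, 1, 120)
        valid = rng.random(120) > 0.2
        s, ok = smooth_nee(values, valid, width=15)
        bs, bok = brute_force_smooth(values, valid, 15)
        np.testing.assert_array_equal(ok, bok)
        np.testing.assert_allclose(s[ok], bs[bok])

    def test_all_missing_raises(self):
        with pytest.raises(EmptySeriesError):
            smooth_nee(np.ones(30), np.zeros(30, dtype=bool))


def brute_force_windows(smoothed, direction, lo, hi, width=10):
    """Exhaustive scan over every candidate window (the oracle)."""
    half = width // 2
    hits = []
    for d0 in range(lo, hi - width + 2):
        w = smoothed[d0 - 1:d0 + width - 1]
        first, last = w[:half], w[half:]
        if direction == SPRING and (first > 0).all() and (last < 0).all():
            hits.append(d0)
        if direction == AUTUMN and (first < 0).all() and (last > 0).all():
            hits.append(d0)
    return hits


class TestFindTransitionWindow:
    def test_step_series_matches_exhaustive_scan(self):
        s = np.where(np.arange(1, 366) < 120, 1.0, -1.0)
        w = find_transition_window(s, direction=SPRING)
        hits = brute_force_windows(s, SPRING, 1, 200)
        assert (w.start_doy, w.end_doy) == (hits[0], hits[0] + 9) == (115, 124)

    def test_all_positive_series_has_no_transition(self):
        with pytest.raises(NoTransitionError):
            find_transition_window(np.ones(365), direction=SPRING)

    def test_autumn_flickers_take_last_window(self):
        s = -np.ones(365)
        s[199:210] = 1.0   # transient sink->source flicker
        s[209:260] = -1.0
        s[279:] = 1.0      # the real autumn transition
        w = find_transition_window(s, direction=AUTUMN)
        hits = brute_force_windows(s, AUTUMN, 150, 365)
        assert w.start_doy == hits[-1]
        assert w.start_doy == 275

    def test_windows_with_missing_days_skipped(self):
        """A step series has exactly one qualifying window; masking a day
        inside it leaves no retrievable transition."""
        s = np.where(np.arange(1, 366) < 120, 1.0, -1.0)
        ok = np.ones(365, dtype=bool)
        ok[118] = False  # DOY 119, inside the only qualifying window
        with pytest.raises(NoTransitionError):
            find_transition_window(s, ok, SPRING)


class TestZeroIntersection:
    def test_exact_linear_root(self):
        d = np.arange(1.0, 366.0)
        s = -0.5 * (d - 120.0)
        w = TransitionWindow(116, 125, SPRING)
        crossing, slope, extrapolated = zero_intersection(s, w)
        assert crossing == pytest.approx(120.0, abs=1e-9)
        assert slope == pytest.approx(-0.5)
        assert not extrapolated

    def test_symmetric_step_window_closed_form(self):
        """+1 x5 then -1 x5 on DOY 116..125: OLS root at exactly 120.5."""
        s = np.zeros(365)
        s[115:120] = 1.0
        s[120:125] = -1.0
        w = TransitionWindow(116, 125, SPRING)
        crossing, _, _ = zero_intersection(s, w)
        # independent closed form: x̄=120.5, slope = Σ(x-x̄)y/Σ(x-x̄)² on ±0.5..±4.5
        x = np.arange(116, 126, dtype=float)
        y = s[115:125]
        slope = np.sum((x - x.mean()) * y) / np.sum((x - x.mean()) ** 2)
        expect = x.mean() - y.mean() / slope
        assert crossing == pytest.approx(expect, abs=1e-12)
        assert crossing == pytest.approx(120.5, abs=1e-12)

    def test_wrong_slope_raises(self):
        d = np.arange(1.0, 366.0)
        s = 0.5 * (d - 120.0)  # rising through zero: autumn shape
        with pytest.raises(WrongSlopeError):
            zero_intersection(s, TransitionWindow(116, 125, SPRING))

    def test_zero_slope_degenerate(self):
        with pytest.raises((DegenerateFitError, WrongSlopeError)):
            zero_intersection(np.ones(365), TransitionWindow(116, 125, SPRING))


class TestRetrieveCFP:
    def test_noise_free_within_one_day_of_bisection(self, noise_free_nee_params):
        nee, truth = fp.generate_nee_series(noise_free_nee_params, seed=0)
        m = fp.retrieve_cfp(make_flux(nee))
        assert abs(m.scu - truth.true_scu) <= 1.0
        assert abs(m.ecu - truth.true_ecu) <= 1.0

    def test_always_source_year_yields_absent_metrics(self):
        m = fp.retrieve_cfp(make_flux(np.full(365, 1.5)))
        assert m.scu is None and m.ecu is None
        assert "scu" in m.reasons and "ecu" in m.reasons

    def test_noisy_monte_carlo_mean_error_below_three_days(self, noise_free_nee_params):
        """sigma=0.5 g C m-2 d-1 over 100 seeds: MAE well under 3 days."""
        from dataclasses import replace
        p = replace(noise_free_nee_params, noise_sd=0.5)
        errs = []
        for seed in range(100):
            nee, truth = fp.generate_nee_series(p, seed=seed)
            m = fp.retrieve_cfp(make_flux(nee))
            if m.scu is not None:
                errs.append(abs(m.scu - truth.true_scu))
            if m.ecu is not None:
                errs.append(abs(m.ecu - truth.true_ecu))
        assert len(errs) > 150
        assert np.mean(errs) <= 3.0

    @given(shift=st.integers(min_value=-20, max_value=20))
    def test_shift_equivariance(self, shift):
        """Shifting the whole series by k days shifts both dates by k."""
        p = fp.NEEParams(r0=1.0, amplitude=4.0, t_up=140.0, t_down=260.0,
                         noise_sd=0.0)
        nee, _ = fp.generate_nee_series(p, seed=0)
        base = fp.retrieve_cfp(make_flux(nee))
        shifted = np.roll(nee, shift)
        m = fp.retrieve_cfp(make_flux(shifted))
        assert m.scu == pytest.approx(base.scu + shift, abs=1e-6)
        assert m.ecu == pytest.approx(base.ecu + shift, abs=1e-6)

    def test_sign_flip_swaps_pattern_roles(self, noise_free_nee_params):
        """Negated NEE turns the spring pattern into the autumn one."""
        nee, _ = fp.generate_nee_series(noise_free_nee_params, seed=0)
        smoothed, ok = smooth_nee(nee)
        w_spring = find_transition_window(smoothed, ok, SPRING)
        w_autumn_flipped = find_transition_window(-smoothed, ok, AUTUMN,
                                                  search_range=(1, 200))
        assert (w_spring.start_doy, w_spring.end_doy) == (
            w_autumn_flipped.start_doy, w_autumn_flipped.end_doy)

    def test_smoothing_bias_grows_for_steep_unbalanced_curves(self):
        """The moving average biases the crossing early in spring when the
        crossing sits below the uptake inflection (R0/A < 0.5); the bias
        magnitude decreases with the transition time constant."""
        biases = []
        for s in (5.0, 12.0):
            p = fp.NEEParams(r0=0.5, amplitude=4.0, s_up=s, s_down=s, noise_sd=0.0)
            nee, truth = fp.generate_nee_series(p, seed=0)
            m = fp.retrieve_cfp(make_flux(nee))
            biases.append(m.scu - truth.true_scu)
        assert biases[0] < biases[1] < 0
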