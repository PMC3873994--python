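"""Synthetic site-year generator with analytically known transition dates.

Every downstream stage is validated against cohorts produced here, so the
noise-free curves are kept simple enough that their transition dates are
recoverable by 1-D root finding:

* daily NEE follows ``NEE(d) = R0 - A * L_up(d) * L_down(d)`` where the
  ``L`` terms are logistic ramps — a respiration baseline ``R0`` (source)
  overcome by a double-logistic uptake pulse of amplitude ``A`` in the
  growing season. The true SCU/ECU are the spring (downward) and autumn
  (upward) zero crossings of the noise-free curve, found by bracketed
  bisection to 1e-6 day.
* the vegetation index follows a double logistic between a winter
  background and a summer plateau, sampled at the 23 MOD13Q1 composite
  start dates; the true SOS/EOS are the greenup/senescence inflections
  (the logistic midpoints) by construction.
* air temperature is an annual sinusoid plus Gaussian noise; precipitation
  a Bernoulli wet-day indicator times an exponential depth.

Cloud contamination depresses VI composites multiplicatively (factor drawn
from [0.3, 0.7]) rather than deleting them, mirroring the negatively biased
noise the upper-envelope filter is designed for.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .errors import GenerationError, NoCrossingError, ParameterError
from .types import (
    COMPOSITE_DOYS,
    DAYS_PER_YEAR,
    DailyFluxSeries,
    SiteYear,
    SyntheticTruth,
    VISeries,
)

_DAYS = np.arange(1, DAYS_PER_YEAR + 1, dtype=float)


# ---------------------------------------------------------------------------
# parameter sets

@dataclass(frozen=True)
class NEEParams:
    """Noise-free daily NEE curve parameters (g C m^-2 d^-1 and days)."""

    r0: float = 1.0          # baseline ecosystem respiration (source)
    amplitude: float = 4.0   # peak uptake amplitude, must exceed r0 to cross zero
    t_up: float = 120.0      # greenup midpoint of the uptake pulse
    s_up: float = 7.0        # greenup time constant
    t_down: float = 270.0    # senescence midpoint
    s_down: float = 7.0      # senescence time constant
    noise_sd: float = 0.5    # additive daily measurement noise


@dataclass(frozen=True)
class VIParams:
    """Noise-free VI annual-cycle parameters (index units and days)."""

    vi_min: float = 0.2      # winter background
    vi_max: float = 0.8      # summer plateau
    t_up: float = 115.0      # greenup inflection == true SOS
    s_up: float = 9.0
    t_down: float = 285.0    # senescence inflection == true EOS
    s_down: float = 9.0
    noise_sd: float = 0.02
    dropout_prob: float = 0.1  # per-composite cloud-contamination probability


@dataclass(frozen=True)
class ClimateParams:
    """Annual air-temperature sinusoid and wet-day precipitation model."""

    tair_mean: float = 8.0       # degC annual mean
    tair_amplitude: float = 14.0  # degC seasonal half-range
    coldest_doy: float = 15.0    # DOY of the sinusoid minimum
    tair_noise_sd: float = 1.5
    wet_prob: float = 0.3        # daily wet-day probability
    wet_mean_mm: float = 5.0     # mean depth of a wet day


# ---------------------------------------------------------------------------
# closed-form curves

def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def nee_curve(d, p: NEEParams):
    """Noise-free NEE at (possibly fractional) DOY ``d``."""
    up = _logistic((np.asarray(d, dtype=float) - p.t_up) / p.s_up)
    down = _logistic(-(np.asarray(d, dtype=float) - p.t_down) / p.s_down)
    return p.r0 - p.amplitude * up * down


def vi_curve(d, p: VIParams):
    """Noise-free VI at DOY ``d``."""
    up = _logistic((np.asarray(d, dtype=float) - p.t_up) / p.s_up)
    down = _logistic(-(np.asarray(d, dtype=float) - p.t_down) / p.s_down)
    return p.vi_min + (p.vi_max - p.vi_min) * up * down


def tair_curve(d, p: ClimateParams):
    """Noise-free air temperature at DOY ``d`` (minimum at coldest_doy)."""
    d = np.asarray(d, dtype=float)
    return p.tair_mean - p.tair_amplitude * np.cos(
        2.0 * np.pi * (d - p.coldest_doy) / DAYS_PER_YEAR
    )


def nee_zero_crossings(p: NEEParams, xtol: float = 1e-8) -> tuple[float, float]:
    """True (SCU, ECU): bracketed-bisection roots of the noise-free curve.

    SCU is the first downward (source -> sink) crossing, ECU the last
    upward one. Raises :class:`NoCrossingError` when the curve never goes
    negative (e.g. amplitude <= r0).
    """
    vals = nee_curve(_DAYS, p)
    sign = np.sign(vals)
    flips = np.flatnonzero(np.diff(sign) != 0)
    down = [i for i in flips if vals[i] > 0 and vals[i + 1] < 0]
    up = [i for i in flips if vals[i] < 0 and vals[i + 1] > 0]
    if not down or not up:
        raise NoCrossingError("noise-free NEE curve never crosses zero")
    f = lambda d: float(nee_curve(d, p))
    scu = brentq(f, _DAYS[down[0]], _DAYS[down[0] + 1], xtol=xtol)
    ecu = brentq(f, _DAYS[up[-1]], _DAYS[up[-1] + 1], xtol=xtol)
    return float(scu), float(ecu)


# ---------------------------------------------------------------------------
# single-series generators

def generate_nee_series(params: NEEParams, seed=0) -> tuple[np.ndarray, SyntheticTruth]:
    """Daily NEE of length 365 plus the truth of its noise-free crossings."""
    scu, ecu = nee_zero_crossings(params)  # NoCrossingError propagates
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, params.noise_sd, DAYS_PER_YEAR) if params.noise_sd > 0 else 0.0
    series = nee_curve(_DAYS, params) + noise
    truth = SyntheticTruth(true_scu=scu, true_ecu=ecu, params={"nee": params})
    return series, truth


def generate_vi_series(params: VIParams, seed=0, site_id: str = "synthetic",
                       year: int = 2000) -> tuple[VISeries, SyntheticTruth]:
    """Composite VI series with noise and multiplicative cloud dropouts."""
    if params.vi_max <= params.vi_min:
        raise ParameterError("vi_max must exceed vi_min")
    if not (0.0 <= params.dropout_prob <= 1.0):
        raise ParameterError("dropout_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    vi = vi_curve(COMPOSITE_DOYS, params)
    if params.noise_sd > 0:
        vi = vi + rng.normal(0.0, params.noise_sd, len(vi))
    dropped = rng.random(len(vi)) < params.dropout_prob
    factors = rng.uniform(0.3, 0.7, len(vi))
    vi = np.where(dropped, vi * factors, vi)
    vi = np.clip(vi, -0.2, 1.0)
    series = VISeries(site_id=site_id, year=year, composite_doy=COMPOSITE_DOYS,
                      vi=vi, valid=np.ones(len(vi), dtype=bool), contaminated=dropped)
    truth = SyntheticTruth(true_sos=params.t_up, true_eos=params.t_down,
                           params={"vi": params})
    return series, truth


def generate_climate_series(params: ClimateParams, seed=0) -> tuple[np.ndarray, np.ndarray]:
    """(tair, precip) daily series of length 365; precip >= 0 everywhere."""
    if params.wet_mean_mm < 0:
        raise ParameterError("wet_mean_mm must be non-negative")
    if not (0.0 <= params.wet_prob <= 1.0):
        raise ParameterError("wet_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    tair = tair_curve(_DAYS, params)
    if params.tair_noise_sd > 0:
        tair = tair + rng.normal(0.0, params.tair_noise_sd, DAYS_PER_YEAR)
    wet = rng.random(DAYS_PER_YEAR) < params.wet_prob
    depth = rng.exponential(params.wet_mean_mm, DAYS_PER_YEAR) if params.wet_mean_mm > 0 else np.zeros(DAYS_PER_YEAR)
    precip = np.where(wet, depth, 0.0)
    return tair, precip


# ---------------------------------------------------------------------------
# cohort generation

@dataclass(frozen=True)
class LinkSpec:
    """Linear link tying a true CFP date to its LSP date and a climate driver.

    ``date = intercept + lsp_coef * lsp_date + driver_coef * driver + noise``
    where the driver is accumulated over ``window`` (start, end offsets in
    days) anchored at the rounded true LSP date.
    """

    intercept: float = 10.0
    lsp_coef: float = 1.0
    driver_coef: float = 0.0
    window: tuple = (-20, 0)
    driver_kind: str = "temperature"  # or "precipitation"
    noise_sd: float = 0.0


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic per-biome cohort.

    Per-site-year phenology shifts: true SOS ~ N(sos_mean, sos_sd), true
    EOS ~ N(eos_mean, eos_sd); the site-year's annual-mean temperature is
    offset by N(0, tair_offset_sd) so degree-day drivers vary across the
    cohort independently of the LSP dates.
    """

    n: int = 30
    biome: str = "deciduous_broadleaf_forest"
    sos_mean: float = 120.0
    sos_sd: float = 12.0
    eos_mean: float = 280.0
    eos_sd: float = 12.0
    scu_link: LinkSpec = field(default_factory=lambda: LinkSpec(10.0, 1.0, 0.0, (-20, 0)))
    ecu_link: LinkSpec = field(default_factory=lambda: LinkSpec(-20.0, 1.0, 0.0, (-20, 0)))
    tair_offset_sd: float = 4.0
    nee: NEEParams = field(default_factory=NEEParams)
    vi: VIParams = field(default_factory=VIParams)
    climate: ClimateParams = field(default_factory=ClimateParams)
    seed: int = 0
    year0: int = 2000
    site_prefix: str = "SYN"

    def __post_init__(self):
        if self.n < 1:
            raise ParameterError("cohort size must be >= 1")
        for sd in (self.sos_sd, self.eos_sd, self.tair_offset_sd,
                   self.scu_link.noise_sd, self.ecu_link.noise_sd):
            if sd < 0:
                raise ParameterError("noise standard deviations must be >= 0")


def _accumulate(daily: np.ndarray, anchor: float, window: tuple, clip_zero: bool) -> float:
    """Inclusive accumulation over the window anchored at round(anchor)."""
    a = int(np.floor(anchor + 0.5))
    lo, hi = a + window[0], a + window[1]
    if lo < 1 or hi > DAYS_PER_YEAR:
        raise GenerationError(f"driver window [{lo}, {hi}] outside the year")
    seg = daily[lo - 1:hi]
    return float(np.sum(np.maximum(seg, 0.0) if clip_zero else seg))


def _solve_midpoints(base: NEEParams, target_scu: float, target_ecu: float,
                     tol: float = 1e-6) -> NEEParams:
    """Back-solve (t_up, t_down) so the noise-free crossings hit the targets.

    The two roots interact only through the opposite logistic tail, so
    alternating 1-D solves converge in a few sweeps; final agreement is
    checked against ``tol``.
    """
    p = base
    for _ in range(8):
        # spring: shift t_up so the downward root lands on target_scu
        def err_up(t_up, p=p):
            return nee_zero_crossings(replace(p, t_up=t_up))[0] - target_scu

        p = replace(p, t_up=_solve_monotone(err_up, target_scu, "SCU"))

        def err_down(t_down, p=p):
            return nee_zero_crossings(replace(p, t_down=t_down))[1] - target_ecu

        p = replace(p, t_down=_solve_monotone(err_down, target_ecu, "ECU"))

        scu, ecu = nee_zero_crossings(p)
        if abs(scu - target_scu) < tol and abs(ecu - target_ecu) < tol:
            return p
    raise GenerationError("midpoint back-solve did not converge")


def _solve_monotone(err, guess: float, label: str) -> float:
    """Root of a monotone-increasing error function near ``guess``.

    The midpoint cannot wander arbitrarily far from the target date — the
    curve loses its zero crossing entirely — so candidate points where the
    crossing disappears are treated as infeasible rather than fatal while
    a sign-bracketing pair is sought on a ladder of offsets.
    """
    evals = []
    for off in (0.0, -2.0, 2.0, -5.0, 5.0, -10.0, 10.0, -20.0, 20.0, -40.0, 40.0):
        t = guess + off
        try:
            v = err(t)
        except NoCrossingError:
            continue
        if v == 0.0:
            return float(t)
        evals.append((t, v))
        lo = [tv for tv in evals if tv[1] < 0]
        hi = [tv for tv in evals if tv[1] > 0]
        if lo and hi:
            a = max(lo, key=lambda tv: tv[0])[0]
            b = min(hi, key=lambda tv: tv[0])[0]
            if a < b:
                return float(brentq(err, a, b, xtol=1e-9))
    raise GenerationError(f"cannot place {label} at {guess:.2f}")


def generate_site_year(spec: CohortSpec, index: int) -> SiteYear:
    """One designed site-year; substream seeded as (spec.seed, index)."""
    rng = np.random.default_rng([spec.seed, index])

    true_sos = float(rng.normal(spec.sos_mean, spec.sos_sd))
    true_eos = float(rng.normal(spec.eos_mean, spec.eos_sd))
    if not (30.0 < true_sos < true_eos < 350.0):
        raise GenerationError(
            f"site-year {index}: infeasible LSP draw sos={true_sos:.1f} eos={true_eos:.1f}"
        )

    clim = replace(spec.climate,
                   tair_mean=spec.climate.tair_mean + float(rng.normal(0.0, spec.tair_offset_sd)))
    tair, precip = generate_climate_series(clim, seed=rng.integers(2**31))

    def driver_value(link: LinkSpec, anchor: float) -> float:
        daily = tair if link.driver_kind == "temperature" else precip
        return _accumulate(daily, anchor, link.window, clip_zero=link.driver_kind == "temperature")

    scu_driver = driver_value(spec.scu_link, true_sos)
    ecu_driver = driver_value(spec.ecu_link, true_eos)
    target_scu = (spec.scu_link.intercept + spec.scu_link.lsp_coef * true_sos
                  + spec.scu_link.driver_coef * scu_driver)
    if spec.scu_link.noise_sd > 0:
        target_scu += float(rng.normal(0.0, spec.scu_link.noise_sd))
    target_ecu = (spec.ecu_link.intercept + spec.ecu_link.lsp_coef * true_eos
                  + spec.ecu_link.driver_coef * ecu_driver)
    if spec.ecu_link.noise_sd > 0:
        target_ecu += float(rng.normal(0.0, spec.ecu_link.noise_sd))
    if not (15.0 < target_scu < target_ecu < 360.0):
        raise GenerationError(
            f"site-year {index}: infeasible link targets scu={target_scu:.1f} ecu={target_ecu:.1f}"
        )

    nee_params = _solve_midpoints(spec.nee, target_scu, target_ecu)
    nee, nee_truth = generate_nee_series(nee_params, seed=rng.integers(2**31))

    vi_params = replace(spec.vi, t_up=true_sos, t_down=true_eos)
    vi, _ = generate_vi_series(vi_params, seed=rng.integers(2**31),
                               site_id=f"{spec.site_prefix}{index:03d}", year=spec.year0)

    flux = DailyFluxSeries(site_id=f"{spec.site_prefix}{index:03d}", year=spec.year0,
                           doy=np.arange(1, DAYS_PER_YEAR + 1),
                           nee=nee, tair=tair, precip=precip)
    truth = SyntheticTruth(
        true_scu=nee_truth.true_scu, true_ecu=nee_truth.true_ecu,
        true_sos=true_sos, true_eos=true_eos,
        params={"nee": nee_params, "vi": vi_params, "climate": clim,
                "scu_driver": scu_driver, "ecu_driver": ecu_driver,
                "target_scu": target_scu, "target_ecu": target_ecu},
    )
    return SiteYear(flux=flux, vi=vi, biome=spec.biome, truth=truth)


def generate_cohort(spec: CohortSpec) -> list[SiteYear]:
    """Generate the full designed cohort (deterministic given spec.seed)."""
    return [generate_site_year(spec, i) for i in range(spec.n)]
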