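"""Land-surface phenology retrieval from composite vegetation-index series.

The raw 16-day composites are cleaned with an iterative upper-envelope
Savitzky-Golay filter (cloud and aerosol contamination bias VI downward, so
points falling below the local polynomial fit are lifted onto it), then
linearly interpolated to a daily curve on which six retrieval methods
operate, spanning the three classic families:

========================  ====================================================
method_id                 definition
========================  ====================================================
global_threshold          first/last crossing of a fixed VI value
local_midpoint            crossing of (annual min + annual max) / 2, extrema
                          estimated as 10% tail means per site-year
local_fraction            crossing of min + fraction * (max - min)
delayed_moving_average    crossing of the curve over its trailing moving
                          average of the previous `lag` composite periods
fit_midpoint              double-logistic fit; inflection parameters
fit_curvature             double-logistic fit; extrema of the curvature
                          change rate of each limb
========================  ====================================================

SOS is the spring (upward) event, EOS the autumn (downward) one, both as
fractional DOY. The registry `LSP_METHODS` is extensible: alternative
definitions can be added without touching the evaluator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import savgol_filter

from .errors import (
    DegenerateAmplitudeError,
    FitFailureError,
    InsufficientDataError,
    ParameterError,
)
from .types import DAYS_PER_YEAR, LSPMetrics, VISeries

log = logging.getLogger(__name__)

_DAYS = np.arange(1, DAYS_PER_YEAR + 1, dtype=float)


@dataclass
class FilteredVISeries:
    """A daily VI curve (DOY 1..365) plus the provenance of its filtering."""

    daily: np.ndarray
    source: Optional[VISeries] = None
    filter_id: str = "savitzky_golay"
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.daily = np.asarray(self.daily, dtype=float)
        if self.daily.shape != (DAYS_PER_YEAR,):
            raise ParameterError("daily curve must cover DOY 1..365")

    @classmethod
    def from_interpolation(cls, vi: VISeries, min_valid: int = 15) -> "FilteredVISeries":
        """Plain daily linear interpolation of the valid composites (no filter)."""
        daily = _interp_daily(vi.composite_doy[vi.valid], vi.vi[vi.valid], min_valid)
        return cls(daily=daily, source=vi, filter_id="linear_interpolation")


def _interp_daily(doys, values, min_valid: int) -> np.ndarray:
    if len(values) < min_valid:
        raise InsufficientDataError(
            f"only {len(values)} valid composites (< {min_valid})")
    # np.interp holds the edge values constant outside the sampled range
    return np.interp(_DAYS, np.asarray(doys, dtype=float), np.asarray(values, dtype=float))


def sg_filter(vi: VISeries, window_points: int = 7, degree: int = 4,
              max_iterations: int = 10, tol: float = 1e-4,
              min_valid: int = 15) -> FilteredVISeries:
    """Iterative upper-envelope Savitzky-Golay filtering of the composites.

    Each pass fits a local polynomial (``window_points`` composites,
    ``degree``) and lifts every original composite lying below the fit
    onto it; the lifted series is refitted. Because VI contamination is
    negatively biased, points far below the initial trend get low weights
    and the retained iterate is the one minimising the weighted
    fitting-effect index (sum of weighted departures from the original
    series) — iterating to convergence would ratchet the envelope above
    the clean seasonal curve. The loop exits early once the mean absolute
    change between iterations drops below ``tol``. The selected envelope
    is linearly interpolated to daily resolution and clipped to the
    physical VI range.
    """
    if degree >= window_points:
        raise ParameterError("degree must be < window_points")
    if window_points % 2 == 0:
        raise ParameterError("window_points must be odd")
    if int(vi.valid.sum()) < min_valid:
        raise InsufficientDataError(
            f"only {int(vi.valid.sum())} valid composites (< {min_valid})")

    # fill invalid composites by interpolation from their valid neighbours
    comp = np.interp(vi.composite_doy.astype(float),
                     vi.composite_doy[vi.valid].astype(float), vi.vi[vi.valid])
    n0 = comp.copy()
    trend = savgol_filter(n0, window_points, degree, mode="interp")
    dist = np.abs(n0 - trend)
    dmax = float(dist.max()) or 1.0
    weights = np.where(n0 >= trend, 1.0, 1.0 - dist / dmax)

    current = n0.copy()
    best, best_index = n0.copy(), np.inf
    iterations = 0
    for iterations in range(1, max_iterations + 1):
        fit = savgol_filter(current, window_points, degree, mode="interp")
        lifted = np.where(n0 < fit, fit, n0)
        index = float(np.sum(np.abs(lifted - n0) * weights))
        if index < best_index:
            best_index, best = index, lifted.copy()
        change = float(np.mean(np.abs(lifted - current)))
        current = lifted
        if change < tol:
            break
    daily = np.clip(_interp_daily(vi.composite_doy, best, min_valid=1), -0.2, 1.0)
    return FilteredVISeries(daily=daily, source=vi, filter_id="savitzky_golay",
                            params={"window_points": window_points, "degree": degree,
                                    "iterations": iterations, "tol": tol})


# ---------------------------------------------------------------------------
# threshold crossings on the daily curve

def _first_upward_crossing(daily, threshold) -> Optional[float]:
    below = daily < threshold
    for i in range(len(daily) - 1):
        if below[i] and daily[i + 1] >= threshold:
            span = daily[i + 1] - daily[i]
            frac = (threshold - daily[i]) / span if span > 0 else 0.0
            return float(i + 1 + frac)  # DOY of index i is i + 1
    return None


def _last_downward_crossing(daily, threshold) -> Optional[float]:
    for i in range(len(daily) - 2, -1, -1):
        if daily[i] >= threshold and daily[i + 1] < threshold:
            span = daily[i] - daily[i + 1]
            frac = (daily[i] - threshold) / span if span > 0 else 0.0
            return float(i + 1 + frac)
    return None


def _threshold_metrics(curve: FilteredVISeries, threshold: float,
                       method_id: str) -> LSPMetrics:
    sos = _first_upward_crossing(curve.daily, threshold)
    eos = _last_downward_crossing(curve.daily, threshold)
    reasons = {}
    if sos is None:
        reasons["sos"] = f"no upward crossing of threshold {threshold:.3f}"
    if eos is None:
        reasons["eos"] = f"no downward crossing of threshold {threshold:.3f}"
    if sos is not None and eos is not None and not (sos < eos):
        reasons["sos"] = reasons["eos"] = (
            f"inconsistent ordering: sos={sos:.2f} >= eos={eos:.2f}")
        sos = eos = None
    return LSPMetrics(sos=sos, eos=eos, method_id=method_id, reasons=reasons)


def robust_extrema(daily, tail: float = 0.10) -> tuple[float, float]:
    """Annual (minimum, maximum) as means of the lowest/highest 10% of days."""
    k = max(1, int(round(tail * len(daily))))
    s = np.sort(np.asarray(daily, dtype=float))
    return float(s[:k].mean()), float(s[-k:].mean())


def lsp_threshold_global(curve: FilteredVISeries, threshold: float) -> LSPMetrics:
    """Global absolute threshold: fixed VI value shared by all site-years."""
    return _threshold_metrics(curve, float(threshold), "global_threshold")


def lsp_threshold_local_fraction(curve: FilteredVISeries, fraction: float = 0.5,
                                 amplitude_floor: float = 0.05,
                                 method_id: str = "local_fraction") -> LSPMetrics:
    """Local relative threshold at min + fraction * (max - min).

    The annual extrema are estimated per site-year as 10%-tail means, which
    makes the threshold robust to residual spikes. Fraction 0.5 is exactly
    the local mean midpoint method.
    """
    if not (0.0 < fraction < 1.0):
        raise ParameterError("fraction must be in (0, 1)")
    vmin, vmax = robust_extrema(curve.daily)
    if vmax - vmin < amplitude_floor:
        raise DegenerateAmplitudeError(
            f"annual amplitude {vmax - vmin:.3f} below floor {amplitude_floor}")
    return _threshold_metrics(curve, vmin + fraction * (vmax - vmin), method_id)


def lsp_threshold_local_midpoint(curve: FilteredVISeries,
                                 amplitude_floor: float = 0.05) -> LSPMetrics:
    """Local mean midpoint threshold: (annual min + annual max) / 2."""
    return lsp_threshold_local_fraction(curve, 0.5, amplitude_floor,
                                        method_id="local_midpoint")


def lsp_delayed_moving_average(curve: FilteredVISeries, lag: int = 5) -> LSPMetrics:
    """Delayed-moving-average method (autoregressive moving average family).

    The prediction at day ``d`` is the mean of the curve at the previous
    ``lag`` composite-equivalent lags (16-day steps). SOS is the first day
    in the greenup half-year where the curve rises above its prediction,
    EOS the last day in the senescence half-year where it drops below.
    """
    if lag < 2:
        raise ParameterError("lag must be >= 2")
    daily = curve.daily
    step = 16
    pred = np.full(DAYS_PER_YEAR, np.nan)
    for i in range(lag * step, DAYS_PER_YEAR):
        pred[i] = np.mean([daily[i - k * step] for k in range(1, lag + 1)])
    diff = daily - pred
    mid = DAYS_PER_YEAR // 2

    sos = None
    first = lag * step
    if diff[first] > 0:
        # already above its prediction on the first defined day
        sos = float(first + 1)
    else:
        for i in range(first, mid):
            if diff[i] <= 0 and diff[i + 1] > 0:
                span = diff[i + 1] - diff[i]
                sos = float(i + 1 + (-diff[i] / span if span > 0 else 0.0))
                break
    eos = None
    for i in range(DAYS_PER_YEAR - 2, mid - 1, -1):
        if np.isfinite(diff[i]) and diff[i] >= 0 and diff[i + 1] < 0:
            span = diff[i] - diff[i + 1]
            eos = float(i + 1 + (diff[i] / span if span > 0 else 0.0))
            break
    reasons = {}
    if sos is None:
        reasons["sos"] = "curve never crosses above its delayed moving average"
    if eos is None:
        reasons["eos"] = "curve never crosses below its delayed moving average"
    if sos is not None and eos is not None and not (sos < eos):
        reasons["sos"] = reasons["eos"] = "inconsistent ordering"
        sos = eos = None
    return LSPMetrics(sos=sos, eos=eos, method_id="delayed_moving_average",
                      reasons=reasons)


# ---------------------------------------------------------------------------
# function fitting

def double_logistic(t, base, amp, t1, s1, t2, s2):
    """Single-season double logistic: background + amplitude * up * down."""
    t = np.asarray(t, dtype=float)
    up = 1.0 / (1.0 + np.exp(-(t - t1) / s1))
    down = 1.0 / (1.0 + np.exp((t - t2) / s2))
    return base + amp * up * down


def fit_double_logistic(doys, values) -> dict:
    """Nonlinear least squares from 4 deterministic starts; best fit wins."""
    doys = np.asarray(doys, dtype=float)
    values = np.asarray(values, dtype=float)
    vmin, vmax = float(values.min()), float(values.max())
    amp0 = max(vmax - vmin, 1e-3)
    mid = vmin + 0.5 * amp0
    above = doys[values > mid]
    t1g = float(above.min()) if len(above) else 120.0
    t2g = float(above.max()) if len(above) else 280.0
    starts = [
        (vmin, amp0, t1g, 10.0, t2g, 10.0),
        (vmin, amp0, t1g - 20.0, 5.0, t2g + 20.0, 5.0),
        (vmin, amp0, t1g + 20.0, 20.0, t2g - 20.0, 20.0),
        (vmin, amp0, 100.0, 10.0, 280.0, 10.0),
    ]
    lower = [-0.2, 1e-3, 1.0, 0.5, 30.0, 0.5]
    upper = [1.0, 1.2, 330.0, 60.0, 365.0, 60.0]

    def resid(theta):
        return double_logistic(doys, *theta) - values

    best = None
    for x0 in starts:
        x0 = np.clip(x0, lower, upper)
        try:
            res = least_squares(resid, x0, bounds=(lower, upper), method="trf",
                                max_nfev=2000)
        except Exception:  # noqa: BLE001 - a failed start is just skipped
            continue
        if not np.isfinite(res.cost):
            continue
        if res.x[4] <= res.x[2]:  # senescence must follow greenup
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitFailureError("double-logistic fit failed from every start")
    base, amp, t1, s1, t2, s2 = best.x
    return {"base": float(base), "amp": float(amp), "t1": float(t1),
            "s1": float(s1), "t2": float(t2), "s2": float(s2),
            "cost": float(best.cost)}


def _curvature_rate_extremum(params: dict, limb: str) -> float:
    """DOY of the Zhang-style curvature-change-rate extremum of one limb.

    Each limb is treated as a single logistic; the onset date is the first
    local maximum of the rate of change of curvature of the rising
    (greenup) limb, and symmetrically the last one of the falling limb.
    """
    t = np.arange(1.0, DAYS_PER_YEAR + 1.0, 0.25)
    if limb == "greenup":
        y = params["base"] + params["amp"] / (1.0 + np.exp(-(t - params["t1"]) / params["s1"]))
        lo, hi = None, params["t1"]
    else:
        y = params["base"] + params["amp"] / (1.0 + np.exp((t - params["t2"]) / params["s2"]))
        lo, hi = params["t2"], None
    dy = np.gradient(y, t)
    d2y = np.gradient(dy, t)
    curvature = d2y / np.power(1.0 + dy ** 2, 1.5)
    rate = np.gradient(curvature, t)
    sel = np.ones_like(t, dtype=bool)
    if lo is not None:
        sel &= t >= lo
    if hi is not None:
        sel &= t <= hi
    if not sel.any():
        raise FitFailureError(f"no {limb} limb inside the year")
    i = np.flatnonzero(sel)[np.argmax(rate[sel])]
    return float(t[i])


def lsp_function_fit(vi_or_curve, criterion: str = "midpoint") -> LSPMetrics:
    """Function-fitting retrieval from raw composites or a daily curve.

    ``criterion='midpoint'`` returns the fitted inflection parameters
    directly; ``criterion='curvature'`` returns the curvature-change-rate
    extrema of the fitted limbs (an earlier SOS / later EOS).
    """
    if criterion not in ("midpoint", "curvature"):
        raise ParameterError(f"unknown criterion {criterion!r}")
    if isinstance(vi_or_curve, VISeries):
        doys = vi_or_curve.composite_doy[vi_or_curve.valid]
        values = vi_or_curve.vi[vi_or_curve.valid]
    else:
        doys, values = _DAYS, vi_or_curve.daily
    try:
        params = fit_double_logistic(doys, values)
    except FitFailureError as exc:
        return LSPMetrics(method_id=f"fit_{criterion}",
                          reasons={"sos": str(exc), "eos": str(exc)})
    if criterion == "midpoint":
        sos, eos = params["t1"], params["t2"]
    else:
        sos = _curvature_rate_extremum(params, "greenup")
        eos = _curvature_rate_extremum(params, "senescence")
    if not (sos < eos):
        return LSPMetrics(method_id=f"fit_{criterion}",
                          reasons={"sos": "inconsistent ordering",
                                   "eos": "inconsistent ordering"})
    return LSPMetrics(sos=float(sos), eos=float(eos), method_id=f"fit_{criterion}")


#: Registry of the six retrieval methods; each entry maps a FilteredVISeries
#: (plus keyword parameters) onto LSPMetrics.
LSP_METHODS: dict[str, Callable[..., LSPMetrics]] = {
    "global_threshold": lsp_threshold_global,
    "local_midpoint": lsp_threshold_local_midpoint,
    "local_fraction": lsp_threshold_local_fraction,
    "delayed_moving_average": lsp_delayed_moving_average,
    "fit_midpoint": lambda curve, **kw: lsp_function_fit(curve, "midpoint"),
    "fit_curvature": lambda curve, **kw: lsp_function_fit(curve, "curvature"),
}


def retrieve_lsp(curve: FilteredVISeries, method: str = "local_midpoint",
                 **params) -> LSPMetrics:
    """Dispatch to a registered retrieval method; failures become reasons."""
    if method not in LSP_METHODS:
        raise ParameterError(f"unknown LSP method {method!r}; have {sorted(LSP_METHODS)}")
    try:
        return LSP_METHODS[method](curve, **params)
    except (DegenerateAmplitudeError, FitFailureError, InsufficientDataError) as exc:
        return LSPMetrics(method_id=method, reasons={"sos": str(exc), "eos": str(exc)})


def evaluate_methods(lsp_by_method: dict[str, list[LSPMetrics]],
                     reference: list[CFPMetricsLike],
                     biomes: Optional[list[str]] = None,
                     metric_pair: tuple[str, str] = ("sos", "scu"),
                     min_pairs: int = 3) -> list["MethodEvaluation"]:
    """Rank retrieval methods against reference carbon-flux dates.

    For each method the paired dates (LSP attribute vs CFP attribute, both
    present) are scored pooled and per biome with R-squared, RMSE (days)
    and bias = mean(LSP - CFP). Ranking: pooled R-squared descending, ties
    by RMSE ascending.
    """
    from .estimation import evaluate_dates  # local import to avoid a cycle

    lsp_attr, cfp_attr = metric_pair
    out = []
    for method_id, lsp_list in lsp_by_method.items():
        if len(lsp_list) != len(reference):
            raise ParameterError(f"{method_id}: cohort length mismatch")
        pairs = [(getattr(l, lsp_attr), getattr(r, cfp_attr), b)
                 for l, r, b in zip(lsp_list, reference,
                                    biomes or [""] * len(reference))
                 if getattr(l, lsp_attr) is not None and getattr(r, cfp_attr) is not None]
        if len(pairs) < min_pairs:
            log.warning("%s: only %d overlapping site-years", method_id, len(pairs))
            continue
        cand = np.array([p[0] for p in pairs])
        ref = np.array([p[1] for p in pairs])
        r2, rmse, bias = evaluate_dates(ref, cand)
        per_biome = {}
        for b in sorted(set(p[2] for p in pairs)):
            sel = [p for p in pairs if p[2] == b]
            if len(sel) >= min_pairs and b:
                per_biome[b] = evaluate_dates(np.array([p[1] for p in sel]),
                                              np.array([p[0] for p in sel]))
        out.append(MethodEvaluation(method_id=method_id,
                                    r_squared=r2, rmse=rmse, bias=bias,
                                    n=len(pairs), per_biome=per_biome))
    out.sort(key=lambda m: (-m.r_squared, m.rmse))
    return out


@dataclass
class MethodEvaluation:
    """Pooled and per-biome agreement of one method with reference dates."""

    method_id: str
    r_squared: float
    rmse: float
    bias: float
    n: int
    vi_kind: str = ""
    per_biome: dict = field(default_factory=dict)


# evaluate_methods references CFPMetrics-like duck types only
CFPMetricsLike = object
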