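"""Climate-driver accumulations over LSP-anchored impact windows.

Candidate impact periods are expressed as day offsets relative to the
satellite-derived anchor date (SOS for the spring metric, EOS for the
autumn one): starts {-60, -50, -40, -30, -20, -10} crossed with ends
{0, +10, +20} give the 18 candidate periods per driver. Both endpoints are
inclusive, so window (-20, 0) spans 21 days. Two drivers are supported:
cumulative daily air temperature above 0 degC (growing degree-days, base 0)
and total precipitation.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import (
    MissingDataError,
    NoCandidateError,
    OutOfRangeError,
    ParameterError,
)
from .types import DAYS_PER_YEAR, DailyFluxSeries

log = logging.getLogger(__name__)

DEFAULT_STARTS = (-60, -50, -40, -30, -20, -10)
DEFAULT_ENDS = (0, 10, 20)

TEMPERATURE = "temperature"
PRECIPITATION = "precipitation"


@dataclass(frozen=True)
class ImpactWindow:
    """An accumulation period in days relative to an LSP anchor date."""

    start_offset: int
    end_offset: int
    anchor_kind: str = "SOS"

    def __post_init__(self):
        if self.start_offset >= self.end_offset:
            raise ParameterError("start_offset must precede end_offset")

    @property
    def n_days(self) -> int:
        """Inclusive length in days."""
        return self.end_offset - self.start_offset + 1


@dataclass
class DriverSelection:
    """The optimal window for one driver, with its screening statistics."""

    driver_kind: str
    window: ImpactWindow
    r_squared: float
    p_value: float
    selected: bool
    slope: float = float("nan")
    intercept: float = float("nan")
    n: int = 0
    all_windows: dict = None  # window -> (r_squared, p_value, n)


def enumerate_impact_windows(starts: Sequence[int] = DEFAULT_STARTS,
                             ends: Sequence[int] = DEFAULT_ENDS,
                             anchor_kind: str = "SOS") -> list[ImpactWindow]:
    """Full cross of start x end offsets, ordered by (start, end)."""
    if sorted(starts) != list(starts) or sorted(ends) != list(ends):
        raise ParameterError("grid offsets must be given in increasing order")
    return [ImpactWindow(s, e, anchor_kind)
            for s, e in itertools.product(starts, ends)]


def _round_anchor(anchor: float) -> int:
    return int(np.floor(float(anchor) + 0.5))


def _window_days(anchor: float, window: ImpactWindow) -> np.ndarray:
    a = _round_anchor(anchor)
    lo, hi = a + window.start_offset, a + window.end_offset
    if lo < 1 or hi > DAYS_PER_YEAR:
        raise OutOfRangeError(
            f"window [{lo}, {hi}] anchored at {anchor:.1f} leaves DOY 1..365")
    return np.arange(lo, hi + 1)


def _extract(daily: np.ndarray, valid: np.ndarray, doy: np.ndarray,
             days: np.ndarray) -> np.ndarray:
    idx = {d: i for i, d in enumerate(doy)}
    missing = [int(d) for d in days if d not in idx or not valid[idx[d]]]
    if missing:
        raise MissingDataError(f"missing daily values on DOY {missing}")
    return daily[[idx[d] for d in days]]


def cumulative_temperature(tair, anchor: float, window: ImpactWindow,
                           valid=None, doy=None) -> float:
    """Degree-days (base 0): sum of max(tair, 0) over the inclusive window."""
    tair = np.asarray(tair, dtype=float)
    valid = np.isfinite(tair) if valid is None else np.asarray(valid, dtype=bool)
    doy = np.arange(1, len(tair) + 1) if doy is None else np.asarray(doy, dtype=int)
    vals = _extract(tair, valid, doy, _window_days(anchor, window))
    return float(np.sum(np.maximum(vals, 0.0)))


def total_precipitation(precip, anchor: float, window: ImpactWindow,
                        valid=None, doy=None) -> float:
    """Total precipitation (mm) over the inclusive window, summed as-is."""
    precip = np.asarray(precip, dtype=float)
    valid = np.isfinite(precip) if valid is None else np.asarray(valid, dtype=bool)
    doy = np.arange(1, len(precip) + 1) if doy is None else np.asarray(doy, dtype=int)
    vals = _extract(precip, valid, doy, _window_days(anchor, window))
    return float(np.sum(vals))


def driver_value(flux: DailyFluxSeries, driver_kind: str, anchor: float,
                 window: ImpactWindow) -> float:
    """Accumulate one driver for one site-year."""
    if driver_kind == TEMPERATURE:
        return cumulative_temperature(flux.tair, anchor, window,
                                      flux.tair_valid, flux.doy)
    if driver_kind == PRECIPITATION:
        return total_precipitation(flux.precip, anchor, window,
                                   flux.precip_valid, flux.doy)
    raise ParameterError(f"unknown driver kind {driver_kind!r}")


def select_optimal_driver(cfp_dates: Sequence[float],
                          anchors: Sequence[float],
                          flux_series: Sequence[DailyFluxSeries],
                          driver_kind: str,
                          windows: Optional[Sequence[ImpactWindow]] = None,
                          min_site_years: int = 5,
                          significance_level: float = 0.05) -> DriverSelection:
    """Pick the impact window whose driver best explains the CFP dates.

    For every candidate window the driver is accumulated per site-year
    (site-years whose window leaves the year or hits missing data are
    dropped from that candidate only) and the CFP date is regressed on it
    by simple least squares. The window with the highest R-squared wins;
    ``selected`` is True only when its regression F-test has
    p < ``significance_level``. Ties on R-squared (within 1e-12) break
    toward the shorter window, then the later start.
    """
    if not (len(cfp_dates) == len(anchors) == len(flux_series)):
        raise ParameterError("cfp_dates, anchors and flux_series must align")
    windows = list(windows) if windows is not None else enumerate_impact_windows()

    results = {}
    for window in windows:
        xs, ys = [], []
        for date, anchor, flux in zip(cfp_dates, anchors, flux_series):
            if date is None or anchor is None:
                continue
            try:
                xs.append(driver_value(flux, driver_kind, anchor, window))
                ys.append(float(date))
            except (OutOfRangeError, MissingDataError) as exc:
                log.debug("%s window (%d,%d): dropping %s: %s", driver_kind,
                          window.start_offset, window.end_offset, flux.site_id, exc)
        if len(xs) < min_site_years:
            continue
        x, y = np.asarray(xs), np.asarray(ys)
        if np.ptp(x) == 0.0:
            # constant driver: no explanatory power, p undefined
            results[window] = (0.0, 1.0, len(x), 0.0, float(np.mean(y)))
            continue
        fit = stats.linregress(x, y)
        # for simple regression the slope t-test equals the overall F-test
        results[window] = (float(fit.rvalue ** 2), float(fit.pvalue), len(x),
                           float(fit.slope), float(fit.intercept))

    if not results:
        raise NoCandidateError(
            f"no {driver_kind} window had >= {min_site_years} complete site-years")

    def rank_key(item):
        window, (r2, _p, _n, _s, _i) = item
        return (-r2, window.n_days, -window.start_offset)

    best_window, (r2, p, n, slope, intercept) = min(results.items(), key=rank_key)
    # explicit tie handling (within 1e-12): shorter window, then later start
    ties = [w for w, v in results.items() if abs(v[0] - r2) <= 1e-12]
    if len(ties) > 1:
        best_window = min(ties, key=lambda w: (w.n_days, -w.start_offset))
        r2, p, n, slope, intercept = results[best_window]
    return DriverSelection(
        driver_kind=driver_kind, window=best_window, r_squared=r2, p_value=p,
        selected=bool(p < significance_level), slope=slope, intercept=intercept,
        n=n, all_windows={w: (v[0], v[1], v[2]) for w, v in results.items()})
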