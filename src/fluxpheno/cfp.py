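"""Carbon-flux phenology retrieval from daily NEE.

The start and end of carbon uptake (SCU/ECU) are retrieved by a three-step
automated procedure: (1) smooth the daily NEE with a 15-day centered moving
average; (2) locate a 10-day transition window whose first five smoothed
values and last five smoothed values straddle zero (source -> sink in
spring, sink -> source in autumn); (3) regress the smoothed NEE in that
window on DOY and report the zero intersection -intercept/slope as a
fractional DOY.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import PipelineConfig
from .errors import (
    DegenerateFitError,
    EmptySeriesError,
    InsufficientDataError,
    NoTransitionError,
    ParameterError,
    WrongSlopeError,
)
from .types import DAYS_PER_YEAR, CFPMetrics, DailyFluxSeries

log = logging.getLogger(__name__)

SPRING = "spring"
AUTUMN = "autumn"

#: Default DOY search intervals for the two transitions; the growing-season
#: halves overlap so a mid-year transition is reachable from either side.
DEFAULT_RANGES = {SPRING: (1, 200), AUTUMN: (150, 365)}


@dataclass(frozen=True)
class TransitionWindow:
    """A sign-pattern window in the smoothed series (inclusive DOY bounds)."""

    start_doy: int
    end_doy: int
    direction: str

    @property
    def width(self) -> int:
        return self.end_doy - self.start_doy + 1


def smooth_nee(values, valid=None, width: int = 15):
    """Centered moving average honouring the validity mask.

    Edge windows truncate to the available days. Missing days are excluded
    from each window's mean; a day whose window holds fewer than half the
    nominal width of valid values is itself marked missing.

    Returns ``(smoothed, smoothed_valid)``.
    """
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.isfinite(values)
    valid = np.asarray(valid, dtype=bool)
    if width < 3 or width % 2 == 0:
        raise ParameterError("smoothing width must be odd and >= 3")
    if not valid.any():
        raise EmptySeriesError("all NEE values missing")
    if int(valid.sum()) < width:
        raise InsufficientDataError(f"fewer than {width} valid days")

    kernel = np.ones(width)
    sums = np.convolve(np.where(valid, values, 0.0), kernel, mode="same")
    counts = np.convolve(valid.astype(float), kernel, mode="same")
    with np.errstate(invalid="ignore"):
        smoothed = np.where(counts > 0, sums / np.maximum(counts, 1.0), np.nan)
    smoothed_valid = counts >= np.ceil(width / 2.0)
    smoothed = np.where(smoothed_valid, smoothed, np.nan)
    return smoothed, smoothed_valid


def find_transition_window(smoothed, smoothed_valid=None, direction: str = SPRING,
                           search_range=None, width: int = 10,
                           doy=None) -> TransitionWindow:
    """Locate the transition window with the required sign pattern.

    Spring returns the FIRST qualifying window in the search range, autumn
    the LAST — so transient mid-season sign flickers cannot truncate the
    uptake period. Windows containing missing days are skipped. Strict
    inequalities: zeros fail the pattern.
    """
    smoothed = np.asarray(smoothed, dtype=float)
    if smoothed_valid is None:
        smoothed_valid = np.isfinite(smoothed)
    if doy is None:
        doy = np.arange(1, len(smoothed) + 1)
    doy = np.asarray(doy, dtype=int)
    if direction not in (SPRING, AUTUMN):
        raise ParameterError(f"unknown direction {direction!r}")
    if width % 2 != 0:
        raise ParameterError("window width must be even (half/half sign split)")
    lo, hi = search_range if search_range is not None else DEFAULT_RANGES[direction]
    half = width // 2

    pos = smoothed > 0
    neg = smoothed < 0
    first_half, second_half = (pos, neg) if direction == SPRING else (neg, pos)

    matches = []
    # candidate windows are consecutive runs of `width` days inside the range
    idx = {d: i for i, d in enumerate(doy)}
    for d0 in range(lo, hi - width + 2):
        ii = [idx.get(d0 + k) for k in range(width)]
        if any(i is None for i in ii):
            continue
        ii = np.asarray(ii)
        if not smoothed_valid[ii].all():
            continue
        if first_half[ii[:half]].all() and second_half[ii[half:]].all():
            matches.append(TransitionWindow(d0, d0 + width - 1, direction))
    if not matches:
        raise NoTransitionError(direction)
    if len(matches) > 1:
        log.debug("%s: %d candidate transition windows; taking %s",
                  direction, len(matches), "first" if direction == SPRING else "last")
    return matches[0] if direction == SPRING else matches[-1]


def zero_intersection(smoothed, window: TransitionWindow, doy=None,
                      slack: float = 5.0) -> tuple[float, float, bool]:
    """OLS of smoothed NEE on DOY inside the window; root at -intercept/slope.

    The slope must be negative for spring and positive for autumn
    (:class:`WrongSlopeError` otherwise). Returns ``(crossing_doy, slope,
    extrapolated)`` where ``extrapolated`` flags a root outside
    [window start - slack, window end + slack].
    """
    smoothed = np.asarray(smoothed, dtype=float)
    if doy is None:
        doy = np.arange(1, len(smoothed) + 1)
    doy = np.asarray(doy, dtype=int)
    sel = (doy >= window.start_doy) & (doy <= window.end_doy)
    x = doy[sel].astype(float)
    y = smoothed[sel]
    slope, intercept = np.polyfit(x, y, 1)
    if abs(slope) < 1e-12 * max(1.0, float(np.abs(y).max())):
        raise DegenerateFitError("zero slope in transition window")
    if window.direction == SPRING and slope >= 0:
        raise WrongSlopeError("spring transition requires a negative slope")
    if window.direction == AUTUMN and slope <= 0:
        raise WrongSlopeError("autumn transition requires a positive slope")
    crossing = -intercept / slope
    extrapolated = not (window.start_doy - slack <= crossing <= window.end_doy + slack)
    if extrapolated:
        log.warning("zero intersection %.2f outside window [%d, %d] +/- %g",
                    crossing, window.start_doy, window.end_doy, slack)
    return float(crossing), float(slope), extrapolated


def retrieve_cfp(series: DailyFluxSeries, config: PipelineConfig | None = None) -> CFPMetrics:
    """Compose the three retrieval steps for both transitions.

    Failures never escape: an unretrievable metric is absent with its
    reason recorded (an always-source year, a wrong-slope fit, ...). When
    both dates are found but SCU >= ECU, both are dropped with a
    cross-inconsistency reason.
    """
    cfg = config or PipelineConfig()
    reasons: dict = {}
    diagnostics: dict = {}
    dates: dict = {SPRING: None, AUTUMN: None}

    try:
        smoothed, smoothed_valid = smooth_nee(series.nee, series.nee_valid, cfg.smooth_width)
    except Exception as exc:  # noqa: BLE001 - encoded, never raised past here
        return CFPMetrics(reasons={"scu": str(exc), "ecu": str(exc)})

    ranges = {SPRING: cfg.spring_range, AUTUMN: cfg.autumn_range}
    keys = {SPRING: "scu", AUTUMN: "ecu"}
    for direction in (SPRING, AUTUMN):
        try:
            window = find_transition_window(
                smoothed, smoothed_valid, direction, ranges[direction],
                cfg.window_width, doy=series.doy)
            crossing, slope, extrapolated = zero_intersection(smoothed, window, doy=series.doy)
            dates[direction] = crossing
            diagnostics[keys[direction]] = {
                "window": (window.start_doy, window.end_doy),
                "slope": slope,
                "extrapolated": extrapolated,
            }
        except Exception as exc:  # noqa: BLE001
            reasons[keys[direction]] = str(exc)

    scu, ecu = dates[SPRING], dates[AUTUMN]
    if scu is not None and ecu is not None and not (scu < ecu):
        reasons["scu"] = reasons["ecu"] = (
            f"inconsistent ordering: scu={scu:.2f} >= ecu={ecu:.2f}")
        scu = ecu = None
    return CFPMetrics(scu=scu, ecu=ecu, reasons=reasons, diagnostics=diagnostics)
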