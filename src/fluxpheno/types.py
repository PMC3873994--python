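"""Domain types shared by every pipeline stage.

Day-of-year (DOY) is the time axis throughout: a fixed 365-day calendar,
DOY 1 = 1 January. Transition dates (SCU/ECU from flux data, SOS/EOS from
vegetation-index data) are fractional DOY. The NEE sign convention is
micrometeorological: negative = net carbon uptake (sink), positive = net
release (source).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ValidationError

#: Biome labels used in the synthesis; the set is extensible — any string
#: is accepted as a label, these are the canonical four.
BIOMES = (
    "deciduous_broadleaf_forest",
    "evergreen_needleleaf_forest",
    "grasslands",
    "croplands",
)

DAYS_PER_YEAR = 365
#: MOD13Q1-style nominal composite period start days: 1, 17, ..., 353.
COMPOSITE_DOYS = np.arange(1, DAYS_PER_YEAR + 1, 16)

VI_MIN_VALID = -0.2
VI_MAX_VALID = 1.0


def _as_float(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


def _as_bool(x, n: int) -> np.ndarray:
    a = np.asarray(x, dtype=bool)
    if a.shape != (n,):
        raise ValidationError(f"mask length {a.shape} != series length {n}")
    return a


@dataclass
class DailyFluxSeries:
    """One site-year of daily NEE, air temperature and precipitation.

    Units: NEE in g C m^-2 d^-1, air temperature in degC, precipitation
    in mm. Each variable carries its own validity mask (True = usable).
    """

    site_id: str
    year: int
    doy: np.ndarray
    nee: np.ndarray
    tair: np.ndarray
    precip: np.ndarray
    nee_valid: np.ndarray = None
    tair_valid: np.ndarray = None
    precip_valid: np.ndarray = None

    def __post_init__(self):
        self.doy = np.asarray(self.doy, dtype=int)
        n = len(self.doy)
        if n == 0:
            raise ValidationError("empty flux series")
        if self.doy.min() < 1 or self.doy.max() > DAYS_PER_YEAR:
            raise ValidationError("doy outside 1..365")
        if np.any(np.diff(self.doy) <= 0):
            raise ValidationError("doy not strictly increasing")
        for name in ("nee", "tair", "precip"):
            arr = _as_float(getattr(self, name))
            if arr.shape != (n,):
                raise ValidationError(f"{name} length {arr.shape} != {n}")
            setattr(self, name, arr)
            mask = getattr(self, f"{name}_valid")
            if mask is None:
                mask = np.isfinite(arr)
            setattr(self, f"{name}_valid", _as_bool(mask, n))

    def __len__(self) -> int:
        return len(self.doy)


@dataclass
class VISeries:
    """Composite-period vegetation-index observations for one site-year.

    ``composite_doy`` is the first day of each (nominally 16-day) period.
    ``contaminated`` optionally flags composites known to be cloud-depressed
    (set by the synthetic generator; unknown for real data).
    """

    site_id: str
    year: int
    composite_doy: np.ndarray
    vi: np.ndarray
    vi_kind: str = "NDVI"
    valid: np.ndarray = None
    contaminated: Optional[np.ndarray] = None

    def __post_init__(self):
        self.composite_doy = np.asarray(self.composite_doy, dtype=int)
        n = len(self.composite_doy)
        if n == 0:
            raise ValidationError("empty VI series")
        if np.any(np.diff(self.composite_doy) <= 0):
            raise ValidationError("composite_doy not strictly increasing")
        if self.composite_doy.min() < 1 or self.composite_doy.max() > DAYS_PER_YEAR:
            raise ValidationError("composite_doy outside 1..365")
        if self.vi_kind not in ("NDVI", "EVI"):
            raise ValidationError(f"unknown vi_kind {self.vi_kind!r}")
        self.vi = _as_float(self.vi)
        if self.vi.shape != (n,):
            raise ValidationError("vi length mismatch")
        if self.valid is None:
            self.valid = np.isfinite(self.vi) & (self.vi >= VI_MIN_VALID) & (self.vi <= VI_MAX_VALID)
        self.valid = _as_bool(self.valid, n)
        if self.contaminated is not None:
            self.contaminated = _as_bool(self.contaminated, n)

    def __len__(self) -> int:
        return len(self.composite_doy)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


@dataclass
class CFPMetrics:
    """Carbon-flux phenology dates retrieved from one site-year of NEE.

    ``scu``/``ecu`` are fractional DOY or None when unretrievable; the
    ``reasons`` mapping records why a metric is absent, ``diagnostics``
    records the transition window and regression slope when present.
    """

    scu: Optional[float] = None
    ecu: Optional[float] = None
    reasons: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.scu is not None and self.ecu is not None and not (self.scu < self.ecu):
            raise ValidationError("scu must precede ecu when both present")


@dataclass
class LSPMetrics:
    """Land-surface phenology dates from one site-year of VI data."""

    sos: Optional[float] = None
    eos: Optional[float] = None
    method_id: str = ""
    reasons: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.sos is not None and self.eos is not None and not (self.sos < self.eos):
            raise ValidationError("sos must precede eos when both present")


@dataclass
class SyntheticTruth:
    """Noise-free transition dates and the generator parameters behind them.

    Truth dates are recomputable: re-running the bisection oracle on
    ``params`` reproduces ``true_scu``/``true_ecu`` to 1e-6 day.
    """

    true_scu: Optional[float] = None
    true_ecu: Optional[float] = None
    true_sos: Optional[float] = None
    true_eos: Optional[float] = None
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.true_scu is not None and self.true_ecu is not None:
            if not (self.true_scu < self.true_ecu):
                raise ValidationError("true_scu must precede true_ecu")
        if self.true_sos is not None and self.true_eos is not None:
            if not (self.true_sos < self.true_eos):
                raise ValidationError("true_sos must precede true_eos")


@dataclass
class SiteYear:
    """The analysis unit: one calendar year at one flux-tower site."""

    flux: DailyFluxSeries
    vi: VISeries
    biome: str
    truth: Optional[SyntheticTruth] = None

    def __post_init__(self):
        if self.flux.year != self.vi.year:
            raise ValidationError("flux and VI years differ")
        if self.flux.site_id != self.vi.site_id:
            raise ValidationError("flux and VI site ids differ")

    @property
    def site_id(self) -> str:
        return self.flux.site_id

    @property
    def year(self) -> int:
        return self.flux.year
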