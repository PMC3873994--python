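"""Readers and writers for the columnar text formats the pipeline touches.

Flux tables are AmeriFlux-Level-4-style daily CSV files; VI tables hold one
row per 16-day composite. The default missing-value sentinel is -9999
(AmeriFlux convention). The calendar is a fixed 365-day year: leap-day
(Feb 29) rows, when dates are given, are merged into DOY 59 by averaging.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import FormatError, InsufficientDataError, ValidationError
from .types import DAYS_PER_YEAR, VI_MAX_VALID, VI_MIN_VALID, DailyFluxSeries, VISeries

log = logging.getLogger(__name__)

#: Canonical column name -> default file column name.
DEFAULT_FLUX_DIALECT = {
    "doy": "doy",
    "date": "date",
    "nee": "nee",
    "tair": "tair",
    "precip": "precip",
    "sentinel": -9999,
}

_FLUX_VARS = ("nee", "tair", "precip")


def _resolve(df: pd.DataFrame, name: str) -> pd.Series:
    if name not in df.columns:
        raise FormatError(f"required column {name!r} not found (have {list(df.columns)})")
    return df[name]


def _dates_to_doy(dates: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Convert a date column to 365-day DOY; returns (doy, leap_merge_mask).

    In leap years Feb 29 (dayofyear 60) maps onto DOY 59 and later days
    shift back by one, so every year shares the 1..365 axis.
    """
    dt = pd.to_datetime(dates)
    doy = dt.dt.dayofyear.to_numpy()
    is_leap = dt.dt.is_leap_year.to_numpy()
    merge = is_leap & (doy == 60)
    doy = np.where(is_leap & (doy >= 60), doy - 1, doy)
    return doy.astype(int), merge


def read_daily_flux(path, dialect: dict | None = None, site_id: str = "", year: int | None = None) -> DailyFluxSeries:
    """Read one site-year of daily NEE / air temperature / precipitation.

    ``dialect`` maps the canonical names (doy, date, nee, tair, precip,
    sentinel) onto the file's columns; either a ``doy`` or ``date`` column
    must resolve. Sentinel and unparseable values become masked-missing;
    rows are never silently dropped.
    """
    d = dict(DEFAULT_FLUX_DIALECT)
    if dialect:
        d.update(dialect)
    df = pd.read_csv(path, float_precision="round_trip")
    df.columns = [str(c).strip() for c in df.columns]

    if d["doy"] in df.columns:
        doy = pd.to_numeric(_resolve(df, d["doy"]), errors="raise").to_numpy().astype(int)
        merge = np.zeros(len(doy), dtype=bool)
    elif d["date"] in df.columns:
        doy, merge = _dates_to_doy(_resolve(df, d["date"]))
    else:
        raise FormatError(f"neither {d['doy']!r} nor {d['date']!r} column present")

    sentinel = d["sentinel"]
    values, masks = {}, {}
    for var in _FLUX_VARS:
        col = pd.to_numeric(_resolve(df, d[var]), errors="coerce").to_numpy(dtype=float)
        valid = np.isfinite(col) & (col != sentinel)
        col = np.where(valid, col, np.nan)
        values[var], masks[var] = col, valid

    if merge.any():
        # average Feb 29 into DOY 59 (nan-aware), then drop the extra row
        keep = np.ones(len(doy), dtype=bool)
        for i in np.flatnonzero(merge):
            j = i - 1  # the DOY-59 row precedes Feb 29 in a sorted table
            if j >= 0 and doy[j] == doy[i]:
                for var in _FLUX_VARS:
                    pair = values[var][[j, i]]
                    ok = masks[var][[j, i]]
                    if ok.any():
                        values[var][j] = np.nanmean(pair[ok])
                        masks[var][j] = True
                keep[i] = False
        doy = doy[keep]
        for var in _FLUX_VARS:
            values[var] = values[var][keep]
            masks[var] = masks[var][keep]

    if np.any(np.diff(doy) <= 0):
        raise ValidationError(f"{path}: dates not strictly increasing")

    if year is None:
        year = int(df[d["date"]].iloc[0][:4]) if d["date"] in df.columns else 0
    return DailyFluxSeries(
        site_id=site_id or str(path),
        year=year,
        doy=doy,
        nee=values["nee"],
        tair=values["tair"],
        precip=values["precip"],
        nee_valid=masks["nee"],
        tair_valid=masks["tair"],
        precip_valid=masks["precip"],
    )


def read_vi_series(path, vi_kind: str = "NDVI", min_valid: int = 15,
                   site_id: str = "", year: int = 0) -> VISeries:
    """Read a 16-day-composite VI table (columns composite_doy, vi).

    Out-of-range values (outside [-0.2, 1.0]) are masked, not dropped;
    fewer than ``min_valid`` valid composites raises
    :class:`InsufficientDataError`.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    df.columns = [str(c).strip() for c in df.columns]
    doy = pd.to_numeric(_resolve(df, "composite_doy"), errors="raise").to_numpy().astype(int)
    vi = pd.to_numeric(_resolve(df, "vi"), errors="coerce").to_numpy(dtype=float)
    valid = np.isfinite(vi) & (vi >= VI_MIN_VALID) & (vi <= VI_MAX_VALID)
    n_bad = int((~valid).sum())
    if n_bad:
        log.info("%s: masked %d out-of-range/missing composites", path, n_bad)
    if int(valid.sum()) < min_valid:
        raise InsufficientDataError(
            f"{path}: only {int(valid.sum())} valid composites (< {min_valid})"
        )
    return VISeries(site_id=site_id or str(path), year=year,
                    composite_doy=doy, vi=vi, vi_kind=vi_kind, valid=valid)


RESULT_COLUMNS = ["site_id", "year", "biome", "metric", "value", "method_id"]


def write_results(records, path) -> None:
    """Write per-site-year metric rows as CSV with the standard header.

    ``records`` is an iterable of mappings sharing the result schema; an
    empty iterable yields a header-only file. Floats round-trip exactly
    (written with repr precision).
    """
    rows = list(records)
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS if not rows else None)
    if rows:
        missing = set(RESULT_COLUMNS) - set(df.columns)
        if missing:
            raise FormatError(f"records missing columns {sorted(missing)}")
        df = df[RESULT_COLUMNS]
    df.to_csv(path, index=False)


def read_results(path) -> pd.DataFrame:
    """Read back a results table written by :func:`write_results`."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(RESULT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"results file missing columns {sorted(missing)}")
    return df


def write_flux_csv(series: DailyFluxSeries, path, sentinel: float = -9999) -> None:
    """Write a DailyFluxSeries in the format read_daily_flux expects."""
    df = pd.DataFrame({
        "doy": series.doy,
        "nee": np.where(series.nee_valid, series.nee, sentinel),
        "tair": np.where(series.tair_valid, series.tair, sentinel),
        "precip": np.where(series.precip_valid, series.precip, sentinel),
    })
    df.to_csv(path, index=False)


def write_vi_csv(series: VISeries, path, sentinel: float = -9999) -> None:
    """Write a VISeries in the format read_vi_series expects."""
    df = pd.DataFrame({
        "composite_doy": series.composite_doy,
        "vi": np.where(series.valid, series.vi, sentinel),
    })
    df.to_csv(path, index=False)
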