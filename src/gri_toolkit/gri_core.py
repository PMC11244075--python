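"""Annual grassland resilience index (GRI) from an LAI stack.

The resilience of a pixel-year is the ratio of the deepest stress it
recovered from to the time the recovery took::

    GRI = Ms / Rt

where, for an *abnormal period* (a maximal run of growing-season months
with monthly LAI below the climatological band floor ``MEAN_j - beta*STD_j``),

* ``Ms`` is the band floor minus the lowest monthly LAI of the run,
  evaluated at the calendar month of that minimum (LAI units), and
* ``Rt`` is the number of observed growing-season months from the month of
  the minimum (inclusive) to the first month back inside the band
  (exclusive), minimum 1.

Annual attribution rules:

* an event whose recovery crosses a year boundary is attributed entirely to
  the year the recovery began (the year of the LAI minimum);
* a year with several events gets the arithmetic mean of their GRI values;
* a year with no event inherits the previous year's value;
* years before the first computed value stay nodata (no donor to carry).

The growing season is May–September; October–April is unobserved, so
consecutive seasons are concatenated and ``Rt`` counts observed months
only.  Events that never return inside the band within the record have no
defined ``Rt`` and contribute nothing to the index.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .raster_io import Grid, LAIStack

__all__ = [
    "GROWING_SEASON_MONTHS",
    "MonthlyCube",
    "MonthlyClimatology",
    "AnomalyEvent",
    "AnnualGRIMap",
    "monthly_aggregate",
    "climatology",
    "detect_anomalies",
    "detect_anomalies_series",
    "annual_gri",
    "annual_gri_series",
    "normalize_gri",
    "compute_gri",
]

logger = logging.getLogger(__name__)

#: Calendar months of the growing season (8-day composites, days 121-273).
GROWING_SEASON_MONTHS: tuple[int, ...] = (5, 6, 7, 8, 9)

# provenance codes for AnnualGRIMap
PROV_NODATA = 0
PROV_COMPUTED = 1
PROV_CARRIED = 2
PROV_AVERAGED = 3


def steps_to_months(steps_per_year: int) -> np.ndarray:
    """Calendar month of each within-season composite step.

    Composite step k covers day-of-year 121 + 8k; with the default 20
    steps per year this yields four composites in each of May–September.
    """
    doy = 121 + 8 * np.arange(steps_per_year)
    # day-of-year at each month start (non-leap)
    month_start = {5: 121, 6: 152, 7: 182, 8: 213, 9: 244, 10: 274}
    months = np.zeros(steps_per_year, dtype=int)
    for m in GROWING_SEASON_MONTHS:
        sel = (doy >= month_start[m]) & (doy < month_start[m + 1])
        months[sel] = m
    if np.any(months == 0):
        raise ValueError("composite steps extend beyond the May-September season")
    return months


@dataclass
class MonthlyCube:
    """Monthly-aggregated LAI: (year, growing-season month, row, col)."""

    grid: Grid
    years: np.ndarray
    months: tuple[int, ...]
    values: np.ndarray  # (n_years, n_months, rows, cols), NaN nodata


@dataclass
class MonthlyClimatology:
    """Long-term monthly LAI normals per pixel.

    ``mean_j``/``std_j`` are the across-year mean and standard deviation of
    monthly LAI; ``beta`` scales the band half-width.  Only the *lower*
    bound ``mean_j - beta*std_j`` (the band floor) triggers anomalies.
    """

    grid: Grid
    months: tuple[int, ...]
    mean_j: np.ndarray  # (n_months, rows, cols)
    std_j: np.ndarray
    beta: float = 1.0

    @property
    def band_floor(self) -> np.ndarray:
        return self.mean_j - self.beta * self.std_j


@dataclass
class AnomalyEvent:
    """One sub-band excursion of a pixel's monthly LAI series."""

    pixel: int
    start_year: int  # year of the LAI minimum (start of recovery)
    start_month: int  # calendar month of the minimum
    ms: float  # maximum stress, LAI units (> 0)
    rt: int | None  # recovery time, observed months (None if unresolved)
    resolved: bool
    lai_lowest: float
    cross_year: bool = False  # recovery ran past the season/record boundary

    @property
    def gri(self) -> float | None:
        return self.ms / self.rt if self.resolved and self.rt else None


@dataclass
class AnnualGRIMap:
    """Per pixel-year raw and normalized GRI with provenance codes."""

    grid: Grid
    years: np.ndarray
    raw: np.ndarray  # (n_years, rows, cols)
    normalized: np.ndarray | None = None
    provenance: np.ndarray | None = None  # int8 codes, see PROV_*
    normalization_scope: str | None = None
    beta: float | None = None


def monthly_aggregate(stack: LAIStack) -> MonthlyCube:
    """Mean of valid 8-day composites within each calendar month.

    A month whose composites are all invalid is nodata for that pixel-year.
    """
    step_months = steps_to_months(stack.steps_per_year)
    months = tuple(m for m in GROWING_SEASON_MONTHS if np.any(step_months == m))
    out = np.full((stack.n_years, len(months), *stack.grid.shape), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)  # all-NaN slices
        for k, m in enumerate(months):
            out[:, k] = np.nanmean(stack.values[:, step_months == m], axis=1)
    return MonthlyCube(stack.grid, stack.years, months, out)


def climatology(
    monthly: MonthlyCube,
    beta: float = 1.0,
    std_mode: Literal["population", "sample"] = "population",
) -> MonthlyClimatology:
    """Across-year monthly mean and standard deviation per pixel.

    Pixel-months with fewer than two valid years carry no climatology
    (NaN), since a standard deviation needs at least two observations.
    The population formula (divide by N) is the default; the 22-year
    record is treated as the full reference period rather than a sample.
    """
    vals = monthly.values
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        n_valid = np.sum(~np.isnan(vals), axis=0)
        mean_j = np.nanmean(vals, axis=0)
        ddof = 0 if std_mode == "population" else 1
        std_j = np.nanstd(vals, axis=0, ddof=ddof)
    bad = n_valid < 2
    mean_j[bad] = np.nan
    std_j[bad] = np.nan
    return MonthlyClimatology(monthly.grid, monthly.months, mean_j, std_j, beta)


def detect_anomalies_series(
    series: np.ndarray,
    floor: np.ndarray,
    years: np.ndarray,
    months: Sequence[int],
    pixel: int = 0,
) -> list[AnomalyEvent]:
    """Detect sub-band events in one pixel's concatenated monthly series.

    ``series`` and ``floor`` are flat arrays of length n_years*n_months in
    season-concatenated order (year-major).  ``floor`` repeats the band
    floor of each calendar month across years.
    """
    n_months = len(months)
    below = series < floor  # NaN compares False on either side
    events: list[AnomalyEvent] = []
    t = 0
    n = len(series)
    while t < n:
        if not below[t]:
            t += 1
            continue
        # maximal run of consecutive below-band months
        e = t
        while e + 1 < n and below[e + 1]:
            e += 1
        run = slice(t, e + 1)
        trough_rel = int(np.argmin(series[run]))
        trough = t + trough_rel
        lai_lowest = float(series[trough])
        ms = float(floor[trough] - lai_lowest)
        # resolved only if the month after the run is observed and valid
        after = e + 1
        resolved = after < n and np.isfinite(series[after]) and not below[after]
        rt = (e - trough + 1) if resolved else None
        yi, mi = divmod(trough, n_months)
        cross_year = resolved and (e // n_months != trough // n_months)
        if ms > 0:
            events.append(
                AnomalyEvent(
                    pixel=pixel,
                    start_year=int(years[yi]),
                    start_month=int(months[mi]),
                    ms=ms,
                    rt=rt,
                    resolved=bool(resolved),
                    lai_lowest=lai_lowest,
                    cross_year=bool(cross_year),
                )
            )
        t = e + 1
    return events


def detect_anomalies(
    monthly: MonthlyCube, clim: MonthlyClimatology
) -> list[AnomalyEvent]:
    """Detect anomaly events for every pixel of a monthly cube."""
    n_years, n_months, nrows, ncols = monthly.values.shape
    floor_pm = clim.band_floor  # (n_months, rows, cols)
    events: list[AnomalyEvent] = []
    flat_vals = monthly.values.reshape(n_years * n_months, -1)
    flat_floor = np.tile(floor_pm.reshape(n_months, -1), (n_years, 1))
    any_below = np.any(flat_vals < flat_floor, axis=0)
    for pid in np.flatnonzero(any_below):
        events.extend(
            detect_anomalies_series(
                flat_vals[:, pid], flat_floor[:, pid], monthly.years,
                monthly.months, pixel=int(pid),
            )
        )
    return events


def annual_gri_series(
    events: Iterable[AnomalyEvent], years: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Annual raw GRI for one pixel from its event list.

    Returns ``(gri, provenance)`` arrays over ``years``.  Resolved events
    contribute Ms/Rt to their start year; multiple events in a year are
    averaged; empty years inherit the previous value; leading empty years
    are nodata.
    """
    years = np.asarray(years, dtype=int)
    per_year: dict[int, list[float]] = {}
    for ev in events:
        if ev.resolved and ev.rt:
            per_year.setdefault(ev.start_year, []).append(ev.ms / ev.rt)
    gri = np.full(len(years), np.nan)
    prov = np.full(len(years), PROV_NODATA, dtype=np.int8)
    prev = np.nan
    for k, yr in enumerate(years):
        vals = per_year.get(int(yr))
        if vals:
            gri[k] = float(np.mean(vals))
            prov[k] = PROV_AVERAGED if len(vals) > 1 else PROV_COMPUTED
            prev = gri[k]
        elif np.isfinite(prev):
            gri[k] = prev
            prov[k] = PROV_CARRIED
    return gri, prov


def annual_gri(
    events: Iterable[AnomalyEvent], years: Sequence[int], grid: Grid,
    beta: float | None = None,
) -> AnnualGRIMap:
    """Assemble the per-pixel annual raw GRI cube from a full event list."""
    years = np.asarray(years, dtype=int)
    by_pixel: dict[int, list[AnomalyEvent]] = {}
    for ev in events:
        by_pixel.setdefault(ev.pixel, []).append(ev)
    raw = np.full((len(years), grid.size), np.nan)
    prov = np.full((len(years), grid.size), PROV_NODATA, dtype=np.int8)
    for pid, evs in by_pixel.items():
        raw[:, pid], prov[:, pid] = annual_gri_series(evs, years)
    return AnnualGRIMap(
        grid, years,
        raw.reshape(len(years), *grid.shape),
        provenance=prov.reshape(len(years), *grid.shape),
        beta=beta,
    )


def normalize_gri(
    gri_map: AnnualGRIMap,
    scope: Literal["per_year", "global"] = "per_year",
) -> AnnualGRIMap:
    """Min–max rescale the raw GRI cube to [0, 1].

    ``per_year`` rescales each annual map by its own spatial min/max (each
    year's extremes pin 0 and 1); ``global`` uses one min/max over the
    whole cube, preserving cross-year ordering — the form trend analysis
    consumes.  A scope with a single distinct value normalizes to 0 with a
    warning.
    """
    raw = gri_map.raw
    norm = np.full_like(raw, np.nan)

    def _rescale(block: np.ndarray) -> np.ndarray:
        valid = np.isfinite(block)
        if not valid.any():
            return np.full_like(block, np.nan)
        lo, hi = np.nanmin(block), np.nanmax(block)
        if hi == lo:
            logger.warning("degenerate normalization scope: max == min; mapping to 0")
            out = np.where(valid, 0.0, np.nan)
            return out
        return (block - lo) / (hi - lo)

    if scope == "per_year":
        for k in range(raw.shape[0]):
            norm[k] = _rescale(raw[k])
    elif scope == "global":
        norm = _rescale(raw)
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return AnnualGRIMap(
        gri_map.grid, gri_map.years, raw, normalized=norm,
        provenance=gri_map.provenance, normalization_scope=scope,
        beta=gri_map.beta,
    )


def compute_gri(
    stack: LAIStack,
    beta: float = 1.0,
    mask: np.ndarray | None = None,
    std_mode: Literal["population", "sample"] = "population",
    normalization_scope: Literal["per_year", "global"] = "per_year",
) -> tuple[AnnualGRIMap, list[AnomalyEvent]]:
    """End-to-end pipeline: LAI stack → annual GRI cube + event table.

    ``mask`` (e.g. the persistent-grassland mask) restricts the analysis;
    unmasked pixels are nodata throughout.
    """
    values = stack.values
    if mask is not None:
        values = np.where(mask[None, None], stack.values, np.nan)
        stack = LAIStack(stack.grid, stack.years, stack.steps_per_year, values)
    monthly = monthly_aggregate(stack)
    clim = climatology(monthly, beta=beta, std_mode=std_mode)
    events = detect_anomalies(monthly, clim)
    gri_map = annual_gri(events, stack.years, stack.grid, beta=beta)
    return normalize_gri(gri_map, scope=normalization_scope), events
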