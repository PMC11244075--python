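"""Summary surfaces: annual mean series, grade maps and class-area tables.

Turns per-pixel maps into the numbers an assessment reports: the spatially
averaged annual GRI trajectory with its overall and per-year relative
change, the multi-year mean GRI graded into bins, and per-class area
tables (pixel count, km², percent of valid area) with improved/degraded
roll-ups.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster_io import Grid
from .trend_analysis import CLASS_LABELS

__all__ = [
    "annual_mean_series",
    "grade_map",
    "class_area_table",
    "rollup_trend_areas",
    "run_manifest",
]

DEFAULT_GRADE_BINS = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)

IMPROVEMENT_CLASSES = (
    "modest_improvement",
    "significant_improvement",
    "extremely_significant_improvement",
)
DEGRADATION_CLASSES = (
    "modest_degradation",
    "significant_degradation",
    "extremely_significant_degradation",
)


@dataclass
class AnnualSeries:
    """Spatial-mean GRI per year plus headline change statistics.

    ``overall_change_percent`` is the relative change from the first to
    the last year's mean, and ``annual_change_percent`` that figure
    divided by the record length in years (simple division, the
    convention of the reported pair it mirrors; a geometric rate is
    available separately).
    """

    years: np.ndarray
    mean: np.ndarray
    overall_mean: float
    overall_change_percent: float
    annual_change_percent: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "mean_gri": self.mean})


def relative_change_percent(start: float, end: float) -> float:
    """Relative change (end-start)/start as a percent."""
    if start == 0:
        return np.nan
    return (end - start) / start * 100.0


def annual_mean_series(cube: np.ndarray, years: np.ndarray) -> AnnualSeries:
    """Spatial mean over valid pixels for each annual map of a cube."""
    years = np.asarray(years)
    flat = cube.reshape(len(years), -1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(flat, axis=1)
    valid = np.isfinite(mean)
    if valid.sum() >= 2:
        first, last = mean[valid][0], mean[valid][-1]
        overall = relative_change_percent(first, last)
        annual = overall / len(years)
    else:
        overall = annual = np.nan
    return AnnualSeries(
        years, mean,
        float(np.nanmean(mean)) if valid.any() else np.nan,
        overall, annual,
    )


def geometric_annual_change_percent(start: float, end: float, n_years: int) -> float:
    """Compound annual change rate, percent."""
    if start <= 0 or end <= 0 or n_years < 1:
        return np.nan
    return ((end / start) ** (1.0 / n_years) - 1.0) * 100.0


def grade_map(
    mean_gri: np.ndarray,
    grid: Grid,
    bins: tuple[float, ...] = DEFAULT_GRADE_BINS,
    pixel_area_km2: float | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Grade a mean-GRI map into bins and tabulate per-grade areas.

    Default bins are five equal 0.2-wide grades over [0, 1]; grade g
    covers [bins[g-1], bins[g]) with the last bin closed above.  Values
    outside the bin range are clipped into the end grades with a warning.
    Returns (grade codes 1..len(bins)-1, 0 nodata; AreaTable frame).
    """
    bins = tuple(bins)
    if any(b2 <= b1 for b1, b2 in zip(bins, bins[1:])):
        raise ValueError("bins must be strictly increasing")
    vals = np.asarray(mean_gri, dtype=float).reshape(grid.shape)
    ok = np.isfinite(vals)
    if ok.any() and (np.nanmin(vals) < bins[0] or np.nanmax(vals) > bins[-1]):
        warnings.warn("values outside the grade bins were clipped", stacklevel=2)
    clipped = np.clip(vals, bins[0], bins[-1])
    grades = np.zeros(grid.shape, dtype=np.int8)
    grades[ok] = np.clip(
        np.digitize(clipped[ok], bins[1:-1], right=False) + 1, 1, len(bins) - 1
    )
    area = pixel_area_km2 if pixel_area_km2 is not None else grid.pixel_area_km2()
    labels = {
        g: f"{bins[g - 1]:g}-{bins[g]:g}" for g in range(1, len(bins))
    }
    rows = []
    n_valid = int(ok.sum())
    for g, lab in labels.items():
        cnt = int(np.sum(grades == g))
        rows.append(
            {
                "grade": g,
                "range": lab,
                "pixels": cnt,
                "area_km2": cnt * area,
                "percent": 100.0 * cnt / n_valid if n_valid else np.nan,
            }
        )
    return grades, pd.DataFrame(rows)


def class_area_table(
    class_map: np.ndarray,
    pixel_area_km2: float,
    labels: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Per-class pixel count, area and percent of valid area.

    ``labels`` defaults to the six-plus-one trend classes; codes < 0 are
    nodata.  Percents partition the valid area (sum to 100).
    """
    labels = labels if labels is not None else CLASS_LABELS
    codes = np.asarray(class_map)
    valid = codes >= 0
    n_valid = int(valid.sum())
    rows = []
    for code, lab in labels.items():
        cnt = int(np.sum(codes == code))
        rows.append(
            {
                "code": code,
                "class": lab,
                "pixels": cnt,
                "area_km2": cnt * pixel_area_km2,
                "percent": 100.0 * cnt / n_valid if n_valid else np.nan,
            }
        )
    return pd.DataFrame(rows)


def rollup_trend_areas(area_table: pd.DataFrame) -> pd.DataFrame:
    """Improved / degraded / no-change roll-up of a trend-class AreaTable.

    'improved' sums the three improvement classes, 'degraded' the three
    degradation classes; with percents partitioning the valid area the
    three roll-up percents again sum to 100.
    """
    t = area_table.set_index("class")
    groups = {
        "improved": IMPROVEMENT_CLASSES,
        "degraded": DEGRADATION_CLASSES,
        "no_change": ("no_change",),
    }
    rows = []
    for name, members in groups.items():
        sub = t.loc[[m for m in members if m in t.index]]
        rows.append(
            {
                "group": name,
                "pixels": int(sub["pixels"].sum()),
                "area_km2": float(sub["area_km2"].sum()),
                "percent": float(sub["percent"].sum()),
            }
        )
    return pd.DataFrame(rows)


def run_manifest(path, **settings) -> None:
    """Write the run's provenance settings (beta, scopes, seed, ...) as JSON."""
    with open(path, "w") as fh:
        json.dump(settings, fh, indent=2, sort_keys=True, default=str)
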