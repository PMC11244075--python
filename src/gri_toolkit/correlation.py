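"""Pixel-wise Pearson correlation of annual GRI with annual climate.

Each pixel's 22-year GRI series is correlated with its co-located annual
climate series (mean annual temperature or precipitation).  Significance
uses the two-sided t test on n-2 degrees of freedom,
t = r sqrt((n-2)/(1-r^2)), and pixels are classed into five mutually
exclusive significance classes:

    sig_negative   p < 0.05, r < 0
    negative       0.05 <= p < 0.1, r < 0
    nonsignificant p >= 0.1
    positive       0.05 <= p < 0.1, r > 0
    sig_positive   p < 0.05, r > 0

together with the fraction of valid area falling in each class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .raster_io import Grid

__all__ = [
    "SIG_CLASSES",
    "CorrelationMap",
    "pearson_r",
    "correlation_significance",
    "classify_significance",
    "correlation_map",
]

SIG_CLASSES: tuple[str, ...] = (
    "sig_negative", "negative", "nonsignificant", "positive", "sig_positive",
)
_CLASS_CODES = {name: k for k, name in enumerate(SIG_CLASSES)}


@dataclass
class CorrelationMap:
    grid: Grid
    r: np.ndarray  # (rows, cols)
    p: np.ndarray
    n: np.ndarray  # paired-year count per pixel
    classes: np.ndarray  # int8 codes into SIG_CLASSES; -1 nodata
    area_fractions: pd.DataFrame  # per class: pixel count, percent of valid


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation of two equal-length series.

    NaN years are dropped pairwise; a constant series has no defined
    correlation and returns NaN with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        return np.nan
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant series: correlation undefined", stacklevel=2)
        return np.nan
    return float(stats.pearsonr(x, y).statistic)


def correlation_significance(r: float, n: int) -> float:
    """Two-sided p-value of a Pearson r via the t test on n-2 df."""
    if not np.isfinite(r) or n < 3:
        return np.nan
    if abs(r) >= 1:
        return 0.0
    t = r * np.sqrt((n - 2) / (1 - r * r))
    return float(2 * stats.t.sf(abs(t), n - 2))


def classify_significance(r: float, p: float) -> str:
    if not (np.isfinite(r) and np.isfinite(p)):
        raise ValueError("r and p must be finite")
    if p < 0.05:
        return "sig_positive" if r > 0 else "sig_negative"
    if p < 0.1:
        return "positive" if r > 0 else "negative"
    return "nonsignificant"


def correlation_map(
    gri_cube: np.ndarray,
    climate_cube: np.ndarray,
    grid: Grid,
) -> CorrelationMap:
    """Pixel-wise Pearson r, p and significance class over two cubes.

    Both cubes are (n_years, rows, cols) on one grid; pairing is
    complete-case per pixel (only years valid in both series), with the
    per-pixel n recorded.  The area-fraction table gives the percent of
    valid pixels in each of the five significance classes (summing to
    100).
    """
    if gri_cube.shape != climate_cube.shape:
        raise ValueError("cubes must share shape (years, rows, cols)")
    n_years = gri_cube.shape[0]
    x = gri_cube.reshape(n_years, -1)
    y = climate_cube.reshape(n_years, -1)
    npx = x.shape[1]

    ok = np.isfinite(x) & np.isfinite(y)
    n = ok.sum(axis=0)
    xm = np.where(ok, x, np.nan)
    ym = np.where(ok, y, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        xc = xm - np.nanmean(xm, axis=0)
        yc = ym - np.nanmean(ym, axis=0)
        sxy = np.nansum(xc * yc, axis=0)
        sxx = np.nansum(xc * xc, axis=0)
        syy = np.nansum(yc * yc, axis=0)
    r = np.full(npx, np.nan)
    valid = (n >= 3) & (sxx > 0) & (syy > 0)
    r[valid] = sxy[valid] / np.sqrt(sxx[valid] * syy[valid])
    r = np.clip(r, -1.0, 1.0, out=r)

    p = np.full(npx, np.nan)
    df = n - 2
    interior = valid & (np.abs(r) < 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r[interior] * np.sqrt(df[interior] / (1 - r[interior] ** 2))
    p[interior] = 2 * stats.t.sf(np.abs(t), df[interior])
    p[valid & (np.abs(r) >= 1)] = 0.0

    classes = np.full(npx, -1, dtype=np.int8)
    for pid in np.flatnonzero(valid):
        classes[pid] = _CLASS_CODES[classify_significance(r[pid], p[pid])]

    n_valid = int(valid.sum())
    counts = [int(np.sum(classes == _CLASS_CODES[c])) for c in SIG_CLASSES]
    fractions = pd.DataFrame(
        {
            "class": SIG_CLASSES,
            "pixels": counts,
            "percent": [100.0 * c / n_valid if n_valid else np.nan for c in counts],
        }
    )
    return CorrelationMap(
        grid,
        r.reshape(grid.shape),
        p.reshape(grid.shape),
        n.reshape(grid.shape),
        classes.reshape(grid.shape),
        fractions,
    )
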