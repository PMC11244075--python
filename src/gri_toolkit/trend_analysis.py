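"""Per-pixel trend estimation and significance classing.

The GRI trend of every pixel is summarized by the Theil–Sen median slope
(median of all pairwise slopes, robust to outliers) combined with the
Mann–Kendall rank test:

    S      = sum_{i<j} sgn(x_j - x_i)
    Var(S) = n(n-1)(2n+5)/18          (optionally tie-corrected)
    Z      = (S-1)/sqrt(Var S)  if S > 0
             0                  if S = 0
             (S+1)/sqrt(Var S)  if S < 0

and classed into six trend types (plus no-change) at |Z| thresholds 1.96
(95 %) and 2.58 (99 %).  Climate-element trends use the ordinary
least-squares slope against the year index instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, NamedTuple

import numpy as np
from scipy import stats

from .raster_io import Grid

__all__ = [
    "CLASS_LABELS",
    "TrendResult",
    "TrendMap",
    "theil_sen_slope",
    "mk_test",
    "classify_trend",
    "ols_slope",
    "trend_map",
]

#: class-code → label; improvement codes 1-3, degradation 4-6, 0 no change
CLASS_LABELS: dict[int, str] = {
    0: "no_change",
    1: "extremely_significant_improvement",
    2: "significant_improvement",
    3: "modest_improvement",
    4: "modest_degradation",
    5: "significant_degradation",
    6: "extremely_significant_degradation",
}
LABEL_CODES = {v: k for k, v in CLASS_LABELS.items()}


class MKStats(NamedTuple):
    s: float
    var_s: float
    z: float


@dataclass
class TrendResult:
    pixel: int
    slope: float
    s: float
    var_s: float
    z: float
    trend_class: str


@dataclass
class TrendMap:
    grid: Grid
    slope: np.ndarray  # (rows, cols)
    z: np.ndarray
    classes: np.ndarray  # int8 codes per CLASS_LABELS; -1 nodata
    method: str = "theil_sen"


def theil_sen_slope(series: np.ndarray, times: np.ndarray | None = None) -> float:
    """Median of all pairwise slopes (x_j - x_i)/(t_j - t_i), i < j."""
    series = np.asarray(series, dtype=float)
    valid = np.isfinite(series)
    if times is None:
        times = np.arange(len(series), dtype=float)
    times = np.asarray(times, dtype=float)[valid]
    series = series[valid]
    if len(series) < 2:
        return np.nan
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    slope, _, _, _ = stats.theilslopes(series, times)
    return float(slope)


def mk_test(series: np.ndarray, tie_correction: bool = False) -> MKStats:
    """Mann–Kendall S, Var(S) and continuity-corrected Z for one series.

    Requires at least 3 valid points.  ``tie_correction`` subtracts
    sum t_k(t_k-1)(2t_k+5)/18 from Var(S) for tied groups — off by
    default, but relevant to GRI series because the carry-forward rule
    manufactures ties.
    """
    x = np.asarray(series, dtype=float)
    x = x[np.isfinite(x)]
    n = len(x)
    if n < 3:
        return MKStats(np.nan, np.nan, np.nan)
    diff = np.sign(x[None, :] - x[:, None])  # diff[i, j] = sgn(x_j - x_i)
    s = float(np.triu(diff, 1).sum())
    var_s = n * (n - 1) * (2 * n + 5) / 18.0
    if tie_correction:
        _, counts = np.unique(x, return_counts=True)
        ties = counts[counts > 1]
        var_s -= float(np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    if var_s <= 0:
        return MKStats(s, var_s, 0.0)
    if s > 0:
        z = (s - 1) / np.sqrt(var_s)
    elif s < 0:
        z = (s + 1) / np.sqrt(var_s)
    else:
        z = 0.0
    return MKStats(s, var_s, float(z))


def classify_trend(
    slope: float, z: float, z1: float = 1.96, z2: float = 2.58
) -> str:
    """Six-class trend type from (sign of slope, |Z|).

    |Z| >= z2 → extremely significant, z1 <= |Z| < z2 → significant,
    |Z| < z1 → modest; the sign of the slope picks improvement vs
    degradation; an exactly zero slope is no_change.
    """
    if not (np.isfinite(slope) and np.isfinite(z)):
        raise ValueError("slope and z must be finite")
    if slope == 0:
        return "no_change"
    az = abs(z)
    level = "extremely_significant" if az >= z2 else (
        "significant" if az >= z1 else "modest"
    )
    kind = "improvement" if slope > 0 else "degradation"
    return f"{level}_{kind}"


def ols_slope(series: np.ndarray, times: np.ndarray | None = None) -> float:
    """Closed-form least-squares slope of a series against its time index.

    slope = (N·Σ i·x_i − Σi·Σx_i) / (N·Σ i² − (Σi)²), i = 1..N.
    """
    x = np.asarray(series, dtype=float)
    valid = np.isfinite(x)
    if times is None:
        times = np.arange(1, len(x) + 1, dtype=float)
    t = np.asarray(times, dtype=float)[valid]
    x = x[valid]
    n = len(x)
    if n < 2:
        return np.nan
    denom = n * np.sum(t * t) - np.sum(t) ** 2
    return float((n * np.sum(t * x) - np.sum(t) * np.sum(x)) / denom)


def _mk_vectorized(cube: np.ndarray, tie_correction: bool) -> tuple[np.ndarray, np.ndarray]:
    """S and Z for every column of a (n_years, n_px) complete-case matrix."""
    n, npx = cube.shape
    iu, ju = np.triu_indices(n, 1)
    s = np.sign(cube[ju] - cube[iu]).sum(axis=0)
    var_s = np.full(npx, n * (n - 1) * (2 * n + 5) / 18.0)
    if tie_correction:
        for p in range(npx):
            _, counts = np.unique(cube[:, p], return_counts=True)
            ties = counts[counts > 1]
            var_s[p] -= np.sum(ties * (ties - 1) * (2 * ties + 5)) / 18.0
    z = np.zeros(npx)
    pos, neg = (s > 0) & (var_s > 0), (s < 0) & (var_s > 0)
    z[pos] = (s[pos] - 1) / np.sqrt(var_s[pos])
    z[neg] = (s[neg] + 1) / np.sqrt(var_s[neg])
    return s, z


def trend_map(
    cube: np.ndarray,
    grid: Grid,
    times: np.ndarray | None = None,
    method: Literal["theil_sen", "ols"] = "theil_sen",
    tie_correction: bool = False,
    z1: float = 1.96,
    z2: float = 2.58,
) -> TrendMap:
    """Pixel-wise trend over a (n_years, rows, cols) cube.

    ``theil_sen`` pairs the median slope with the Mann–Kendall class map
    (the GRI pathway); ``ols`` computes the least-squares slope only (the
    climate pathway — its Z and class planes are nodata).  Pixels with
    missing years use their valid subset; fewer than 3 valid years (2 for
    OLS) is nodata.
    """
    n_years = cube.shape[0]
    flat = cube.reshape(n_years, -1)
    npx = flat.shape[1]
    if times is None:
        times = np.arange(n_years, dtype=float)
    slope = np.full(npx, np.nan)
    z = np.full(npx, np.nan)
    classes = np.full(npx, -1, dtype=np.int8)

    complete = np.all(np.isfinite(flat), axis=0)
    some = np.any(np.isfinite(flat), axis=0)

    if method == "ols":
        t = np.asarray(times, dtype=float)
        idx = np.flatnonzero(complete)
        if idx.size:
            xc = flat[:, idx]
            tc = t - t.mean()
            slope[idx] = tc @ xc / np.sum(tc * tc)
        for p in np.flatnonzero(some & ~complete):
            slope[p] = ols_slope(flat[:, p], times)
        return TrendMap(grid, slope.reshape(grid.shape), z.reshape(grid.shape),
                        classes.reshape(grid.shape), method="ols")

    idx = np.flatnonzero(complete)
    if idx.size and n_years >= 3:
        sub = flat[:, idx]
        iu, ju = np.triu_indices(n_years, 1)
        pair_slopes = (sub[ju] - sub[iu]) / (times[ju] - times[iu])[:, None]
        slope[idx] = np.median(pair_slopes, axis=0)
        _, z[idx] = _mk_vectorized(sub, tie_correction)
    for p in np.flatnonzero(some & ~complete):
        v = flat[:, p]
        ok = np.isfinite(v)
        if ok.sum() >= 3:
            slope[p] = theil_sen_slope(v, np.asarray(times, dtype=float))
            _, _, z[p] = mk_test(v, tie_correction)
    good = np.isfinite(slope) & np.isfinite(z)
    for p in np.flatnonzero(good):
        classes[p] = LABEL_CODES[classify_trend(slope[p], z[p], z1, z2)]
    return TrendMap(grid, slope.reshape(grid.shape), z.reshape(grid.shape),
                    classes.reshape(grid.shape))
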