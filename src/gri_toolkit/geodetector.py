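"""Factor detector of spatial stratified heterogeneity (geographical detector).

The q-statistic measures how much a categorical stratification of space
explains a response surface:

    q = 1 - sum_i n_i sigma_i^2 / (n sigma^2)

with population variances, where stratum i holds n_i pixels with response
variance sigma_i^2 and sigma^2 is the variance over all n pixels.  q is 1
when strata are internally homogeneous and 0 when stratification explains
nothing.  Per-factor q values are compared through the relative
contribution rate

    RCR_i = q_i / sum_j q_j * 100 %

the share of total explanatory power carried by factor i.  Continuous
driving factors (latitude, MAT, MAP, GDP, population density) are
discretized into m strata first; the quantile method with m = 5 is the
default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .raster_io import FactorLayer, Grid

__all__ = [
    "QResult",
    "discretize_factor",
    "discretize_values",
    "q_statistic",
    "q_permutation_pvalue",
    "rcr",
    "factor_attribution",
]


@dataclass
class QResult:
    """Explanatory power of one stratification of one response surface."""

    factor: str
    q: float
    m: int  # number of (nonempty) strata
    n: int  # total sample size
    sigma2: float  # total population variance
    strata_stats: pd.DataFrame  # per stratum: label, n_i, sigma_i^2


def discretize_values(
    values: np.ndarray,
    method: Literal["quantile", "equal_interval", "natural_breaks"] = "quantile",
    m: int = 5,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Label a 1-D continuous sample with strata 1..m (0 = invalid).

    ``quantile`` yields near-equal stratum sizes; ``equal_interval`` cuts
    the value range evenly; ``natural_breaks`` uses 1-D k-means cluster
    boundaries (a k-means analogue of Jenks breaks).  If the data hold
    fewer distinct values than m, m is reduced with a warning.
    """
    values = np.asarray(values, dtype=float)
    labels = np.zeros(len(values), dtype=np.int64)
    ok = np.isfinite(values)
    v = values[ok]
    if v.size == 0:
        return labels
    distinct = np.unique(v)
    if len(distinct) < m:
        warnings.warn(
            f"only {len(distinct)} distinct values; reducing strata from {m}",
            stacklevel=2,
        )
        m = max(len(distinct), 1)
    if m == 1:
        labels[ok] = 1
        return labels
    if method == "quantile":
        edges = np.quantile(v, np.linspace(0, 1, m + 1)[1:-1])
        lab = np.searchsorted(edges, v, side="right") + 1
    elif method == "equal_interval":
        edges = np.linspace(v.min(), v.max(), m + 1)[1:-1]
        lab = np.searchsorted(edges, v, side="right") + 1
    elif method == "natural_breaks":
        from sklearn.cluster import KMeans

        seed = int(rng.integers(2**31)) if rng is not None else 0
        km = KMeans(n_clusters=m, n_init=10, random_state=seed).fit(v.reshape(-1, 1))
        order = np.argsort(km.cluster_centers_.ravel())
        remap = np.empty(m, dtype=np.int64)
        remap[order] = np.arange(1, m + 1)
        lab = remap[km.labels_]
    else:
        raise ValueError(f"unknown method {method!r}")
    labels[ok] = lab
    return labels


def discretize_factor(
    layer: FactorLayer,
    method: Literal["quantile", "equal_interval", "natural_breaks"] = "quantile",
    m: int = 5,
    rng: np.random.Generator | None = None,
) -> FactorLayer:
    """Discretize a continuous factor layer into m strata (categorical
    layers pass through unchanged)."""
    if layer.kind == "categorical":
        return layer
    labels = discretize_values(layer.values.ravel(), method, m, rng)
    return FactorLayer(layer.grid, labels.reshape(layer.grid.shape),
                       "categorical", layer.name)


def q_statistic(values: np.ndarray, strata: np.ndarray, factor: str = "") -> QResult:
    """q = 1 - SSW/SST over valid (value, stratum) pairs.

    Population variances; pixels with NaN response or stratum label <= 0
    are excluded.  Singleton strata contribute zero within-stratum
    variance but count toward n — they inflate q, so a warning is raised.
    Zero total variance leaves q undefined (NaN) with a warning.
    """
    values = np.asarray(values, dtype=float).ravel()
    strata = np.asarray(strata).ravel()
    if values.shape != strata.shape:
        raise ValueError("values and strata must align")
    if np.issubdtype(strata.dtype, np.number):
        ok = np.isfinite(values) & (strata > 0)
    else:  # string/object labels: every labelled pixel is valid
        ok = np.isfinite(values)
    v, s = values[ok], strata[ok]
    n = len(v)
    if n < 2:
        raise ValueError("need at least 2 valid pixels")
    sigma2 = float(np.var(v))
    labels, inverse, counts = np.unique(s, return_inverse=True, return_counts=True)
    sums = np.bincount(inverse, weights=v)
    sqsums = np.bincount(inverse, weights=v * v)
    with np.errstate(invalid="ignore"):
        sigma2_i = sqsums / counts - (sums / counts) ** 2
    sigma2_i = np.maximum(sigma2_i, 0.0)  # clamp negative rounding residue
    if np.any(counts == 1):
        warnings.warn(
            f"{int(np.sum(counts == 1))} singleton strata contribute zero "
            "within-stratum variance and inflate q",
            stacklevel=2,
        )
    stats_df = pd.DataFrame({"stratum": labels, "n_i": counts, "sigma2_i": sigma2_i})
    if sigma2 == 0:
        warnings.warn("zero total variance: q undefined", stacklevel=2)
        return QResult(factor, np.nan, len(labels), n, sigma2, stats_df)
    ssw = float(np.sum(counts * sigma2_i))
    q = 1.0 - ssw / (n * sigma2)
    q = min(max(q, 0.0), 1.0)
    return QResult(factor, q, len(labels), n, sigma2, stats_df)


def q_permutation_pvalue(
    values: np.ndarray,
    strata: np.ndarray,
    n_perm: int = 999,
    rng: np.random.Generator | None = None,
) -> float:
    """Permutation p-value for q (optional diagnostic beyond the printed
    method): the fraction of stratum-label permutations with q at least as
    large as observed."""
    rng = rng or np.random.default_rng()
    values = np.asarray(values, dtype=float).ravel()
    strata = np.asarray(strata).ravel()
    ok = np.isfinite(values) & (strata > 0)
    v, s = values[ok], strata[ok].copy()
    q_obs = q_statistic(v, s).q
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(s)
        if q_statistic(v, s).q >= q_obs:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def rcr(q_results: Sequence[QResult] | dict[str, float]) -> pd.DataFrame:
    """Relative contribution rates: each factor's q as a percent of Σq."""
    if isinstance(q_results, dict):
        items = list(q_results.items())
    else:
        items = [(r.factor, r.q) for r in q_results]
    names = [k for k, _ in items]
    qs = np.array([v for _, v in items], dtype=float)
    if np.any(qs < 0) or np.any(~np.isfinite(qs)):
        raise ValueError("q values must be finite and non-negative")
    total = qs.sum()
    if total == 0:
        raise ValueError("all q values are zero: RCR undefined")
    return pd.DataFrame({"factor": names, "q": qs, "rcr_percent": qs / total * 100.0})


def factor_attribution(
    gri_map: np.ndarray,
    factors: Sequence[FactorLayer],
    grid: Grid,
    regions: FactorLayer | None = None,
    method: Literal["quantile", "equal_interval", "natural_breaks"] = "quantile",
    m: int = 5,
    min_region_pixels: int = 30,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """q and RCR of each driving factor for one response map, per scope.

    ``gri_map`` is a single response surface (one epoch's GRI map or the
    multi-year mean).  Scopes are the whole region plus, when ``regions``
    is given, each sub-region label; sub-regions with fewer than
    ``min_region_pixels`` valid pixels are skipped with a warning.
    Returns a long table (scope, factor, q, m, n, rcr_percent).
    """
    response = np.asarray(gri_map, dtype=float).ravel()
    strata_per_factor = {
        f.name or f"factor_{k}": discretize_factor(f, method, m, rng).values.ravel()
        for k, f in enumerate(factors)
    }
    scopes: list[tuple[str, np.ndarray]] = [("region", np.ones(grid.size, bool))]
    if regions is not None:
        reg = regions.values.ravel()
        for code in np.unique(reg[reg > 0]):
            scopes.append((f"subregion_{int(code)}", reg == code))

    rows = []
    for scope_name, scope_mask in scopes:
        valid = scope_mask & np.isfinite(response)
        # complete-case: every factor must be stratified at the pixel
        for s in strata_per_factor.values():
            valid &= s > 0
        if valid.sum() < min_region_pixels:
            warnings.warn(
                f"scope {scope_name}: {int(valid.sum())} valid pixels < "
                f"{min_region_pixels}; skipped",
                stacklevel=2,
            )
            continue
        results = [
            q_statistic(response[valid], s[valid], factor=name)
            for name, s in strata_per_factor.items()
        ]
        table = rcr(results)
        for res, (_, row) in zip(results, table.iterrows()):
            rows.append(
                {
                    "scope": scope_name,
                    "factor": res.factor,
                    "q": res.q,
                    "m": res.m,
                    "n": res.n,
                    "rcr_percent": row["rcr_percent"],
                }
            )
    return pd.DataFrame(rows)
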