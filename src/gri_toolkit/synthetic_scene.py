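"""Self-contained synthetic scenes with known ground truth.

Stands in for the real inputs of a grassland-resilience analysis — a
multi-year stack of 8-day growing-season LAI composites, annual land-cover
rasters, annual climate surfaces and socio-economic layers — so every
pipeline stage can be exercised and verified without any download.

Each pixel carries a smooth seasonal LAI cycle (harmonic over the
May–September composites, amplitude increasing northwards) that repeats
across years, plus additive Gaussian composite noise.  Anomaly events are
*injected*: for a chosen pixel, start month and duration, the monthly LAI
is carved below the pixel's climatological band floor with the single
trough at ``floor - depth`` in the start month and a linear recovery, and
the month after the run is pinned at the seasonal baseline (at/above the
floor), so the designed recovery time is well defined.

Because injecting an event shifts the very climatology (MEAN_j, STD_j)
that defines the band, designed values are solved by fixed-point iteration
per pixel until the final band floor minus the trough equals the requested
depth to ~1e-12.  The ground-truth event table and annual GRI are then
produced by running the package's own aggregation/detection on the
noise-free stack, so at zero noise the pipeline output matches the truth
bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import gri_core
from .gri_core import GROWING_SEASON_MONTHS, AnomalyEvent, steps_to_months
from .raster_io import FactorLayer, Grid, LAIStack

__all__ = [
    "SceneConfigError",
    "EventSpec",
    "SceneConfig",
    "TruthTable",
    "Scene",
    "generate_scene",
    "inject_anomaly",
]

_FP_TOL = 1e-13
_FP_MAX_ITER = 500


class SceneConfigError(ValueError):
    """Raised when an event specification cannot be realized."""


@dataclass(frozen=True)
class EventSpec:
    """One injected anomaly: a sub-band excursion of known depth/duration.

    ``depth`` is in LAI units below the final band floor at the trough;
    ``duration`` counts below-band growing-season months, the trough being
    the first.  Events starting late in a season continue in May of the
    next year (seasons are concatenated).
    """

    pixel: int
    start_year: int
    start_month: int
    depth: float
    duration: int

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise SceneConfigError("event depth must be > 0")
        if self.duration < 1:
            raise SceneConfigError("event duration must be >= 1")
        if self.start_month not in GROWING_SEASON_MONTHS:
            raise SceneConfigError("events start within May-September")


@dataclass
class SceneConfig:
    """Study conditions of the synthetic scene.

    Defaults mirror the analysed record: a 40x40 pixel grassland scene,
    22 years (2000-2021) of 20 growing-season composites each (440 planes),
    band parameter beta = 1.  ``noise_sd`` is the additive composite-level
    LAI noise (~5 % of the mean seasonal amplitude by default);
    ``n_events`` random anomalies are injected unless an explicit
    ``event_spec`` is supplied.
    """

    nrows: int = 40
    ncols: int = 40
    x0: float = 121.6  # deg E, west edge
    y0: float = 48.6  # deg N, north edge
    cell: float = 0.1  # deg
    years: tuple[int, ...] = tuple(range(2000, 2022))
    steps_per_year: int = 20
    beta: float = 1.0
    base_lai: float = 0.4
    amplitude: float = 1.2  # seasonal amplitude at mid-latitude
    amplitude_lat_gradient: float = 0.10  # per degree northwards
    noise_sd: float = 0.06
    n_events: int = 60
    event_spec: tuple[EventSpec, ...] | None = None
    grass_fraction: float = 0.85  # share of pixels persistently grassland
    grass_code: int = 3
    crop_code: int = 1
    seed: int = 0
    # climate surfaces: value = base + lat_grad*(lat-lat_mid) +
    #                   lon_grad*(lon-lon_mid) + trend*(year-y0) + noise
    mat_base: float = 4.5
    mat_lat_gradient: float = -0.9
    mat_trend: float = 0.03
    mat_noise_sd: float = 0.4
    map_base: float = 475.0
    map_lon_gradient: float = -45.0
    map_trend: float = 2.0
    map_noise_sd: float = 35.0
    epochs: tuple[int, ...] = (2000, 2005, 2010, 2015, 2020)


@dataclass
class TruthTable:
    """Ground truth of a generated scene.

    ``events`` are the operational truth (exactly what zero-noise
    detection yields); ``specs`` the designed depths/durations they
    realize; ``annual_raw`` the truth annual GRI cube under the
    attribution rules.
    """

    specs: tuple[EventSpec, ...]
    events: list[AnomalyEvent]
    annual_raw: np.ndarray  # (n_years, rows, cols)
    persistent_mask: np.ndarray  # bool (rows, cols)

    def events_df(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "pixel": e.pixel,
                    "start_year": e.start_year,
                    "start_month": e.start_month,
                    "ms": e.ms,
                    "rt": e.rt,
                    "resolved": e.resolved,
                    "lai_lowest": e.lai_lowest,
                    "cross_year": e.cross_year,
                }
                for e in self.events
            ]
        )


@dataclass
class Scene:
    config: SceneConfig
    grid: Grid
    stack: LAIStack
    landcover: list[FactorLayer]  # one categorical layer per year
    mat: np.ndarray  # (n_years, rows, cols) degC
    map_precip: np.ndarray  # (n_years, rows, cols) mm
    gdp: dict[int, FactorLayer]  # per epoch
    pd_density: dict[int, FactorLayer]  # per epoch
    truth: TruthTable


# ---------------------------------------------------------------------------
# anomaly injection
# ---------------------------------------------------------------------------

def inject_anomaly(
    series: np.ndarray,
    clim_band_floor: np.ndarray,
    start: int,
    depth: float,
    duration: int,
) -> np.ndarray:
    """Carve one event into a concatenated monthly series (static floor).

    Sets ``duration`` consecutive months below the given per-month band
    floor, the single trough at ``floor[start] - depth``, recovering
    linearly toward the floor, and pins the month after the run at the
    floor (back in band).  Events running past the record end are emitted
    truncated (designed-unresolved).  This is the single-event primitive;
    :func:`generate_scene` additionally re-solves the floor self-
    consistently after injection.
    """
    out = np.asarray(series, dtype=float).copy()
    n = len(out)
    if start >= n:
        raise SceneConfigError("event starts past the end of the record")
    v0 = clim_band_floor[start] - depth
    end = min(start + duration, n)
    for i in range(start, end):
        frac = (i - start) / duration
        vi = v0 + (clim_band_floor[i] - v0) * frac
        if i > start and not (v0 < vi < clim_band_floor[i]):
            raise SceneConfigError(
                "event extends into a month whose band floor is at or below "
                "the designed trough; increase depth or move the event"
            )
        out[i] = vi
    if end < n:
        out[end] = max(out[end], clim_band_floor[end])
    return out


def _seasonal_shape(months: Sequence[int]) -> np.ndarray:
    """Unit seasonal shape peaking in July: sin over May..September."""
    m = np.asarray(months, dtype=float)
    return np.sin(np.pi * (m - 4.5) / 5.0)


def _solve_pixel_design(
    baseline: np.ndarray,  # (n_years, n_months) noise-free seasonal values
    specs: list[EventSpec],
    years: np.ndarray,
    months: Sequence[int],
    beta: float,
) -> np.ndarray:
    """Designed monthly values for one pixel, self-consistent with the
    climatology of the result (fixed-point iteration)."""
    n_years, n_months = baseline.shape
    month_index = {m: k for k, m in enumerate(months)}
    flat_base = baseline.reshape(-1)
    n = len(flat_base)

    plans = []  # (t0, duration, depth, trailing index or None)
    occupied: set[int] = set()
    for sp in specs:
        yi = int(np.searchsorted(years, sp.start_year))
        if yi >= n_years or years[yi] != sp.start_year:
            raise SceneConfigError(f"event year {sp.start_year} outside record")
        t0 = yi * n_months + month_index[sp.start_month]
        span = set(range(t0, min(t0 + sp.duration + 1, n)))
        if span & occupied:
            raise SceneConfigError(
                f"overlapping events on pixel {sp.pixel} near year {sp.start_year}"
            )
        occupied |= span
        plans.append((t0, sp.duration, sp.depth))

    flat = flat_base.copy()
    for _ in range(_FP_MAX_ITER):
        vals = flat.reshape(n_years, n_months)
        floor_m = vals.mean(axis=0) - beta * vals.std(axis=0)
        floor = np.tile(floor_m, n_years)
        new = flat_base.copy()
        for t0, duration, depth in plans:
            v0 = floor[t0] - depth
            end = min(t0 + duration, n)
            for i in range(t0, end):
                frac = (i - t0) / duration
                new[i] = v0 + (floor[i] - v0) * frac
            # trailing month stays at the seasonal baseline (in band)
        delta = float(np.max(np.abs(new - flat)))
        flat = new
        if delta < _FP_TOL:
            break
    else:
        raise SceneConfigError("event design did not converge")

    # validate the converged design against the final floor
    vals = flat.reshape(n_years, n_months)
    floor_m = vals.mean(axis=0) - beta * vals.std(axis=0)
    floor = np.tile(floor_m, n_years)
    for t0, duration, depth in plans:
        end = min(t0 + duration, n)
        v0 = flat[t0]
        if v0 < 0:
            raise SceneConfigError("designed trough LAI < 0; reduce depth")
        for i in range(t0, end):
            if not flat[i] < floor[i]:
                raise SceneConfigError(
                    "event month not below band after solving; the run spans "
                    "months whose floor sits below the designed trough"
                )
            if i > t0 and not flat[i] > v0:
                raise SceneConfigError("trough is not the unique run minimum")
        if end < n and end not in {p[0] for p in plans} and flat[end] < floor[end]:
            raise SceneConfigError("recovery month fell below the band")
    return flat


# ---------------------------------------------------------------------------
# random event placement
# ---------------------------------------------------------------------------

def _random_event_specs(
    cfg: SceneConfig,
    rng: np.random.Generator,
    grass_pixels: np.ndarray,
    amp: np.ndarray,
) -> list[EventSpec]:
    """Draw non-overlapping events on grassland pixels.

    Also seeds one deliberate instance of each attribution rule: a pixel
    with two events in one year, a September event recovering the next
    May, and an unresolved event running past the record end.
    """
    months = GROWING_SEASON_MONTHS
    n_months = len(months)
    shape = _seasonal_shape(months)
    n_years = len(cfg.years)
    specs: list[EventSpec] = []
    occupied: dict[int, set[int]] = {}

    def floor_est(pid: int, mi: int) -> float:
        return cfg.base_lai + amp.ravel()[pid] * shape[mi % n_months]

    def try_add(pid, yi, mi, depth, duration) -> bool:
        t0 = yi * n_months + mi
        span = set(range(t0, t0 + duration + 1))
        if span & occupied.get(pid, set()):
            return False
        # conservative feasibility guard: injecting the event lowers the
        # band floor itself (the anomalous year drags MEAN_j and STD_j), so
        # allow ~0.5*depth of floor drop before validating exactly later
        floors = [floor_est(pid, (mi + k)) for k in range(duration)]
        v0 = floors[0] - 1.5 * depth
        if v0 < 0.05 or any(f - 0.5 * depth <= v0 + 0.05 for f in floors):
            return False
        # the trough must undercut the pixel's lowest monthly baseline, so
        # that no composite-noise dip in a neighbouring month can merge
        # into the run and relocate the run minimum
        min_baseline = cfg.base_lai + amp.ravel()[pid] * shape.min()
        if v0 > min_baseline - 0.12:
            return False
        occupied.setdefault(pid, set()).update(span)
        specs.append(
            EventSpec(int(pid), int(cfg.years[yi]), months[mi], float(depth),
                      int(duration))
        )
        return True

    # deliberate rule-coverage events
    special = [p for p in grass_pixels[:4]]
    if len(special) >= 3 and n_years >= 3:
        try_add(special[0], 2, 0, 0.35, 1)  # two events, one year
        try_add(special[0], 2, 3, 0.6, 1)
        try_add(special[1], 4, 4, 0.4, 2)  # September -> next May
        try_add(special[2], n_years - 1, 4, 0.4, 3)  # runs past the record

    budget = 0
    while len(specs) < cfg.n_events and budget < 50 * cfg.n_events:
        budget += 1
        pid = int(rng.choice(grass_pixels))
        yi = int(rng.integers(1, n_years))
        mi = int(rng.integers(0, n_months))
        duration = int(rng.integers(1, 5))
        depth = float(rng.uniform(0.3, 0.7))
        try_add(pid, yi, mi, depth, duration)
    if len(specs) < cfg.n_events:
        raise SceneConfigError("could not place the requested number of events")
    return specs


# ---------------------------------------------------------------------------
# scene generation
# ---------------------------------------------------------------------------

def generate_scene(config: SceneConfig | None = None) -> Scene:
    """Generate a full synthetic scene with ground truth.

    Deterministic: the same config (including seed) regenerates the scene
    bit for bit.
    """
    cfg = config or SceneConfig()
    rng = np.random.default_rng(cfg.seed)
    grid = Grid(cfg.x0, cfg.y0, cfg.cell, cfg.cell, (cfg.nrows, cfg.ncols))
    years = np.asarray(cfg.years)
    n_years = len(years)
    months = GROWING_SEASON_MONTHS
    n_months = len(months)
    npx = grid.size

    lat = grid.latitudes().ravel()
    lon = np.tile(grid.x_centers(), (cfg.nrows, 1)).ravel()
    lat_mid, lon_mid = float(lat.mean()), float(lon.mean())

    amp = cfg.amplitude + cfg.amplitude_lat_gradient * (lat - lat_mid)
    amp = amp + rng.normal(0.0, 0.02, npx)
    shape = _seasonal_shape(months)
    baseline = cfg.base_lai + amp[None, :] * shape[:, None]  # (n_months, npx)

    # land cover: persistent grassland subset + pixels that flip class
    order = rng.permutation(npx)
    n_grass = int(round(cfg.grass_fraction * npx))
    grass_pixels = np.sort(order[:n_grass])
    persistent = np.zeros(npx, dtype=bool)
    persistent[grass_pixels] = True
    flicker = order[n_grass:]
    lc_years = np.full((n_years, npx), cfg.grass_code, dtype=np.int64)
    for pid in flicker:
        k = int(rng.integers(1, max(2, n_years // 3)))
        flips = rng.choice(n_years, size=k, replace=False)
        lc_years[flips, pid] = cfg.crop_code
    landcover = [
        FactorLayer(grid, lc_years[k].reshape(grid.shape), "categorical",
                    f"landcover_{years[k]}")
        for k in range(n_years)
    ]

    # events and the self-consistent designed monthly matrix
    if cfg.event_spec is not None:
        specs = list(cfg.event_spec)
    else:
        specs = _random_event_specs(cfg, rng, grass_pixels, amp)
    by_pixel: dict[int, list[EventSpec]] = {}
    for sp in specs:
        by_pixel.setdefault(sp.pixel, []).append(sp)

    designed = np.repeat(baseline.T[:, None, :], n_years, axis=1)  # (npx, ny, nm)
    controlled = np.zeros((npx, n_years * n_months), dtype=bool)
    for pid, pix_specs in by_pixel.items():
        base_pm = np.tile(baseline[:, pid], (n_years, 1))
        flat = _solve_pixel_design(base_pm, pix_specs, years, months, cfg.beta)
        designed[pid] = flat.reshape(n_years, n_months)
        month_index = {m: k for k, m in enumerate(months)}
        for sp in pix_specs:
            yi = int(np.searchsorted(years, sp.start_year))
            t0 = yi * n_months + month_index[sp.start_month]
            hi = min(t0 + sp.duration + 1, n_years * n_months)
            controlled[pid, t0:hi] = True

    # noise-free stack: composites flat within each month
    step_months = steps_to_months(cfg.steps_per_year)
    month_of_step = np.array([months.index(m) for m in step_months])
    vals0 = designed[:, :, month_of_step]  # (npx, n_years, steps)
    stack0 = LAIStack(
        grid, years, cfg.steps_per_year,
        np.ascontiguousarray(vals0.transpose(1, 2, 0)).reshape(
            n_years, cfg.steps_per_year, *grid.shape),
    )

    # operational truth from the noise-free stack
    monthly0 = gri_core.monthly_aggregate(stack0)
    clim0 = gri_core.climatology(monthly0, beta=cfg.beta)
    truth_events = gri_core.detect_anomalies(monthly0, clim0)
    truth_map = gri_core.annual_gri(truth_events, years, grid, beta=cfg.beta)
    truth = TruthTable(tuple(specs), truth_events, truth_map.raw,
                       persistent.reshape(grid.shape))

    # emitted stack: composite noise, centred within event-controlled months
    noise = rng.normal(0.0, cfg.noise_sd, size=(npx, n_years, cfg.steps_per_year))
    if cfg.noise_sd > 0:
        for mi in range(n_months):
            sel = month_of_step == mi
            block = noise[:, :, sel]
            centred = block - block.mean(axis=2, keepdims=True)
            ctrl = controlled.reshape(npx, n_years, n_months)[:, :, mi]
            noise[:, :, sel] = np.where(ctrl[:, :, None], centred, block)
        values = np.clip(vals0 + noise, 0.0, None)
    else:
        values = vals0
    stack = LAIStack(
        grid, years, cfg.steps_per_year,
        np.ascontiguousarray(values.transpose(1, 2, 0)).reshape(
            n_years, cfg.steps_per_year, *grid.shape),
    )

    # climate cubes
    yr_idx = (years - years[0]).astype(float)
    mat = (
        cfg.mat_base
        + cfg.mat_lat_gradient * (lat - lat_mid)[None, :]
        + cfg.mat_trend * yr_idx[:, None]
        + rng.normal(0.0, cfg.mat_noise_sd, (n_years, npx))
    ).reshape(n_years, *grid.shape)
    map_precip = (
        cfg.map_base
        + cfg.map_lon_gradient * (lon - lon_mid)[None, :]
        + cfg.map_trend * yr_idx[:, None]
        + rng.normal(0.0, cfg.map_noise_sd, (n_years, npx))
    ).reshape(n_years, *grid.shape)

    # socio-economic surfaces: a few population/activity centres, per epoch
    n_centres = 5
    cy = rng.uniform(lat.min(), lat.max(), n_centres)
    cx = rng.uniform(lon.min(), lon.max(), n_centres)
    weight = rng.uniform(0.5, 2.0, n_centres)
    dist2 = (lat[:, None] - cy[None, :]) ** 2 + (lon[:, None] - cx[None, :]) ** 2
    blobs = np.sum(weight[None, :] * np.exp(-dist2 / (2 * 0.6**2)), axis=1)
    gdp_base = 50.0 + 400.0 * blobs
    pd_base = 5.0 + 60.0 * blobs
    gdp, pdens = {}, {}
    for k, ep in enumerate(cfg.epochs):
        growth = 1.0 + 0.25 * k
        gdp[ep] = FactorLayer(
            grid,
            (gdp_base * growth * np.exp(rng.normal(0, 0.05, npx))).reshape(grid.shape),
            "continuous", "gdp",
        )
        pdens[ep] = FactorLayer(
            grid,
            (pd_base * (1.0 + 0.05 * k) * np.exp(rng.normal(0, 0.05, npx))).reshape(grid.shape),
            "continuous", "pd",
        )

    return Scene(cfg, grid, stack, landcover, mat, map_precip, gdp, pdens, truth)
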