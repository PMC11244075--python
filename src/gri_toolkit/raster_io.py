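"""Gridded input/output, grid alignment and the persistent-grassland mask.

All analysis arrays are ``float64`` with ``NaN`` as the in-memory nodata
sentinel; the sentinel value stored on disk is :attr:`Grid.nodata`.  Pixels
are addressed ``(row, col)`` with row 0 at the north edge, and flat pixel
ids are row-major (``pid = row * ncols + col``), the convention every other
module uses for per-pixel tables.

Formats
-------
* single-band maps: ESRI ASCII grid (``.asc``), a plain-text georeferenced
  raster; class maps carry their value→label table in a ``.labels.json``
  sidecar.
* multi-band stacks (LAI, climate): CF-style NetCDF (classic format,
  dimensions ``time/y/x``) through :mod:`xarray`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import xarray as xr

__all__ = [
    "Grid",
    "LAIStack",
    "FactorLayer",
    "AlignmentError",
    "read_map",
    "write_map",
    "read_stack",
    "write_stack",
    "build_grassland_mask",
    "resample_to",
]

EARTH_RADIUS_KM = 6371.0088


class AlignmentError(ValueError):
    """Raised when rasters that must share a grid do not."""


@dataclass(frozen=True)
class Grid:
    """Georeferencing of a north-up, axis-aligned raster.

    Parameters
    ----------
    x0, y0
        Coordinates of the *outer corner* of pixel (0, 0) — the west edge
        and the north edge respectively.
    dx, dy
        Pixel size, both positive; rows advance southwards (decreasing y).
    shape
        ``(rows, cols)``.
    crs
        Free-form identifier, e.g. ``"EPSG:4326"``.  Only equality is
        checked when aligning; no reprojection machinery is attached.
    nodata
        Sentinel written to disk in place of NaN.
    """

    x0: float
    y0: float
    dx: float
    dy: float
    shape: tuple[int, int]
    crs: str = "EPSG:4326"
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("pixel size must be positive")
        if self.shape[0] < 1 or self.shape[1] < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def nrows(self) -> int:
        return self.shape[0]

    @property
    def ncols(self) -> int:
        return self.shape[1]

    @property
    def size(self) -> int:
        return self.nrows * self.ncols

    def x_centers(self) -> np.ndarray:
        return self.x0 + (np.arange(self.ncols) + 0.5) * self.dx

    def y_centers(self) -> np.ndarray:
        return self.y0 - (np.arange(self.nrows) + 0.5) * self.dy

    def latitudes(self) -> np.ndarray:
        """Pixel-center latitude, broadcast to the full grid.

        For a geographic CRS the y coordinate *is* latitude; for projected
        grids this is still the north–south coordinate and serves the same
        role as a monotone 'geographic position' factor.
        """
        return np.repeat(self.y_centers()[:, None], self.ncols, axis=1)

    def pixel_area_km2(self) -> float:
        """Nominal pixel area.

        Projected grids (metre units) use dx·dy directly; geographic grids
        use the spherical cell area at the grid's central latitude.
        """
        if self.crs.upper() in ("EPSG:4326", "WGS84", "CRS:84"):
            lat_mid = math.radians(float(np.mean(self.y_centers())))
            km_per_deg = EARTH_RADIUS_KM * math.pi / 180.0
            return self.dx * km_per_deg * math.cos(lat_mid) * self.dy * km_per_deg
        return self.dx * self.dy / 1.0e6

    def same_geometry(self, other: "Grid", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and self.crs == other.crs
            and abs(self.x0 - other.x0) <= tol
            and abs(self.y0 - other.y0) <= tol
            and abs(self.dx - other.dx) <= tol
            and abs(self.dy - other.dy) <= tol
        )


@dataclass
class LAIStack:
    """Leaf-area-index stack: (year, within-season step, row, col).

    LAI is dimensionless (m² leaf per m² ground) and non-negative wherever
    valid; invalid cells are NaN.
    """

    grid: Grid
    years: np.ndarray  # strictly increasing calendar years
    steps_per_year: int
    values: np.ndarray  # float64 (n_years, steps_per_year, rows, cols)

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        if np.any(np.diff(self.years) <= 0):
            raise ValueError("years must be strictly increasing")
        expected = (len(self.years), self.steps_per_year, *self.grid.shape)
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} != {expected}")
        if np.nanmin(self.values, initial=0.0) < 0:
            raise ValueError("valid LAI must be >= 0")

    @property
    def n_years(self) -> int:
        return len(self.years)


@dataclass
class FactorLayer:
    """One scalar per pixel: a driving-factor surface (latitude, MAT, MAP,
    GDP, population density) or a categorical layer (land cover, strata)."""

    grid: Grid
    values: np.ndarray  # (rows, cols); float (NaN nodata) or int codes
    kind: Literal["continuous", "categorical"]
    name: str = ""

    def __post_init__(self) -> None:
        if self.values.shape != self.grid.shape:
            raise ValueError("layer shape does not match grid")
        if self.kind == "categorical" and not np.issubdtype(
            self.values.dtype, np.integer
        ):
            raise ValueError("categorical layers hold integer labels")


# ---------------------------------------------------------------------------
# ESRI ASCII grid (single band, text)
# ---------------------------------------------------------------------------

def write_map(
    values: np.ndarray,
    grid: Grid,
    path: str | Path,
    labels: dict[int, str] | None = None,
) -> Path:
    """Write a single-band map as an ESRI ASCII grid.

    NaN cells become ``grid.nodata``.  ``labels`` (for class maps) is
    written to a ``<path>.labels.json`` sidecar so the value→label table
    survives the round trip.
    """
    path = Path(path)
    arr = np.asarray(values, dtype=float).reshape(grid.shape)
    out = np.where(np.isnan(arr), grid.nodata, arr)
    header = (
        f"ncols {grid.ncols}\n"
        f"nrows {grid.nrows}\n"
        f"xllcorner {grid.x0!r}\n"
        f"yllcorner {grid.y0 - grid.nrows * grid.dy!r}\n"
        f"cellsize {grid.dx!r}\n"
        f"NODATA_value {grid.nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for row in out:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")
    if labels is not None:
        sidecar = path.with_suffix(path.suffix + ".labels.json")
        sidecar.write_text(json.dumps({str(k): v for k, v in labels.items()}))
    return path


def read_map(
    path: str | Path, crs: str = "EPSG:4326"
) -> tuple[np.ndarray, Grid, dict[int, str] | None]:
    """Read an ESRI ASCII grid; returns (values with NaN nodata, Grid, labels)."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh, dtype=float)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    data = data.reshape(nrows, ncols)
    cell = header["cellsize"]
    nodata = header.get("nodata_value", -9999.0)
    grid = Grid(
        x0=header["xllcorner"],
        y0=header["yllcorner"] + nrows * cell,
        dx=cell,
        dy=cell,
        shape=(nrows, ncols),
        crs=crs,
        nodata=nodata,
    )
    values = np.where(data == nodata, np.nan, data)
    sidecar = path.with_suffix(path.suffix + ".labels.json")
    labels = None
    if sidecar.exists():
        labels = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
    return values, grid, labels


# ---------------------------------------------------------------------------
# NetCDF stacks
# ---------------------------------------------------------------------------

def _grid_to_coords(grid: Grid) -> dict[str, np.ndarray]:
    return {"y": grid.y_centers(), "x": grid.x_centers()}


def write_stack(stack: LAIStack, path: str | Path) -> Path:
    """Write an LAI stack to CF-style NetCDF (classic format, scipy engine)."""
    path = Path(path)
    n_years, steps = stack.n_years, stack.steps_per_year
    time = np.arange(n_years * steps)
    da = xr.DataArray(
        stack.values.reshape(n_years * steps, *stack.grid.shape),
        dims=("time", "y", "x"),
        coords={"time": time, **_grid_to_coords(stack.grid)},
        name="lai",
        attrs={"units": "m2 m-2", "long_name": "leaf area index"},
    )
    ds = da.to_dataset()
    ds["year"] = ("time", np.repeat(stack.years, steps))
    ds["step"] = ("time", np.tile(np.arange(steps), n_years))
    ds.attrs.update(
        crs=stack.grid.crs,
        nodata=stack.grid.nodata,
        steps_per_year=steps,
    )
    ds.to_netcdf(path, engine="scipy")
    return path


def read_stack(
    paths: str | Path | Sequence[str | Path],
    season_spec: dict | None = None,
) -> LAIStack:
    """Read an LAI stack from one NetCDF file or a list of per-plane files.

    ``season_spec`` maps plane index to (year, step) labels when the files
    themselves carry none: ``{"years": [...], "steps_per_year": k}``.
    Every plane must share one grid; a mismatch raises
    :class:`AlignmentError` naming the offending file, and a missing
    (year, step) plane raises a gap error.
    """
    if isinstance(paths, (str, Path)):
        ds = xr.open_dataset(paths, engine="scipy")
        grid = _grid_from_coords(ds, str(ds.attrs.get("crs", "EPSG:4326")),
                                 float(ds.attrs.get("nodata", -9999.0)))
        steps = int(ds.attrs["steps_per_year"])
        years = np.unique(np.asarray(ds["year"]))
        values = np.asarray(ds["lai"], dtype=float)
        ds.close()
        nodata = grid.nodata
        values = np.where(values == nodata, np.nan, values)
        n_years = values.shape[0] // steps
        if n_years * steps != values.shape[0]:
            raise ValueError("incomplete stack: missing (year, step) planes")
        return LAIStack(grid, years, steps, values.reshape(n_years, steps, *grid.shape))

    paths = [Path(p) for p in paths]
    if season_spec is None:
        raise ValueError("season_spec required for per-plane file lists")
    years = np.asarray(season_spec["years"], dtype=int)
    steps = int(season_spec["steps_per_year"])
    if len(paths) != len(years) * steps:
        raise ValueError(
            f"expected {len(years) * steps} planes "
            f"({len(years)} years x {steps} steps), got {len(paths)}"
        )
    planes, grid = [], None
    for p in paths:
        vals, g, _ = read_map(p)
        if grid is None:
            grid = g
        elif not grid.same_geometry(g):
            raise AlignmentError(f"grid of {p} does not match {paths[0]}")
        planes.append(vals)
    values = np.stack(planes).reshape(len(years), steps, *grid.shape)
    return LAIStack(grid, years, steps, values)


def _grid_from_coords(ds: xr.Dataset, crs: str, nodata: float) -> Grid:
    y = np.asarray(ds["y"])
    x = np.asarray(ds["x"])
    dy = float(abs(y[1] - y[0])) if len(y) > 1 else 1.0
    dx = float(x[1] - x[0]) if len(x) > 1 else 1.0
    return Grid(
        x0=float(x[0]) - dx / 2,
        y0=float(y[0]) + dy / 2,
        dx=dx,
        dy=dy,
        shape=(len(y), len(x)),
        crs=crs,
        nodata=nodata,
    )


# ---------------------------------------------------------------------------
# Grassland mask and resampling
# ---------------------------------------------------------------------------

def build_grassland_mask(
    landcover_stacks: Sequence[FactorLayer | np.ndarray],
    grass_code: int,
    mode: str = "persistence",
) -> np.ndarray:
    """Boolean mask of pixels classified grassland in *every* supplied year.

    Mirrors the persistent-grassland rule: only land whose cover class
    stayed grassland through the whole record enters the analysis.
    """
    if mode != "persistence":
        raise ValueError(f"unknown mode {mode!r}")
    layers = [
        lyr.values if isinstance(lyr, FactorLayer) else np.asarray(lyr)
        for lyr in landcover_stacks
    ]
    if not layers:
        raise ValueError("at least one land-cover year is required")
    shape = layers[0].shape
    codes_present = np.unique(np.concatenate([l.ravel() for l in layers]))
    if grass_code not in codes_present:
        raise ValueError(
            f"class code {grass_code} absent; codes present: {codes_present.tolist()}"
        )
    mask = np.ones(shape, dtype=bool)
    for lyr in layers:
        if lyr.shape != shape:
            raise AlignmentError("land-cover years are on different grids")
        mask &= lyr == grass_code
    return mask


def resample_to(
    layer: FactorLayer,
    target: Grid,
    method: str = "nearest",
    threshold: float = 0.5,
    category: int | None = None,
) -> FactorLayer:
    """Resample a layer onto ``target``.

    Methods
    -------
    nearest
        Valid for both kinds; identity when grids already coincide.
    bilinear
        Continuous layers only.
    majority
        Categorical only; modal code among contributing source pixels.
    fraction_threshold
        Categorical only; output is 1 where the areal fraction of
        ``category`` among contributing source pixels is **>= threshold**,
        else 0.  This is the aggregation rule used for 'grass iff grass
        fraction >= t'.
    """
    src_grid, values = layer.grid, layer.values
    if layer.kind == "categorical" and method == "bilinear":
        raise ValueError("bilinear resampling is invalid for categorical layers")
    if layer.kind == "continuous" and method in ("majority", "fraction_threshold"):
        raise ValueError(f"{method} is invalid for continuous layers")
    if src_grid.crs != target.crs:
        raise AlignmentError(
            f"CRS mismatch: {src_grid.crs} vs {target.crs} (no reprojection support)"
        )

    tx = target.x_centers()
    ty = target.y_centers()

    if method == "nearest":
        cols = np.clip(((tx - src_grid.x0) / src_grid.dx).astype(int), 0, src_grid.ncols - 1)
        rows = np.clip(((src_grid.y0 - ty) / src_grid.dy).astype(int), 0, src_grid.nrows - 1)
        out = values[np.ix_(rows, cols)]
        return FactorLayer(target, out, layer.kind, layer.name)

    if method == "bilinear":
        from scipy.interpolate import RegularGridInterpolator

        interp = RegularGridInterpolator(
            (src_grid.y_centers()[::-1], src_grid.x_centers()),
            np.asarray(values, dtype=float)[::-1, :],
            method="linear",
            bounds_error=False,
            fill_value=None,
        )
        yy, xx = np.meshgrid(ty, tx, indexing="ij")
        out = interp(np.column_stack([yy.ravel(), xx.ravel()])).reshape(target.shape)
        return FactorLayer(target, out, layer.kind, layer.name)

    # block-aggregation methods: assign each source pixel to the target cell
    # containing its center, then reduce per cell
    sy = src_grid.y_centers()
    sx = src_grid.x_centers()
    trow = np.floor((target.y0 - sy) / target.dy).astype(int)
    tcol = np.floor((sx - target.x0) / target.dx).astype(int)
    in_y = (trow >= 0) & (trow < target.nrows)
    in_x = (tcol >= 0) & (tcol < target.ncols)
    rr, cc = np.meshgrid(trow[in_y], tcol[in_x], indexing="ij")
    cells = rr * target.ncols + cc
    src = values[np.ix_(in_y, in_x)]

    if method == "majority":
        out = np.full(target.size, -1, dtype=values.dtype)
        order = np.argsort(cells.ravel(), kind="stable")
        flat_cells = cells.ravel()[order]
        flat_vals = src.ravel()[order]
        starts = np.flatnonzero(np.r_[True, np.diff(flat_cells) != 0])
        for s, e in zip(starts, np.r_[starts[1:], len(flat_cells)]):
            vals, counts = np.unique(flat_vals[s:e], return_counts=True)
            out[flat_cells[s]] = vals[np.argmax(counts)]
        return FactorLayer(target, out.reshape(target.shape), "categorical", layer.name)

    if method == "fraction_threshold":
        if category is None:
            raise ValueError("fraction_threshold requires the category code")
        hits = np.bincount(cells.ravel(), weights=(src == category).ravel(),
                           minlength=target.size)
        tot = np.bincount(cells.ravel(), minlength=target.size)
        with np.errstate(invalid="ignore"):
            frac = np.where(tot > 0, hits / np.maximum(tot, 1), np.nan)
        out = (frac >= threshold).astype(np.int64)
        return FactorLayer(target, out.reshape(target.shape), "categorical", layer.name)

    raise ValueError(f"unknown method {method!r}")


def latitude_layer(grid: Grid) -> FactorLayer:
    """Factor layer of pixel-center latitudes, synthesized from the grid."""
    return FactorLayer(grid, grid.latitudes(), "continuous", "latitude")
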