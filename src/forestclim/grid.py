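"""Georeferenced grids: container, masking, resampling and temporal aggregation.

All raster stages of the pipeline share one currency, :class:`GeoGrid` — a 2-D
field of values on a regular lat/lon grid with a validity mask.  The analysis
grid is 0.05° (~5 km at the equator); rows run south from the northwest corner
and columns run east, so cell ``(i, j)`` has center

    lon = origin_lon + (j + 0.5) * res
    lat = origin_lat - (i + 0.5) * res

where ``(origin_lon, origin_lat)`` is the northwest *corner* of the grid.
Masked cells are excluded from every downstream computation; no operation here
ever invents a value for a masked cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "GeoGrid",
    "QCRule",
    "upscale_mean",
    "resample_bilinear",
    "apply_qc",
    "temporal_average",
    "read_netcdf",
    "write_netcdf",
    "grid_to_table",
]


@dataclass
class GeoGrid:
    """A 2-D georeferenced field with validity mask.

    Parameters
    ----------
    values : ndarray, shape (n_lat, n_lon)
        Cell values; units depend on the variable (% for forest cover and
        albedo, °C for LST, mm/month for ET).
    mask : ndarray of bool, same shape
        True where the cell is valid.
    origin_lon, origin_lat : float
        Degrees of the grid's northwest cell corner.
    res : float
        Cell size in degrees (0.05 on the analysis grid).
    """

    values: np.ndarray
    mask: np.ndarray
    origin_lon: float
    origin_lat: float
    res: float = 0.05

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask must have identical shape")
        if self.values.size == 0:
            raise ValueError("empty grid")
        if self.res <= 0:
            raise ValueError("res must be positive")

    # -- geometry -----------------------------------------------------------
    @property
    def n_lat(self) -> int:
        return self.values.shape[0]

    @property
    def n_lon(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def lon_center(self, j) -> np.ndarray:
        return self.origin_lon + (np.asarray(j) + 0.5) * self.res

    def lat_center(self, i) -> np.ndarray:
        return self.origin_lat - (np.asarray(i) + 0.5) * self.res

    @property
    def lons(self) -> np.ndarray:
        return self.lon_center(np.arange(self.n_lon))

    @property
    def lats(self) -> np.ndarray:
        return self.lat_center(np.arange(self.n_lat))

    def same_geometry(self, other: "GeoGrid", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.res - other.res) < tol
            and abs(self.origin_lon - other.origin_lon) < tol
            and abs(self.origin_lat - other.origin_lat) < tol
        )

    def copy(self) -> "GeoGrid":
        return replace(self, values=self.values.copy(), mask=self.mask.copy())

    @classmethod
    def full_like(cls, other: "GeoGrid", fill: float = np.nan, valid: bool = True) -> "GeoGrid":
        return cls(
            values=np.full(other.shape, fill, dtype=float),
            mask=np.full(other.shape, valid, dtype=bool),
            origin_lon=other.origin_lon,
            origin_lat=other.origin_lat,
            res=other.res,
        )


@dataclass(frozen=True)
class QCRule:
    """Quality-control rule for one climate variable.

    Defaults follow the MODIS product conventions used throughout:
    LST cells are kept only when the estimated emissivity error is ≤ 0.02 and
    the LST error is ≤ 2 K; albedo cells only when flagged 0, 1 or 2 (best,
    good, mixed); coarse ET cells only when all 36 fine subpixels of the
    0.05° cell contained data.
    """

    variable: str  # one of {"LST", "ET", "albedo"}
    max_emissivity_error: float = 0.02
    max_lst_error: float = 2.0
    allowed_flags: frozenset = frozenset({0, 1, 2})
    required_subpixels: int = 36

    def __post_init__(self) -> None:
        if self.variable not in {"LST", "ET", "albedo"}:
            raise ValueError(f"unknown variable {self.variable!r}")


def _check_geometry(a: GeoGrid, b: GeoGrid) -> None:
    if not a.same_geometry(b):
        raise ValueError("grids are not co-registered (geometry mismatch)")


# ---------------------------------------------------------------------------
# resolution changes
# ---------------------------------------------------------------------------

def upscale_mean(fine: GeoGrid, factor: int, *, allow_partial: bool = False) -> GeoGrid:
    """Aggregate a fine grid to a coarser one by block averaging.

    Each coarse cell is the arithmetic mean of the *valid* fine cells in its
    ``factor x factor`` block; a coarse cell with zero valid fine cells is
    masked.  With ``allow_partial`` the trailing partial blocks at the east
    and south edges are aggregated too; otherwise ``factor`` must divide both
    dimensions.
    """
    if factor <= 0 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    nlat, nlon = fine.shape
    if not allow_partial and (nlat % factor or nlon % factor):
        raise ValueError(
            f"factor {factor} does not divide grid shape {fine.shape}; "
            "pass allow_partial=True to aggregate edge blocks"
        )
    out_nlat = -(-nlat // factor) if allow_partial else nlat // factor
    out_nlon = -(-nlon // factor) if allow_partial else nlon // factor
    vals = np.zeros((out_nlat, out_nlon))
    mask = np.zeros((out_nlat, out_nlon), dtype=bool)
    for bi in range(out_nlat):
        for bj in range(out_nlon):
            block_v = fine.values[bi * factor : (bi + 1) * factor, bj * factor : (bj + 1) * factor]
            block_m = fine.mask[bi * factor : (bi + 1) * factor, bj * factor : (bj + 1) * factor]
            if block_m.any():
                vals[bi, bj] = block_v[block_m].mean()
                mask[bi, bj] = True
            else:
                vals[bi, bj] = np.nan
    return GeoGrid(vals, mask, fine.origin_lon, fine.origin_lat, fine.res * factor)


def resample_bilinear(src: GeoGrid, target: GeoGrid) -> GeoGrid:
    """Resample ``src`` onto the geometry of ``target`` by bilinear interpolation.

    Each target cell center takes the bilinear interpolation of the four
    surrounding source cell centers.  Masking is conservative: a target cell
    is masked if any of its four surrounding source cells is masked, or if
    its center falls outside the hull of source cell centers.
    """
    if src.n_lat < 2 or src.n_lon < 2:
        raise ValueError("source grid must have at least 2 cells along each axis")
    # interpolate on (lat, lon) center coordinates; lats descend, so flip rows
    src_lats = src.lats[::-1]
    src_lons = src.lons
    vals = np.where(src.mask, src.values, 0.0)[::-1, :]
    valid = src.mask.astype(float)[::-1, :]
    interp_v = RegularGridInterpolator(
        (src_lats, src_lons), vals, method="linear", bounds_error=False, fill_value=np.nan
    )
    interp_m = RegularGridInterpolator(
        (src_lats, src_lons), valid, method="linear", bounds_error=False, fill_value=0.0
    )
    tlat, tlon = np.meshgrid(target.lats, target.lons, indexing="ij")
    pts = np.column_stack([tlat.ravel(), tlon.ravel()])
    out = interp_v(pts).reshape(target.shape)
    # all four neighbors valid <=> interpolated validity is exactly 1
    mfrac = interp_m(pts).reshape(target.shape)
    mask = (mfrac > 1.0 - 1e-9) & np.isfinite(out)
    out = np.where(mask, out, np.nan)
    return GeoGrid(out, mask, target.origin_lon, target.origin_lat, target.res)


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def apply_qc(values: GeoGrid, qc_layers: Mapping[str, GeoGrid], rule: QCRule) -> GeoGrid:
    """Mask cells failing a QC rule; values are never altered.

    ``qc_layers`` supplies co-registered companion layers keyed by name:
    LST expects ``emissivity_error`` and ``lst_error``; albedo expects
    ``flag``; ET expects ``valid_subpixels`` (count of fine pixels with data
    in each coarse cell).
    """
    required = {
        "LST": ("emissivity_error", "lst_error"),
        "albedo": ("flag",),
        "ET": ("valid_subpixels",),
    }[rule.variable]
    for name in required:
        if name not in qc_layers:
            raise ValueError(f"missing QC layer {name!r} for variable {rule.variable}")
        _check_geometry(values, qc_layers[name])

    ok = np.ones(values.shape, dtype=bool)
    if rule.variable == "LST":
        ok &= qc_layers["emissivity_error"].values <= rule.max_emissivity_error
        ok &= qc_layers["lst_error"].values <= rule.max_lst_error
    elif rule.variable == "albedo":
        flags = qc_layers["flag"].values
        ok &= np.isin(flags, list(rule.allowed_flags))
    else:  # ET
        ok &= qc_layers["valid_subpixels"].values >= rule.required_subpixels
    out = values.copy()
    out.mask &= ok
    out.values = np.where(out.mask, out.values, np.nan)
    return out


# ---------------------------------------------------------------------------
# temporal aggregation
# ---------------------------------------------------------------------------

def _mean_grids(grids: Sequence[GeoGrid], require_all: bool) -> GeoGrid:
    """Per-cell arithmetic mean of a stack of co-registered grids."""
    if not grids:
        raise ValueError("empty stack")
    first = grids[0]
    for g in grids[1:]:
        _check_geometry(first, g)
    stack = np.stack([np.where(g.mask, g.values, np.nan) for g in grids])
    valid = np.stack([g.mask for g in grids])
    count = valid.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nansum(stack, axis=0) / np.where(count > 0, count, np.nan)
    mask = (count == len(grids)) if require_all else (count > 0)
    mean = np.where(mask, mean, np.nan)
    return GeoGrid(mean, mask, first.origin_lon, first.origin_lat, first.res)


def temporal_average(monthly_stack, mode: str, *, require_all: bool = False) -> GeoGrid:
    """Hierarchical temporal means yielding one annual grid.

    ``mode`` selects the aggregation path and the expected stack layout:

    ``day_night_then_annual``
        ``[(day, night), ...]`` one tuple per month: day and night are
        averaged (unweighted two-term mean) within each month, then across
        months.
    ``eightday_to_monthly_to_annual``
        ``[(month_label, grid), ...]`` 8-day composites: composites are
        averaged within each month label, then the monthly means are
        averaged.  With unequal composite counts this differs from pooling
        all composites.
    ``monthly_to_annual``
        ``[grid, ...]`` plain monthly grids averaged directly.

    With the default any-valid policy a cell contributes whenever at least one
    member of an intermediate mean is valid, and the annual value requires at
    least one valid month; ``require_all`` demands every member instead.
    """
    if mode == "monthly_to_annual":
        return _mean_grids(list(monthly_stack), require_all)
    if mode == "day_night_then_annual":
        monthly = [_mean_grids([d, n], require_all) for d, n in monthly_stack]
        return _mean_grids(monthly, require_all)
    if mode == "eightday_to_monthly_to_annual":
        by_month: dict = {}
        for label, g in monthly_stack:
            by_month.setdefault(label, []).append(g)
        monthly = [_mean_grids(gs, require_all) for _, gs in sorted(by_month.items())]
        return _mean_grids(monthly, require_all)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_netcdf(grids: Mapping[str, GeoGrid], path) -> None:
    """Write named grids to a NetCDF3 file (scipy backend, portable)."""
    first = next(iter(grids.values()))
    data = {}
    for name, g in grids.items():
        _check_geometry(first, g)
        data[name] = xr.DataArray(
            np.where(g.mask, g.values, np.nan),
            dims=("lat", "lon"),
            coords={"lat": g.lats, "lon": g.lons},
        )
    ds = xr.Dataset(data, attrs={"res": first.res})
    ds.to_netcdf(path, engine="scipy")


def read_netcdf(path, variables: Iterable[str] | None = None) -> dict[str, GeoGrid]:
    """Read named grids back from a NetCDF file written by :func:`write_netcdf`."""
    with xr.open_dataset(path, engine="scipy") as ds:
        names = list(variables) if variables is not None else list(ds.data_vars)
        out = {}
        for name in names:
            da = ds[name]
            lats = np.asarray(da["lat"])
            lons = np.asarray(da["lon"])
            res = float(ds.attrs.get("res", abs(lats[1] - lats[0]) if len(lats) > 1 else 0.05))
            vals = np.asarray(da, dtype=float)
            if len(lats) > 1 and lats[1] > lats[0]:  # ensure rows run south
                vals = vals[::-1, :]
                lats = lats[::-1]
            mask = np.isfinite(vals)
            out[name] = GeoGrid(
                values=vals,
                mask=mask,
                origin_lon=float(lons[0]) - 0.5 * res,
                origin_lat=float(lats[0]) + 0.5 * res,
                res=res,
            )
    return out


def grid_to_table(grid: GeoGrid) -> pd.DataFrame:
    """Export a grid's valid cells as (lon, lat, value) triples."""
    ii, jj = np.nonzero(grid.mask)
    return pd.DataFrame(
        {
            "lon": grid.lon_center(jj),
            "lat": grid.lat_center(ii),
            "value": grid.values[ii, jj],
        }
    )
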