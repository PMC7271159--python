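"""Gridded flux/driver containers, netCDF I/O, regridding and global integrals.

All fields live on rectilinear lat/lon grids (cell centres plus edge arrays,
latitudes ordered south to north, longitudes in [-180, 180)).  The canonical
internal unit for gross primary productivity (GPP) is g C m-2 month-1 on a
fixed 365-day (no-leap) calendar; file readers convert at the boundary.
"""
from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import xarray as xr
import yaml

EARTH_RADIUS_M = 6_371_000.0
#: no-leap calendar month lengths, days
DAYS_IN_MONTH = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
SECONDS_IN_MONTH = DAYS_IN_MONTH * 86400.0

GPP_VAR_NAMES = ("GPP", "gpp", "gpp_flux")
_KG_S_UNITS = {"kg C m-2 s-1", "kgC m-2 s-1", "kg m-2 s-1", "kg C m⁻² s⁻¹"}
_G_MONTH_UNITS = {"g C m-2 month-1", "gC m-2 month-1", "g m-2 month-1",
                  "g C m⁻² month⁻¹"}


# ---------------------------------------------------------------------------
# grid specification and land mask
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Rectilinear grid defined by strictly monotone cell-edge arrays."""

    lat_edges: np.ndarray
    lon_edges: np.ndarray

    def __post_init__(self):
        lat = np.asarray(self.lat_edges, dtype=float)
        lon = np.asarray(self.lon_edges, dtype=float)
        object.__setattr__(self, "lat_edges", lat)
        object.__setattr__(self, "lon_edges", lon)
        if lat.ndim != 1 or lon.ndim != 1 or lat.size < 2 or lon.size < 2:
            raise ValueError("edge arrays must be 1-D with at least two edges")
        if not (np.all(np.diff(lat) > 0) and np.all(np.diff(lon) > 0)):
            raise ValueError("grid edges must be strictly monotone increasing")
        if lat.min() < -90 - 1e-9 or lat.max() > 90 + 1e-9:
            raise ValueError("latitude edges must lie within [-90, 90]")

    @classmethod
    def regular(cls, n_lat: int, n_lon: int,
                lat_range=(-90.0, 90.0), lon_range=(-180.0, 180.0)) -> "GridSpec":
        return cls(np.linspace(*lat_range, n_lat + 1),
                   np.linspace(*lon_range, n_lon + 1))

    @property
    def lat(self) -> np.ndarray:
        return 0.5 * (self.lat_edges[:-1] + self.lat_edges[1:])

    @property
    def lon(self) -> np.ndarray:
        return 0.5 * (self.lon_edges[:-1] + self.lon_edges[1:])

    @property
    def shape(self) -> tuple[int, int]:
        return self.lat.size, self.lon.size

    @property
    def resolution(self) -> float:
        return float(np.mean(np.diff(self.lat_edges)))

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"lat_edges": self.lat_edges.tolist(),
                            "lon_edges": self.lon_edges.tolist()}, fh)

    @classmethod
    def from_yaml(cls, path: str) -> "GridSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(np.asarray(d["lat_edges"]), np.asarray(d["lon_edges"]))


@dataclass
class LandMask:
    """Per-cell surface classification: exactly one of vegetated/barren/water."""

    vegetated: np.ndarray
    barren: np.ndarray
    water: np.ndarray

    def __post_init__(self):
        v, b, w = (np.asarray(a, dtype=bool) for a in
                   (self.vegetated, self.barren, self.water))
        if not (v.shape == b.shape == w.shape):
            raise ValueError("mask components must share one shape")
        if not np.all(v.astype(int) + b.astype(int) + w.astype(int) == 1):
            raise ValueError("each cell must be exactly one of "
                             "vegetated/barren/water")
        self.vegetated, self.barren, self.water = v, b, w

    @property
    def shape(self):
        return self.vegetated.shape

    def to_yaml(self, path: str) -> None:
        code = np.where(self.vegetated, 1, np.where(self.barren, 2, 0))
        with open(path, "w") as fh:
            yaml.safe_dump({"legend": {0: "water", 1: "vegetated", 2: "barren"},
                            "cells": code.astype(int).tolist()}, fh)

    @classmethod
    def from_yaml(cls, path: str) -> "LandMask":
        with open(path) as fh:
            code = np.asarray(yaml.safe_load(fh)["cells"])
        return cls(code == 1, code == 2, code == 0)


# ---------------------------------------------------------------------------
# time axis helpers (no-leap monthly calendar)
# ---------------------------------------------------------------------------

def monthly_coords(year_start: int, n_years: int) -> dict:
    """Integer time index with year/month auxiliary coordinates."""
    n = n_years * 12
    t = np.arange(n)
    return {"time": t,
            "year": ("time", year_start + t // 12),
            "month": ("time", t % 12 + 1)}


def _check_monthly(year: np.ndarray, month: np.ndarray) -> None:
    idx = year.astype(int) * 12 + (month.astype(int) - 1)
    if idx.size % 12 != 0:
        raise ValueError("time axis length must be divisible by 12")
    if not np.all(np.diff(idx) == 1):
        raise ValueError("time axis must be contiguous monthly")


# ---------------------------------------------------------------------------
# field containers
# ---------------------------------------------------------------------------

@dataclass
class FluxField:
    """One model x one experiment of monthly GPP, g C m-2 month-1."""

    data: xr.DataArray            # dims (time, lat, lon)
    model_id: str = ""
    experiment_id: str = ""

    def __post_init__(self):
        if self.data.dims != ("time", "lat", "lon"):
            raise ValueError("FluxField data must have dims (time, lat, lon)")
        _check_monthly(self.data["year"].values, self.data["month"].values)
        vals = self.data.values
        neg = vals < 0
        if neg.any():
            if vals.min() < -1e-9:
                raise ValueError(
                    f"negative GPP below tolerance: min={vals.min():g}")
            vals[neg] = 0.0

    @property
    def values(self) -> np.ndarray:
        return self.data.values

    @property
    def years(self) -> np.ndarray:
        return np.unique(self.data["year"].values)

    def annual(self) -> xr.DataArray:
        """Annual totals, g C m-2 a-1, dims (year, lat, lon)."""
        return self.data.groupby("year").sum("time")


@dataclass
class DriverFields:
    """Co-registered monthly climate forcing: tas [K], pr [mm/month],
    rsds [W m-2]."""

    tas: xr.DataArray
    pr: xr.DataArray
    rsds: xr.DataArray

    def __post_init__(self):
        for name, da in (("tas", self.tas), ("pr", self.pr),
                         ("rsds", self.rsds)):
            if da.dims != ("time", "lat", "lon"):
                raise ValueError(f"{name} must have dims (time, lat, lon)")
            if da.shape != self.tas.shape:
                raise ValueError("driver fields must share one shape")
        t = self.tas.values
        if t.min() < 150 or t.max() > 350:
            raise ValueError("tas outside physical range [150, 350] K")
        if self.pr.values.min() < 0 or self.rsds.values.min() < 0:
            raise ValueError("pr and rsds must be non-negative")

    @property
    def shape(self):
        return self.tas.shape


def make_data_array(values: np.ndarray, grid: GridSpec,
                    year_start: int) -> xr.DataArray:
    """Wrap a (time, lat, lon) array on `grid` with monthly coordinates."""
    n_years = values.shape[0] // 12
    coords = monthly_coords(year_start, n_years)
    coords["lat"] = grid.lat
    coords["lon"] = grid.lon
    return xr.DataArray(values, dims=("time", "lat", "lon"), coords=coords)


# ---------------------------------------------------------------------------
# area weights and global integration
# ---------------------------------------------------------------------------

def area_weights(grid: GridSpec) -> np.ndarray:
    """Spherical cell areas, m^2: A = R^2 * dlon * (sin(lat2) - sin(lat1))."""
    lat = np.radians(grid.lat_edges)
    lon = np.radians(grid.lon_edges)
    band = EARTH_RADIUS_M ** 2 * (np.sin(lat[1:]) - np.sin(lat[:-1]))
    return np.outer(band, np.diff(lon))


def global_series(da: xr.DataArray, weights: np.ndarray,
                  vegetated: np.ndarray) -> xr.DataArray:
    """Area-integrate any monthly per-cell flux (g C m-2 month-1) over
    vegetated cells into an annual series in Pg C a-1.  Accepts signed
    fields (e.g. factor effects)."""
    w = np.where(vegetated, weights, 0.0)
    annual = da.groupby("year").sum("time")          # g C m-2 a-1
    series = (annual * xr.DataArray(w, dims=("lat", "lon"))).sum(("lat", "lon"))
    return series * 1e-15


def global_integral(flux: FluxField, weights: np.ndarray,
                    mask: LandMask) -> xr.DataArray:
    """Annual global GPP over vegetated cells, Pg C a-1."""
    if not mask.vegetated.any():
        raise ValueError("no vegetated cells in mask")
    return global_series(flux.data, weights, mask.vegetated)


# ---------------------------------------------------------------------------
# conservative regridding
# ---------------------------------------------------------------------------

def _overlap(src_edges: np.ndarray, tgt_edges: np.ndarray) -> np.ndarray:
    """(n_tgt, n_src) interval-overlap lengths between two edge arrays."""
    lo = np.maximum(tgt_edges[:-1, None], src_edges[None, :-1])
    hi = np.minimum(tgt_edges[1:, None], src_edges[None, 1:])
    return np.clip(hi - lo, 0.0, None)


def regrid(flux: FluxField, target: GridSpec, source: GridSpec) -> FluxField:
    """First-order conservative (area-weighted) remap onto `target`.

    Overlap areas are exact for rectilinear grids: the sine of latitude is
    the area-true coordinate, so latitude overlaps are computed in sin(lat).
    Preserves the global area-weighted integral when the target covers the
    source domain.
    """
    w_lat = _overlap(np.sin(np.radians(source.lat_edges)),
                     np.sin(np.radians(target.lat_edges)))
    w_lon = _overlap(source.lon_edges, target.lon_edges)
    denom = w_lat.sum(axis=1, keepdims=True) @ w_lon.sum(axis=1, keepdims=True).T
    if not np.all(denom > 0):
        raise ValueError("target grid does not overlap the source grid")
    num = np.einsum("ai,tij,bj->tab", w_lat, flux.values, w_lon)
    out = num / denom[None, :, :]
    da = make_data_array(out, target, int(flux.data["year"].values[0]))
    return FluxField(da, model_id=flux.model_id,
                     experiment_id=flux.experiment_id)


# ---------------------------------------------------------------------------
# netCDF I/O
# ---------------------------------------------------------------------------

def write_flux(flux: FluxField, path: str) -> None:
    ds = xr.Dataset({"GPP": flux.data})
    ds["GPP"].attrs["units"] = "g C m-2 month-1"
    ds.attrs["model_id"] = flux.model_id
    ds.attrs["experiment_id"] = flux.experiment_id
    ds.to_netcdf(path)


def read_flux(path: str, canonical_units: bool = True) -> FluxField:
    """Read a CF-style netCDF GPP file; convert to g C m-2 month-1.

    Units must be declared on the GPP variable (kg C m-2 s-1 or
    g C m-2 month-1).  Rate units are converted with per-month day counts
    of the no-leap calendar.  model_id/experiment_id are taken from global
    attributes, falling back to a `<model>_<experiment>.nc` filename
    convention.
    """
    with xr.open_dataset(path) as ds:
        ds = ds.load()
    name = next((v for v in GPP_VAR_NAMES if v in ds), None)
    if name is None:
        raise ValueError(f"no recognized GPP variable in {path}; "
                         f"expected one of {GPP_VAR_NAMES}")
    da = ds[name]
    units = da.attrs.get("units")
    if units is None:
        raise ValueError(f"variable '{name}' has no units attribute")
    if "year" in ds:
        year = np.asarray(ds["year"].values)
        month = np.asarray(ds["month"].values)
    else:  # CF datetime axis
        tt = xr.decode_cf(ds)[name]["time"]
        year = tt.dt.year.values
        month = tt.dt.month.values
    _check_monthly(year, month)
    vals = np.asarray(da.values, dtype=float)
    if canonical_units:
        if units in _KG_S_UNITS:
            vals = vals * 1000.0 * SECONDS_IN_MONTH[month - 1][:, None, None]
        elif units in _G_MONTH_UNITS:
            pass
        else:
            raise ValueError(f"unsupported GPP units '{units}' on '{name}'")
    out = xr.DataArray(
        vals, dims=("time", "lat", "lon"),
        coords={"time": np.arange(vals.shape[0]),
                "year": ("time", year), "month": ("time", month),
                "lat": np.asarray(ds["lat"].values),
                "lon": np.asarray(ds["lon"].values)})
    stem = os.path.basename(path).rsplit(".", 1)[0]
    parts = stem.split("_")
    model = ds.attrs.get("model_id") or (parts[0] if parts else "")
    exper = ds.attrs.get("experiment_id") or \
        (parts[1] if len(parts) > 1 else "")
    return FluxField(out, model_id=str(model), experiment_id=str(exper))


def write_drivers(drv: DriverFields, path: str) -> None:
    ds = xr.Dataset({"tas": drv.tas, "pr": drv.pr, "rsds": drv.rsds})
    ds["tas"].attrs["units"] = "K"
    ds["pr"].attrs["units"] = "mm month-1"
    ds["rsds"].attrs["units"] = "W m-2"
    ds.to_netcdf(path)


def read_drivers(path: str) -> DriverFields:
    with xr.open_dataset(path) as ds:
        ds = ds.load()
    coords = {"time": ds["time"].values,
              "year": ("time", ds["year"].values),
              "month": ("time", ds["month"].values),
              "lat": ds["lat"].values, "lon": ds["lon"].values}

    def _wrap(name):
        return xr.DataArray(np.asarray(ds[name].values, dtype=float),
                            dims=("time", "lat", "lon"), coords=coords)

    return DriverFields(_wrap("tas"), _wrap("pr"), _wrap("rsds"))
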