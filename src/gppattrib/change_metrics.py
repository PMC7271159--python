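"""Long-term GPP change diagnostics.

Per-cell diagnostics comparing a late period (default 1981-2010) with an
early period (default 1901-1930):

* change in mean annual GPP (g C m-2 a-1),
* change in mean seasonal amplitude (max - min of the 12 monthly values,
  computed per year and then period-averaged),
* interannual-variability (IAV) ratio: SD of deseasonalized monthly
  anomalies in the late period over the early period — a volatility index
  (2 means year-to-year variability doubled),
* an ensemble bootstrap significance mask for the mean change.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import xarray as xr

from .grid_io import FluxField, LandMask

DEFAULT_EARLY = (1901, 1930)
DEFAULT_LATE = (1981, 2010)


def _check_period(field: FluxField, period) -> None:
    years = field.years
    if period[0] < years.min() or period[1] > years.max():
        raise ValueError(f"period {period} not covered by time axis "
                         f"[{years.min()}, {years.max()}]")


def _period_sel(da: xr.DataArray, period) -> xr.DataArray:
    yr = da["year"] if "year" in da.coords else da["time"]
    return da.sel(time=(yr >= period[0]) & (yr <= period[1])) \
        if "time" in da.dims else da.sel(year=slice(period[0], period[1]))


def delta_mean(field: FluxField, early=DEFAULT_EARLY,
               late=DEFAULT_LATE) -> xr.DataArray:
    """Late minus early mean annual GPP, g C m-2 a-1 per cell."""
    _check_period(field, early)
    _check_period(field, late)
    annual = field.annual()
    return (annual.sel(year=slice(*late)).mean("year") -
            annual.sel(year=slice(*early)).mean("year"))


def _yearly_amplitude(field: FluxField) -> xr.DataArray:
    grp = field.data.groupby("year")
    return grp.max("time") - grp.min("time")


def delta_amplitude(field: FluxField, early=DEFAULT_EARLY,
                    late=DEFAULT_LATE) -> xr.DataArray:
    """Late minus early mean seasonal amplitude, g C m-2 month-1 per cell."""
    _check_period(field, early)
    _check_period(field, late)
    amp = _yearly_amplitude(field)
    return (amp.sel(year=slice(*late)).mean("year") -
            amp.sel(year=slice(*early)).mean("year"))


def deseasonalize(field: FluxField, period) -> xr.DataArray:
    """Monthly anomalies within `period` relative to that period's own
    monthly climatology (so each calendar month has exactly zero mean)."""
    da = field.data
    sel = da.sel(time=(da["year"] >= period[0]) & (da["year"] <= period[1]))
    return sel.groupby("month") - sel.groupby("month").mean("time")


def iav_ratio(field: FluxField, early=DEFAULT_EARLY,
              late=DEFAULT_LATE) -> xr.DataArray:
    """SD(deseasonalized late) / SD(deseasonalized early) per cell.

    Cells with zero early-period anomaly variance are returned as NaN
    (undefined), not zero.
    """
    _check_period(field, early)
    _check_period(field, late)
    sd_early = deseasonalize(field, early).std("time", ddof=0)
    sd_late = deseasonalize(field, late).std("time", ddof=0)
    zero = sd_early.values == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} cells have zero early-period "
                      "variance; IAV ratio undefined there")
    return sd_late / sd_early.where(sd_early > 0)


def significance_mask(deltas: np.ndarray, replicates: int = 1000,
                      level: float = 90.0, seed: int = 0) -> np.ndarray:
    """Cells where the bootstrap CI of the ensemble-mean change excludes 0.

    `deltas` has shape (n_models, ...); models are resampled with
    replacement.  The interval is studentized (bootstrap-t): with ~10
    ensemble members the plain percentile interval is anticonservative,
    while the bootstrap-t interval holds its nominal level.  With fewer
    than 3 members no cell is significant.
    """
    deltas = np.asarray(deltas, dtype=float)
    n = deltas.shape[0]
    if n < 3:
        warnings.warn("fewer than 3 ensemble members; "
                      "no cell flagged significant")
        return np.zeros(deltas.shape[1:], dtype=bool)
    rng = np.random.default_rng(seed)
    flat = deltas.reshape(n, -1)
    mean = flat.mean(axis=0)
    se = flat.std(axis=0, ddof=1) / np.sqrt(n)
    idx = rng.integers(0, n, size=(replicates, n))
    res = flat[idx]                                   # (reps, n, cells)
    se_rep = res.std(axis=1, ddof=1) / np.sqrt(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (res.mean(axis=1) - mean) / se_rep
    t = np.where(np.isfinite(t), t, 0.0)              # degenerate resamples
    alpha = (100.0 - level) / 2.0
    lo = mean - np.percentile(t, 100.0 - alpha, axis=0) * se
    hi = mean - np.percentile(t, alpha, axis=0) * se
    sig = (lo > 0) | (hi < 0)
    sig[se == 0] = mean[se == 0] != 0                 # exact-consensus cells
    return sig.reshape(deltas.shape[1:])


def areal_fraction(mask2d: np.ndarray, weights: np.ndarray,
                   land: LandMask) -> float:
    """Area-weighted percent of the vegetated surface where mask2d is True."""
    veg_area = weights[land.vegetated].sum()
    return 100.0 * weights[mask2d & land.vegetated].sum() / veg_area


@dataclass
class ChangeMaps:
    """Ensemble change diagnostics on a common grid."""

    delta_mean: xr.DataArray        # g C m-2 a-1
    delta_amplitude: xr.DataArray   # g C m-2 month-1
    iav_ratio: xr.DataArray         # dimensionless, NaN where undefined
    significant: np.ndarray         # bool per cell
    period_early: tuple
    period_late: tuple
    n_models: int

    def to_netcdf(self, path: str) -> None:
        ds = xr.Dataset({"delta_mean": self.delta_mean,
                         "delta_amplitude": self.delta_amplitude,
                         "iav_ratio": self.iav_ratio,
                         "significant": (("lat", "lon"),
                                         self.significant.astype("i1"))})
        ds.attrs["period_early"] = list(self.period_early)
        ds.attrs["period_late"] = list(self.period_late)
        ds.attrs["n_models"] = self.n_models
        ds.to_netcdf(path)


def compute_change_maps(fields: list[FluxField], land: LandMask,
                        early=DEFAULT_EARLY, late=DEFAULT_LATE,
                        replicates: int = 1000, seed: int = 0) -> ChangeMaps:
    """Consensus (unweighted multi-model mean) change maps plus the
    bootstrap significance mask; one field per model."""
    ids = [f.model_id for f in fields]
    if len(set(ids)) != len(ids):
        raise ValueError("one realization per model required")
    dmeans = np.stack([delta_mean(f, early, late).values for f in fields])
    damps = np.stack([delta_amplitude(f, early, late).values for f in fields])
    ratios = np.stack([iav_ratio(f, early, late).values for f in fields])
    template = delta_mean(fields[0], early, late)
    sig = significance_mask(dmeans, replicates=replicates, seed=seed)
    sig &= land.vegetated
    wrap = lambda a: xr.DataArray(a, dims=("lat", "lon"),
                                  coords=template.coords)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_ratio = np.nanmean(ratios, axis=0)
    return ChangeMaps(delta_mean=wrap(dmeans.mean(axis=0)),
                      delta_amplitude=wrap(damps.mean(axis=0)),
                      iav_ratio=wrap(mean_ratio),
                      significant=sig, period_early=tuple(early),
                      period_late=tuple(late), n_models=len(fields))
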