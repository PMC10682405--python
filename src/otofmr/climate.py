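"""Bias-corrected SST ensembles and threshold-crossing-year maps.

Operates on gridded sea-surface-temperature cubes — xarray DataArrays with
dims ``(time, lat, lon)`` for monthly data or ``(year, lat, lon)`` for
seasonal means.  The processing chain mirrors the standard anomaly method
for multi-model projections:

1. :func:`seasonal_mean` — per-cell seasonal (e.g. July–September) means.
2. :func:`bias_correct` — remove each model's reference-year state and add
   the observed reference-year field, so the corrected series is anchored
   to observations while retaining the model's projected change.
3. :func:`ensemble_mean` — cell-wise multi-model mean and sd, with
   per-model regional z-scores for outlier screening (reported, never
   auto-excluded).
4. :func:`crossing_year` — per-cell first year whose seasonal mean reaches
   a physiological threshold (here 28 °C for juvenile bluefin tuna);
   absent (NaN) where the threshold is never met in the window.
5. :func:`regional_trajectory` — cosine-latitude-weighted regional mean
   trajectories with inter-model spread.

No regridding is performed: all cubes must share a grid.  NetCDF I/O uses
xarray's scipy backend (classic netCDF-3); Kelvin inputs are converted to
Celsius on read when units say so.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import xarray as xr

JAS = (7, 8, 9)


def _require_dims(da: xr.DataArray, dims: tuple[str, ...]) -> None:
    missing = [d for d in dims if d not in da.dims]
    if missing:
        raise ValueError(f"cube is missing dims {missing}; has {tuple(da.dims)}")


def _check_aligned(a: xr.DataArray, b: xr.DataArray, what: str = "cubes") -> None:
    for dim in ("lat", "lon"):
        if not np.array_equal(a[dim].values, b[dim].values):
            raise ValueError(f"{what} are on different grids (mismatched {dim})")


def seasonal_mean(cube: xr.DataArray, months: Sequence[int] = JAS) -> xr.DataArray:
    """Per-cell, per-year mean over a set of calendar months.

    ``cube`` must be monthly with a datetime-like ``time`` coordinate.
    Returns a cube with a ``year`` dimension.  All requested months must be
    present in every year used.
    """
    _require_dims(cube, ("time", "lat", "lon"))
    months = tuple(sorted(set(int(m) for m in months)))
    have = set(np.unique(cube["time"].dt.month.values))
    missing = [m for m in months if m not in have]
    if missing:
        raise ValueError(f"requested months {missing} absent from cube")
    sel = cube.sel(time=cube["time"].dt.month.isin(months))
    out = sel.groupby(sel["time"].dt.year).mean("time")
    out = out.rename({"year": "year"})
    out.attrs.update(cube.attrs)
    out.attrs["season_months"] = months
    return out


def to_celsius(cube: xr.DataArray) -> xr.DataArray:
    """Convert a cube with Kelvin units to °C; °C cubes pass through."""
    units = str(cube.attrs.get("units", "")).lower()
    if units in {"k", "kelvin"}:
        out = cube - 273.15
        out.attrs.update(cube.attrs)
        out.attrs["units"] = "degC"
        return out
    return cube


def bias_correct(cube: xr.DataArray, obs_ref: xr.DataArray, ref_year: int = 2016) -> xr.DataArray:
    """Anchor a model's seasonal series to observations at a reference year.

    ``corrected(cell, y) = (cube(cell, y) - cube(cell, ref_year)) +
    obs_ref(cell, ref_year)``.  The corrected series equals the observation
    exactly at ``ref_year`` and retains the model's projected anomalies.
    """
    _require_dims(cube, ("year", "lat", "lon"))
    _check_aligned(cube, obs_ref, "model and observation cubes")
    if ref_year not in cube["year"].values:
        raise ValueError(f"reference year {ref_year} absent from model cube")
    obs_years = obs_ref["year"].values if "year" in obs_ref.dims else None
    if obs_years is not None:
        if ref_year not in obs_years:
            raise ValueError(f"reference year {ref_year} absent from observed cube")
        obs_field = obs_ref.sel(year=ref_year)
    else:
        obs_field = obs_ref
    anom = cube - cube.sel(year=ref_year)
    out = anom + obs_field
    out.attrs.update(cube.attrs)
    out.attrs["bias_corrected_to"] = int(ref_year)
    return out.transpose(*cube.dims)


def ensemble_mean(cubes: Iterable[xr.DataArray]):
    """Multi-model mean and spread, with per-model outlier z-scores.

    Returns ``(mean_cube, sd_cube, zscores)`` where ``zscores`` is a Series
    (model_id -> z) of each model's overall regional-mean SST standardised
    across models.  |z| > 2 flags a candidate outlier; nothing is excluded
    automatically.
    """
    cubes = list(cubes)
    if len(cubes) < 2:
        raise ValueError("an ensemble needs at least 2 model cubes")
    first = cubes[0]
    for c in cubes[1:]:
        _check_aligned(first, c)
        tdim = "year" if "year" in first.dims else "time"
        if not np.array_equal(first[tdim].values, c[tdim].values):
            raise ValueError("ensemble members cover different years")
    model_ids = [str(c.attrs.get("model_id", f"model{i}")) for i, c in enumerate(cubes)]
    stacked = xr.concat(cubes, dim=pd.Index(model_ids, name="model"))
    mean = stacked.mean("model")
    sd = stacked.std("model", ddof=1)
    regional = stacked.mean([d for d in stacked.dims if d != "model"])
    mu, sigma = float(regional.mean()), float(regional.std(ddof=1))
    if sigma == 0:
        z = xr.zeros_like(regional)
    else:
        z = (regional - mu) / sigma
    zscores = pd.Series(z.values, index=model_ids, name="zscore")
    mean.attrs["n_models"] = len(cubes)
    return mean, sd, zscores


def crossing_year(
    cube: xr.DataArray,
    threshold: float = 28.0,
    window: tuple[int, int] | None = None,
) -> xr.DataArray:
    """Per-cell first year whose seasonal mean reaches ``threshold``.

    A cell crosses in the first year ``y`` within ``window`` with
    ``value >= threshold`` (single-year criterion, no persistence
    requirement).  Cells never reaching the threshold are NaN — the map's
    "will not exceed within the timeframe" state.
    """
    _require_dims(cube, ("year", "lat", "lon"))
    years = cube["year"].values
    if window is not None:
        y0, y1 = window
        mask_years = (years >= y0) & (years <= y1)
        if not mask_years.any():
            raise ValueError(f"window {window} contains none of the cube's years")
        cube = cube.sel(year=years[mask_years])
        years = cube["year"].values
    exceed = (cube >= threshold).values  # (year, lat, lon)
    order = np.argsort(years)
    exceed = exceed[order]
    years_sorted = years[order]
    any_cross = exceed.any(axis=0)
    first_idx = exceed.argmax(axis=0)
    first = np.where(any_cross, years_sorted[first_idx], np.nan)
    out = xr.DataArray(
        first.astype(float),
        coords={"lat": cube["lat"], "lon": cube["lon"]},
        dims=("lat", "lon"),
        name="first_year",
        attrs={"threshold": float(threshold), "season_months": cube.attrs.get("season_months")},
    )
    return out


def regional_trajectory(
    cubes: Iterable[xr.DataArray] | xr.DataArray,
    region_mask: xr.DataArray | None = None,
    area_weights: xr.DataArray | None = None,
) -> pd.DataFrame:
    """Cosine-latitude-weighted regional mean SST per year, with model spread.

    ``region_mask`` is a boolean (lat, lon) DataArray selecting the region
    (whole domain when omitted); ``area_weights`` overrides the default
    cos(latitude) weights.  Returns a DataFrame indexed by year with
    columns ``mean`` and ``sd`` (sd 0 for a single cube).
    """
    if isinstance(cubes, xr.DataArray):
        cubes = [cubes]
    cubes = list(cubes)
    if not cubes:
        raise ValueError("no cubes supplied")
    first = cubes[0]
    _require_dims(first, ("year", "lat", "lon"))
    if region_mask is None:
        region_mask = xr.ones_like(first.isel(year=0), dtype=bool)
    if not bool(region_mask.any()):
        raise ValueError("region mask selects no cells")
    if area_weights is None:
        area_weights = np.cos(np.deg2rad(first["lat"])).broadcast_like(region_mask)
    weights = area_weights.where(region_mask, 0.0)

    per_model = []
    for c in cubes:
        _check_aligned(first, c)
        wmean = c.weighted(weights).mean(("lat", "lon"))
        per_model.append(wmean.values)
    arr = np.asarray(per_model)  # (model, year)
    years = first["year"].values
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else np.zeros_like(mean)
    return pd.DataFrame({"mean": mean, "sd": sd}, index=pd.Index(years, name="year"))


def make_synthetic_sst(
    model_id: str = "model0",
    years: Sequence[int] = range(2016, 2101),
    lat: Sequence[float] = (30.0, 35.0, 40.0),
    lon: Sequence[float] = (0.0, 5.0, 10.0),
    base: float = 26.0,
    trend_per_year: float = 0.03,
    bias: float = 0.0,
    seasonal_amplitude: float = 4.0,
    noise_sd: float = 0.0,
    monthly: bool = True,
    seed: int = 0,
) -> xr.DataArray:
    """Synthetic SST cube with a prescribed warming trend and model bias.

    Monthly cubes get a sinusoidal seasonal cycle peaking in August;
    ``bias`` is a constant offset emulating a model's systematic error
    relative to observations.  Used by tests and the climate fixtures —
    this is purely synthetic plumbing, not a climate model emulator.
    """
    years = np.asarray(list(years), dtype=int)
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    rng = np.random.default_rng(seed)
    ref = years[0]
    if monthly:
        time = pd.date_range(f"{years[0]}-01-01", f"{years[-1]}-12-01", freq="MS")
        yr = time.year.values
        month = time.month.values
        seasonal = seasonal_amplitude * np.cos(2 * np.pi * (month - 8) / 12.0)
        series = base + bias + trend_per_year * (yr - ref) + seasonal
        data = np.tile(series[:, None, None], (1, lat.size, lon.size))
        if noise_sd > 0:
            data = data + rng.normal(0, noise_sd, size=data.shape)
        da = xr.DataArray(
            data,
            coords={"time": time, "lat": lat, "lon": lon},
            dims=("time", "lat", "lon"),
            name="sst",
        )
    else:
        series = base + bias + trend_per_year * (years - ref)
        data = np.tile(series[:, None, None], (1, lat.size, lon.size))
        if noise_sd > 0:
            data = data + rng.normal(0, noise_sd, size=data.shape)
        da = xr.DataArray(
            data,
            coords={"year": years, "lat": lat, "lon": lon},
            dims=("year", "lat", "lon"),
            name="sst",
        )
    da.attrs.update({"model_id": model_id, "units": "degC"})
    return da


def read_sst(path, var: str | None = None) -> xr.DataArray:
    """Read an SST cube from netCDF (scipy backend), normalising names/units.

    Picks ``sst`` or ``tos`` automatically unless ``var`` names the
    variable; renames ``latitude``/``longitude`` to ``lat``/``lon``;
    converts Kelvin to °C.
    """
    ds = xr.open_dataset(path, engine="scipy")
    if var is None:
        for cand in ("sst", "tos"):
            if cand in ds.data_vars:
                var = cand
                break
        else:
            raise ValueError(f"no sst/tos variable found in {path}; has {list(ds.data_vars)}")
    da = ds[var]
    rename = {k: v for k, v in {"latitude": "lat", "longitude": "lon"}.items() if k in da.dims}
    if rename:
        da = da.rename(rename)
    return to_celsius(da)


def write_sst(da: xr.DataArray, path) -> None:
    """Write a cube to classic netCDF-3 via the scipy backend."""
    name = da.name or "sst"
    da = da.copy()
    # netCDF3 cannot store tuple attrs
    da.attrs = {k: (list(v) if isinstance(v, tuple) else v) for k, v in da.attrs.items() if v is not None}
    da.to_dataset(name=name).to_netcdf(path, engine="scipy")
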