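"""Anomaly construction, detrending, smoothing, and analysis-mask building.

The processing order is fixed and enforced by provenance flags on the cube:
monthly anomalies first, then per-pixel linear detrending, then the centered
3-month running mean (the same filter the ONI applies to sea-surface
temperatures).  Calling a stage out of order raises.

Missing data (NaN) propagate: a climatological mean ignores missing months, a
detrended pixel needs at least 3 valid time steps, and a smoothed value is
missing whenever any member of its window is missing.
"""

from __future__ import annotations

import numpy as np
import xarray as xr

from ensotel.cube import calendar_months, check_same_grid, get_flag, with_flag
from ensotel.oni import running_mean3_array


def monthly_climatology(cube: xr.DataArray, overall: bool = False) -> xr.DataArray:
    """Per-pixel calendar-month means over the whole record.

    Requires a whole number of years so every calendar month is represented
    equally.  With ``overall=True`` the single all-months mean is replicated
    into all 12 fields (the coarser anomaly definition, kept as a switch).
    """
    n = cube.sizes["time"]
    if n % 12 != 0:
        raise ValueError(f"cube covers {n} months — climatology needs whole years")
    months = calendar_months(cube)
    data = cube.values
    if overall:
        mean = np.nanmean(data, axis=0)
        fields = np.broadcast_to(mean, (12,) + mean.shape).copy()
    else:
        fields = np.empty((12,) + data.shape[1:])
        for m in range(1, 13):
            sel = months == m
            block = data[sel]
            count = np.isfinite(block).sum(axis=0)
            total = np.nansum(block, axis=0)
            fields[m - 1] = np.where(count > 0,
                                     total / np.maximum(count, 1), np.nan)
    return xr.DataArray(
        fields, dims=("month", "y", "x"),
        coords={"month": np.arange(1, 13), "y": cube["y"], "x": cube["x"]},
        attrs={"variable": cube.attrs.get("variable", ""), "role": "climatology"},
    )


def to_anomalies(cube: xr.DataArray, climatology: xr.DataArray) -> xr.DataArray:
    """Subtract the calendar-month climatology from every time step."""
    if get_flag(cube, "anomalized"):
        raise ValueError("cube is already anomalized")
    if climatology.sizes.get("month") != 12:
        missing = sorted(set(range(1, 13)) - set(np.atleast_1d(
            climatology.coords.get("month", np.array([])).values).tolist()))
        raise ValueError(f"climatology incomplete; missing months {missing}")
    check_same_grid(cube, climatology)
    months = calendar_months(cube)
    anom = cube.values - climatology.values[months - 1]
    out = cube.copy(data=anom)
    out.attrs = dict(cube.attrs)
    return with_flag(out, "anomalized")


def detrend_linear(anom: xr.DataArray) -> xr.DataArray:
    """Remove the per-pixel ordinary-least-squares line over time.

    Missing-aware: the fit uses each pixel's valid months only; pixels with
    fewer than 3 valid time steps become entirely missing.
    """
    if not get_flag(anom, "anomalized"):
        raise ValueError("detrend_linear expects an anomalized cube")
    if get_flag(anom, "detrended"):
        raise ValueError("cube is already detrended")
    data = anom.values
    n = data.shape[0]
    t = np.arange(n, dtype=float)[:, None, None]
    valid = np.isfinite(data)
    count = valid.sum(axis=0)

    tv = np.where(valid, t, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_mean = np.nanmean(tv, axis=0)
        y_mean = np.nanmean(data, axis=0)
        dt = tv - t_mean
        dy = data - y_mean
        sxx = np.nansum(dt * dt, axis=0)
        sxy = np.nansum(dt * np.where(valid, dy, np.nan), axis=0)
        slope = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), np.nan)
        resid = data - (y_mean + slope * dt)

    resid[:, count < 3] = np.nan
    out = anom.copy(data=resid)
    out.attrs = dict(anom.attrs)
    return with_flag(out, "detrended")


def running_mean3_cube(anom: xr.DataArray) -> xr.DataArray:
    """Centered 3-month running mean per pixel, 2-term windows at the edges.

    Same edge convention as the index smoother, so cube and index stay
    aligned month-for-month.  A window touching a missing value is missing.
    """
    if not get_flag(anom, "detrended"):
        raise ValueError("running_mean3_cube expects a detrended cube "
                         "(order: anomalies -> detrend -> smooth)")
    if get_flag(anom, "smoothed"):
        raise ValueError("cube is already smoothed")
    out = anom.copy(data=running_mean3_array(anom.values))
    out.attrs = dict(anom.attrs)
    return with_flag(out, "smoothed")


def preprocess_cube(cube: xr.DataArray, overall_mean: bool = False) -> xr.DataArray:
    """Convenience chain: anomalies -> linear detrend -> 3-month smoothing."""
    clim = monthly_climatology(cube, overall=overall_mean)
    return running_mean3_cube(detrend_linear(to_anomalies(cube, clim)))


def preprocess_index(series, anomalize: bool = True,
                     detrend: bool = True):
    """Apply the cube preprocessing (anomalies, detrend, smoothing) to the index.

    The default correlation workflow smooths the ocean index but does not
    anomalize or detrend it (it is already an anomaly series with an updating
    baseline).  This helper exists for users who want the index treated
    identically to the terrestrial cubes — required, e.g., for a noise-free
    proportional field to correlate at exactly ±1 with the index.
    """
    from ensotel.oni import MonthlyIndexSeries

    if series.smoothed:
        raise ValueError("preprocess the raw series; it is already smoothed")
    v = series.values.astype(float).copy()
    n = len(v)
    if anomalize:
        if n % 12 != 0:
            raise ValueError("anomalizing the index needs whole years")
        months = (np.arange(n) + series.start[1] - 1) % 12
        for m in range(12):
            v[months == m] -= v[months == m].mean()
    if detrend:
        t = np.arange(n, dtype=float)
        coef = np.polynomial.polynomial.polyfit(t, v, 1)
        v -= coef[0] + coef[1] * t
    return MonthlyIndexSeries(start=series.start,
                              values=running_mean3_array(v), smoothed=True)


def deforestation_filter(
    loss_raster_fine: np.ndarray,
    target_shape: tuple[int, int],
    rule: str = "any",
    threshold: float = 0.0,
) -> np.ndarray:
    """Aggregate a fine binary loss raster to the analysis grid and keep clean cells.

    Returns a boolean grid, True where the cell is RETAINED.  Rule ``"any"``
    (the conservative default) drops a coarse cell containing one or more
    loss pixels; rule ``"fraction"`` drops cells whose loss fraction strictly
    exceeds ``threshold``.
    """
    loss = np.asarray(loss_raster_fine)
    rows, cols = target_shape
    fr, fc = loss.shape
    if fr % rows or fc % cols:
        raise ValueError(
            f"fine raster {loss.shape} is not an integer multiple of {target_shape}"
        )
    ky, kx = fr // rows, fc // cols
    frac = (loss.astype(float)
            .reshape(rows, ky, cols, kx)
            .mean(axis=(1, 3)))
    if rule == "any":
        return frac == 0.0
    if rule == "fraction":
        return ~(frac > threshold)
    raise ValueError(f"unknown rule {rule!r}; use 'any' or 'fraction'")


def combine_masks(suitability: np.ndarray, forest_retained: np.ndarray) -> np.ndarray:
    """Logical AND of the crop-suitability and deforestation-retained masks."""
    a = np.asarray(suitability, dtype=bool)
    b = np.asarray(forest_retained, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shape mismatch: {a.shape} vs {b.shape}")
    return a & b
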