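"""Monthly grid-stack container helpers.

A "cube" is an :class:`xarray.DataArray` with dims ``(time, y, x)``, a monthly
``time`` coordinate (timestamps at month start), and attrs carrying the
variable name, units, a simple geotransform (``x0, y0, dx, dy, crs`` —
north-up, pixel-center registration), and three integer provenance flags
``anomalized / detrended / smoothed`` that enforce the processing order.
Missing data are NaN.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr

FLAG_NAMES = ("anomalized", "detrended", "smoothed")

#: Default geotransform for synthetic grids (arbitrary tropical window).
DEFAULT_GEO = {"x0": -90.0, "y0": 20.0, "dx": 0.05, "dy": -0.05,
               "crs": "EPSG:4326"}


def make_cube(
    data: np.ndarray,
    start: tuple[int, int] = (1992, 1),
    variable: str = "var",
    units: str = "",
    geo: dict | None = None,
) -> xr.DataArray:
    """Wrap a (time, rows, cols) array as a cube DataArray."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise ValueError("cube data must be 3-D (time, y, x)")
    geo = dict(DEFAULT_GEO if geo is None else geo)
    t0 = pd.Period(year=start[0], month=start[1], freq="M").to_timestamp()
    time = pd.date_range(t0, periods=data.shape[0], freq="MS")
    ny, nx = data.shape[1:]
    y = geo["y0"] + geo["dy"] * (np.arange(ny) + 0.5)
    x = geo["x0"] + geo["dx"] * (np.arange(nx) + 0.5)
    attrs = {"variable": variable, "units": units, **geo}
    attrs.update({f: 0 for f in FLAG_NAMES})
    return xr.DataArray(
        data, dims=("time", "y", "x"),
        coords={"time": time, "y": y, "x": x},
        attrs=attrs, name=variable,
    )


def get_flag(cube: xr.DataArray, name: str) -> bool:
    if name not in FLAG_NAMES:
        raise KeyError(name)
    return bool(cube.attrs.get(name, 0))


def with_flag(cube: xr.DataArray, name: str, value: bool = True) -> xr.DataArray:
    if name not in FLAG_NAMES:
        raise KeyError(name)
    out = cube.copy(deep=False)
    out.attrs = dict(cube.attrs)
    out.attrs[name] = int(value)
    return out


def time_periods(cube: xr.DataArray) -> pd.PeriodIndex:
    return pd.DatetimeIndex(cube["time"].values).to_period("M")


def calendar_months(cube: xr.DataArray) -> np.ndarray:
    """1-based calendar month of each time step."""
    return pd.DatetimeIndex(cube["time"].values).month.to_numpy()


def check_same_grid(*cubes_or_masks) -> tuple[int, int]:
    """Assert identical (rows, cols) across cubes/2-D grids; return the shape."""
    shapes = []
    for obj in cubes_or_masks:
        arr = obj.values if hasattr(obj, "values") else np.asarray(obj)
        shapes.append(arr.shape[-2:])
    first = shapes[0]
    if any(s != first for s in shapes[1:]):
        raise ValueError(f"grid shape mismatch: {shapes}")
    return first
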