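"""File round-tripping: NetCDF cubes, TIFF grids with JSON georeferencing, CSV.

Cubes travel as NetCDF (classic format via the scipy backend; dimensions
time/y/x, CF-style time units).  Masks and map grids travel as single- or
multi-page TIFF written by tifffile, with the geotransform and CRS in a JSON
sidecar (``<name>.tif`` + ``<name>.json``) since no GeoTIFF writer is
assumed.  Grid registration between cubes and masks must match exactly; this
module checks, it never resamples.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import xarray as xr

from ensotel.cube import DEFAULT_GEO, FLAG_NAMES
from ensotel.oni import MonthlyIndexSeries, PhaseLabelSeries
from ensotel.synthetic import GroundTruth
from ensotel.teleconnection import CorrelationMap

_GEO_KEYS = ("x0", "y0", "dx", "dy", "crs")


def write_cube(cube: xr.DataArray, path) -> Path:
    path = Path(path)
    name = str(cube.attrs.get("variable", cube.name or "var"))
    ds = cube.to_dataset(name=name)
    ds.to_netcdf(path, engine="scipy")
    return path


def read_cube(path) -> xr.DataArray:
    with xr.open_dataset(path, engine="scipy") as ds:
        names = list(ds.data_vars)
        if len(names) != 1:
            raise ValueError(f"{path} holds {len(names)} variables; expected 1")
        da = ds[names[0]].load()
    for f in FLAG_NAMES:
        da.attrs.setdefault(f, 0)
        da.attrs[f] = int(da.attrs[f])
    return da


def geo_of(obj) -> dict:
    attrs = getattr(obj, "attrs", {})
    return {k: attrs.get(k, DEFAULT_GEO[k]) for k in _GEO_KEYS}


def write_grid_tiff(grid: np.ndarray, path, geo: dict | None = None,
                    band_names: list[str] | None = None) -> Path:
    """Write a 2-D grid (or stack of 2-D bands) as TIFF + JSON sidecar."""
    path = Path(path)
    arr = np.asarray(grid)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    elif arr.dtype == object:
        raise TypeError("encode object grids to integer codes before writing")
    tifffile.imwrite(path, arr, photometric="minisblack")
    sidecar = dict(DEFAULT_GEO if geo is None else geo)
    if band_names:
        sidecar["band_names"] = band_names
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_grid_tiff(path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    arr = tifffile.imread(path)
    sidecar = path.with_suffix(".json")
    geo = json.loads(sidecar.read_text()) if sidecar.exists() else dict(DEFAULT_GEO)
    return arr, geo


def write_corr_map(cmap: CorrelationMap, path, geo: dict | None = None) -> Path:
    """Correlation map as a 3-band (r, p, n) TIFF with JSON sidecar."""
    path = Path(path)
    stack = np.stack([cmap.r, cmap.p, cmap.n.astype(float)])
    sidecar_geo = dict(DEFAULT_GEO if geo is None else geo)
    sidecar_geo.update(
        {"variable": cmap.variable, "phase": cmap.phase,
         "lag": int(cmap.lag), "alpha": float(cmap.alpha)}
    )
    return write_grid_tiff(stack.astype(np.float64), path, geo=sidecar_geo,
                           band_names=["r", "p", "n"])


def read_corr_map(path) -> CorrelationMap:
    arr, meta = read_grid_tiff(path)
    if arr.ndim != 3 or arr.shape[0] != 3:
        raise ValueError(f"{path} is not a 3-band correlation map")
    return CorrelationMap(
        variable=str(meta.get("variable", "")),
        phase=str(meta["phase"]),
        lag=int(meta["lag"]),
        r=arr[0], p=arr[1], n=arr[2].astype(int),
        alpha=float(meta.get("alpha", 0.05)),
    )


def write_index_csv(series: MonthlyIndexSeries, path) -> Path:
    path = Path(path)
    series.to_frame().to_csv(path, index=False)
    return path


def write_labels_csv(labels: PhaseLabelSeries, path) -> Path:
    path = Path(path)
    labels.to_frame().to_csv(path, index=False)
    return path


def read_labels_csv(path) -> PhaseLabelSeries:
    df = pd.read_csv(path)
    return PhaseLabelSeries(
        start=(int(df["year"].iloc[0]), int(df["month"].iloc[0])),
        labels=df["phase"].to_numpy(dtype=object),
    )


def write_ground_truth(truth: GroundTruth, prefix) -> tuple[Path, Path]:
    """Ground truth as a per-pixel CSV plus a JSON sidecar of event months."""
    prefix = Path(prefix)
    rows, cols = truth.beta_field.shape
    ii, jj = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    df = pd.DataFrame({
        "row": ii.ravel(), "col": jj.ravel(),
        "beta": truth.beta_field.ravel(),
        "lag": truth.lag_field.ravel(),
        "signal": truth.signal_mask.ravel().astype(int),
    })
    csv_path = prefix.with_suffix(".csv")
    df.to_csv(csv_path, index=False)
    json_path = prefix.with_suffix(".json")
    json_path.write_text(json.dumps(
        {phase: np.asarray(idx).tolist()
         for phase, idx in truth.event_months.items()},
        indent=2,
    ))
    return csv_path, json_path
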