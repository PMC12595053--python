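"""Per-pixel, phase-conditional, lagged Pearson correlation maps.

For a chosen ENSO phase the index is sampled at the phase-labelled months t
and each pixel's anomaly series at t + lag (positive lag = field responds
after the index; months where t + lag falls outside the record are dropped
pixel-wise).  The per-pixel sample Pearson r gets a two-sided p-value from
the t transform  t = r * sqrt((n-2) / (1-r^2)).

Serial correlation caveat: 3-month-smoothed series are autocorrelated, which
makes the naive t-test anticonservative.  No effective-sample-size correction
is applied by default (matching the per-pixel p < 0.05 mapping rule this
pipeline implements); ``use_neff=True`` enables a Bretherton-style lag-1
correction of the degrees of freedom for users who want conservative maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import xarray as xr
from scipy import stats

from ensotel.cube import check_same_grid, get_flag
from ensotel.oni import EL_NINO, LA_NINA, MonthlyIndexSeries, PhaseLabelSeries


@dataclass(frozen=True)
class CorrelationMap:
    """Per-pixel r / p / n grids for one variable, phase, and lag."""

    variable: str
    phase: str
    lag: int
    r: np.ndarray
    p: np.ndarray
    n: np.ndarray
    alpha: float = 0.05

    def __post_init__(self):
        if self.r.shape != self.p.shape or self.r.shape != self.n.shape:
            raise ValueError("r, p, n grids must share a shape")
        defined = np.isfinite(self.r)
        if defined.any():
            vals = self.r[defined]
            if np.any(np.abs(vals) > 1 + 1e-12):
                raise ValueError("correlation values outside [-1, 1]")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.r.shape

    @property
    def empty(self) -> bool:
        return not np.isfinite(self.r).any()

    def to_dataset(self) -> xr.Dataset:
        ds = xr.Dataset(
            {
                "r": (("y", "x"), self.r),
                "p": (("y", "x"), self.p),
                "n": (("y", "x"), self.n.astype(np.int32)),
            },
            attrs={"variable": self.variable, "phase": self.phase,
                   "lag": int(self.lag), "alpha": float(self.alpha)},
        )
        return ds

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "CorrelationMap":
        return cls(
            variable=str(ds.attrs.get("variable", "")),
            phase=str(ds.attrs["phase"]),
            lag=int(ds.attrs["lag"]),
            r=np.asarray(ds["r"].values, dtype=float),
            p=np.asarray(ds["p"].values, dtype=float),
            n=np.asarray(ds["n"].values),
            alpha=float(ds.attrs.get("alpha", 0.05)),
        )


def phase_months(labels: PhaseLabelSeries, phase: str) -> np.ndarray:
    """Ordered indices of the months carrying the given phase label."""
    if phase not in (EL_NINO, LA_NINA):
        raise ValueError(f"unknown phase {phase!r}; use {EL_NINO!r} or {LA_NINA!r}")
    return np.flatnonzero(labels.labels == phase)


def _lag1_autocorr(sel: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Lag-1 autocorrelation using consecutive-in-time sampled pairs only.

    ``values`` is (k,) or (k, m) sampled at months ``sel`` (sorted).  Pairs
    (i, i+1) with sel[i+1] == sel[i] + 1 enter the estimate; with fewer than
    3 such pairs the autocorrelation is taken as 0 (no correction).
    """
    adj = np.flatnonzero(np.diff(sel) == 1)
    v = values if values.ndim == 2 else values[:, None]
    out = np.zeros(v.shape[1])
    if len(adj) >= 3:
        a = v[adj]
        b = v[adj + 1]
        am = np.nanmean(a, axis=0)
        bm = np.nanmean(b, axis=0)
        da, db = a - am, b - bm
        num = np.nansum(da * db, axis=0)
        den = np.sqrt(np.nansum(da**2, axis=0) * np.nansum(db**2, axis=0))
        good = den > 0
        out[good] = num[good] / den[good]
    return out if values.ndim == 2 else out[:1]


def _t_pvalue(r: np.ndarray, df: np.ndarray) -> np.ndarray:
    """Two-sided p from the t transform, elementwise; |r| = 1 gives p = 0."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = 1.0 - r * r
        tstat = np.where(denom > 0, np.abs(r) * np.sqrt(df / np.where(denom > 0, denom, 1.0)), np.inf)
    p = 2.0 * stats.t.sf(tstat, np.maximum(df, 1e-9))
    p = np.where(np.isfinite(r) & (df > 0), p, np.nan)
    return np.where(np.isfinite(r) & (denom <= 0), 0.0, p)


def pearson(
    x: np.ndarray, y: np.ndarray, min_n: int = 8
) -> tuple[float, float, int]:
    """Sample Pearson r with a two-sided t-based p for one pair of vectors.

    Pairs with a missing member are dropped.  Fewer than ``min_n`` complete
    pairs, or zero variance in either vector, gives an undefined result
    (NaN, NaN, n) rather than an exception.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < max(min_n, 3):
        return (np.nan, np.nan, n)
    xs, ys = x[ok], y[ok]
    dx = xs - xs.mean()
    dy = ys - ys.mean()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    # degenerate (constant up to float rounding) input -> undefined, not 0
    tol_x = n * (1e-12 * np.max(np.abs(xs), initial=0.0)) ** 2
    tol_y = n * (1e-12 * np.max(np.abs(ys), initial=0.0)) ** 2
    if sxx <= tol_x or syy <= tol_y:
        return (np.nan, np.nan, n)
    r = float(dx @ dy) / np.sqrt(sxx * syy)
    r = float(np.clip(r, -1.0, 1.0))
    p = float(_t_pvalue(np.array(r), np.array(n - 2, dtype=float)))
    return (r, p, n)


def _pearson_grid(
    x: np.ndarray, Y: np.ndarray, min_n: int, sel: np.ndarray, use_neff: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized missing-aware Pearson of one vector against many columns.

    x: (k,) finite; Y: (k, m) possibly NaN; returns (r, p, n) of length m.
    """
    valid = np.isfinite(Y)
    n = valid.sum(axis=0).astype(float)
    xcol = x[:, None]
    xv = np.where(valid, xcol, 0.0)
    yv = np.where(valid, Y, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nx = np.where(n > 0, n, 1.0)
        xm = xv.sum(axis=0) / nx
        ym = yv.sum(axis=0) / nx
        dx = np.where(valid, xcol - xm, 0.0)
        dy = np.where(valid, Y - ym, 0.0)
        sxx = (dx * dx).sum(axis=0)
        syy = (dy * dy).sum(axis=0)
        sxy = (dx * dy).sum(axis=0)
        # constant-up-to-rounding series are degenerate, not zero-correlated;
        # the y tolerance references the cube-wide scale so that pixels whose
        # variance is pure float residue (e.g. exact climatology subtraction)
        # come out undefined rather than spuriously correlated
        tol_x = n * (1e-12 * np.abs(xv).max(initial=0.0)) ** 2
        tol_y = n * (1e-12 * np.abs(yv).max(initial=0.0)) ** 2
        ok = (sxx > tol_x) & (syy > tol_y)
        den = np.sqrt(np.where(ok, sxx * syy, 1.0))
        r = np.where(ok, sxy / den, np.nan)
    r = np.where(n >= max(min_n, 3), r, np.nan)
    r = np.clip(r, -1.0, 1.0)

    df = n - 2.0
    if use_neff:
        r1x = _lag1_autocorr(sel, x)[0]
        r1y = _lag1_autocorr(sel, np.where(valid, Y, np.nan))
        prod = np.clip(r1x * r1y, -0.99, 0.99)
        n_eff = n * (1.0 - prod) / (1.0 + prod)
        df = np.minimum(n, np.maximum(n_eff, 3.0)) - 2.0
    p = _t_pvalue(r, df)
    nn = n.astype(int)
    return r, p, nn


def correlation_map(
    anom_cube: xr.DataArray,
    index: MonthlyIndexSeries,
    labels: PhaseLabelSeries,
    phase: str,
    lag: int = 0,
    mask: np.ndarray | None = None,
    alpha: float = 0.05,
    min_n: int = 8,
    use_neff: bool = False,
    require_smoothed: bool = True,
) -> CorrelationMap:
    """Correlate the smoothed index with each pixel's anomaly series.

    Only months labelled with ``phase`` enter; the field is taken at t + lag.
    Pixels outside ``mask`` (True = analyse) or with fewer than ``min_n``
    complete pairs are undefined (NaN).  ``require_smoothed=False`` admits an
    unsmoothed cube, e.g. for calibration studies on raw noise.
    """
    if require_smoothed and not get_flag(anom_cube, "smoothed"):
        raise ValueError("correlation_map expects a smoothed anomaly cube")
    if not index.smoothed:
        raise ValueError("correlation_map expects a smoothed index")
    nt = anom_cube.sizes["time"]
    if len(index) != nt or len(labels) != nt:
        raise ValueError("index, labels, and cube must share the time axis")
    if abs(lag) > 3:
        warnings.warn(f"lag {lag} outside the usual -3..+3 window", stacklevel=2)

    shape = check_same_grid(anom_cube)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != shape:
            raise ValueError("mask shape mismatch with cube grid")
    else:
        mask = np.ones(shape, dtype=bool)

    variable = str(anom_cube.attrs.get("variable", anom_cube.name or ""))
    r_grid = np.full(shape, np.nan)
    p_grid = np.full(shape, np.nan)
    n_grid = np.zeros(shape, dtype=int)

    months = phase_months(labels, phase)
    keep = (months + lag >= 0) & (months + lag < nt)
    months = months[keep]
    if len(months) == 0:
        return CorrelationMap(variable=variable, phase=phase, lag=lag,
                              r=r_grid, p=p_grid, n=n_grid, alpha=alpha)

    x = index.values[months]
    data = anom_cube.values[months + lag]          # (k, rows, cols)
    Y = data[:, mask]
    r, p, n = _pearson_grid(x, Y, min_n=min_n, sel=months, use_neff=use_neff)
    r_grid[mask] = r
    p_grid[mask] = p
    n_grid[mask] = n
    return CorrelationMap(variable=variable, phase=phase, lag=lag,
                          r=r_grid, p=p_grid, n=n_grid, alpha=alpha)


def significance_mask(cmap: CorrelationMap, alpha: float = 0.05) -> np.ndarray:
    """True where r is defined and p < alpha (strict inequality)."""
    return np.isfinite(cmap.r) & np.isfinite(cmap.p) & (cmap.p < alpha)


def summarize(cmap: CorrelationMap) -> dict:
    """One-row summary: fraction significant and median r over defined pixels."""
    defined = np.isfinite(cmap.r)
    sig = significance_mask(cmap, cmap.alpha)
    return {
        "variable": cmap.variable,
        "phase": cmap.phase,
        "lag": cmap.lag,
        "n_defined": int(defined.sum()),
        "pct_significant": (100.0 * sig.sum() / defined.sum()) if defined.any() else np.nan,
        "median_r": float(np.median(cmap.r[defined])) if defined.any() else np.nan,
    }
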