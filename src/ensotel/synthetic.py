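"""Synthetic ocean-index series and teleconnected data cubes with known truth.

The generator emulates the statistical structure the downstream analysis
assumes: an AR(1) monthly ocean index with warm/cool excursions beyond
±0.5 °C, and gridded monthly fields built as

    field[t, i, j] = climatology(month of t) + trend_slope * t
                     + beta[i, j] * index[t - lag[i, j]] + noise

where ``beta`` is the per-pixel teleconnection slope (field units per °C) and
``lag`` the per-pixel response delay in months (positive = field responds
AFTER the index; out-of-range lagged positions contribute zero).  Paired
sun/shade productivity cubes share this structure with independent beta/lag
fields, so every typology category and lag transition can be constructed by
design.

Defaults mirror the study layout: 348 months (29 years starting 1992-01) and
an AR(1) coefficient / innovation scale giving a stationary SD of ~0.5 °C, so
a realistic fraction of months crosses the phase thresholds.  No attempt is
made to mimic real spatial covariance or ENSO spectral structure beyond AR(1).

Reproducibility: one root seed; each component (index, each named cube, masks)
draws from its own deterministically derived substream, so adding a variable
never perturbs the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import xarray as xr

from ensotel.cube import make_cube
from ensotel.oni import (
    EL_NINO,
    LA_NINA,
    MonthlyIndexSeries,
    classify_phases,
    running_mean3,
)

_INDEX_STREAM = 0
_CUBE_STREAM = 1
_MASK_STREAM = 2


def _rng(seed: int, stream: int, name: str = "") -> np.random.Generator:
    """Deterministic per-component substream of a single root seed."""
    keys = [int(seed), int(stream)]
    if name:
        keys.append(zlib.crc32(name.encode()) & 0x7FFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(keys))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic scenario.

    Attributes
    ----------
    n_months : length of the simulated record (≥ 24).
    grid_shape : (rows, cols) of the analysis grid.
    ar1_coeff : AR(1) coefficient of the index, in [0, 1).
    index_noise_sd : SD of the index innovations, °C.
    beta_field : scalar or (rows, cols) teleconnection slope, field units/°C.
    lag_field : scalar or (rows, cols) integer response lag, months in [−3, 3].
    trend_slope : linear trend, field units per month.
    seasonal_amplitude : amplitude of the default sinusoid climatology.
    noise_sd : SD of the per-pixel field noise, field units.
    seed : root seed for all substreams.
    climatology : optional explicit 12 monthly values (overrides the sinusoid).
    start : (year, month) of the first record.
    """

    n_months: int = 348
    grid_shape: tuple[int, int] = (40, 40)
    ar1_coeff: float = 0.8
    index_noise_sd: float = 0.3
    beta_field: float | np.ndarray = 0.0
    lag_field: int | np.ndarray = 0
    trend_slope: float = 0.0
    seasonal_amplitude: float = 1.0
    noise_sd: float = 0.5
    seed: int = 0
    climatology: np.ndarray | None = None
    start: tuple[int, int] = (1992, 1)

    def __post_init__(self):
        if self.n_months < 24:
            raise ValueError("n_months must be at least 24 (two whole years)")
        r, c = self.grid_shape
        if r <= 0 or c <= 0:
            raise ValueError("grid_shape must be positive")
        for name in ("ar1_coeff", "index_noise_sd", "trend_slope",
                     "seasonal_amplitude", "noise_sd"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if not (0.0 <= self.ar1_coeff < 1.0):
            raise ValueError("ar1_coeff must lie in [0, 1)")
        if self.index_noise_sd < 0 or self.noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.climatology is not None and len(np.atleast_1d(self.climatology)) != 12:
            raise ValueError("climatology must have 12 monthly values")

    def beta_array(self) -> np.ndarray:
        b = np.broadcast_to(np.asarray(self.beta_field, dtype=float),
                            self.grid_shape)
        if not np.all(np.isfinite(b)):
            raise ValueError("beta_field must be finite")
        return np.array(b)

    def lag_array(self) -> np.ndarray:
        lag = np.broadcast_to(np.asarray(self.lag_field), self.grid_shape)
        lag = np.array(lag, dtype=int)
        return lag

    def climatology_table(self) -> np.ndarray:
        """12 monthly climatology values; a fixed sinusoid unless supplied."""
        if self.climatology is not None:
            return np.asarray(self.climatology, dtype=float)
        m = np.arange(12)
        return self.seasonal_amplitude * np.sin(2.0 * np.pi * m / 12.0)


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually planted, for end-to-end verification."""

    beta_field: np.ndarray
    lag_field: np.ndarray
    signal_mask: np.ndarray          # True where beta != 0
    event_months: Mapping[str, np.ndarray] = field(default_factory=dict)


def generate_index(config: SimulationConfig) -> MonthlyIndexSeries:
    """Simulate the raw (unsmoothed) monthly AR(1) ocean index.

    x_t = ar1_coeff * x_{t-1} + eps_t,  eps_t ~ N(0, index_noise_sd^2),
    x_0 = eps_0.  The realization is recentered to zero mean, emulating the
    ONI's anomaly baseline (NOAA recomputes it on updating 30-year base
    periods precisely so the index stays centered); without this a persistent
    AR(1) draw can spend a whole record on one side of zero, which the real
    index cannot.  When noise is exactly zero the series is left untouched so
    degenerate constructions (all-zero, constant-offset) pass through.  The
    3-month ONI smoothing is deliberately NOT applied here; it belongs to the
    phase-classification stage.
    """
    rng = _rng(config.seed, _INDEX_STREAM)
    eps = rng.normal(0.0, config.index_noise_sd, size=config.n_months)
    x = np.empty(config.n_months)
    x[0] = eps[0]
    a = config.ar1_coeff
    for t in range(1, config.n_months):
        x[t] = a * x[t - 1] + eps[t]
    if config.index_noise_sd > 0:
        x -= x.mean()
    return MonthlyIndexSeries(start=config.start, values=x, smoothed=False)


def _event_months(index: MonthlyIndexSeries, threshold: float = 0.5) -> dict:
    labels = classify_phases(running_mean3(index), threshold=threshold).labels
    return {
        EL_NINO: np.flatnonzero(labels == EL_NINO),
        LA_NINA: np.flatnonzero(labels == LA_NINA),
    }


def _lagged_index_matrix(values: np.ndarray, lags: np.ndarray) -> dict[int, np.ndarray]:
    """index[t - L] for each distinct lag L, zero where t - L is out of range."""
    n = len(values)
    out = {}
    for L in np.unique(lags):
        s = np.zeros(n)
        if L >= 0:
            s[L:] = values[: n - L] if L > 0 else values
        else:
            s[:L] = values[-L:]
        out[int(L)] = s
    return out


def generate_cube(
    config: SimulationConfig,
    index: MonthlyIndexSeries,
    variable_name: str = "var",
    units: str = "",
) -> tuple[xr.DataArray, GroundTruth]:
    """Build one teleconnected monthly cube plus its ground truth.

    Pixel (i, j) at month t is climatology + trend + beta[i,j] * index at
    t − lag[i,j] (zero outside the record) + Gaussian noise.
    """
    if len(index) != config.n_months:
        raise ValueError(
            f"index length {len(index)} != n_months {config.n_months}"
        )
    beta = config.beta_array()
    lag = config.lag_array()
    if beta.shape != config.grid_shape or lag.shape != config.grid_shape:
        raise ValueError("beta_field / lag_field shape mismatch with grid_shape")

    n, (rows, cols) = config.n_months, config.grid_shape
    clim = config.climatology_table()
    months = (np.arange(n) + (config.start[1] - 1)) % 12
    t_axis = np.arange(n, dtype=float)

    base = clim[months] + config.trend_slope * t_axis          # (n,)
    data = np.broadcast_to(base[:, None, None], (n, rows, cols)).copy()

    shifted = _lagged_index_matrix(index.values, lag)
    for L, series in shifted.items():
        sel = lag == L
        if sel.any():
            data[:, sel] += beta[sel][None, :] * series[:, None]

    if config.noise_sd > 0:
        rng = _rng(config.seed, _CUBE_STREAM, variable_name)
        data += rng.normal(0.0, config.noise_sd, size=data.shape)

    cube = make_cube(data, start=config.start, variable=variable_name, units=units)
    truth = GroundTruth(
        beta_field=beta,
        lag_field=lag,
        signal_mask=beta != 0,
        event_months=_event_months(index),
    )
    return cube, truth


def generate_gpp_pair(
    config_sun: SimulationConfig,
    config_shade: SimulationConfig,
    index: MonthlyIndexSeries,
) -> tuple[tuple[xr.DataArray, GroundTruth], tuple[xr.DataArray, GroundTruth]]:
    """Paired sunlit/shaded productivity cubes with independent beta/lag fields."""
    if config_sun.grid_shape != config_shade.grid_shape:
        raise ValueError("sun and shade configs must share grid_shape")
    if config_sun.n_months != config_shade.n_months:
        raise ValueError("sun and shade configs must share n_months")
    sun = generate_cube(config_sun, index, "gpp_sun", units="gC m-2 month-1")
    shade = generate_cube(config_shade, index, "gpp_shade", units="gC m-2 month-1")
    return sun, shade


#: Signal-pixel fraction of each climate variable in the bundled scenario.
#: Distinct spatial extents give the six variables distinct entropies, so the
#: EWM weight ordering is non-trivial by construction (patchier -> heavier).
SCENARIO_SIGNAL_FRACTION = {
    "tmax": 0.50, "tmin": 0.60, "vpd": 0.25,
    "pr": 0.40, "soil": 0.45, "pdsi": 0.55,
}

#: Teleconnection sign per variable under a warming index: temperatures and
#: atmospheric dryness rise, water availability falls (drought-type response).
SCENARIO_BETA_SIGN = {
    "tmax": +1.0, "tmin": +1.0, "vpd": +1.0,
    "pr": -1.0, "soil": -1.0, "pdsi": -1.0,
}


def default_scenario(
    seed: int = 0,
    n_months: int = 348,
    grid_shape: tuple[int, int] = (40, 40),
    noise_sd: float = 0.5,
    shade_lag: int = 1,
    beta_scale: float = 1.0,
) -> dict:
    """The bundled synthetic study: six climate cubes, a GPP pair, and masks.

    Layout (rows x cols):

    * each climate variable has |beta| = beta_scale on a contiguous block
      covering its ``SCENARIO_SIGNAL_FRACTION`` of pixels, zero elsewhere;
    * GPP quadrants plant the four sensitivity categories — top-left: sun and
      shade both decrease; top-right: both increase; bottom-left: opposite
      responses with the canopy (sun) less productive; bottom-right: opposite
      responses with the subcanopy (shade) less productive;
    * the shade cube responds ``shade_lag`` months after the index, the sun
      cube at lag 0;
    * a 90%-suitable mask and a 2% fine-scale forest-loss raster at 4x
      resolution.

    Returns a dict with keys ``index``, ``climate`` (name -> (cube, truth)),
    ``gpp_sun``, ``gpp_shade`` (each (cube, truth)), ``suitability``,
    ``loss_fine``, and ``configs``.
    """
    rows, cols = grid_shape
    base = dict(n_months=n_months, grid_shape=grid_shape, noise_sd=noise_sd,
                seed=seed)
    index_cfg = SimulationConfig(**base)
    index = generate_index(index_cfg)

    climate = {}
    configs = {"index": index_cfg}
    npix = rows * cols
    for name, fraction in SCENARIO_SIGNAL_FRACTION.items():
        beta = np.zeros(grid_shape)
        n_signal = int(round(fraction * npix))
        flat = beta.reshape(-1)
        flat[:n_signal] = beta_scale * SCENARIO_BETA_SIGN[name]
        cfg = SimulationConfig(**base, beta_field=beta)
        climate[name] = generate_cube(cfg, index, name)
        configs[name] = cfg

    beta_sun = np.zeros(grid_shape)
    beta_shade = np.zeros(grid_shape)
    half_r, half_c = rows // 2, cols // 2
    b = beta_scale
    beta_sun[:half_r, :half_c] = -b    # both decrease
    beta_shade[:half_r, :half_c] = -b
    beta_sun[:half_r, half_c:] = +b    # both increase
    beta_shade[:half_r, half_c:] = +b
    beta_sun[half_r:, :half_c] = -b    # opposite: canopy less productive
    beta_shade[half_r:, :half_c] = +b
    beta_sun[half_r:, half_c:] = +b    # opposite: subcanopy less productive
    beta_shade[half_r:, half_c:] = -b
    cfg_sun = SimulationConfig(**base, beta_field=beta_sun)
    cfg_shade = SimulationConfig(**base, beta_field=beta_shade,
                                 lag_field=shade_lag)
    (sun, truth_sun), (shade, truth_shade) = generate_gpp_pair(
        cfg_sun, cfg_shade, index
    )
    configs["gpp_sun"], configs["gpp_shade"] = cfg_sun, cfg_shade

    suitability, loss_fine = generate_masks(
        grid_shape, suitable_fraction=0.9, loss_fraction=0.02,
        fine_factor=4, seed=seed,
    )
    return {
        "index": index,
        "climate": climate,
        "gpp_sun": (sun, truth_sun),
        "gpp_shade": (shade, truth_shade),
        "suitability": suitability,
        "loss_fine": loss_fine,
        "configs": configs,
    }


def generate_masks(
    grid_shape: tuple[int, int],
    suitable_fraction: float = 0.9,
    loss_fraction: float = 0.05,
    fine_factor: int = 4,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Random crop-suitability mask and fine-resolution forest-loss raster.

    Returns a boolean (rows, cols) suitability grid and a binary uint8 loss
    raster at ``fine_factor`` times the resolution, ready for aggregation by
    the deforestation filter.
    """
    if not (0.0 <= suitable_fraction <= 1.0 and 0.0 <= loss_fraction <= 1.0):
        raise ValueError("fractions must lie in [0, 1]")
    if int(fine_factor) != fine_factor or fine_factor < 1:
        raise ValueError("fine_factor must be a positive integer")
    rows, cols = grid_shape
    rng = _rng(seed, _MASK_STREAM)
    suitability = rng.random((rows, cols)) < suitable_fraction
    fine = (rows * fine_factor, cols * fine_factor)
    loss = (rng.random(fine) < loss_fraction).astype(np.uint8)
    return suitability, loss
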