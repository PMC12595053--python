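"""Lagged-response profiles and non-significant-to-significant transition maps.

The timing of a productivity response to the ocean index is probed by
correlating at lags -3..+3 months (positive lag = field responds after the
index).  For each lag the distribution of per-pixel r over the analysis mask
is summarized boxplot-style; the transition detector scans consecutive lag
pairs for a change in the sign of the median r and the transition map then
classifies pixels that switch from non-significant at the earlier lag to
significant at the later one, by the direction of the later-lag response.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ensotel.cube import check_same_grid
from ensotel.oni import EL_NINO, LA_NINA
from ensotel.teleconnection import CorrelationMap, significance_mask

LAGS = tuple(range(-3, 4))

TRANSITION_CODES = {"none": 0, "increase": 1, "decrease": 2}


def lag_profiles(
    corr_maps: Mapping[int, CorrelationMap] | Sequence[CorrelationMap],
    mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Boxplot-style summary of per-pixel r at each lag -3..+3.

    All masked pixels with a defined r enter (no significance filter).
    Returns a DataFrame with one row per lag: median, quartiles, Tukey
    whiskers, and the pixel count; counts of 0 flag an empty domain.
    """
    if not isinstance(corr_maps, Mapping):
        corr_maps = {m.lag: m for m in corr_maps}
    missing = [lag for lag in LAGS if lag not in corr_maps]
    if missing:
        raise ValueError(f"missing correlation maps for lag(s) {missing}")
    phases = {m.phase for m in corr_maps.values()}
    if len(phases) != 1:
        raise ValueError(f"maps mix phases {sorted(phases)}")
    shape = check_same_grid(*[m.r for m in corr_maps.values()])
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    rows = []
    for lag in LAGS:
        r = corr_maps[lag].r
        vals = r[mask & np.isfinite(r)]
        if vals.size:
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            iqr = q3 - q1
            lo = vals[vals >= q1 - 1.5 * iqr].min()
            hi = vals[vals <= q3 + 1.5 * iqr].max()
        else:
            q1 = med = q3 = lo = hi = np.nan
        rows.append({"lag": lag, "median": med, "q1": q1, "q3": q3,
                     "whisker_lo": lo, "whisker_hi": hi,
                     "count": int(vals.size)})
    df = pd.DataFrame(rows)
    df.attrs["phase"] = next(iter(phases))
    return df


def detect_transition(profile: pd.DataFrame,
                      default: tuple[int, int] = (-1, 0)) -> tuple[int, int]:
    """Earliest consecutive lag pair where the median r changes sign.

    A change to or from exactly 0 counts.  If no sign change exists across
    -3..+3 the conventional default pair (-1, 0) is returned, matching the
    reporting convention of depicting the -1 -> 0 transition for
    comparability.  Magnitude-only changes are not detected automatically;
    pick the pair manually where that is wanted.
    """
    prof = profile.sort_values("lag")
    if list(prof["lag"]) != list(LAGS):
        raise ValueError(f"profile must cover lags {LAGS}")
    medians = prof["median"].to_numpy()
    if np.any(~np.isfinite(medians)):
        return default
    signs = np.sign(medians)
    for i in range(len(LAGS) - 1):
        if signs[i] != signs[i + 1]:
            return (LAGS[i], LAGS[i + 1])
    return default


def transition_map(
    cmap_a: CorrelationMap,
    cmap_b: CorrelationMap,
    phase: str,
    alpha: float = 0.05,
) -> np.ndarray:
    """Classify pixels turning significant between two consecutive lags.

    Pixels non-significant at lag a and significant at lag b are classed by
    the direction of the lag-b response: increased productivity is r > 0
    under El Niño or r < 0 under La Niña, decreased is the reverse.  All
    other pixels are "none".  Returns an object-dtype grid over
    {"increase", "decrease", "none"}.
    """
    if phase not in (EL_NINO, LA_NINA):
        raise ValueError(f"unknown phase {phase!r}")
    if cmap_a.phase != phase or cmap_b.phase != phase:
        raise ValueError("both maps must match the requested phase")
    if cmap_b.lag - cmap_a.lag != 1:
        raise ValueError(
            f"lags must be consecutive (a then a+1); got {cmap_a.lag}, {cmap_b.lag}"
        )
    check_same_grid(cmap_a.r, cmap_b.r)
    sig_a = significance_mask(cmap_a, alpha)
    sig_b = significance_mask(cmap_b, alpha)
    turned = ~sig_a & sig_b

    out = np.full(cmap_a.grid_shape, "none", dtype=object)
    flip = 1 if phase == EL_NINO else -1
    r_b = np.nan_to_num(cmap_b.r)
    out[turned & (flip * r_b > 0)] = "increase"
    out[turned & (flip * r_b < 0)] = "decrease"
    return out


def transition_codes(tmap: np.ndarray) -> np.ndarray:
    """Integer-coded transition map for raster export."""
    out = np.zeros(tmap.shape, dtype=np.int16)
    for name, code in TRANSITION_CODES.items():
        out[tmap == name] = code
    return out
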