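"""Sun/shade productivity direction and the four-class sensitivity typology.

Correlations between the ocean index and sunlit-leaf / shaded-leaf gross
primary productivity (GPP) are converted to per-pixel productivity
directions: +1 (increased productivity), -1 (decreased), 0 (no significant
response).  Because a warm-phase positive correlation means productivity
rises with warming while a cool-phase positive correlation means it rises as
the Pacific cools, the sign is phase-adjusted: direction = sign(r) under
El Niño and -sign(r) under La Niña, so +1 always reads "more productive under
the warm extreme of this phase's forcing".

The paired directions feed a 2x2 typology of canopy (sun) vs subcanopy
(shade) response:

    both_increase        sun +1, shade +1
    both_decrease        sun -1, shade -1
    sun_decrease_only    sun -1, shade not -1 (0 or +1)
    shade_decrease_only  shade -1, sun not -1
    none                 neither significant (both 0), or (+1, 0)/(0, +1)
                         — an increase on one layer only is not a
                         decrease class; reported as the residual

Category shares are reported against ALL masked pixels, so they need not sum
to 100% once "none" pixels exist.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ensotel.cube import check_same_grid
from ensotel.oni import EL_NINO, LA_NINA
from ensotel.teleconnection import CorrelationMap, significance_mask

CATEGORIES = (
    "both_increase",
    "both_decrease",
    "sun_decrease_only",
    "shade_decrease_only",
    "none",
)

#: Integer codes for map export.
CATEGORY_CODES = {name: i for i, name in enumerate(CATEGORIES, start=1)}


@dataclass(frozen=True)
class SensitivityMap:
    """Per-pixel typology category plus the two direction grids."""

    phase: str
    category: np.ndarray            # dtype object, one of CATEGORIES (NaN-free)
    sun_direction: np.ndarray       # {-1, 0, +1}
    shade_direction: np.ndarray     # {-1, 0, +1}

    def __post_init__(self):
        check_same_grid(self.category, self.sun_direction, self.shade_direction)

    def codes(self) -> np.ndarray:
        out = np.zeros(self.category.shape, dtype=np.int16)
        for name, code in CATEGORY_CODES.items():
            out[self.category == name] = code
        return out


def productivity_direction(cmap: CorrelationMap, phase: str) -> np.ndarray:
    """Phase-adjusted productivity direction grid in {-1, 0, +1}.

    Significant pixels get sign(r) under El Niño and -sign(r) under La Niña;
    non-significant or undefined pixels get 0.
    """
    if phase not in (EL_NINO, LA_NINA):
        raise ValueError(f"unknown phase {phase!r}")
    if cmap.phase != phase:
        raise ValueError(f"map phase {cmap.phase!r} does not match {phase!r}")
    sig = significance_mask(cmap, cmap.alpha)
    flip = 1 if phase == EL_NINO else -1
    direction = np.zeros(cmap.grid_shape, dtype=int)
    direction[sig] = flip * np.sign(np.nan_to_num(cmap.r[sig])).astype(int)
    return direction


def typology(sun_dir: np.ndarray, shade_dir: np.ndarray,
             phase: str = "") -> SensitivityMap:
    """Combine sun and shade direction grids into the 2x2 typology."""
    sun = np.asarray(sun_dir)
    shade = np.asarray(shade_dir)
    check_same_grid(sun, shade)
    for name, grid in (("sun", sun), ("shade", shade)):
        bad = set(np.unique(grid)) - {-1, 0, 1}
        if bad:
            raise ValueError(f"invalid {name} direction values: {sorted(bad)}")

    category = np.full(sun.shape, "none", dtype=object)
    category[(sun == 1) & (shade == 1)] = "both_increase"
    category[(sun == -1) & (shade == -1)] = "both_decrease"
    category[(sun == -1) & (shade != -1)] = "sun_decrease_only"
    category[(shade == -1) & (sun != -1)] = "shade_decrease_only"
    return SensitivityMap(phase=phase, category=category,
                          sun_direction=sun, shade_direction=shade)


def area_percentages(smap: SensitivityMap, mask: np.ndarray) -> pd.DataFrame:
    """Percentage of masked pixels in each category (denominator = mask size).

    The four response categories plus the "none" residual sum to 100% of the
    masked domain; the response categories alone need not.
    """
    mask = np.asarray(mask, dtype=bool)
    check_same_grid(smap.category, mask)
    total = int(mask.sum())
    if total == 0:
        raise ValueError("empty analysis mask")
    rows = []
    for name in CATEGORIES:
        count = int(((smap.category == name) & mask).sum())
        rows.append({"category": name, "n_pixels": count,
                     "percent": 100.0 * count / total})
    return pd.DataFrame(rows)
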