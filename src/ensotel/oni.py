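"""Ocean-index parsing, smoothing, and ENSO phase classification.

The Oceanic Niño Index (ONI) is distributed by NOAA as a 3-month running mean
of Niño 3.4 sea-surface-temperature anomalies; months at or beyond ±0.5 °C are
conventionally labelled El Niño (warm) or La Niña (cool).  This module parses
the two common layouts of such files, applies the centered 3-month running
mean, labels every month, and extracts NOAA-style multi-month episodes for
reporting.

Conventions
-----------
* The threshold comparison is boundary-inclusive: a smoothed value of exactly
  +0.5 °C is El Niño, exactly −0.5 °C is La Niña.  Configurable via
  ``threshold``.
* The running mean keeps series length: the first and last months use the
  available 2-month partial window so the series stays aligned with 348-month
  data cubes.
* Phase filtering downstream uses per-month labels; the 5-month episode rule
  implemented by :func:`extract_episodes` is reporting convenience only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

EL_NINO = "elnino"
LA_NINA = "lanina"
NEUTRAL = "neutral"
PHASES = (EL_NINO, LA_NINA)

#: NOAA 3-month season codes mapped to the center month of the window.
SEASON_CENTER_MONTH = {
    "DJF": 1, "JFM": 2, "FMA": 3, "MAM": 4, "AMJ": 5, "MJJ": 6,
    "JJA": 7, "JAS": 8, "ASO": 9, "SON": 10, "OND": 11, "NDJ": 12,
}


def running_mean3_array(a: np.ndarray) -> np.ndarray:
    """Centered 3-month running mean along axis 0 with 2-term edge windows.

    NaNs propagate: a window containing a missing value yields a missing
    value (including the 2-term edge windows).
    """
    a = np.asarray(a, dtype=float)
    if a.shape[0] < 3:
        raise ValueError("running mean needs at least 3 time steps")
    out = np.empty_like(a)
    out[1:-1] = (a[:-2] + a[1:-1] + a[2:]) / 3.0
    out[0] = (a[0] + a[1]) / 2.0
    out[-1] = (a[-2] + a[-1]) / 2.0
    return out


@dataclass(frozen=True)
class MonthlyIndexSeries:
    """A gap-free monthly ocean-index series (°C anomaly).

    Parameters
    ----------
    start
        (year, month) of the first value.
    values
        Ordered monthly values; must be finite.
    smoothed
        True once the 3-month running mean has been applied.
    """

    start: tuple[int, int]
    values: np.ndarray
    smoothed: bool = False

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        year, month = self.start
        if not (1 <= month <= 12):
            raise ValueError(f"start month {month} out of range 1..12")
        if self.values.ndim != 1:
            raise ValueError("index values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("index values must be finite (no gaps, no NaN)")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def periods(self) -> pd.PeriodIndex:
        return pd.period_range(
            start=pd.Period(year=self.start[0], month=self.start[1], freq="M"),
            periods=len(self.values),
            freq="M",
        )

    def to_frame(self) -> pd.DataFrame:
        p = self.periods
        return pd.DataFrame({"year": p.year, "month": p.month, "value": self.values})


@dataclass(frozen=True)
class PhaseLabelSeries:
    """Per-month ENSO phase labels aligned to a :class:`MonthlyIndexSeries`."""

    start: tuple[int, int]
    labels: np.ndarray

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=object)
        bad = set(labels) - {EL_NINO, LA_NINA, NEUTRAL}
        if bad:
            raise ValueError(f"unknown phase labels: {sorted(bad)}")
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def periods(self) -> pd.PeriodIndex:
        return pd.period_range(
            start=pd.Period(year=self.start[0], month=self.start[1], freq="M"),
            periods=len(self.labels),
            freq="M",
        )

    def to_frame(self) -> pd.DataFrame:
        p = self.periods
        return pd.DataFrame({"year": p.year, "month": p.month, "phase": self.labels})


@dataclass(frozen=True)
class Episode:
    phase: str
    start: tuple[int, int]   # (year, month) of first month in the run
    end: tuple[int, int]     # (year, month) of last month, inclusive
    n_months: int


@dataclass(frozen=True)
class EventCatalog:
    """Ordered, non-overlapping multi-month warm/cool episodes."""

    episodes: tuple[Episode, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.episodes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "phase": e.phase,
                    "start_year": e.start[0], "start_month": e.start[1],
                    "end_year": e.end[0], "end_month": e.end[1],
                    "n_months": e.n_months,
                }
                for e in self.episodes
            ],
            columns=["phase", "start_year", "start_month",
                     "end_year", "end_month", "n_months"],
        )


def _find_column(columns: Sequence[str], candidates: Iterable[str]) -> str | None:
    lowered = {c.lower().strip(): c for c in columns}
    for cand in candidates:
        if cand in lowered:
            return lowered[cand]
    return None


def parse_index_csv(path) -> MonthlyIndexSeries:
    """Read an ONI-style CSV into a continuous monthly series.

    Two layouts are accepted: numeric ``year`` + ``month`` columns, or a NOAA
    3-month season code (DJF…NDJ, mapped to its center month) + year.  Rows
    may appear in any order; the output is sorted.  A gap in the monthly
    sequence is a hard error listing the missing months.
    """
    df = pd.read_csv(path)
    cols = list(df.columns)
    year_col = _find_column(cols, ("year", "yr"))
    month_col = _find_column(cols, ("month", "mon", "mm"))
    season_col = _find_column(cols, ("season", "seas"))
    value_col = _find_column(cols, ("value", "anom", "oni", "index", "total"))
    if year_col is None or value_col is None:
        raise ValueError(
            f"cannot identify year/value columns among {cols}; expected a "
            "year column plus one of value/anom/oni/index"
        )

    if month_col is not None:
        months = pd.to_numeric(df[month_col], errors="coerce")
    elif season_col is not None:
        codes = df[season_col].astype(str).str.strip().str.upper()
        unknown = sorted(set(codes) - set(SEASON_CENTER_MONTH))
        if unknown:
            raise ValueError(f"unknown season codes: {unknown}")
        months = codes.map(SEASON_CENTER_MONTH)
    else:
        raise ValueError("no month or season column found")

    years = pd.to_numeric(df[year_col], errors="coerce")
    values = pd.to_numeric(df[value_col], errors="coerce")
    for name, series in (("year", years), ("month", months), ("value", values)):
        bad_rows = series[series.isna()].index.tolist()
        if bad_rows:
            raise ValueError(
                f"unparseable {name} in row(s) {bad_rows} of {path}"
            )

    periods = pd.PeriodIndex(
        [pd.Period(year=int(y), month=int(m), freq="M")
         for y, m in zip(years, months)]
    )
    order = np.argsort(periods)
    periods = periods[order]
    vals = values.to_numpy()[order]

    if periods.has_duplicates:
        dups = periods[periods.duplicated()].astype(str).tolist()
        raise ValueError(f"duplicate months in {path}: {dups}")
    full = pd.period_range(periods[0], periods[-1], freq="M")
    if len(full) != len(periods):
        missing = full.difference(periods).astype(str).tolist()
        raise ValueError(f"gap in monthly series {path}; missing: {missing}")

    return MonthlyIndexSeries(
        start=(periods[0].year, periods[0].month), values=vals, smoothed=False
    )


def running_mean3(series: MonthlyIndexSeries) -> MonthlyIndexSeries:
    """Apply the centered 3-month running mean (ONI smoothing).

    Edge months use the available 2-month partial window so the output has
    the same length and start month as the input.  Applying it twice is an
    error — the ``smoothed`` flag enforces single application.
    """
    if series.smoothed:
        raise ValueError("series is already smoothed; refusing to smooth twice")
    return replace(series, values=running_mean3_array(series.values), smoothed=True)


def classify_phases(
    series: MonthlyIndexSeries, threshold: float = 0.5
) -> PhaseLabelSeries:
    """Label each month El Niño (≥ +threshold), La Niña (≤ −threshold), or neutral.

    The comparison is boundary-inclusive.  The series must already carry the
    3-month running mean (``smoothed`` flag), matching the ONI definition.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if not series.smoothed:
        raise ValueError("classify_phases expects a smoothed (3-month mean) series")
    v = series.values
    labels = np.full(len(v), NEUTRAL, dtype=object)
    labels[v >= threshold] = EL_NINO
    labels[v <= -threshold] = LA_NINA
    return PhaseLabelSeries(start=series.start, labels=labels)


def extract_episodes(labels: PhaseLabelSeries, min_length: int = 5) -> EventCatalog:
    """List maximal runs of a non-neutral phase lasting ≥ ``min_length`` months.

    Mirrors NOAA's episode convention (5 consecutive overlapping seasons).
    The catalog is for reporting; phase filtering of data uses the per-month
    labels directly, not episode membership.
    """
    periods = labels.periods
    arr = labels.labels
    episodes: list[Episode] = []
    i = 0
    n = len(arr)
    while i < n:
        if arr[i] == NEUTRAL:
            i += 1
            continue
        j = i
        while j + 1 < n and arr[j + 1] == arr[i]:
            j += 1
        run = j - i + 1
        if run >= min_length:
            episodes.append(
                Episode(
                    phase=arr[i],
                    start=(periods[i].year, periods[i].month),
                    end=(periods[j].year, periods[j].month),
                    n_months=run,
                )
            )
        i = j + 1
    return EventCatalog(episodes=tuple(episodes))
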