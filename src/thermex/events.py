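"""Detection and classification of daytime, nighttime and compound temperature extremes.

A heat wave (cold spell) is a run of at least ``min_duration`` consecutive
days on which a daily temperature metric is at or above (below) a
community-specific percentile threshold.  Daytime events are detected on the
daily maximum temperature, nighttime events on the daily minimum.  The daily
minimum recorded on calendar day *t* occurs in the early morning, i.e. during
the night preceding that day's maximum, so the night paired with daytime *t*
is represented by ``tmin[t]`` and every day receives exactly one of four
labels:

====================  =========================================
``compound``          day and (preceding) night both qualifying
``daytime_only``      day qualifying, night not
``nighttime_only``    night qualifying, day not
``none``              neither
====================  =========================================

Heat waves are searched within the hot season (May-September), cold spells
within the cold season (November-March); cold-season blocks span the turn of
the year and runs may cross 31 December.  Missing temperature days break runs
and are excluded from threshold computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HEAT_WAVE = "heat_wave"
COLD_SPELL = "cold_spell"

HEAT_PERCENTILES = (75.0, 77.5, 80.0, 82.5, 85.0, 87.5, 90.0, 92.5, 95.0)
COLD_PERCENTILES = (25.0, 22.5, 20.0, 17.5, 15.0, 12.5, 10.0, 7.5, 5.0)
DURATIONS = (2, 3)

HOT_SEASON_MONTHS = (5, 6, 7, 8, 9)
COLD_SEASON_MONTHS = (11, 12, 1, 2, 3)

EVENT_TYPES = ("daytime_only", "nighttime_only", "compound")

#: humidity strata assigned on event days
LOW, HIGH, NOT_APPLICABLE = "low", "high", "not_applicable"


@dataclass(frozen=True)
class EventDefinition:
    """One (kind, percentile threshold, minimum duration) event rule."""

    kind: str
    percentile: float
    min_duration: int

    def __post_init__(self) -> None:
        if self.kind not in (HEAT_WAVE, COLD_SPELL):
            raise ValueError(f"unknown event kind {self.kind!r}")
        allowed = HEAT_PERCENTILES if self.kind == HEAT_WAVE else COLD_PERCENTILES
        if self.percentile not in allowed:
            raise ValueError(
                f"percentile {self.percentile} not in the {self.kind} grid {allowed}"
            )
        if self.min_duration not in DURATIONS:
            raise ValueError("min_duration must be 2 or 3 days")

    @property
    def direction(self) -> str:
        """Comparison direction: 'ge' for heat, 'le' for cold."""
        return "ge" if self.kind == HEAT_WAVE else "le"

    @property
    def severity(self) -> float:
        """Distance of the threshold percentile from the median (tie-break key)."""
        return abs(self.percentile - 50.0)

    def label(self) -> str:
        return f"{self.kind}_p{self.percentile:g}_d{self.min_duration}"


def enumerate_definitions(kind: str) -> list[EventDefinition]:
    """All 18 definitions of one kind: 9 percentiles x 2 durations.

    Order is deterministic: ascending severity (percentile ascending for heat
    waves, descending for cold spells), then duration 2 before 3.
    """
    if kind == HEAT_WAVE:
        percentiles = HEAT_PERCENTILES
    elif kind == COLD_SPELL:
        percentiles = COLD_PERCENTILES
    else:
        raise ValueError(f"unknown event kind {kind!r}")
    return [
        EventDefinition(kind, p, d) for p in percentiles for d in DURATIONS
    ]


def season_mask(dates: pd.Series | pd.DatetimeIndex, kind: str) -> np.ndarray:
    """Boolean mask of days inside the analysis season for ``kind``."""
    months = pd.DatetimeIndex(dates).month
    if kind == HEAT_WAVE:
        return np.isin(months, HOT_SEASON_MONTHS)
    if kind == COLD_SPELL:
        return np.isin(months, COLD_SEASON_MONTHS)
    raise ValueError(f"unknown event kind {kind!r}")


def season_blocks(dates: pd.Series | pd.DatetimeIndex, kind: str) -> list[np.ndarray]:
    """Positional index arrays of contiguous in-season runs of days.

    Cold-season blocks continue across 31 December.  A gap in the supplied
    dates (missing day) starts a new block: runs never bridge a gap.
    """
    dates = pd.DatetimeIndex(dates)
    mask = season_mask(dates, kind)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    day = dates.asi8 // 86_400_000_000_000
    breaks = np.flatnonzero((np.diff(idx) != 1) | (np.diff(day[idx]) != 1)) + 1
    return [np.asarray(b) for b in np.split(idx, breaks)]


def compute_threshold(values: np.ndarray, percentile: float) -> float:
    """Empirical percentile of season-restricted temperatures.

    Uses the linear-interpolation quantile rule (the common default of
    mainstream statistical software).  Missing values are ignored.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("cannot compute a threshold from all-missing input")
    if values.size < 30:
        logger.warning("threshold computed from only %d non-missing days", values.size)
    return float(np.quantile(values, percentile / 100.0))


def flag_event_days(
    series: np.ndarray,
    threshold: float,
    direction: str,
    min_duration: int,
) -> np.ndarray:
    """Flag days belonging to a maximal qualifying run of >= ``min_duration`` days.

    ``direction`` is ``'ge'`` (heat) or ``'le'`` (cold).  The input is assumed
    contiguous in time; missing (NaN) days break runs.
    """
    x = np.asarray(series, dtype=float)
    if direction == "ge":
        meets = x >= threshold
    elif direction == "le":
        meets = x <= threshold
    else:
        raise ValueError("direction must be 'ge' or 'le'")
    meets &= np.isfinite(x)
    flags = np.zeros(x.size, dtype=bool)
    i = 0
    n = x.size
    while i < n:
        if meets[i]:
            j = i
            while j < n and meets[j]:
                j += 1
            if j - i >= min_duration:
                flags[i:j] = True
            i = j
        else:
            i += 1
    return flags


def classify_events(day_flags: np.ndarray, night_flags: np.ndarray) -> np.ndarray:
    """Per-day three-way event label from aligned daytime/nighttime flags.

    Under the paired-night convention (the minimum recorded on day *t* is the
    night preceding that day's maximum), compound(t) = day(t) AND night(t).
    """
    day_flags = np.asarray(day_flags, dtype=bool)
    night_flags = np.asarray(night_flags, dtype=bool)
    if day_flags.shape != night_flags.shape:
        raise ValueError("day and night flags are misaligned")
    out = np.full(day_flags.shape, "none", dtype=object)
    out[day_flags & ~night_flags] = "daytime_only"
    out[~day_flags & night_flags] = "nighttime_only"
    out[day_flags & night_flags] = "compound"
    return out


def build_event_calendar(
    dates: pd.Series | pd.DatetimeIndex,
    tmax: np.ndarray,
    tmin: np.ndarray,
    definition: EventDefinition,
) -> pd.DataFrame:
    """Apply one definition to a daily series and label every day.

    Thresholds are the definition's percentile of the community's own
    season-restricted days pooled over all years (daytime threshold from tmax,
    nighttime from tmin).  Returns a frame aligned to ``dates`` with columns
    ``date, kind, day_flag, night_flag, event_type, humidity_stratum``;
    out-of-season days are labelled ``none``.
    """
    dates = pd.DatetimeIndex(dates)
    tmax = np.asarray(tmax, dtype=float)
    tmin = np.asarray(tmin, dtype=float)
    if not (dates.size == tmax.size == tmin.size):
        raise ValueError("dates, tmax and tmin must be aligned")
    mask = season_mask(dates, definition.kind)
    day_thr = compute_threshold(tmax[mask], definition.percentile)
    night_thr = compute_threshold(tmin[mask], definition.percentile)
    day_flags = np.zeros(dates.size, dtype=bool)
    night_flags = np.zeros(dates.size, dtype=bool)
    for block in season_blocks(dates, definition.kind):
        day_flags[block] = flag_event_days(
            tmax[block], day_thr, definition.direction, definition.min_duration
        )
        night_flags[block] = flag_event_days(
            tmin[block], night_thr, definition.direction, definition.min_duration
        )
    return pd.DataFrame(
        {
            "date": dates,
            "kind": definition.kind,
            "day_flag": day_flags,
            "night_flag": night_flags,
            "event_type": classify_events(day_flags, night_flags),
            "humidity_stratum": NOT_APPLICABLE,
        }
    )


def split_by_humidity(
    calendar: pd.DataFrame, rh: np.ndarray, cutoff: float
) -> pd.DataFrame:
    """Assign each event day to the low/high relative-humidity stratum.

    Event days with rh >= cutoff go to the high stratum (ties high); non-event
    days stay ``not_applicable``.  Event days with missing rh get stratum
    ``missing`` and are logged.
    """
    if not np.isfinite(cutoff):
        raise ValueError("humidity cutoff must be finite")
    rh = np.asarray(rh, dtype=float)
    if rh.size != len(calendar):
        raise ValueError("rh series misaligned with calendar")
    out = calendar.copy()
    stratum = np.full(len(out), NOT_APPLICABLE, dtype=object)
    is_event = (out["event_type"] != "none").to_numpy()
    missing = is_event & ~np.isfinite(rh)
    if missing.any():
        logger.warning("%d event days have missing relative humidity", missing.sum())
        stratum[missing] = "missing"
    ok = is_event & np.isfinite(rh)
    stratum[ok & (rh >= cutoff)] = HIGH
    stratum[ok & (rh < cutoff)] = LOW
    out["humidity_stratum"] = stratum
    return out


def national_rh_median(panels: list[pd.DataFrame], season: str = "both") -> float:
    """Pooled median relative humidity across all community-days.

    ``season`` restricts pooling to the analysis seasons: ``'both'`` (union of
    the hot and cold seasons, the default national cutoff), ``'heat_wave'``
    (May-September) or ``'cold_spell'`` (November-March).
    """
    if not panels:
        raise ValueError("at least one community panel is required")
    pooled = []
    for panel in panels:
        rh = panel["rh"].to_numpy(dtype=float)
        if season == "both":
            m = season_mask(panel["date"], HEAT_WAVE) | season_mask(
                panel["date"], COLD_SPELL
            )
        else:
            m = season_mask(panel["date"], season)
        pooled.append(rh[m])
    return float(np.nanmedian(np.concatenate(pooled)))


def annual_event_days(calendar: pd.DataFrame) -> dict[str, float]:
    """Mean number of event days per year, by event type.

    The divisor is the number of distinct calendar years the calendar spans.
    """
    out = {t: 0.0 for t in EVENT_TYPES}
    if len(calendar) == 0:
        return out
    n_years = pd.DatetimeIndex(calendar["date"]).year.nunique()
    counts = calendar["event_type"].value_counts()
    for t in EVENT_TYPES:
        out[t] = float(counts.get(t, 0)) / n_years
    return out
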