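"""Calendar and slot-accounting utilities.

All timestamps are UTC on the Gregorian calendar (leap days, no leap
seconds).  The analysis works on a fixed daily "daylight window", a
half-open hour interval such as [06:00, 18:00), sampled at a regular
sub-hourly cadence (15 min by default, the SEVIRI repeat cycle).  The
year is divided into 36 dekads (10-day periods), the last one absorbing
the remainder of the year (days 351 to 365/366).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

#: default daylight window, half-open [start, stop) in whole UTC hours
DAYLIGHT_WINDOW: tuple[int, int] = (6, 18)

#: boreal summer months (June-July-August)
JJA: tuple[int, ...] = (6, 7, 8)


def dekad_of_doy(doy):
    """Dekad index (1..36) for a day-of-year; dekad 36 absorbs days 351+."""
    return np.minimum((np.asarray(doy) - 1) // 10 + 1, 36)


def dekad_of(timestamps) -> np.ndarray:
    """Dekad index (1..36) of each timestamp."""
    idx = pd.DatetimeIndex(np.atleast_1d(np.asarray(timestamps, dtype="datetime64[ns]")))
    return dekad_of_doy(idx.dayofyear.to_numpy())


def dekad_mid_doy(dekad: int) -> float:
    """Mid-point day-of-year of a dekad (dekad 36 uses the 365-day midpoint)."""
    if not 1 <= dekad <= 36:
        raise ValueError(f"dekad must be in 1..36, got {dekad}")
    if dekad < 36:
        return (dekad - 1) * 10 + 5.5
    return (350 + 366) / 2  # centre of the absorbing final dekad


def decimal_year(timestamps) -> np.ndarray:
    """Convert timestamps to decimal years (year + elapsed fraction)."""
    idx = pd.DatetimeIndex(np.atleast_1d(np.asarray(timestamps, dtype="datetime64[ns]")))
    year_start = pd.to_datetime({"year": idx.year, "month": 1, "day": 1})
    year_end = pd.to_datetime({"year": idx.year + 1, "month": 1, "day": 1})
    frac = (idx.asi8 - year_start.astype("int64")) / (
        year_end.astype("int64") - year_start.astype("int64")
    )
    return idx.year.to_numpy() + frac.to_numpy()


@dataclass(frozen=True)
class SlotCalendar:
    """A regular observation calendar: dates × daily slots.

    Parameters
    ----------
    start, end : datetime.date
        First and last calendar day, both inclusive.
    cadence_minutes : int
        Slot spacing; must divide 60.
    daylight : (int, int)
        Half-open hour window [h0, h1) retained each day.
    months : tuple of int, optional
        If given, only days whose calendar month is in this set are kept
        (e.g. ``(6, 7, 8)`` for JJA).
    """

    start: date
    end: date
    cadence_minutes: int = 15
    daylight: tuple[int, int] = DAYLIGHT_WINDOW
    months: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"calendar end {self.end} precedes start {self.start}")
        if 60 % self.cadence_minutes != 0:
            raise ValueError("cadence_minutes must divide 60")
        h0, h1 = self.daylight
        if not (0 <= h0 < h1 <= 24):
            raise ValueError(f"invalid daylight window {self.daylight}")

    @property
    def slots_per_day(self) -> int:
        h0, h1 = self.daylight
        return (h1 - h0) * 60 // self.cadence_minutes

    def days(self) -> pd.DatetimeIndex:
        d = pd.date_range(self.start, self.end, freq="D")
        if self.months is not None:
            d = d[d.month.isin(self.months)]
        return d

    def timestamps(self) -> pd.DatetimeIndex:
        """Explicit enumeration of every retained slot (brute force)."""
        h0, _ = self.daylight
        offs = (
            np.arange(self.slots_per_day) * np.timedelta64(self.cadence_minutes, "m")
            + np.timedelta64(h0, "h")
        )
        days = self.days().values[:, None]
        return pd.DatetimeIndex((days + offs[None, :]).ravel())


def count_slots(calendar: SlotCalendar) -> int:
    """Exact retained-slot count: (number of kept days) × (slots per day)."""
    return len(calendar.days()) * calendar.slots_per_day
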