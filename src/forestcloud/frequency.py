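"""Cloud-frequency surfaces and box series from cloud-mask stacks.

Cloud frequency is the fraction of *valid* daytime slots flagged cloudy
(missing slots are excluded from numerator and denominator).  Box
statistics average the per-pixel frequency over the box pixels; the
non-forest reference pools its boxes with equal weight per box.
Frequency maps keep their integer cloudy/valid counts so that composites
recombine exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CLOUD, MISSING, Box, CloudMaskStack
from .timeutils import JJA, dekad_of_doy

__all__ = [
    "FrequencyMap",
    "frequency_map",
    "box_daily_series",
    "box_dekadal_series",
    "dekadal_difference_series",
    "diurnal_cycle",
    "day_bin_table",
]



def _nanmean(a, axis=None):
    """nanmean that stays quiet on all-NaN slices (result NaN)."""
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(a, axis=axis)


class EmptyWindowError(ValueError):
    """No slots fall inside the requested season/hour window."""


@dataclass
class FrequencyMap:
    """Per-pixel cloud frequency over a time window.

    ``values`` = n_cloud / n_valid (NaN where no valid slot); the integer
    count fields are retained so that weighted recombinations of several
    maps reproduce a pooled map bit-exactly.
    """

    n_cloud: np.ndarray
    n_valid: np.ndarray
    window: str = ""

    @property
    def values(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n_valid > 0, self.n_cloud / self.n_valid, np.nan)

    def box_mean(self, box: Box) -> float:
        return float(_nanmean(self.values[Box(*box).slices()]))


def _select(masks: CloudMaskStack, season=None, hours=None) -> np.ndarray:
    keep = np.ones(len(masks.times), dtype=bool)
    if season is not None:
        keep &= masks.times.month.isin(tuple(season))
    if hours is not None:
        h0, h1 = hours
        h = masks.times.hour.to_numpy()
        keep &= (h >= h0) & (h < h1)
    return keep


def _counts(flags: np.ndarray, axis=0) -> tuple[np.ndarray, np.ndarray]:
    n_cloud = (flags == CLOUD).sum(axis=axis)
    n_valid = (flags != MISSING).sum(axis=axis)
    return n_cloud, n_valid


def frequency_map(
    masks: CloudMaskStack,
    season: tuple[int, ...] | None = None,
    hours: tuple[int, int] | None = None,
    window: str = "",
) -> FrequencyMap:
    """Per-pixel cloudy/(cloudy+clear) fraction over a season × hour window."""
    keep = _select(masks, season, hours)
    if not keep.any():
        raise EmptyWindowError("no slots in the requested window")
    n_cloud, n_valid = _counts(masks.flags[keep])
    return FrequencyMap(n_cloud=n_cloud, n_valid=n_valid, window=window)


def _box_day_pixel_freq(
    masks: CloudMaskStack, box: Box, season=None, hours=None
) -> tuple[pd.DatetimeIndex, np.ndarray, np.ndarray]:
    """Per (day, pixel) cloudy and valid counts inside a box."""
    keep = _select(masks, season, hours)
    if not keep.any():
        raise EmptyWindowError("no slots in the requested window")
    rs, cs = Box(*box).slices()
    flags = masks.flags[keep][:, rs, cs]
    days = masks.times[keep].normalize()
    uniq, inv = np.unique(days.values, return_inverse=True)
    nday = len(uniq)
    npix = flags.shape[1] * flags.shape[2]
    flat = flags.reshape(len(days), npix)
    n_cloud = np.zeros((nday, npix), dtype=np.int64)
    n_valid = np.zeros((nday, npix), dtype=np.int64)
    np.add.at(n_cloud, inv, flat == CLOUD)
    np.add.at(n_valid, inv, flat != MISSING)
    return pd.DatetimeIndex(uniq), n_cloud, n_valid


def box_daily_series(
    masks: CloudMaskStack,
    box: Box,
    season: tuple[int, ...] | None = None,
    hours: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Daily box series: mean over box pixels of the day's per-pixel frequency.

    Returns a DataFrame indexed by day with columns ``value`` (NaN where
    the day has no valid slot) and ``n`` (valid slots summed over box
    pixels).
    """
    days, n_cloud, n_valid = _box_day_pixel_freq(masks, box, season, hours)
    with np.errstate(invalid="ignore", divide="ignore"):
        pix_freq = np.where(n_valid > 0, n_cloud / n_valid, np.nan)
    value = _nanmean(pix_freq, axis=1) if pix_freq.size else np.array([])
    return pd.DataFrame({"value": value, "n": n_valid.sum(axis=1)}, index=days)


def box_dekadal_series(
    masks: CloudMaskStack,
    box: Box,
    season: tuple[int, ...] | None = None,
    hours: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Dekadal box series (calendar year-dekad periods).

    Each dekad value is the box mean of the per-pixel frequency pooled
    over the dekad's days, i.e. the slot-weighted mean of the daily
    values.  Indexed by the mid-dekad timestamp.
    """
    days, n_cloud, n_valid = _box_day_pixel_freq(masks, box, season, hours)
    key = days.year.to_numpy() * 100 + (dekad_of_doy(days.dayofyear.to_numpy()))
    uniq, inv = np.unique(key, return_inverse=True)
    nc = np.zeros((len(uniq), n_cloud.shape[1]), dtype=np.int64)
    nv = np.zeros_like(nc)
    np.add.at(nc, inv, n_cloud)
    np.add.at(nv, inv, n_valid)
    with np.errstate(invalid="ignore", divide="ignore"):
        pix = np.where(nv > 0, nc / nv, np.nan)
    value = _nanmean(pix, axis=1)
    mid = [_dekad_mid_timestamp(k) for k in uniq]
    return pd.DataFrame({"value": value, "n": nv.sum(axis=1)}, index=pd.DatetimeIndex(mid))


def _dekad_mid_timestamp(key: int) -> pd.Timestamp:
    year, dekad = divmod(int(key), 100)
    from .timeutils import dekad_mid_doy

    return pd.Timestamp(f"{year}-01-01") + pd.Timedelta(days=dekad_mid_doy(dekad) - 1)


def dekadal_difference_series(
    masks: CloudMaskStack,
    forest_box: Box,
    nonforest_boxes: list[Box],
    season: tuple[int, ...] | None = None,
    hours: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Per dekad: forest box frequency minus the non-forest reference.

    The reference is the equal-weight mean of the non-forest box means
    (per box, not per pixel).
    """
    forest = box_dekadal_series(masks, forest_box, season, hours)
    refs = [box_dekadal_series(masks, b, season, hours) for b in nonforest_boxes]
    ref_value = sum(r["value"] for r in refs) / len(refs)
    out = pd.DataFrame(
        {
            "value": forest["value"] - ref_value,
            "n": forest["n"] + sum(r["n"] for r in refs),
        },
        index=forest.index,
    )
    return out


def diurnal_cycle(
    masks: CloudMaskStack,
    box: Box,
    season: tuple[int, ...] | None = JJA,
    hours: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Mean frequency per integer UTC hour over the box and season days."""
    keep = _select(masks, season, hours)
    if not keep.any():
        raise EmptyWindowError("no slots in the requested window")
    rs, cs = Box(*box).slices()
    flags = masks.flags[keep][:, rs, cs]
    hour = masks.times[keep].hour.to_numpy()
    uniq, inv = np.unique(hour, return_inverse=True)
    npix = flags.shape[1] * flags.shape[2]
    flat = flags.reshape(len(hour), npix)
    n_cloud = np.zeros((len(uniq), npix), dtype=np.int64)
    n_valid = np.zeros_like(n_cloud)
    np.add.at(n_cloud, inv, flat == CLOUD)
    np.add.at(n_valid, inv, flat != MISSING)
    with np.errstate(invalid="ignore", divide="ignore"):
        pix = np.where(n_valid > 0, n_cloud / n_valid, np.nan)
    value = _nanmean(pix, axis=1)
    return pd.DataFrame({"value": value, "n": n_valid.sum(axis=1)}, index=pd.Index(uniq, name="hour"))


def day_bin_table(
    masks: CloudMaskStack,
    box: Box,
    by: str,
    season: tuple[int, ...] | None = None,
    hours: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Day × bin matrix of box-mean frequency, for day-resampling bootstraps.

    ``by`` is ``"hour"`` (each day contributes its box-mean frequency at
    each UTC hour) or ``"dekad"`` (each day contributes one value, in
    its year-dekad column).  Cells with no valid slot are NaN.
    """
    keep = _select(masks, season, hours)
    if not keep.any():
        raise EmptyWindowError("no slots in the requested window")
    rs, cs = Box(*box).slices()
    flags = masks.flags[keep][:, rs, cs]
    times = masks.times[keep]
    days = times.normalize()
    uniq_days, day_inv = np.unique(days.values, return_inverse=True)
    if by == "hour":
        col_key = times.hour.to_numpy()
    elif by == "dekad":
        col_key = dekad_of_doy(times.dayofyear.to_numpy())
    else:
        raise ValueError("by must be 'hour' or 'dekad'")
    uniq_cols, col_inv = np.unique(col_key, return_inverse=True)
    npix = flags.shape[1] * flags.shape[2]
    flat = flags.reshape(len(times), npix)
    cell = day_inv * len(uniq_cols) + col_inv
    n_cloud = np.zeros((len(uniq_days) * len(uniq_cols), npix), dtype=np.int64)
    n_valid = np.zeros_like(n_cloud)
    np.add.at(n_cloud, cell, flat == CLOUD)
    np.add.at(n_valid, cell, flat != MISSING)
    with np.errstate(invalid="ignore", divide="ignore"):
        pix = np.where(n_valid > 0, n_cloud / n_valid, np.nan)
    with np.errstate(invalid="ignore"):
        vals = _nanmean(pix, axis=1).reshape(len(uniq_days), len(uniq_cols))
    return pd.DataFrame(vals, index=pd.DatetimeIndex(uniq_days), columns=uniq_cols)
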