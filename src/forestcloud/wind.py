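"""Wind-conditioned cloud-frequency composites.

Days are classified by the regional daily 10-m meridional wind
(default classes v < −1, −1 ≤ v ≤ 1, v > 1 m s⁻¹; positive v blows from
south to north) and optionally into 8 direction sectors (meteorological
convention: the direction the wind blows FROM).  Per class, the cloud
frequency map is recomputed over that class's days; because the maps
carry integer cloudy/valid counts, the class composites recombine
exactly to the all-days map.  Each class map gets its own 90th-percentile
level and exceedance mask, which accounts for differences in mean
cloudiness between wind regimes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import WATER, CloudMaskStack, LandCoverMap
from .frequency import FrequencyMap, _counts, _select
from .timeutils import JJA

__all__ = [
    "SECTOR_NAMES",
    "DayClassification",
    "CompositeResult",
    "classify_days",
    "composite_frequency",
    "class_percentile_level",
    "sector_from_direction",
    "wind_sector",
    "recombine",
    "exceedance_centroid",
]

SECTOR_NAMES = ("N", "NE", "E", "SE", "S", "SW", "W", "NW")


@dataclass
class DayClassification:
    """Per-day wind class labels.

    ``table`` is indexed by day with columns ``v10``, ``u10``,
    ``speed_class`` and ``sector``; ``class_days`` maps each speed-class
    label to its days.
    """

    table: pd.DataFrame
    edges: tuple[float, ...]

    @property
    def labels(self) -> list[str]:
        return _class_labels(self.edges)

    def class_days(self, label: str) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.table.index[self.table["speed_class"] == label])

    def counts(self) -> pd.Series:
        return self.table["speed_class"].value_counts().reindex(self.labels, fill_value=0)


def _class_labels(edges) -> list[str]:
    e = list(edges)
    labels = [f"v<{e[0]:g}"]
    labels += [f"{a:g}<=v<={b:g}" for a, b in zip(e[:-1], e[1:])]
    labels.append(f"v>{e[-1]:g}")
    return labels


def _speed_class_index(v: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Interval index for each v.

    A value equal to an edge is assigned inward: ties at a positive edge
    go to the lower interval, ties at a non-positive edge to the upper
    one, so a symmetric central class (e.g. −1 ≤ v ≤ 1) is closed on
    both sides.
    """
    idx = np.searchsorted(edges, v, side="right")
    for j, e in enumerate(edges):
        if e > 0:
            idx[v == e] = j
    return idx


def sector_from_direction(met_dir_degrees) -> np.ndarray:
    """8-sector label for a meteorological direction (degrees FROM north).

    Sectors are 45° wide and centred on the compass points (N covers
    (337.5°, 22.5°]); a boundary value belongs to the lower sector.
    """
    d = np.asarray(met_dir_degrees, float) % 360.0
    idx = np.ceil((d - 22.5) / 45.0).astype(int) % 8
    return np.array(SECTOR_NAMES)[idx]


def wind_sector(u, v) -> np.ndarray:
    """8-sector label of the direction the wind blows FROM, given u/v."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    return sector_from_direction(np.degrees(np.arctan2(-u, -v)))


def classify_days(
    wind: pd.DataFrame, edges: tuple[float, ...] = (-1.0, 1.0)
) -> DayClassification:
    """Label every day of a daily u10/v10 series by meridional-wind class."""
    if len(wind) == 0:
        raise ValueError("empty wind series")
    edges_arr = np.asarray(sorted(edges), float)
    w = wind.copy()
    w.index = pd.DatetimeIndex(w.index).normalize()
    v = w["v10"].to_numpy(float)
    labels = np.array(_class_labels(edges_arr))
    table = pd.DataFrame(
        {
            "u10": w["u10"].to_numpy(float),
            "v10": v,
            "speed_class": labels[_speed_class_index(v, edges_arr)],
            "sector": wind_sector(w["u10"].to_numpy(float), v),
        },
        index=w.index,
    )
    return DayClassification(table=table, edges=tuple(edges_arr))


@dataclass
class CompositeResult:
    """One wind-class composite: map, day count, q90 level + exceedance."""

    label: str
    freq: FrequencyMap
    n_days: int
    q90_level: float
    exceedance: np.ndarray
    mean_u: float
    mean_v: float


def class_percentile_level(
    fmap: FrequencyMap, q: float = 90.0, domain: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Empirical q-quantile (linear interpolation) of the map's valid pixels
    and the mask of pixels at or above it."""
    vals = fmap.values
    valid = np.isfinite(vals)
    if domain is not None:
        valid &= domain
    if valid.sum() < 10:
        raise ValueError(f"only {int(valid.sum())} valid pixels; need >= 10")
    level = float(np.quantile(vals[valid], q / 100.0, method="linear"))
    mask = np.zeros(vals.shape, dtype=bool)
    mask[valid] = vals[valid] >= level
    return level, mask


def composite_frequency(
    masks: CloudMaskStack,
    classification: DayClassification,
    season: tuple[int, ...] | None = JJA,
    hours: tuple[int, int] | None = None,
    min_days: int = 1,
    landcover: LandCoverMap | None = None,
    q: float = 90.0,
) -> dict[str, CompositeResult]:
    """Per-wind-class frequency maps with 90th-percentile exceedance masks.

    The quantile domain excludes water pixels when a land-cover map is
    supplied.  Classes with fewer than ``min_days`` days in the window
    are dropped with a warning.
    """
    keep = _select(masks, season, hours)
    days = masks.times.normalize()
    domain = None if landcover is None else ~landcover.mask(WATER)
    out: dict[str, CompositeResult] = {}
    for label in classification.labels:
        cdays = classification.class_days(label)
        sel = keep & days.isin(cdays)
        n_days = len(np.unique(days[sel].values))
        if n_days < min_days or sel.sum() == 0:
            warnings.warn(f"wind class {label!r}: {n_days} day(s) in window; dropped",
                          stacklevel=2)
            continue
        n_cloud, n_valid = _counts(masks.flags[sel])
        fmap = FrequencyMap(n_cloud=n_cloud, n_valid=n_valid, window=label)
        level, exceed = class_percentile_level(fmap, q=q, domain=domain)
        sub = classification.table.loc[classification.table.index.isin(days[sel])]
        out[label] = CompositeResult(
            label=label,
            freq=fmap,
            n_days=n_days,
            q90_level=level,
            exceedance=exceed,
            mean_u=float(sub["u10"].mean()),
            mean_v=float(sub["v10"].mean()),
        )
    if not out:
        raise ValueError("no wind class retained any days in the window")
    return out


def recombine(composites: dict[str, CompositeResult]) -> FrequencyMap:
    """Slot-weighted recombination of class maps (sums the integer counts),
    identical to the map computed over the union of the class days."""
    labels = list(composites)
    n_cloud = sum(composites[k].freq.n_cloud for k in labels)
    n_valid = sum(composites[k].freq.n_valid for k in labels)
    return FrequencyMap(n_cloud=n_cloud, n_valid=n_valid, window="recombined")


def exceedance_centroid(mask: np.ndarray) -> tuple[float, float]:
    """(row, col) centroid of an exceedance mask."""
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("empty exceedance mask")
    return float(rows.mean()), float(cols.mean())
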