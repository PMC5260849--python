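"""In-memory containers shared across pipeline stages.

Rasters are north-up numpy arrays (row 0 = north) on an abstract km grid
(1 px = 1 km by default; no map projection).  Image stacks are dense
``(time, y, x)`` arrays whose time axis holds only the retained daylight
slots.  Cloud-mask flags use the byte convention 0 = clear, 1 = cloud,
255 = missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

# land-cover class codes
FOREST = 1
NONFOREST = 2
WATER = 3

# cloud-mask flag codes
CLEAR = 0
CLOUD = 1
MISSING = 255

#: sentinel for a missing digital count (counts are 10-bit, 0..1023)
COUNT_FILL = -1


class Box(NamedTuple):
    """Half-open pixel rectangle [r0, r1) × [c0, c1)."""

    r0: int
    r1: int
    c0: int
    c1: int

    def slices(self) -> tuple[slice, slice]:
        return slice(self.r0, self.r1), slice(self.c0, self.c1)

    @property
    def npix(self) -> int:
        return (self.r1 - self.r0) * (self.c1 - self.c0)

    def contains(self, other: "Box") -> bool:
        return (
            self.r0 <= other.r0
            and other.r1 <= self.r1
            and self.c0 <= other.c0
            and other.c1 <= self.c1
        )


@dataclass
class LandCoverMap:
    """Categorical land-cover raster with named analysis boxes.

    Attributes
    ----------
    classes : (ny, nx) uint8 array of FOREST / NONFOREST / WATER codes.
    boxes : mapping of box name to :class:`Box` (pixel coordinates).
    damage_zone : optional :class:`Box`, the storm-damaged sub-rectangle
        of the forest (windthrow area).
    pixel_km : pixel edge length in km.
    """

    classes: np.ndarray
    boxes: dict[str, Box] = field(default_factory=dict)
    damage_zone: Box | None = None
    pixel_km: float = 1.0

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=np.uint8)
        if self.classes.ndim != 2:
            raise ValueError("classes raster must be 2-D")
        valid = np.isin(self.classes, (FOREST, NONFOREST, WATER))
        if not valid.all():
            raise ValueError("class raster has unassigned pixels")
        ny, nx = self.classes.shape
        grid = Box(0, ny, 0, nx)
        for name, box in self.boxes.items():
            if not grid.contains(Box(*box)):
                raise ValueError(f"box {name!r} {box} outside {ny}x{nx} grid")
        if self.damage_zone is not None:
            dz = Box(*self.damage_zone)
            if not grid.contains(dz):
                raise ValueError(f"damage_zone {dz} outside grid")
            if not (self.classes[dz.slices()] == FOREST).all():
                raise ValueError("damage_zone must lie entirely inside forest")

    @property
    def shape(self) -> tuple[int, int]:
        return self.classes.shape

    def mask(self, cls: int) -> np.ndarray:
        return self.classes == cls


@dataclass
class CountStack:
    """Stack of integer digital counts at the retained daylight slots.

    ``counts`` is an int16 ``(time, ny, nx)`` array; missing observations
    carry the sentinel :data:`COUNT_FILL`.
    """

    times: pd.DatetimeIndex
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.times = pd.DatetimeIndex(self.times)
        self.counts = np.asarray(self.counts, dtype=np.int16)
        if self.counts.ndim != 3 or self.counts.shape[0] != len(self.times):
            raise ValueError("counts must be (time, y, x) aligned with times")
        if len(self.times) and not self.times.is_monotonic_increasing:
            raise ValueError("timestamps must be increasing")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.counts.shape

    def valid(self) -> np.ndarray:
        return self.counts != COUNT_FILL


@dataclass
class CloudMaskStack:
    """Per-slot cloud flags (0 clear / 1 cloud / 255 missing), uint8."""

    times: pd.DatetimeIndex
    flags: np.ndarray
    threshold_counts: int | None = None

    def __post_init__(self) -> None:
        self.times = pd.DatetimeIndex(self.times)
        self.flags = np.asarray(self.flags, dtype=np.uint8)
        if self.flags.ndim != 3 or self.flags.shape[0] != len(self.times):
            raise ValueError("flags must be (time, y, x) aligned with times")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.flags.shape

    @classmethod
    def from_bool(
        cls,
        times,
        cloud: np.ndarray,
        missing: np.ndarray | None = None,
        threshold_counts: int | None = None,
    ) -> "CloudMaskStack":
        flags = np.where(cloud, CLOUD, CLEAR).astype(np.uint8)
        if missing is not None:
            flags[missing] = MISSING
        return cls(times, flags, threshold_counts)
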