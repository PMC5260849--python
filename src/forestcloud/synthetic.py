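"""Synthetic geostationary scenes with known cloud truth.

The generator emulates, statistically, the ingredients of a broadband
visible (HRV-like) record over a flat forest/cropland landscape:

* a per-pixel clear-sky digital-count level that rises with surface
  albedo (forest is the dark class) and follows smooth diurnal and
  seasonal cycles, constant within each (dekad, hour) bin;
* Bernoulli cloud occurrence per pixel and 15-min slot, with a summer
  (JJA) probability enhancement over forest of order 0.05-0.15;
* downwind displacement of the enhancement field by an integer pixel
  offset proportional to the daily regional 10-m wind;
* an optional "windthrow" breakpoint: after the storm date the
  enhancement inside the damage zone collapses to a small residual;
* additive count brightening for cloudy pixels plus Gaussian sensor
  noise, quantised to 10-bit integer counts.

Everything is driven by a single integer seed; a given configuration is
bit-reproducible.  The wind series is an *input* (daily u10/v10); when
none is supplied a plausible one is drawn from the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from datetime import date

import numpy as np
import pandas as pd

from .containers import (
    COUNT_FILL,
    FOREST,
    NONFOREST,
    WATER,
    Box,
    CountStack,
    LandCoverMap,
)
from .timeutils import JJA, SlotCalendar, dekad_mid_doy, dekad_of_doy

__all__ = [
    "SimConfig",
    "TruthStack",
    "build_landcover",
    "demo_landcover",
    "simulate_truth",
    "render_counts",
    "simulate_scene",
    "draw_wind",
    "synthesize_dekadal_difference",
    "with_seed",
]


@dataclass(frozen=True)
class SimConfig:
    """Generator settings.  Defaults are the study conditions.

    Probabilities are per 15-min slot; counts are 10-bit digital counts.
    ``albedo_*`` ranges bracket the broadband surface albedos of the two
    land classes; a single value per class is drawn from its range.
    """

    start: date = date(2004, 1, 1)
    years: int = 2
    daylight_window: tuple[int, int] = (6, 18)
    cadence_minutes: int = 15
    albedo_forest: tuple[float, float] = (0.11, 0.14)
    albedo_nonforest: tuple[float, float] = (0.16, 0.19)
    albedo_water: float = 0.06
    clear_base_counts: float = 1500.0
    cloud_boost_counts: float = 50.0
    noise_sd: float = 2.0
    p_cloud_base: float = 0.3
    delta_forest_jja: float = 0.10
    diurnal_lead_hours: float = 0.0
    wind_displacement_km_per_ms: float = 2.0
    klaus_date: date | None = None
    klaus_residual_delta: float = 0.020
    missing_rate: float = 0.0
    months: tuple[int, ...] | None = None  # restrict the record to these months
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_cloud_base", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        enh = self.delta_forest_jja
        if self.klaus_date is not None:
            enh = max(enh, self.klaus_residual_delta)
        if not 0.0 <= self.p_cloud_base + enh <= 1.0:
            raise ValueError("p_cloud_base plus enhancement must stay within [0, 1]")
        if not 0.0 <= self.clear_base_counts:
            raise ValueError("clear_base_counts must be non-negative")
        if self.years < 1:
            raise ValueError("years must be >= 1")
        if 60 % self.cadence_minutes != 0:
            raise ValueError("cadence_minutes must divide 60")

    def calendar(self, months: tuple[int, ...] | None = None) -> SlotCalendar:
        months = self.months if months is None else months
        end = (
            pd.Timestamp(self.start) + pd.DateOffset(years=self.years) - pd.Timedelta(days=1)
        ).date()
        return SlotCalendar(
            start=self.start,
            end=end,
            cadence_minutes=self.cadence_minutes,
            daylight=self.daylight_window,
            months=months,
        )


@dataclass
class TruthStack:
    """Ground truth of a simulated record.

    ``clearsky_counts`` is the integer-valued clear-sky level per pixel
    and (dekad, daylight-hour) bin; ``true_cloud`` the Bernoulli cloud
    field per retained slot; ``wind`` the daily u10/v10 series used.
    """

    times: pd.DatetimeIndex
    clearsky_counts: np.ndarray  # (36, n_hours, ny, nx) float32, integer-valued
    true_cloud: np.ndarray  # (nt, ny, nx) bool
    wind: pd.DataFrame  # index: date; columns u10, v10 [m s-1]
    landcover: LandCoverMap
    config: SimConfig

    def cloud_mask_stack(self):
        """Truth as a :class:`~forestcloud.containers.CloudMaskStack`."""
        from .containers import CloudMaskStack

        return CloudMaskStack.from_bool(self.times, self.true_cloud)


def build_landcover(
    nx: int,
    ny: int,
    forest_rect: Box | tuple,
    boxes: dict[str, Box | tuple] | None = None,
    damage_rect: Box | tuple | None = None,
    water_rect: Box | tuple | None = None,
    pixel_km: float = 1.0,
) -> LandCoverMap:
    """Assemble a categorical raster: non-forest background + forest rectangle.

    ``damage_rect`` must lie inside ``forest_rect``; all rectangles are
    half-open pixel boxes and must lie inside the grid.
    """
    grid = Box(0, ny, 0, nx)
    forest = Box(*forest_rect)
    if not grid.contains(forest):
        raise ValueError(f"forest_rect {forest} outside {ny}x{nx} grid")
    classes = np.full((ny, nx), NONFOREST, dtype=np.uint8)
    if water_rect is not None:
        w = Box(*water_rect)
        if not grid.contains(w):
            raise ValueError(f"water_rect {w} outside grid")
        classes[w.slices()] = WATER
    classes[forest.slices()] = FOREST
    if damage_rect is not None and not forest.contains(Box(*damage_rect)):
        raise ValueError(f"damage_rect {damage_rect} not inside forest_rect {forest}")
    named = {k: Box(*v) for k, v in (boxes or {}).items()}
    return LandCoverMap(
        classes=classes,
        boxes=named,
        damage_zone=Box(*damage_rect) if damage_rect is not None else None,
        pixel_km=pixel_km,
    )


def demo_landcover(ny: int = 200, nx: int = 200, damage: bool = False) -> LandCoverMap:
    """Default landscape: a large central forest block with one forest and
    two non-forest focus boxes, scaled to the grid.

    At the default 200×200 km grid the forest block is 110×110 km
    (≈12,100 km²), comparable to the larger of the two real study
    regions.
    """

    def rect(fr0, fr1, fc0, fc1):
        return Box(round(fr0 * ny), round(fr1 * ny), round(fc0 * nx), round(fc1 * nx))

    forest = rect(0.25, 0.80, 0.25, 0.80)
    boxes = {
        "forest": rect(0.45, 0.60, 0.45, 0.60),
        "nonforest_1": rect(0.025, 0.175, 0.45, 0.60),
        "nonforest_2": rect(0.45, 0.60, 0.025, 0.175),
    }
    damage_rect = rect(0.30, 0.55, 0.30, 0.55) if damage else None
    return build_landcover(
        nx, ny, forest_rect=forest, boxes=boxes, damage_rect=damage_rect
    )


def _albedo_map(landcover: LandCoverMap, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    a_forest = rng.uniform(*cfg.albedo_forest)
    a_nonforest = rng.uniform(*cfg.albedo_nonforest)
    albedo = np.full(landcover.shape, a_nonforest, dtype=np.float64)
    albedo[landcover.mask(FOREST)] = a_forest
    albedo[landcover.mask(WATER)] = cfg.albedo_water
    return albedo


def _elevation_factor(cfg: SimConfig) -> np.ndarray:
    """Smooth diurnal × seasonal factor per (dekad, daylight hour), in (0, 1]."""
    h0, h1 = cfg.daylight_window
    hours = np.arange(h0, h1)
    diurnal = np.sin(np.pi * (hours + 0.5 - h0) / (h1 - h0))
    mid = np.array([dekad_mid_doy(d) for d in range(1, 37)])
    seasonal = 0.55 + 0.45 * np.cos(2 * np.pi * (mid - 172.0) / 365.25)
    return seasonal[:, None] * diurnal[None, :]


def _clearsky_truth(landcover: LandCoverMap, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    albedo = _albedo_map(landcover, cfg, rng)
    ef = _elevation_factor(cfg)  # (36, nh)
    clear = cfg.clear_base_counts * albedo[None, None, :, :] * ef[:, :, None, None]
    return np.rint(np.clip(clear, 0, 1023)).astype(np.float32)


def _hour_weights(cfg: SimConfig) -> np.ndarray:
    """Diurnal modulation of the forest enhancement, normalised to mean 1.

    With the default ``diurnal_lead_hours == 0`` the enhancement is flat
    over the daylight window (plain Bernoulli p_cloud_base + delta over
    forest).  A positive lead applies a sinusoidal profile shifted
    earlier in the day (earlier cloud onset over forest) whose daily
    mean stays equal to the configured enhancement.
    """
    h0, h1 = cfg.daylight_window
    hours = np.arange(h0, h1)
    if cfg.diurnal_lead_hours == 0:
        return np.ones(len(hours))
    f = np.sin(np.pi * (hours + 0.5 - h0 + cfg.diurnal_lead_hours) / (h1 - h0))
    f = np.clip(f, 0.0, None)
    if f.sum() == 0:
        raise ValueError("diurnal_lead_hours leaves no enhancement in the window")
    return f / f.mean()


def draw_wind(days: pd.DatetimeIndex, rng: np.random.Generator) -> pd.DataFrame:
    """Fallback daily 10-m wind: mild south-westerly bias, iid days."""
    u = rng.normal(0.5, 2.0, len(days))
    v = rng.normal(0.5, 2.5, len(days))
    return pd.DataFrame({"u10": u, "v10": v}, index=days.normalize())


def _shift2d(f: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Shift a 2-D field by integer offsets, zero-filling exposed edges."""
    out = np.zeros_like(f)
    ny, nx = f.shape
    r0s, r1s = max(0, -dr), min(ny, ny - dr)
    c0s, c1s = max(0, -dc), min(nx, nx - dc)
    if r0s < r1s and c0s < c1s:
        out[r0s + dr : r1s + dr, c0s + dc : c1s + dc] = f[r0s:r1s, c0s:c1s]
    return out


def simulate_truth(
    landcover: LandCoverMap,
    cfg: SimConfig,
    wind: pd.DataFrame | None = None,
) -> TruthStack:
    """Draw the ground-truth record (clear-sky levels, cloud field, wind).

    Cloud occurrence is independent Bernoulli per pixel-slot with
    probability ``p_cloud_base``, plus ``delta_forest_jja`` over forest
    pixels during JJA (zero outside JJA), modulated diurnally, displaced
    downwind by ``wind_displacement_km_per_ms × wind`` (rounded to whole
    pixels), and — after ``klaus_date`` — reduced to
    ``klaus_residual_delta`` inside the damage zone.
    """
    cal = cfg.calendar()
    days = cal.days()
    if len(days) == 0:
        raise ValueError("empty record: calendar contains no days")
    times = cal.timestamps()
    ny, nx = landcover.shape
    spd = cal.slots_per_day
    h0, h1 = cfg.daylight_window
    slots_per_hour = 60 // cfg.cadence_minutes

    ss = np.random.SeedSequence(cfg.seed)
    rng_static, rng_wind, rng_cloud = (np.random.default_rng(s) for s in ss.spawn(3))

    clearsky = _clearsky_truth(landcover, cfg, rng_static)
    if wind is None:
        wind = draw_wind(days, rng_wind)
    else:
        wind = wind.copy()
        wind.index = pd.DatetimeIndex(wind.index).normalize()
        missing_days = days.normalize().difference(wind.index)
        if len(missing_days):
            raise ValueError(
                f"wind series missing {len(missing_days)} record days "
                f"(first: {missing_days[0].date()})"
            )

    g = _hour_weights(cfg)  # per daylight hour
    g_slot = np.repeat(g, slots_per_hour)  # per slot of day

    forest = landcover.mask(FOREST).astype(np.float64)
    months = days.month.to_numpy()
    in_jja = np.isin(months, JJA)
    klaus_ts = pd.Timestamp(cfg.klaus_date) if cfg.klaus_date is not None else None

    true_cloud = np.empty((len(times), ny, nx), dtype=bool)
    coeff = cfg.wind_displacement_km_per_ms / landcover.pixel_km
    dz = landcover.damage_zone
    wind_aligned = wind.reindex(days.normalize())
    u_day = wind_aligned["u10"].to_numpy()
    v_day = wind_aligned["v10"].to_numpy()

    for i, day in enumerate(days):
        enh = np.zeros((ny, nx))
        if in_jja[i] and cfg.delta_forest_jja != 0.0:
            enh = cfg.delta_forest_jja * forest
        if (
            in_jja[i]
            and klaus_ts is not None
            and dz is not None
            and day >= klaus_ts
        ):
            enh = enh.copy()
            enh[dz.slices()] = cfg.klaus_residual_delta
        if enh.any():
            # southerly wind (v>0) displaces the enhancement north (row 0 = north)
            dr = -int(np.rint(coeff * v_day[i]))
            dc = int(np.rint(coeff * u_day[i]))
            if dr or dc:
                enh = _shift2d(enh, dr, dc)
            p = np.clip(cfg.p_cloud_base + g_slot[:, None, None] * enh[None, :, :], 0.0, 1.0)
        else:
            p = np.full((spd, 1, 1), cfg.p_cloud_base)
        draws = rng_cloud.random((spd, ny, nx))
        true_cloud[i * spd : (i + 1) * spd] = draws < p

    return TruthStack(
        times=times,
        clearsky_counts=clearsky,
        true_cloud=true_cloud,
        wind=wind,
        landcover=landcover,
        config=cfg,
    )


def render_counts(
    truth: TruthStack, cfg: SimConfig | None = None, detection_threshold: float = 10.0
) -> CountStack:
    """Quantise the truth into a 10-bit digital-count stack.

    count = round(clear-sky + boost·1[cloud] + Gaussian noise), clipped
    to [0, 1023]; missing observations injected at ``missing_rate`` and
    stored as the fill sentinel.
    """
    cfg = truth.config if cfg is None else cfg
    if cfg.cloud_boost_counts <= detection_threshold:
        warnings.warn(
            f"cloud_boost_counts={cfg.cloud_boost_counts} does not exceed the "
            f"downstream detection threshold ({detection_threshold}); clouds "
            "will be undetectable by construction",
            stacklevel=2,
        )
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(4)[3])
    times = truth.times
    nt, ny, nx = truth.true_cloud.shape
    h0, _ = cfg.daylight_window
    dekads = dekad_of_doy(times.dayofyear.to_numpy()) - 1
    hour_idx = times.hour.to_numpy() - h0

    counts = np.empty((nt, ny, nx), dtype=np.int16)
    chunk = max(1, 2_000_000 // (ny * nx))  # slots per chunk, bounds temporaries
    for s in range(0, nt, chunk):
        e = min(nt, s + chunk)
        clear = truth.clearsky_counts[dekads[s:e], hour_idx[s:e]].astype(np.float64)
        vals = clear + cfg.cloud_boost_counts * truth.true_cloud[s:e]
        if cfg.noise_sd > 0:
            vals = vals + rng.normal(0.0, cfg.noise_sd, vals.shape)
        counts[s:e] = np.clip(np.rint(vals), 0, 1023).astype(np.int16)
    if cfg.missing_rate > 0:
        miss = rng.random((nt, ny, nx)) < cfg.missing_rate
        counts[miss] = COUNT_FILL
    return CountStack(times=times, counts=counts)


def simulate_scene(
    landcover: LandCoverMap, cfg: SimConfig, wind: pd.DataFrame | None = None
) -> tuple[TruthStack, CountStack]:
    """Convenience wrapper: truth + rendered counts in one call."""
    truth = simulate_truth(landcover, cfg, wind=wind)
    return truth, render_counts(truth)


def with_seed(cfg: SimConfig, seed: int) -> SimConfig:
    """Copy of a config with a different seed (replicate experiments)."""
    return replace(cfg, seed=seed)


def synthesize_dekadal_difference(
    a_pre: float = 0.114,
    a_post: float = 0.020,
    breakpoint: str | date = date(2009, 1, 24),
    start_year: int = 2004,
    end_year: int = 2013,
    c: float = 0.0,
    b: float = 0.0,
    phi: float = 0.04,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> pd.Series:
    """Dekadal forest-minus-non-forest difference series from the seasonal
    model itself: d(t) = c + b·t + A·sin²(π(t − φ)) + ε, with the
    amplitude stepping from ``a_pre`` to ``a_post`` at the breakpoint.

    Default amplitudes are the study's pre/post-windthrow values; the
    default phase puts the seasonal peak in early July.  Returns a
    Series indexed by mid-dekad timestamps.
    """
    from .seasonal import squared_sine
    from .timeutils import decimal_year, dekad_mid_doy

    idx = pd.DatetimeIndex(
        [
            pd.Timestamp(f"{y}-01-01") + pd.Timedelta(days=dekad_mid_doy(dk) - 1)
            for y in range(start_year, end_year + 1)
            for dk in range(1, 37)
        ]
    )
    t = decimal_year(idx)
    amp = np.where(idx < pd.Timestamp(breakpoint), a_pre, a_post)
    rng = np.random.default_rng(seed)
    vals = squared_sine(t - start_year, c, b, amp, phi) + rng.normal(0.0, noise_sd, len(t))
    return pd.Series(vals, index=idx, name="value")
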