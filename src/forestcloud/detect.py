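"""Empirical broadband-visible cloud detection.

Cloudy pixels brighten a visible scene, so in a long record the densest
(darkest) mode of the count distribution marks the clear-sky level.
The detector therefore:

1. bins every daylight observation by (dekad, UTC hour);
2. estimates, per pixel and bin, the clear-sky count as the centre of
   the steepest section of the empirical cumulative distribution
   function — operationalised as the integer count ``v`` maximising
   ``ECDF(v + w/2) − ECDF(v − w/2)`` for a count window of width
   ``window_w`` (default 3 counts), ties broken toward the smallest
   ``v`` since clouds only brighten;
3. flags a slot cloudy when its count strictly exceeds the clear-sky
   climatology by a constant threshold (default 10 counts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CLEAR, CLOUD, COUNT_FILL, MISSING, CloudMaskStack, CountStack
from .timeutils import DAYLIGHT_WINDOW, dekad_of_doy

__all__ = [
    "BinScheme",
    "ClearSkyClimatology",
    "time_bin",
    "ecdf_steepest",
    "build_clearsky_climatology",
    "detect_clouds",
]


class OutOfWindowError(ValueError):
    """Timestamp outside the daylight window."""


class InsufficientDataError(ValueError):
    """Not enough samples to estimate a clear-sky level."""


@dataclass(frozen=True)
class BinScheme:
    """(dekad, hour) binning: 36 dekads × the daylight hours.

    Dekad = min(⌊(doy−1)/10⌋ + 1, 36); hour = floor UTC hour, restricted
    to the half-open daylight window.
    """

    daylight: tuple[int, int] = DAYLIGHT_WINDOW

    @property
    def hours(self) -> np.ndarray:
        return np.arange(self.daylight[0], self.daylight[1])

    @property
    def n_hours(self) -> int:
        return self.daylight[1] - self.daylight[0]

    @property
    def n_bins(self) -> int:
        return 36 * self.n_hours


def time_bin(timestamp, scheme: BinScheme = BinScheme()) -> tuple[int, int]:
    """Map one timestamp to its (dekad, hour) bin; errors outside daylight."""
    ts = pd.Timestamp(timestamp)
    h0, h1 = scheme.daylight
    if not h0 <= ts.hour < h1:
        raise OutOfWindowError(f"{ts} outside daylight window [{h0:02d}:00, {h1:02d}:00)")
    return int(dekad_of_doy(ts.dayofyear)), ts.hour


def _bin_indices(times: pd.DatetimeIndex, scheme: BinScheme) -> np.ndarray:
    h0, h1 = scheme.daylight
    hours = times.hour.to_numpy()
    if ((hours < h0) | (hours >= h1)).any():
        raise OutOfWindowError("stack contains timestamps outside the daylight window")
    dk = dekad_of_doy(times.dayofyear.to_numpy()) - 1
    return dk * scheme.n_hours + (hours - h0)


def ecdf_steepest(samples, window_w: int = 3) -> int:
    """Clear-sky count of one sample set: steepest-ECDF-section centre.

    Returns the integer ``v`` (in the sample range) maximising the
    number of samples in ``(v − w/2, v + w/2]``; ties go to the smallest
    ``v``.
    """
    s = np.asarray(samples)
    if s.size == 0:
        raise InsufficientDataError("empty sample set")
    if window_w < 1:
        raise ValueError("window_w must be >= 1")
    s = np.sort(s.astype(np.int64).ravel())
    lo, hi = int(s[0]), int(s[-1])
    v = np.arange(lo, hi + 1)
    n_in = np.searchsorted(s, v + window_w / 2, side="right") - np.searchsorted(
        s, v - window_w / 2, side="right"
    )
    return int(v[np.argmax(n_in)])  # argmax takes the first (smallest) maximiser


@dataclass
class ClearSkyClimatology:
    """Per-pixel clear-sky counts on the (dekad, hour) bin lattice.

    ``values`` is ``(36, n_hours, ny, nx)`` float32, NaN where the bin
    had fewer than ``min_samples`` valid observations.
    """

    values: np.ndarray
    sample_count: np.ndarray
    scheme: BinScheme
    window_w: int
    min_samples: int

    @property
    def n_valid_bins(self) -> int:
        return int(np.isfinite(self.values).sum())


def build_clearsky_climatology(
    stack: CountStack,
    scheme: BinScheme = BinScheme(),
    window_w: int = 3,
    min_samples: int = 20,
) -> ClearSkyClimatology:
    """Estimate the clear-sky level per pixel and (dekad, hour) bin.

    All valid observations falling in a bin across all years are pooled;
    bins with fewer than ``min_samples`` samples are marked invalid
    (NaN) rather than extrapolated.
    """
    nt, ny, nx = stack.shape
    npx = ny * nx
    bins = _bin_indices(stack.times, scheme)
    values = np.full((scheme.n_bins, npx), np.nan, dtype=np.float32)
    nsamp = np.zeros((scheme.n_bins, npx), dtype=np.int32)

    counts2d = stack.counts.reshape(nt, npx)
    valid2d = stack.valid().reshape(nt, npx)
    order = np.argsort(bins, kind="stable")
    sorted_bins = bins[order]
    edges = np.flatnonzero(np.diff(sorted_bins)) + 1
    groups = np.split(order, edges)

    half = window_w / 2.0
    for rows in groups:
        b = int(bins[rows[0]])
        c = counts2d[rows].astype(np.int64)  # (nsamp_bin, npx)
        ok = valid2d[rows]
        n_ok = ok.sum(axis=0)
        nsamp[b] = n_ok
        est_px = np.flatnonzero(n_ok >= min_samples)
        if est_px.size == 0:
            continue
        c = c[:, est_px]
        ok = ok[:, est_px]
        # per-pixel histogram over the local count range, missing excluded
        cmin = np.where(ok, c, np.iinfo(np.int64).max).min(axis=0)
        offs = np.where(ok, c - cmin[None, :], -1)
        span = int(offs.max()) + 1
        # sentinel column `span` collects missing samples, dropped afterwards
        offs = np.where(ok, offs, span)
        flat = np.arange(est_px.size)[None, :] * (span + 1) + offs
        hist = np.bincount(flat.ravel(), minlength=est_px.size * (span + 1))
        hist = hist.reshape(est_px.size, span + 1)[:, :span]
        # samples within (v - w/2, v + w/2] of integer candidate v
        reach_lo = int(np.ceil(-half + 1e-9))  # smallest integer offset > -w/2
        reach_hi = int(np.floor(half + 1e-9))  # largest integer offset <= w/2
        width = reach_hi - reach_lo + 1
        padded = np.zeros((est_px.size, span + width - 1), dtype=hist.dtype)
        padded[:, -reach_lo : -reach_lo + span] = hist
        win = np.lib.stride_tricks.sliding_window_view(padded, width, axis=1).sum(axis=2)
        best = win.argmax(axis=1)  # first maximiser -> smallest candidate v
        values[b, est_px] = (cmin + best).astype(np.float32)

    return ClearSkyClimatology(
        values=values.reshape(scheme.n_bins // scheme.n_hours, scheme.n_hours, ny, nx),
        sample_count=nsamp.reshape(scheme.n_bins // scheme.n_hours, scheme.n_hours, ny, nx),
        scheme=scheme,
        window_w=window_w,
        min_samples=min_samples,
    )


def detect_clouds(
    stack: CountStack, clim: ClearSkyClimatology, threshold: int = 10
) -> CloudMaskStack:
    """Threshold-exceedance cloud mask.

    flag = cloud iff count > climatology + threshold (strict); clear iff
    count ≤ climatology + threshold; missing where the observation or
    the bin climatology is missing.
    """
    scheme = clim.scheme
    bins = _bin_indices(stack.times, scheme)
    nt, ny, nx = stack.shape
    clim_flat = clim.values.reshape(scheme.n_bins, ny, nx)
    flags = np.empty((nt, ny, nx), dtype=np.uint8)
    chunk = max(1, 4_000_000 // (ny * nx))
    for s in range(0, nt, chunk):
        e = min(nt, s + chunk)
        cl = clim_flat[bins[s:e]]
        counts = stack.counts[s:e]
        cloudy = counts > cl + threshold
        flags[s:e] = np.where(cloudy, CLOUD, CLEAR)
        bad = (counts == COUNT_FILL) | ~np.isfinite(cl)
        flags[s:e][bad] = MISSING
    return CloudMaskStack(times=stack.times, flags=flags, threshold_counts=threshold)
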