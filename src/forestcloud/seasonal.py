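"""Squared-sine-with-trend model for dekadal difference series.

The forest-minus-non-forest cloud-frequency difference has a seasonal
cycle peaking in summer.  It is modelled as

    d(t) = c + b·t + A·sin²(π(t − φ)),   t in decimal years,

i.e. an offset, a linear trend and a harmonic of fixed 1-year period
with amplitude A ≥ 0 and phase φ ∈ [0, 1) (the cycle peaks at
t = φ + ½ mod 1).  Fitting is nonlinear least squares with multi-start
over the phase; parameter confidence intervals come from the asymptotic
(Jacobian-based) covariance by default, with a dekad-resampling
percentile bootstrap as an option.  A storm breakpoint is handled by two
independent segment fits and the pre/post amplitude ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .timeutils import decimal_year

__all__ = ["SineFit", "AmplitudeChange", "fit_squared_sine", "amplitude_change"]

_PARAMS = ("c", "b", "A", "phi")


class FitError(RuntimeError):
    """Nonlinear fit failed from every start."""


def squared_sine(t, c, b, A, phi):
    """Model d(t) = c + b·t + A·sin²(π(t − φ)), period 1 year."""
    return c + b * t + A * np.sin(np.pi * (t - phi)) ** 2


@dataclass
class SineFit:
    """Fitted squared-sine-with-trend model for one segment."""

    params: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    se: dict[str, float]
    resid_sd: float
    n: int
    t0: float
    segment: str = ""
    ci_method: str = "asymptotic"
    extras: dict = field(default_factory=dict)

    @property
    def amplitude(self) -> float:
        return self.params["A"]

    def predict(self, t_years: np.ndarray) -> np.ndarray:
        t = np.asarray(t_years, float) - self.t0
        return squared_sine(t, *(self.params[k] for k in _PARAMS))


def _canonicalize(p: np.ndarray) -> np.ndarray:
    """Map (c, b, A, phi) to the equivalent A ≥ 0, φ ∈ [0, 1) form.

    Uses A·sin²(π(t−φ)) = −A·sin²(π(t−φ−½)) + A and the period-1
    identity φ ≡ φ + 1.
    """
    c, b, A, phi = p
    if A < 0:
        c, A, phi = c + A, -A, phi + 0.5
    phi = phi % 1.0
    if 1.0 - phi < 1e-7:  # numerically at the seam: same phase as 0
        phi = 0.0
    return np.array([c, b, A, phi])


def _series_to_ty(series, t0=None) -> tuple[np.ndarray, np.ndarray, float]:
    if isinstance(series, pd.DataFrame):
        series = series["value"]
    s = pd.Series(series).dropna()
    if isinstance(s.index, pd.DatetimeIndex):
        t_abs = decimal_year(s.index)
    else:
        t_abs = s.index.to_numpy(float)
    y = s.to_numpy(float)
    t0 = float(np.floor(t_abs.min())) if t0 is None else float(t0)
    return t_abs - t0, y, t0


def fit_squared_sine(
    series,
    t0: float | None = None,
    ci: str = "asymptotic",
    n_boot: int = 1000,
    seed: int = 0,
    segment: str = "",
) -> SineFit:
    """Fit the squared-sine-with-trend model to a dekadal series.

    ``series`` is a pandas Series/DataFrame indexed by timestamps
    (converted to decimal years) or by decimal years directly.  Requires
    ≥ 8 non-missing points spanning ≥ 0.95 years (phase
    identifiability).  Multi-start over φ ∈ {0, 0.25, 0.5, 0.75}; the
    best-SSE solution is canonicalised to A ≥ 0, φ ∈ [0, 1).
    """
    t, y, t0 = _series_to_ty(series, t0)
    if len(y) < 8:
        raise ValueError(f"need >= 8 non-missing dekads, got {len(y)}")
    if t.max() - t.min() < 0.95:
        raise ValueError("series must span at least one year for phase identifiability")

    amp0 = float(y.max() - y.min())
    # degenerate constant series: A = 0 by convention
    if amp0 == 0.0:
        params = {"c": float(y[0]), "b": 0.0, "A": 0.0, "phi": 0.0}
        zero = {k: (params[k], params[k]) for k in _PARAMS}
        return SineFit(params=params, ci95=zero, se=dict.fromkeys(_PARAMS, 0.0),
                       resid_sd=0.0, n=len(y), t0=t0, segment=segment, ci_method=ci)

    best = None
    for phi0 in (0.0, 0.25, 0.5, 0.75):
        p0 = [float(y.min()), 0.0, max(amp0, 1e-6), phi0]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                popt, pcov = optimize.curve_fit(
                    squared_sine, t, y, p0=p0, method="lm", maxfev=20000
                )
        except RuntimeError:
            continue
        sse = float(((y - squared_sine(t, *popt)) ** 2).sum())
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        raise FitError("squared-sine fit did not converge from any start")

    popt = _canonicalize(best[1])
    # refit once from the canonical point so the covariance matches it
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", optimize.OptimizeWarning)
        try:
            popt, pcov = optimize.curve_fit(
                squared_sine, t, y, p0=popt, method="lm", maxfev=20000
            )
        except RuntimeError as err:  # pragma: no cover - canonical start is a solution
            raise FitError(str(err)) from err
    popt = _canonicalize(popt)
    resid = y - squared_sine(t, *popt)
    n, k = len(y), len(_PARAMS)
    resid_sd = float(np.sqrt(resid @ resid / max(n - k, 1)))

    if np.abs(popt[2]) < 1e-9 * max(1.0, np.abs(popt[0])):
        popt[2], popt[3] = 0.0, 0.0

    params = dict(zip(_PARAMS, map(float, popt)))
    if ci == "asymptotic":
        se_arr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
        tq = stats.t.ppf(0.975, max(n - k, 1))
        lo, hi = popt - tq * se_arr, popt + tq * se_arr
        se = dict(zip(_PARAMS, map(float, se_arr)))
        ci95 = {p: (float(lo[i]), float(hi[i])) for i, p in enumerate(_PARAMS)}
    elif ci == "bootstrap":
        rng = np.random.default_rng(seed)
        reps = np.full((n_boot, k), np.nan)
        for ib in range(n_boot):
            idx = rng.integers(0, n, n)
            try:
                pb, _ = optimize.curve_fit(
                    squared_sine, t[idx], y[idx], p0=popt, method="lm", maxfev=5000
                )
                reps[ib] = _canonicalize(pb)
            except RuntimeError:
                continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            lo = np.nanpercentile(reps, 2.5, axis=0)
            hi = np.nanpercentile(reps, 97.5, axis=0)
            se = dict(zip(_PARAMS, map(float, np.nanstd(reps, axis=0))))
        ci95 = {p: (float(lo[i]), float(hi[i])) for i, p in enumerate(_PARAMS)}
    else:
        raise ValueError("ci must be 'asymptotic' or 'bootstrap'")

    return SineFit(params=params, ci95=ci95, se=se, resid_sd=resid_sd, n=n, t0=t0,
                   segment=segment, ci_method=ci)


@dataclass
class AmplitudeChange:
    """Pre/post-breakpoint amplitudes and their ratio."""

    fit_pre: SineFit
    fit_post: SineFit
    breakpoint: pd.Timestamp

    @property
    def A_pre(self) -> float:
        return self.fit_pre.amplitude

    @property
    def A_post(self) -> float:
        return self.fit_post.amplitude

    @property
    def ratio(self) -> float:
        return self.A_post / self.A_pre if self.A_pre > 0 else np.nan

    @property
    def ci_pre(self) -> tuple[float, float]:
        return self.fit_pre.ci95["A"]

    @property
    def ci_post(self) -> tuple[float, float]:
        return self.fit_post.ci95["A"]


def amplitude_change(series, breakpoint, **fit_kwargs) -> AmplitudeChange:
    """Independent squared-sine fits before and after a breakpoint date.

    ``series`` is indexed by timestamps; each segment must satisfy the
    :func:`fit_squared_sine` preconditions (≥ 8 dekads spanning ≥ 1
    year), otherwise a segment error is raised.
    """
    if isinstance(series, pd.DataFrame):
        series = series["value"]
    s = pd.Series(series).dropna()
    if not isinstance(s.index, pd.DatetimeIndex):
        raise ValueError("amplitude_change needs a timestamp-indexed series")
    bp = pd.Timestamp(breakpoint)
    if not (s.index.min() < bp < s.index.max()):
        raise ValueError(f"breakpoint {bp.date()} outside the series range")
    pre, post = s[s.index < bp], s[s.index >= bp]
    try:
        fit_pre = fit_squared_sine(pre, segment="pre", **fit_kwargs)
    except ValueError as err:
        raise ValueError(f"pre-breakpoint segment: {err}") from err
    try:
        fit_post = fit_squared_sine(post, segment="post", **fit_kwargs)
    except ValueError as err:
        raise ValueError(f"post-breakpoint segment: {err}") from err
    return AmplitudeChange(fit_pre=fit_pre, fit_post=fit_post, breakpoint=bp)
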