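"""Statistical comparison of forest and non-forest box series.

Daily box-mean cloud frequencies are compared with a Welch two-sample
t-test (unequal variances; daily values treated as independent).
Binned series get nonparametric uncertainty from a day-resampling
bootstrap: days are drawn with replacement and the bin means recomputed,
yielding central 50% and 95% percentile intervals.  Significance of the
forest-minus-non-forest difference resamples days *jointly* for the two
series, preserving the day-level synoptic correlation between boxes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult",
    "ttest_two_boxes",
    "bootstrap_percentile_intervals",
    "significant_bins",
]


@dataclass(frozen=True)
class TestResult:
    """Welch two-sample t-test outcome."""

    t: float
    p: float
    n_a: int
    n_b: int
    df: float


def ttest_two_boxes(a, b) -> TestResult:
    """Welch t-test on two daily series (missing values dropped).

    Degenerate input with zero variance in both samples and equal means
    returns t = 0, p = 1.
    """
    xa = pd.Series(a["value"] if isinstance(a, pd.DataFrame) else a).dropna().to_numpy(float)
    xb = pd.Series(b["value"] if isinstance(b, pd.DataFrame) else b).dropna().to_numpy(float)
    if len(xa) < 2 or len(xb) < 2:
        raise ValueError("need at least 2 non-missing values per series")
    if xa.var(ddof=1) == 0 and xb.var(ddof=1) == 0:
        if xa.mean() == xb.mean():
            return TestResult(t=0.0, p=1.0, n_a=len(xa), n_b=len(xb), df=float(len(xa) + len(xb) - 2))
        return TestResult(t=np.inf * np.sign(xa.mean() - xb.mean()), p=0.0,
                          n_a=len(xa), n_b=len(xb), df=float(len(xa) + len(xb) - 2))
    res = stats.ttest_ind(xa, xb, equal_var=False)
    return TestResult(
        t=float(res.statistic), p=float(res.pvalue), n_a=len(xa), n_b=len(xb), df=float(res.df)
    )


def _boot_bin_means(values: np.ndarray, n_boot: int, rng: np.random.Generator) -> np.ndarray:
    """(n_boot, n_bins) bin means under day resampling of a day×bin matrix."""
    n_days = values.shape[0]
    idx = rng.integers(0, n_days, size=(n_boot, n_days))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(values[idx], axis=1)


def bootstrap_percentile_intervals(
    table: pd.DataFrame, n_boot: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """Bootstrap 50% and 95% percentile intervals per bin.

    ``table`` is a day × bin matrix of box-mean values (NaN = day does
    not contribute to that bin), as produced by
    :func:`forestcloud.frequency.day_bin_table`.  Days are resampled
    with replacement ``n_boot`` times; per bin the 2.5/25/75/97.5
    percentiles of the resampled bin mean are reported alongside the
    point estimate (the observed bin mean).
    """
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; intervals will be noisy", stacklevel=2)
    rng = np.random.default_rng(seed)
    values = table.to_numpy(float)
    boots = _boot_bin_means(values, n_boot, rng)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        est = np.nanmean(values, axis=0)
        q = np.nanpercentile(boots, [2.5, 25.0, 75.0, 97.5], axis=0)
    out = pd.DataFrame(
        {
            "estimate": est,
            "q025": q[0],
            "q25": q[1],
            "q75": q[2],
            "q975": q[3],
            "n_days": (~np.isnan(values)).sum(axis=0),
        },
        index=table.columns,
    )
    out.attrs["n_boot"] = n_boot
    out.attrs["seed"] = seed
    return out


def significant_bins(
    forest: pd.DataFrame,
    nonforest: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    method: str = "difference",
) -> pd.Series:
    """Bins where forest and non-forest differ at the 95% level.

    ``method="difference"`` (default): resample days jointly and test
    whether the bootstrap 95% interval of the per-bin mean difference
    excludes 0.  ``method="overlap"``: conservative alternative that
    marks bins whose individual 95% intervals do not overlap.
    """
    if not forest.index.equals(nonforest.index) or not forest.columns.equals(nonforest.columns):
        raise ValueError("forest and nonforest tables are not aligned")
    rng = np.random.default_rng(seed)
    if method == "difference":
        diff = forest.to_numpy(float) - nonforest.to_numpy(float)
        boots = _boot_bin_means(diff, n_boot, rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            lo, hi = np.nanpercentile(boots, [2.5, 97.5], axis=0)
        sig = (lo > 0) | (hi < 0)
    elif method == "overlap":
        fi = bootstrap_percentile_intervals(forest, n_boot, seed)
        ni = bootstrap_percentile_intervals(nonforest, n_boot, seed)
        sig = ((fi["q025"] > ni["q975"]) | (ni["q025"] > fi["q975"])).to_numpy()
    else:
        raise ValueError("method must be 'difference' or 'overlap'")
    return pd.Series(sig, index=forest.columns, name="significant")
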