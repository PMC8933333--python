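"""Preprocessing of regional BOLD series and trial-wise reaction times.

BOLD series (one row per region, sampled at the scanner TR) are linearly
detrended per region, scaled by a single global factor so that the maximum
over all regions equals 4, and resampled to a finer grid by interspersing
unobserved samples (never interpolated); the observed-sample mask keeps
track of which grid points carry data.

Reaction times are screened per run: error trials, misses, implausibly fast
responses (< 0.2 s), and slow outliers (> Q3 + 3*IQR of the correct,
responded trials) are excluded.  Excluded RTs are stored as 0 with their
inclusion mask false, so they can sit in the model's observation vector
while contributing nothing to inversion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import detrend as _linear_detrend

__all__ = [
    "BOLDSeries",
    "BehavioralSeries",
    "preprocess_bold",
    "preprocess_rt",
    "BOLD_TARGET_MAX",
    "RT_FAST_CUTOFF_S",
]

BOLD_TARGET_MAX = 4.0
RT_FAST_CUTOFF_S = 0.2
SLOW_IQR_FACTOR = 3.0


@dataclass
class BOLDSeries:
    """Regional BOLD time series on a regular sampling grid."""

    values: np.ndarray  # regions x samples; NaN at unobserved samples
    tr_s: float  # sampling interval of the grid
    region_labels: tuple[str, ...]
    observed_mask: np.ndarray  # per-sample bool

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def observed(self) -> np.ndarray:
        """Regions x observed-samples matrix (unobserved grid points dropped)."""
        return self.values[:, self.observed_mask]

    @property
    def sample_times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.tr_s


@dataclass
class BehavioralSeries:
    """Per-trial reaction times with exclusion bookkeeping."""

    rt_s: np.ndarray  # seconds; exactly 0 at excluded trials
    include_mask: np.ndarray  # bool
    exclusion_reason: np.ndarray  # {"none","error","miss","fast_outlier","slow_outlier"}

    @property
    def n_trials(self) -> int:
        return len(self.rt_s)

    @property
    def n_included(self) -> int:
        return int(self.include_mask.sum())

    @property
    def included_rts(self) -> np.ndarray:
        return self.rt_s[self.include_mask]


def preprocess_bold(
    raw: np.ndarray,
    tr_s: float,
    target_dt_s: Optional[float] = None,
    region_labels: Optional[Sequence[str]] = None,
) -> BOLDSeries:
    """Detrend, globally rescale, and resample a raw BOLD matrix.

    Parameters
    ----------
    raw : regions x volumes matrix of extracted VOI signals.
    tr_s : acquisition repetition time in seconds.
    target_dt_s : grid spacing after resampling; must divide ``tr_s``
        (e.g. 2.2 -> 1.1 doubles the grid, marking every second grid point
        unobserved).  ``None`` keeps the acquisition grid.
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    n_regions, n_vol = raw.shape
    if region_labels is None:
        region_labels = tuple(f"region{i}" for i in range(n_regions))
    elif len(region_labels) != n_regions:
        raise ValueError("region_labels length does not match raw rows")

    values = np.empty_like(raw)
    for i in range(n_regions):
        if np.ptp(raw[i]) == 0:
            warnings.warn(
                f"region {region_labels[i]!r} is constant (zero variance); "
                "retained as zeros after detrending",
                stacklevel=2,
            )
            values[i] = raw[i] - raw[i].mean()
        else:
            values[i] = _linear_detrend(raw[i], type="linear")

    peak = values.max()
    if peak <= 0:
        raise ValueError("detrended BOLD has non-positive maximum; cannot scale")
    values = values * (BOLD_TARGET_MAX / peak)

    if target_dt_s is None or target_dt_s == tr_s:
        mask = np.ones(n_vol, dtype=bool)
        return BOLDSeries(values, tr_s, tuple(region_labels), mask)

    ratio = tr_s / target_dt_s
    k = int(round(ratio))
    if k < 1 or abs(ratio - k) > 1e-9:
        raise ValueError(
            f"target_dt_s={target_dt_s} must divide tr_s={tr_s} evenly"
        )
    n_grid = (n_vol - 1) * k + 1
    grid = np.full((n_regions, n_grid), np.nan)
    grid[:, ::k] = values
    mask = np.zeros(n_grid, dtype=bool)
    mask[::k] = True
    return BOLDSeries(grid, target_dt_s, tuple(region_labels), mask)


def preprocess_rt(raw_trials: pd.DataFrame) -> BehavioralSeries:
    """Screen trial-wise RTs for errors, misses, and outliers.

    ``raw_trials`` needs columns ``rt_s`` (NaN where no response was given)
    and ``response_correct`` (bool).  The slow-outlier threshold Q3 + 3*IQR
    is computed from the correct, responded trials of this series, so it
    adapts to each run's RT distribution.
    """
    for col in ("rt_s", "response_correct"):
        if col not in raw_trials.columns:
            raise ValueError(f"raw_trials is missing required column {col!r}")
    rt = raw_trials["rt_s"].to_numpy(dtype=float)
    correct = raw_trials["response_correct"].to_numpy(dtype=bool)
    n = len(rt)
    responded = np.isfinite(rt)

    reason = np.full(n, "none", dtype=object)
    reason[~responded] = "miss"
    reason[responded & ~correct] = "error"

    base = rt[responded & correct]
    if base.size:
        q1, q3 = np.percentile(base, [25, 75])
        slow_cut = q3 + SLOW_IQR_FACTOR * (q3 - q1)
        ok = responded & correct
        reason[ok & (rt < RT_FAST_CUTOFF_S)] = "fast_outlier"
        reason[ok & (rt > slow_cut)] = "slow_outlier"

    include = reason == "none"
    if not include.any():
        raise ValueError("all trials excluded; nothing left to fit")
    rt_clean = np.where(include, rt, 0.0)
    return BehavioralSeries(
        rt_s=rt_clean,
        include_mask=include,
        exclusion_reason=np.asarray(reason, dtype=object),
    )
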