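"""Goodness-of-fit, permutation, distribution, and cross-validation statistics.

Model outputs are scored with the coefficient of determination
R^2 = 1 - SS_res / SS_tot and the mean absolute error, and their chance
level is assessed per subject by shuffling the predicted series without
replacement and recounting: the permutation p-value is
(#{shuffled fits at least as good} + 1) / (n_perm + 1), so its smallest
attainable value is 1 / (n_perm + 1).  Simulated and measured reaction-time
distributions are compared with the two-sample Kolmogorov-Smirnov distance,
and generalization with leave-one-trial-out refitting (PRESS).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations as _all_permutations
from typing import Callable, Optional

import numpy as np
from scipy.stats import ks_2samp

__all__ = [
    "FitStats",
    "fit_statistics",
    "permutation_test",
    "ks_distance",
    "loto_press",
    "PressResult",
    "validity_effect",
    "rt_deciles",
]


@dataclass
class FitStats:
    r2: float
    mae: float
    perm_p_r2: Optional[float] = None
    perm_p_mae: Optional[float] = None
    n_perm: Optional[int] = None


def _masked(y, y_hat, mask):
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if len(y) != len(y_hat):
        raise ValueError("observed and predicted series differ in length")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        y, y_hat = y[mask], y_hat[mask]
    if len(y) < 2:
        raise ValueError("need at least 2 included points")
    return y, y_hat


def fit_statistics(
    y: np.ndarray, y_hat: np.ndarray, mask: Optional[np.ndarray] = None
) -> tuple[Optional[float], float]:
    """R^2 and MAE over the included points.

    R^2 may be negative for predictors worse than the mean; it is ``None``
    (with a warning) when the observed series is constant.
    """
    y, y_hat = _masked(y, y_hat, mask)
    resid = y - y_hat
    mae = float(np.mean(np.abs(resid)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("observed series is constant; R^2 undefined", stacklevel=2)
        return None, mae
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return r2, mae


def permutation_test(
    y: np.ndarray,
    y_hat: np.ndarray,
    statistic: str = "r2",
    n_perm: int = 10_000,
    seed: int = 0,
    mask: Optional[np.ndarray] = None,
    exact: bool = False,
) -> float:
    """Permutation p-value of a fit statistic under shuffled predictions.

    The predicted series is shuffled without replacement ``n_perm`` times
    (or, with ``exact=True`` and at most 8 points, fully enumerated) and the
    statistic recomputed; shuffled fits at least as good as the observed one
    (>= for R^2, <= for MAE) count toward
    ``p = (count + 1) / (n_shuffles + 1)``.
    """
    if statistic not in ("r2", "mae"):
        raise ValueError("statistic must be 'r2' or 'mae'")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y, y_hat = _masked(y, y_hat, mask)
    n = len(y)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if np.ptp(y_hat) == 0:
        warnings.warn(
            "constant predictions; every permutation ties and p = 1",
            stacklevel=2,
        )

    def stat(mat: np.ndarray) -> np.ndarray:
        resid = y[None, :] - mat
        if statistic == "mae":
            return np.mean(np.abs(resid), axis=1)
        if ss_tot == 0.0:
            raise ValueError("R^2 permutation test undefined for constant y")
        return 1.0 - np.sum(resid**2, axis=1) / ss_tot

    observed = float(stat(y_hat[None, :])[0])
    if exact:
        if n > 8:
            raise ValueError("exact enumeration supported for n <= 8 only")
        mat = np.array(list(_all_permutations(y_hat)))
    else:
        rng = np.random.default_rng(seed)
        order = np.argsort(rng.random((n_perm, n)), axis=1)
        mat = y_hat[order]
    values = stat(mat)
    better = values >= observed if statistic == "r2" else values <= observed
    return (int(better.sum()) + 1) / (len(values) + 1)


def ks_distance(sample_a: np.ndarray, sample_b: np.ndarray) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov distance and asymptotic p-value."""
    sample_a = np.asarray(sample_a, dtype=float).ravel()
    sample_b = np.asarray(sample_b, dtype=float).ravel()
    if sample_a.size == 0 or sample_b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = ks_2samp(sample_a, sample_b, method="asymp")
    return float(res.statistic), float(res.pvalue)


@dataclass
class PressResult:
    """Leave-one-trial-out squared errors and their sum (PRESS)."""

    press: float
    held_out_sq_err: np.ndarray  # per included trial; NaN where a fold failed
    held_out_mae: float
    n_failed: int


def loto_press(
    y: np.ndarray,
    include_mask: np.ndarray,
    refit_predict: Callable[[np.ndarray], np.ndarray],
) -> PressResult:
    """Leave-one-trial-out cross-validation.

    For each included trial, ``refit_predict`` is called with an inclusion
    mask that drops that trial's likelihood term (priors and all other
    trials unchanged) and must return per-trial predictions for the full
    series; the held-out squared errors accumulate into PRESS.  Folds whose
    refit fails are flagged and excluded with a warning.
    """
    y = np.asarray(y, dtype=float)
    include_mask = np.asarray(include_mask, dtype=bool)
    idx = np.flatnonzero(include_mask)
    if len(idx) < 3:
        raise ValueError("need at least 3 included trials")
    sq = np.full(len(idx), np.nan)
    n_failed = 0
    for k, t in enumerate(idx):
        fold = include_mask.copy()
        fold[t] = False
        try:
            pred = np.asarray(refit_predict(fold), dtype=float)
            sq[k] = (y[t] - pred[t]) ** 2
        except Exception as err:  # noqa: BLE001 - fold failure is data
            n_failed += 1
            warnings.warn(f"fold {t} failed and was excluded: {err}", stacklevel=2)
    ok = np.isfinite(sq)
    if not ok.any():
        raise ValueError("every cross-validation fold failed")
    return PressResult(
        press=float(np.nansum(sq)),
        held_out_sq_err=sq,
        held_out_mae=float(np.mean(np.sqrt(sq[ok]))),
        n_failed=n_failed,
    )


def validity_effect(
    rts: np.ndarray,
    validity: np.ndarray,
    mask: Optional[np.ndarray] = None,
) -> Optional[float]:
    """Mean included invalid RT minus mean included valid RT (seconds)."""
    rts = np.asarray(rts, dtype=float).ravel()
    invalid = np.asarray(validity, dtype=float).ravel() > 0.5
    keep = (
        np.ones(len(rts), dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    )
    if not (invalid & keep).any() or not (~invalid & keep).any():
        return None
    return float(rts[invalid & keep].mean() - rts[~invalid & keep].mean())


def rt_deciles(rts: np.ndarray, mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Deciles (10%..90%) of an RT distribution, as a reporting utility."""
    rts = np.asarray(rts, dtype=float).ravel()
    if mask is not None:
        rts = rts[np.asarray(mask, dtype=bool)]
    return np.percentile(rts, np.arange(10, 100, 10))
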