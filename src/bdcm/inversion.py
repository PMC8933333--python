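"""Variational-Laplace estimation with Gaussian posteriors and Gamma precisions.

The engine maximizes a variational free energy F — a lower bound on the log
model evidence — for models of the form

    y_c = g_c(theta) + eps_c,   eps_c ~ N(0, 1/lambda_c)   (channel c),

with a diagonal Gaussian prior over ``theta`` and a Gamma prior over each
channel's noise precision ``lambda_c``.  The posterior over parameters is
Gaussian (Laplace assumption), updated by Fisher-scoring Gauss-Newton steps
with trust-region step halving whenever a step would decrease F; the
precision posteriors are conjugate Gamma updates.  F decomposes as accuracy
minus complexity and is the model-comparison currency used throughout.

A model object must expose ``param_names`` (list of str), ``prior_mean`` and
``prior_var`` (1-D arrays; prior variance 0 fixes a parameter at its prior
mean and removes it from estimation), and ``predict(theta) -> dict`` mapping
channel names to prediction vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.special import digamma, gammaincinv, gammaln
from scipy.optimize import brentq

__all__ = [
    "GammaHyper",
    "InversionSettings",
    "InversionResult",
    "set_hyperpriors",
    "invert",
    "predict",
]


@dataclass
class GammaHyper:
    """Gamma(shape, rate) hyperprior over a channel's noise precision.

    ``fixed`` (if given) pins the precision at that value instead of
    estimating it; shape and rate are then ignored.
    """

    shape: float = 1e-2
    rate: float = 1e-2
    fixed: Optional[float] = None

    def __post_init__(self) -> None:
        if self.fixed is None and (self.shape <= 0 or self.rate <= 0):
            raise ValueError("Gamma hyperprior shape and rate must be positive")


@dataclass
class InversionSettings:
    """Solver controls for the variational-Laplace scheme."""

    max_iter: int = 64
    f_tol: float = 1e-2  # |dF| convergence threshold
    n_converged: int = 2  # consecutive small-|dF| iterations required
    fd_step: float = 1e-5  # central finite-difference step
    max_halvings: int = 8
    accept_tol: float = 1e-3  # F may decrease by this much per accepted step
    ridge: float = 1e-8


@dataclass
class InversionResult:
    """Posterior moments, precision posteriors, free energy, predictions."""

    posterior_mean: np.ndarray  # full parameter vector (fixed entries = prior mean)
    posterior_cov: np.ndarray  # free parameters only
    free_names: list[str]
    free_idx: np.ndarray
    free_energy: float
    f_trace: list[float]
    converged: bool
    iterations: int
    precisions: dict[str, dict[str, float]]
    predictions: dict[str, np.ndarray]
    param_names: list[str]
    extra: dict = field(default_factory=dict)

    def summary(self) -> "object":
        import pandas as pd

        sd = np.zeros(len(self.param_names))
        sd[self.free_idx] = np.sqrt(np.maximum(np.diag(self.posterior_cov), 0.0))
        return pd.DataFrame(
            {
                "parameter": self.param_names,
                "mean": self.posterior_mean,
                "sd": sd,
                "estimated": [i in set(self.free_idx) for i in range(len(self.param_names))],
            }
        )


def set_hyperpriors(
    expected_variance_explained: tuple[float, float], data_variance: float
) -> GammaHyper:
    """Gamma hyperprior on noise precision from an explained-variance interval.

    A model explaining a fraction ``EV`` of the data variance ``V`` leaves a
    residual variance ``(1 - EV) * V``, i.e. a noise precision
    ``1 / ((1 - EV) * V)``.  Given an interval ``(lo, hi)`` of plausible
    explained variance, the returned Gamma prior places its 10th percentile
    at the precision implied by ``EV = lo`` and its 90th percentile at the
    precision implied by ``EV = hi``, so the central 80% prior mass covers
    the requested explained-variance range.  Deterministic given the data
    scale, and scale-equivariant: rescaling the data rescales the prior so
    the implied interval is unchanged.
    """
    lo, hi = expected_variance_explained
    if not (0.0 < lo < hi < 1.0):
        raise ValueError(
            "expected_variance_explained must satisfy 0 < lo < hi < 1"
        )
    if not np.isfinite(data_variance) or data_variance <= 0:
        raise ValueError("data_variance must be positive and finite")
    lam_lo = 1.0 / ((1.0 - lo) * data_variance)
    lam_hi = 1.0 / ((1.0 - hi) * data_variance)
    ratio = lam_hi / lam_lo

    def qratio_gap(log10_a: float) -> float:
        a = 10.0**log10_a
        with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
            gap = gammaincinv(a, 0.9) / gammaincinv(a, 0.1) - ratio
        # tiny shapes underflow the lower quantile; that side of the
        # bracket always has a (numerically infinite) positive gap
        return gap if np.isfinite(gap) else 1e12

    log10_a = brentq(qratio_gap, -3.0, 4.0, xtol=1e-12)
    shape = 10.0**log10_a
    rate = gammaincinv(shape, 0.1) / lam_lo
    return GammaHyper(shape=shape, rate=rate)


def _jacobian(
    predict_fn: Callable[[np.ndarray], dict],
    theta: np.ndarray,
    free_idx: np.ndarray,
    channels: list[str],
    step: float,
) -> dict[str, np.ndarray]:
    """Central finite-difference Jacobian of each channel's prediction."""
    jac = {c: [] for c in channels}
    for i in free_idx:
        tp = theta.copy()
        tp[i] += step
        gp = predict_fn(tp)
        tm = theta.copy()
        tm[i] -= step
        gm = predict_fn(tm)
        for c in channels:
            jac[c].append((gp[c] - gm[c]) / (2.0 * step))
    return {
        c: (np.stack(cols, axis=1) if cols else np.zeros((0, 0)))
        for c, cols in jac.items()
    }


def _gamma_kl(a: float, b: float, a0: float, b0: float) -> float:
    return float(
        (a - a0) * digamma(a)
        - gammaln(a)
        + gammaln(a0)
        + a0 * (np.log(b) - np.log(b0))
        + a * (b0 - b) / b
    )


def invert(
    model,
    data: dict[str, np.ndarray],
    hyper: dict[str, GammaHyper],
    settings: Optional[InversionSettings] = None,
) -> InversionResult:
    """Fit ``model`` to one or more data channels by variational Laplace.

    ``data`` maps channel names to observation vectors (already restricted
    to observed samples / included trials); ``hyper`` supplies one
    :class:`GammaHyper` per channel.  Channels enter the free energy
    additively, each with its own precision.
    """
    if settings is None:
        settings = InversionSettings()
    if not data:
        raise ValueError("at least one data channel is required")
    channels = sorted(data)
    y = {c: np.asarray(data[c], dtype=float).ravel() for c in channels}
    n_data = {c: len(y[c]) for c in channels}
    for c in channels:
        if c not in hyper:
            raise ValueError(f"missing hyperprior for channel {c!r}")

    mu0 = np.asarray(model.prior_mean, dtype=float).copy()
    var0 = np.asarray(model.prior_var, dtype=float).copy()
    if np.any(var0 < 0):
        raise ValueError("prior variances must be >= 0")
    free_idx = np.flatnonzero(var0 > 0)
    n_free = len(free_idx)
    p0_diag = 1.0 / var0[free_idx] if n_free else np.zeros(0)

    theta = mu0.copy()

    # Gamma posterior state per channel (None where precision is fixed).
    a_post: dict[str, Optional[float]] = {}
    b_post: dict[str, Optional[float]] = {}
    for c in channels:
        if hyper[c].fixed is None:
            a_post[c] = hyper[c].shape + 0.5 * n_data[c]
            b_post[c] = hyper[c].rate
        else:
            a_post[c] = None
            b_post[c] = None

    def lam_bar(c: str) -> float:
        h = hyper[c]
        return h.fixed if h.fixed is not None else a_post[c] / b_post[c]

    def posterior_cov(jac: dict) -> tuple[np.ndarray, np.ndarray]:
        p = np.diag(p0_diag).copy() if n_free else np.zeros((0, 0))
        for c in channels:
            p += lam_bar(c) * (jac[c].T @ jac[c])
        try:
            cov = np.linalg.inv(p)
        except np.linalg.LinAlgError:
            warnings.warn("ill-conditioned curvature; ridge applied", stacklevel=2)
            p = p + settings.ridge * np.eye(n_free)
            cov = np.linalg.inv(p)
        return p, cov

    def free_energy(
        th: np.ndarray, err: dict, jac: dict, cov: np.ndarray
    ) -> float:
        f = 0.0
        for c in channels:
            e = err[c]
            tr = float(np.trace(jac[c] @ cov @ jac[c].T)) if n_free else 0.0
            sse = float(e @ e) + tr
            h = hyper[c]
            if h.fixed is not None:
                lam = h.fixed
                f += 0.5 * n_data[c] * (np.log(lam) - np.log(2 * np.pi)) - 0.5 * lam * sse
            else:
                a, b = a_post[c], b_post[c]
                eloglam = digamma(a) - np.log(b)
                f += 0.5 * n_data[c] * (eloglam - np.log(2 * np.pi))
                f -= 0.5 * (a / b) * sse
                f -= _gamma_kl(a, b, h.shape, h.rate)
        if n_free:
            dm = th[free_idx] - mu0[free_idx]
            sign, logdet_cov = np.linalg.slogdet(cov)
            f -= 0.5 * (
                float(p0_diag @ np.diag(cov))
                + float(dm * p0_diag @ dm)
                - n_free
                + float(np.sum(np.log(var0[free_idx])))
                - logdet_cov
            )
        return float(f)

    def update_b(err: dict, jac: dict, cov: np.ndarray) -> None:
        for c in channels:
            if hyper[c].fixed is None:
                tr = float(np.trace(jac[c] @ cov @ jac[c].T)) if n_free else 0.0
                b_post[c] = hyper[c].rate + 0.5 * (float(err[c] @ err[c]) + tr)

    def residuals(th: np.ndarray) -> tuple[dict, dict]:
        pred = model.predict(th)
        err = {c: y[c] - np.asarray(pred[c], dtype=float).ravel() for c in channels}
        for c in channels:
            if len(np.asarray(pred[c]).ravel()) != n_data[c]:
                raise ValueError(
                    f"prediction length mismatch on channel {c!r}: "
                    f"{n_data[c]} data points vs "
                    f"{len(np.asarray(pred[c]).ravel())} predicted"
                )
        return pred, err

    pred, err = residuals(theta)
    jac = _jacobian(model.predict, theta, free_idx, channels, settings.fd_step)
    p_mat, cov = posterior_cov(jac)
    update_b(err, jac, cov)
    p_mat, cov = posterior_cov(jac)
    f_cur = free_energy(theta, err, jac, cov)
    f_trace = [f_cur]

    converged = False
    n_small = 0
    it = 0
    best = {
        "f": f_cur,
        "theta": theta.copy(),
        "cov": cov.copy(),
        "pred": dict(pred),
        "a": dict(a_post),
        "b": dict(b_post),
    }
    if n_free == 0:
        converged = True
    while it < settings.max_iter and not converged:
        it += 1
        # Gauss-Newton direction at the current mean.
        grad = -p0_diag * (theta[free_idx] - mu0[free_idx])
        for c in channels:
            grad = grad + lam_bar(c) * (jac[c].T @ err[c])
        try:
            delta = np.linalg.solve(p_mat, grad)
        except np.linalg.LinAlgError:
            warnings.warn("ill-conditioned curvature; ridge applied", stacklevel=2)
            delta = np.linalg.solve(
                p_mat + settings.ridge * np.eye(n_free), grad
            )

        # Candidate steps are scored with the curvature at the current mean;
        # the Jacobian is recomputed only once a step is accepted.
        accepted = False
        scale = 1.0
        b_saved = dict(b_post)
        for _ in range(settings.max_halvings + 1):
            th_new = theta.copy()
            th_new[free_idx] += scale * delta
            try:
                pred_new, err_new = residuals(th_new)
            except (FloatingPointError, ZeroDivisionError, OverflowError):
                scale *= 0.5
                continue
            if any(not np.all(np.isfinite(err_new[c])) for c in channels):
                scale *= 0.5
                continue
            for c in channels:
                if hyper[c].fixed is None:
                    b_post[c] = b_saved[c]
            update_b(err_new, jac, cov)
            f_new = free_energy(th_new, err_new, jac, cov)
            if f_new >= f_cur - settings.accept_tol:
                accepted = True
                break
            scale *= 0.5
        if accepted:
            theta, pred, err = th_new, pred_new, err_new
            jac = _jacobian(
                model.predict, theta, free_idx, channels, settings.fd_step
            )
            p_mat, cov = posterior_cov(jac)
            update_b(err, jac, cov)
            p_mat, cov = posterior_cov(jac)
            f_upd = free_energy(theta, err, jac, cov)
            df = f_upd - f_cur
            f_cur = f_upd
        else:
            for c in channels:
                if hyper[c].fixed is None:
                    b_post[c] = b_saved[c]
            df = 0.0
        f_trace.append(f_cur)
        # convergence on lack of progress over the best visited iterate,
        # which is what gets returned (robust to small terminal oscillation)
        progress = f_cur - best["f"]
        if f_cur > best["f"]:
            best = {
                "f": f_cur,
                "theta": theta.copy(),
                "cov": cov.copy(),
                "pred": dict(pred),
                "a": dict(a_post),
                "b": dict(b_post),
            }
        n_small = n_small + 1 if progress < settings.f_tol else 0
        if n_small >= settings.n_converged:
            converged = True
    if not converged and n_free:
        warnings.warn(
            f"inversion did not converge in {settings.max_iter} iterations",
            stacklevel=2,
        )
    theta = best["theta"]
    cov = best["cov"]
    pred = best["pred"]
    a_post = best["a"]
    b_post = best["b"]
    f_cur = best["f"]

    precisions = {}
    for c in channels:
        h = hyper[c]
        if h.fixed is not None:
            precisions[c] = {"fixed": h.fixed, "mean": h.fixed}
        else:
            precisions[c] = {
                "shape": a_post[c],
                "rate": b_post[c],
                "mean": a_post[c] / b_post[c],
            }

    return InversionResult(
        posterior_mean=theta,
        posterior_cov=cov,
        free_names=[model.param_names[i] for i in free_idx],
        free_idx=free_idx,
        free_energy=f_cur,
        f_trace=f_trace,
        converged=converged,
        iterations=it,
        precisions=precisions,
        predictions={c: np.asarray(pred[c], dtype=float) for c in channels},
        param_names=list(model.param_names),
    )


def predict(result: InversionResult, model) -> dict[str, np.ndarray]:
    """Forward predictions at the posterior mean (used by all fit statistics)."""
    return model.predict(result.posterior_mean)
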