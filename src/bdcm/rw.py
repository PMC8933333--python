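"""Trial-level Rescorla-Wagner generative model of reaction times.

The learner tracks a perceived cue invalidity ``v`` (the running estimate of
the probability that the cue is invalid).  After observing trial ``t`` with
input ``u_t`` (1 = invalid, 0 = valid),

    v_t = v_{t-1} + alpha * delta_t,    delta_t = u_t - v_{t-1},

and the predicted reaction time of trial ``t`` is governed by the perceived
invalidity of the *previous* trial,

    g_t = u_t * (zeta_i + zeta_2 * v_{t-1})
        + (1 - u_t) * (zeta_v + zeta_2 * (1 - v_{t-1})),

with separate bias parameters for valid and invalid trials and a shared
scaling of the prediction.  Surprising (invalid) trials after a streak of
valid ones therefore produce the slowest predicted responses.

Fitting uses the variational-Laplace engine with Gaussian priors
(alpha: mean 0.5, sd 0.5, estimated on the logit scale so that
0 < alpha <= 1; zeta_v, zeta_i, zeta_2: mean 0, sd 1; v0: mean 0.5, sd 1).
Excluded trials contribute nothing to the likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import expit, logit

from .inversion import (
    GammaHyper,
    InversionResult,
    InversionSettings,
    invert,
    set_hyperpriors,
)
from .preprocess import BehavioralSeries

__all__ = [
    "RWParams",
    "RWTrajectory",
    "RWModel",
    "rw_evolve",
    "rw_observe",
    "rw_trajectory",
    "rw_simulate",
    "rw_fit",
]

# Prior sd of alpha on the logit scale: the stated sd of 0.5 on the natural
# (0, 1] scale mapped through the inverse-logit derivative at the prior mean
# (d alpha / d logit = 0.25 at alpha = 0.5).
ALPHA_LOGIT_PRIOR_SD = 0.5 / 0.25


@dataclass
class RWParams:
    """Learning rate, condition biases, prediction scaling, initial belief."""

    alpha: float
    zeta_v: float
    zeta_i: float
    zeta_2: float
    v0: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")


@dataclass
class RWTrajectory:
    """Per-trial perceived invalidity, prediction errors, and predicted RTs."""

    v: np.ndarray  # v_t after observing trial t
    delta: np.ndarray  # u_t - v_{t-1}
    g: np.ndarray  # predicted RT of trial t (seconds)


def rw_evolve(v_prev: float, u_t: float, alpha: float) -> float:
    """One belief update: ``v_prev + alpha * (u_t - v_prev)``."""
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    return v_prev + alpha * (u_t - v_prev)


def rw_observe(v_prev: float, u_t: float, params: RWParams) -> float:
    """Predicted RT given the previous trial's perceived invalidity."""
    return u_t * (params.zeta_i + params.zeta_2 * v_prev) + (1.0 - u_t) * (
        params.zeta_v + params.zeta_2 * (1.0 - v_prev)
    )


def rw_trajectory(params: RWParams, u: np.ndarray) -> RWTrajectory:
    """Deterministic belief/prediction trajectory over a validity sequence."""
    u = np.asarray(u, dtype=float)
    n = len(u)
    v = np.empty(n)
    delta = np.empty(n)
    g = np.empty(n)
    v_prev = params.v0
    for t in range(n):
        g[t] = rw_observe(v_prev, u[t], params)
        delta[t] = u[t] - v_prev
        v[t] = v_prev + params.alpha * delta[t]
        v_prev = v[t]
    return RWTrajectory(v=v, delta=delta, g=g)


def rw_simulate(
    params: RWParams,
    validity_sequence: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[RWTrajectory, np.ndarray]:
    """Simulate noisy RTs: the deterministic trajectory plus Gaussian noise."""
    traj = rw_trajectory(params, validity_sequence)
    rng = np.random.default_rng(seed)
    rts = traj.g + (rng.normal(0.0, noise_sd, size=len(traj.g)) if noise_sd else 0.0)
    return traj, rts


class RWModel:
    """Inversion-protocol wrapper: parameter vector <-> RW predictions.

    Parameter vector layout: [logit(alpha), zeta_v, zeta_i, zeta_2, v0].
    """

    channel = "rt"

    def __init__(
        self,
        validity_sequence: np.ndarray,
        include_mask: Optional[np.ndarray] = None,
        prior_mean: Optional[np.ndarray] = None,
        prior_var: Optional[np.ndarray] = None,
    ) -> None:
        self.u = np.asarray(validity_sequence, dtype=float)
        if include_mask is None:
            include_mask = np.ones(len(self.u), dtype=bool)
        self.include_mask = np.asarray(include_mask, dtype=bool)
        self.param_names = ["alpha_logit", "zeta_v", "zeta_i", "zeta_2", "v0"]
        self.prior_mean = (
            np.array([0.0, 0.0, 0.0, 0.0, 0.5])
            if prior_mean is None
            else np.asarray(prior_mean, dtype=float)
        )
        self.prior_var = (
            np.array([ALPHA_LOGIT_PRIOR_SD**2, 1.0, 1.0, 1.0, 1.0])
            if prior_var is None
            else np.asarray(prior_var, dtype=float)
        )

    def params_from_theta(self, theta: np.ndarray) -> RWParams:
        return RWParams(
            alpha=float(np.clip(expit(theta[0]), 1e-12, 1.0)),
            zeta_v=float(theta[1]),
            zeta_i=float(theta[2]),
            zeta_2=float(theta[3]),
            v0=float(np.clip(theta[4], 0.0, 1.0)),
        )

    def predict(self, theta: np.ndarray) -> dict[str, np.ndarray]:
        traj = rw_trajectory(self.params_from_theta(theta), self.u)
        return {self.channel: traj.g[self.include_mask]}


def rw_fit(
    behavior: BehavioralSeries,
    validity_sequence: np.ndarray,
    priors: Optional[tuple[np.ndarray, np.ndarray]] = None,
    settings: Optional[InversionSettings] = None,
    explained_variance: tuple[float, float] = (0.1, 0.9),
    hyper: Optional[GammaHyper] = None,
) -> InversionResult:
    """Variational-Laplace fit of the RW model to screened reaction times.

    Returns an :class:`InversionResult`; the posterior-mean parameters on
    their natural scale are available as ``result.extra["params"]``.
    """
    u = np.asarray(validity_sequence, dtype=float)
    if len(u) != behavior.n_trials:
        raise ValueError("validity sequence length does not match trials")
    n_inc = behavior.n_included
    if n_inc < 2:
        raise ValueError("need at least 2 included trials")
    model = RWModel(
        u,
        behavior.include_mask,
        prior_mean=None if priors is None else priors[0],
        prior_var=None if priors is None else priors[1],
    )
    if n_inc < len(model.param_names):
        warnings.warn(
            f"only {n_inc} included trials for {len(model.param_names)} "
            "parameters; the posterior will track the prior closely",
            stacklevel=2,
        )
    if np.ptp(u[behavior.include_mask]) == 0:
        warnings.warn(
            "degenerate validity sequence (single condition); condition "
            "biases are not separately identifiable",
            stacklevel=2,
        )
    y = behavior.included_rts
    if hyper is None:
        var_y = float(np.var(y))
        hyper = (
            set_hyperpriors(explained_variance, var_y)
            if var_y > 0
            else GammaHyper(fixed=1.0)
        )
    result = invert(model, {model.channel: y}, {model.channel: hyper}, settings)
    result.extra["params"] = model.params_from_theta(result.posterior_mean)
    return result
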