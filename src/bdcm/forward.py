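"""Deterministic forward model: neural, hemodynamic, and behavioral dynamics.

Three coupled layers generate the data:

* neural states ``x`` follow the bilinear flow
  ``dx/dt = A x + sum_j u_j B_j x + C u``;
* each region's neural activity drives a four-state balloon/Windkessel
  cascade (vasodilatory signal ``s``, inflow ``f``, venous volume ``v``,
  deoxyhemoglobin ``q``) whose static nonlinearity yields the BOLD signal;
* a scalar behavioral response state ``r`` follows the discrete map
  ``r[k+1] = h(x[k], u[k]) - decay * r[k]`` with
  ``h = A_r x + sum_j u_j B_rj x + C_r u``, read out through a steep,
  bounded sigmoid ``s(r) = 3 / (1 + exp(-100 (rho + r)))`` so that
  predicted reaction times always lie strictly between 0 and 3 s.

The behavioral layer reads the neural states but never feeds back on them,
so BOLD predictions are invariant to the behavioral parameters.
Integration is explicit Euler on the micro-time grid of the input streams
(flow, volume, and deoxyhemoglobin are integrated in log space to keep them
positive); the behavioral map updates once per micro-step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import expit

from .design import InputStreams
from .network import BDCMParams, HemodynamicParams, NetworkStructure

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(fn):
            return fn

        return wrap


__all__ = [
    "StateTrajectory",
    "neural_derivative",
    "hemodynamic_derivative",
    "bold_signal",
    "hemodynamic_observe",
    "response_evolve",
    "rt_observe",
    "rt_read_bins",
    "integrate",
    "RT_UPPER_BOUND_S",
    "SIGMOID_SCALE",
]

RT_UPPER_BOUND_S = 3.0
SIGMOID_SCALE = 100.0
DEFAULT_OVERSAMPLE = 8  # micro-steps per BOLD grid sample


@dataclass
class StateTrajectory:
    """Micro-time state trajectories and sampled predictions."""

    x: np.ndarray  # (T+1) x R neural states
    z: np.ndarray  # (T+1) x R x 4 hemodynamic states (s, ln f, ln v, ln q)
    r: np.ndarray  # (T+1,) behavioral response state
    y_pred: np.ndarray  # regions x samples BOLD at the sample grid
    s_pred: np.ndarray  # per-trial predicted RT (seconds)
    sample_bins: np.ndarray
    rt_bins: np.ndarray
    dt_s: float


def neural_derivative(
    x: np.ndarray, u: np.ndarray, params: BDCMParams
) -> np.ndarray:
    """Bilinear neural flow ``A x + sum_j u_j B_j x + C u``."""
    dx = params.A @ x + params.C @ u
    for j in range(len(u)):
        if u[j] != 0.0:
            dx = dx + u[j] * (params.B[j] @ x)
    return dx


def response_evolve(
    r_t: float, x: np.ndarray, u: np.ndarray, params: BDCMParams
) -> float:
    """One step of the behavioral map ``h(x, u) - decay * r``."""
    h = float(params.ar @ x + params.cr @ u)
    for j in range(len(u)):
        if u[j] != 0.0:
            h += u[j] * float(params.br[j] @ x)
    return h - params.decay * r_t


def rt_observe(r, rho: float):
    """Bounded sigmoid readout ``3 / (1 + exp(-100 (rho + r)))`` (seconds).

    Saturates to the 3-s upper bound as the response state grows without
    bound and never overflows.
    """
    return RT_UPPER_BOUND_S * expit(SIGMOID_SCALE * (rho + np.asarray(r, dtype=float)))


def hemodynamic_derivative(
    z: np.ndarray, x_i: float, phi: HemodynamicParams
) -> np.ndarray:
    """Balloon-model flow for one region in (s, ln f, ln v, ln q) coordinates."""
    sh, lf, lv, lq = z
    f = np.exp(lf)
    v = np.exp(lv)
    q = np.exp(lq)
    fv = v ** (1.0 / phi.alpha)  # outflow through the balloon
    ef = 1.0 - (1.0 - phi.e0) ** (1.0 / f)  # oxygen extraction at flow f
    return np.array(
        [
            x_i - phi.kappa * sh - phi.gamma * (f - 1.0),
            sh / f,
            (f - fv) / (phi.tau * v),
            (f * ef / phi.e0 - fv * q / v) / (phi.tau * q),
        ]
    )


def bold_signal(z: np.ndarray, phi: HemodynamicParams) -> np.ndarray:
    """Static BOLD nonlinearity from hemodynamic states (any leading shape)."""
    v = np.exp(z[..., 2])
    q = np.exp(z[..., 3])
    k1 = 7.0 * phi.e0
    k2 = 2.0
    k3 = 2.0 * phi.e0 - 0.2
    return phi.v0 * (k1 * (1.0 - q) + k2 * (1.0 - q / v) + k3 * (1.0 - v))


@njit(cache=True)
def _euler_core(A, B, C, ar, br, cr, decay, uT, dt, kappa, gamma, tau, alpha, e0):
    T, J = uT.shape
    R = A.shape[0]
    x = np.zeros((T + 1, R))
    z = np.zeros((T + 1, R, 4))
    r = np.zeros(T + 1)
    for k in range(T):
        xk = x[k]
        uk = uT[k]
        dx = A @ xk + C @ uk
        h = ar @ xk + cr @ uk
        for j in range(J):
            if uk[j] != 0.0:
                dx = dx + uk[j] * (B[j] @ xk)
                h += uk[j] * (br[j] @ xk)
        x[k + 1] = xk + dt * dx
        r[k + 1] = h - decay * r[k]
        for i in range(R):
            sh = z[k, i, 0]
            # log-states clamped to +-10: far outside physiology, so hitting
            # the clamp marks a diverging trial step without 0/0 arithmetic
            lf = min(max(z[k, i, 1], -10.0), 10.0)
            lv = min(max(z[k, i, 2], -10.0), 10.0)
            lq = min(max(z[k, i, 3], -10.0), 10.0)
            f = np.exp(lf)
            v = np.exp(lv)
            q = np.exp(lq)
            fv = v ** (1.0 / alpha)
            ef = 1.0 - (1.0 - e0) ** (1.0 / f)
            z[k + 1, i, 0] = sh + dt * (xk[i] - kappa * sh - gamma * (f - 1.0))
            z[k + 1, i, 1] = lf + dt * (sh / f)
            z[k + 1, i, 2] = lv + dt * ((f - fv) / (tau * v))
            z[k + 1, i, 3] = lq + dt * ((f * ef / e0 - fv * q / v) / (tau * q))
    return x, z, r


def rt_read_bins(
    onset_bins: np.ndarray, oversample: int, n_bins: int
) -> np.ndarray:
    """Micro-time bins at which trial RTs are read from the response state.

    Behavioral observations are assigned to the first resampled-grid point
    strictly after each target onset, so the readout always includes the
    trial's own input impulse and falls within one grid step (about a
    typical response latency) of the onset.
    """
    bins = (np.asarray(onset_bins) // oversample + 1) * oversample
    return np.minimum(bins, n_bins)


def integrate(
    structure: Optional[NetworkStructure],
    params: BDCMParams,
    streams: InputStreams,
    sample_bins: np.ndarray,
    rt_bins: Optional[np.ndarray] = None,
    oversample: int = DEFAULT_OVERSAMPLE,
) -> StateTrajectory:
    """Integrate the full generative model on the micro-time grid.

    ``sample_bins`` are the micro indices of the BOLD sampling grid;
    ``rt_bins`` the micro indices at which trial RTs are read (defaults to
    :func:`rt_read_bins` of the streams' onset bins).  Initial states are 0.
    """
    if structure is not None:
        params.validate(structure)
    u = np.ascontiguousarray(streams.u, dtype=float)
    dt = streams.dt_s
    T = u.shape[1]
    sample_bins = np.asarray(sample_bins, dtype=int)
    if sample_bins.size and sample_bins.max() > T:
        raise ValueError("sample_bins extend beyond the input streams")
    if rt_bins is None:
        rt_bins = rt_read_bins(streams.onset_bins, oversample, T)
    rt_bins = np.asarray(rt_bins, dtype=int)

    # crude stability proxy for the explicit-Euler neural update
    row_scale = np.abs(params.A).sum(axis=1).max() if params.A.size else 0.0
    if dt * row_scale > 1.0:
        warnings.warn(
            f"micro-time step {dt} s may exceed the stability bound of the "
            "neural dynamics; consider a finer grid",
            stacklevel=2,
        )

    x, z, r = _euler_core(
        np.ascontiguousarray(params.A, dtype=float),
        np.ascontiguousarray(params.B, dtype=float),
        np.ascontiguousarray(params.C, dtype=float),
        np.ascontiguousarray(params.ar, dtype=float),
        np.ascontiguousarray(params.br, dtype=float),
        np.ascontiguousarray(params.cr, dtype=float),
        float(params.decay),
        np.ascontiguousarray(u.T),
        float(dt),
        params.phi.kappa,
        params.phi.gamma,
        params.phi.tau,
        params.phi.alpha,
        params.phi.e0,
    )
    for name, arr in (("neural", x), ("hemodynamic", z), ("behavioral", r)):
        if not np.all(np.isfinite(arr)):
            bad = int(np.argwhere(~np.isfinite(arr))[0][0])
            raise FloatingPointError(
                f"non-finite {name} state at micro-time bin {bad} "
                f"(t = {bad * dt:.3f} s); the trajectory diverged"
            )

    # huge-but-finite states (a rejected trial step) may overflow here;
    # the non-finite predictions are screened by the caller
    with np.errstate(over="ignore", invalid="ignore"):
        y = bold_signal(z[sample_bins], params.phi).T  # regions x samples
        s_pred = rt_observe(r[rt_bins], params.rho)
    if not np.all(np.isfinite(y)):
        bad = int(np.argwhere(~np.isfinite(y))[0][1])
        raise FloatingPointError(
            f"non-finite BOLD prediction at micro-time bin "
            f"{int(sample_bins[bad])}; the trajectory diverged"
        )
    return StateTrajectory(
        x=x,
        z=z,
        r=r,
        y_pred=y,
        s_pred=np.asarray(s_pred, dtype=float),
        sample_bins=sample_bins,
        rt_bins=rt_bins,
        dt_s=dt,
    )


def hemodynamic_observe(
    x_traj: np.ndarray,
    phi: HemodynamicParams,
    dt: float,
    sample_bins: Optional[np.ndarray] = None,
) -> np.ndarray:
    """BOLD prediction from a given neural trajectory (regions x micro-time).

    Integrates the balloon cascade per region with explicit Euler in log
    space and applies the static BOLD nonlinearity; used directly in tests
    and diagnostics, and implicitly by :func:`integrate`.
    """
    x_traj = np.atleast_2d(np.asarray(x_traj, dtype=float))
    n_regions, T = x_traj.shape
    z = np.zeros((n_regions, 4))
    out = np.zeros((n_regions, T))
    for k in range(T):
        out[:, k] = bold_signal(z, phi)
        for i in range(n_regions):
            z[i] += dt * hemodynamic_derivative(z[i], x_traj[i, k], phi)
        if not np.all(np.isfinite(z)):
            raise FloatingPointError(
                f"non-finite hemodynamic state at micro-time bin {k + 1}"
            )
    if sample_bins is not None:
        out = out[:, np.asarray(sample_bins, dtype=int)]
    return out
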