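"""Parameter-vector wrapper exposing the generative model to the inversion engine.

:class:`BDCMModel` flattens the masked entries of the neural matrices, the
hemodynamic scaling factors, and the behavioral parameters into a single
vector with diagonal Gaussian priors, and maps a vector back to a full
:class:`~bdcm.network.BDCMParams` for integration.  Self-connections are
estimated as latent values ``d`` with ``A[i, i] = -0.5 * exp(d)``, and the
hemodynamic decay and transit time as shared log-scaling factors, so these
quantities keep their physiological sign for any vector.

Setting the prior mean *and* variance of every behavioral parameter
(``ar``, ``br``, ``cr``, ``decay``, ``rho``) to zero makes the behavioral
branch inert and the model a classical DCM of the BOLD channel alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .design import InputStreams
from .forward import DEFAULT_OVERSAMPLE, StateTrajectory, integrate, rt_read_bins
from .network import BDCMParams, HemodynamicParams, NetworkStructure
from .preprocess import BehavioralSeries, BOLDSeries

__all__ = ["PriorBlock", "BDCMModel", "DEFAULT_PRIOR_SD"]

# Default prior standard deviations per parameter block (documented package
# constants in the spirit of common DCM defaults; the behavioral decay prior
# is centered on 0.5 so the response state forgets within a few steps).
DEFAULT_PRIOR_SD = {
    "A": 0.5,
    "A_diag": 0.5,  # latent log-scale of the self-connections
    "B": 4.0,  # impulse-scale modulations are large relative to couplings
    "C": 0.5,
    "hemo": 0.125,  # log-scales of kappa and tau
    "ar": 1.0,
    "br": 1.0,
    "cr": 1.0,
    "decay": 1.0,
    "rho": 1.0,
}
DECAY_PRIOR_MEAN = 0.5


@dataclass
class PriorBlock:
    """Prior mean/sd override for one named parameter block."""

    mean: Optional[float] = None
    sd: Optional[float] = None


class BDCMModel:
    """Joint BOLD + reaction-time model over a fixed design.

    Parameters
    ----------
    structure : network masks (connections, inputs, output regions).
    streams : centered micro-time input streams of the run.
    bold : preprocessed BOLD series whose observed samples form the BOLD
        channel; ``None`` for a behavior-only model.
    behavior : screened reaction times whose included trials form the RT
        channel; ``None`` for a BOLD-only (classical DCM) fit.
    estimate_behavior : fix all behavioral parameters at 0 when False
        (classical DCM); their prior variances become 0.
    estimate_hemo : whether the hemodynamic log-scales are estimated.
    """

    def __init__(
        self,
        structure: NetworkStructure,
        streams: InputStreams,
        bold: Optional[BOLDSeries] = None,
        behavior: Optional[BehavioralSeries] = None,
        phi: Optional[HemodynamicParams] = None,
        estimate_behavior: bool = True,
        estimate_hemo: bool = True,
        prior_overrides: Optional[dict[str, PriorBlock]] = None,
        oversample: int = DEFAULT_OVERSAMPLE,
    ) -> None:
        self.structure = structure
        self.streams = streams
        self.bold = bold
        self.behavior = behavior
        self.phi = phi or HemodynamicParams()
        self.oversample = oversample
        self.estimate_behavior = estimate_behavior

        if bold is not None:
            times = bold.sample_times[bold.observed_mask]
            self.sample_bins = np.round(times / streams.dt_s).astype(int)
            if self.sample_bins.max(initial=0) > streams.n_bins:
                raise ValueError("BOLD samples extend beyond the input streams")
        else:
            self.sample_bins = np.arange(0)
        self.rt_bins = rt_read_bins(
            streams.onset_bins, oversample, streams.n_bins
        )

        overrides = prior_overrides or {}

        def block(name: str, default_mean: float = 0.0) -> tuple[float, float]:
            ov = overrides.get(name, PriorBlock())
            mean = default_mean if ov.mean is None else ov.mean
            sd = DEFAULT_PRIOR_SD[name] if ov.sd is None else ov.sd
            return mean, sd

        labels = structure.region_labels
        entries: list[tuple] = []  # (kind, index-tuple)
        names: list[str] = []
        means: list[float] = []
        sds: list[float] = []

        def add(kind, idx, name, mean, sd):
            entries.append((kind, idx))
            names.append(name)
            means.append(mean)
            sds.append(sd)

        m, s = block("A_diag")
        for i in range(structure.n_regions):
            add("A_diag", (i,), f"A_self[{labels[i]}]", m, s)
        m, s = block("A")
        for i, j in zip(*np.nonzero(structure.A_mask)):
            if i != j:
                add("A", (int(i), int(j)), f"A[{labels[i]}<-{labels[j]}]", m, s)
        m, s = block("B")
        for k in range(structure.n_inputs):
            for i, j in zip(*np.nonzero(structure.B_masks[k])):
                add(
                    "B",
                    (k, int(i), int(j)),
                    f"B{k + 1}[{labels[i]}<-{labels[j]}]",
                    m,
                    s,
                )
        m, s = block("C")
        for i, k in zip(*np.nonzero(structure.C_mask)):
            add("C", (int(i), int(k)), f"C[{labels[i]}<-u{k + 1}]", m, s)
        if estimate_hemo:
            m, s = block("hemo")
            add("hemo_kappa", (), "hemo_log_kappa", m, s)
            add("hemo_tau", (), "hemo_log_tau", m, s)
        beh_scale = 1.0 if estimate_behavior else 0.0
        m, s = block("ar")
        for i in np.flatnonzero(structure.Ar_mask):
            add("ar", (int(i),), f"Ar[{labels[i]}]", m * beh_scale, s * beh_scale)
        m, s = block("br")
        for k in range(structure.n_inputs):
            for i in np.flatnonzero(structure.Br_masks[k]):
                add(
                    "br",
                    (k, int(i)),
                    f"Br{k + 1}[{labels[i]}]",
                    m * beh_scale,
                    s * beh_scale,
                )
        m, s = block("cr")
        for k in np.flatnonzero(structure.Cr_mask):
            add("cr", (int(k),), f"Cr[u{k + 1}]", m * beh_scale, s * beh_scale)
        m, s = block("decay", DECAY_PRIOR_MEAN)
        add("decay", (), "decay", m * beh_scale, s * beh_scale)
        m, s = block("rho")
        add("rho", (), "rho", m * beh_scale, s * beh_scale)

        self._entries = entries
        self.param_names = names
        self.prior_mean = np.asarray(means, dtype=float)
        self.prior_var = np.asarray(sds, dtype=float) ** 2

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def n_estimated(self) -> int:
        return int(np.sum(self.prior_var > 0))

    def params_from_theta(self, theta: np.ndarray) -> BDCMParams:
        """Assemble full generative parameters from a flat vector."""
        p = BDCMParams.zeros(self.structure)
        p.phi = HemodynamicParams(
            kappa=self.phi.kappa,
            gamma=self.phi.gamma,
            tau=self.phi.tau,
            alpha=self.phi.alpha,
            e0=self.phi.e0,
            v0=self.phi.v0,
        )
        for val, (kind, idx) in zip(theta, self._entries):
            if kind == "A_diag":
                p.A[idx[0], idx[0]] = -0.5 * np.exp(val)
            elif kind == "A":
                p.A[idx] = val
            elif kind == "B":
                p.B[idx] = val
            elif kind == "C":
                p.C[idx] = val
            elif kind == "hemo_kappa":
                p.phi.kappa = self.phi.kappa * np.exp(val)
            elif kind == "hemo_tau":
                p.phi.tau = self.phi.tau * np.exp(val)
            elif kind == "ar":
                p.ar[idx] = val
            elif kind == "br":
                p.br[idx] = val
            elif kind == "cr":
                p.cr[idx] = val
            elif kind == "decay":
                p.decay = val
            elif kind == "rho":
                p.rho = val
        return p

    def theta_from_params(self, params: BDCMParams) -> np.ndarray:
        """Flat vector for known generative parameters (e.g. ground truth)."""
        theta = np.empty(self.n_params)
        for n, (kind, idx) in enumerate(self._entries):
            if kind == "A_diag":
                a_ii = params.A[idx[0], idx[0]]
                if a_ii >= 0:
                    raise ValueError("self-connections must be negative")
                theta[n] = np.log(-a_ii / 0.5)
            elif kind == "A":
                theta[n] = params.A[idx]
            elif kind == "B":
                theta[n] = params.B[idx]
            elif kind == "C":
                theta[n] = params.C[idx]
            elif kind == "hemo_kappa":
                theta[n] = np.log(params.phi.kappa / self.phi.kappa)
            elif kind == "hemo_tau":
                theta[n] = np.log(params.phi.tau / self.phi.tau)
            elif kind == "ar":
                theta[n] = params.ar[idx]
            elif kind == "br":
                theta[n] = params.br[idx]
            elif kind == "cr":
                theta[n] = params.cr[idx]
            elif kind == "decay":
                theta[n] = params.decay
            elif kind == "rho":
                theta[n] = params.rho
        return theta

    def trajectory(self, theta: np.ndarray) -> StateTrajectory:
        return integrate(
            None,
            self.params_from_theta(theta),
            self.streams,
            self.sample_bins,
            self.rt_bins,
            oversample=self.oversample,
        )

    def predict(self, theta: np.ndarray) -> dict[str, np.ndarray]:
        traj = self.trajectory(theta)
        out: dict[str, np.ndarray] = {}
        if self.bold is not None:
            out["bold"] = traj.y_pred.ravel()
        if self.behavior is not None:
            out["rt"] = traj.s_pred[self.behavior.include_mask]
        return out

    def data(self) -> dict[str, np.ndarray]:
        """The observation vectors matching :meth:`predict`'s channels."""
        out: dict[str, np.ndarray] = {}
        if self.bold is not None:
            out["bold"] = self.bold.observed.ravel()
        if self.behavior is not None:
            out["rt"] = self.behavior.included_rts
        return out
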