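"""Candidate-model construction and Bayesian model selection across subjects.

The candidate space contains four output-region hypotheses (the behavioral
state reads bilateral IPS, FEF, or TPJ, or all six regions), a classical
DCM (behavioral parameters fixed at zero), and two hybrids that inject a
trial-level learning model: one routes its predicted reaction times in as
an extra input stream gated straight to the behavioral state (``bdcm+rw``),
the other replaces the binary invalid-trial input with the learner's
predicted cue invalidity of the previous trial (``bdcm*rw``).

Model selection operates on a subjects x models matrix of free energies:
fixed-effects (FFX) selection sums log evidence over subjects and applies a
softmax under a uniform model prior; random-effects (RFX) selection fits a
variational Dirichlet-multinomial model of per-subject model frequencies
and reports expected frequencies and exceedance probabilities (the
posterior probability that each model is the most frequent one).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.special import digamma, logsumexp
from scipy.stats import beta as beta_dist

from .design import TaskDesign, build_input_streams
from .model import BDCMModel, PriorBlock
from .network import NetworkStructure, default_posner_structure

__all__ = [
    "ModelVariant",
    "ModelEvidenceTable",
    "FFXResult",
    "RFXResult",
    "build_model_variant",
    "ffx_bms",
    "rfx_bms",
    "OUTPUT_REGION_VARIANTS",
]

OUTPUT_REGION_VARIANTS = ("output-IPS", "output-FEF", "output-TPJ", "output-all")
_ALL_VARIANTS = OUTPUT_REGION_VARIANTS + ("classical-DCM", "bDCM+RW", "bDCMxRW")


@dataclass
class ModelVariant:
    """A candidate model: structure, behavioral switches, stream recipe."""

    name: str
    structure: NetworkStructure
    estimate_behavior: bool = True
    include_u3: bool = False
    u2_is_rw_belief: bool = False
    rw_predictions: Optional[np.ndarray] = None  # per-trial RT predictions (u3)
    rw_belief: Optional[np.ndarray] = None  # per-trial v_{t-1} (u2 substitute)
    prior_overrides: dict[str, PriorBlock] = field(default_factory=dict)

    def build_streams(self, design: TaskDesign, dt_s: float):
        """Input streams implementing this variant's input convention."""
        return build_input_streams(
            design,
            dt_s,
            rw_prediction=self.rw_predictions,
            include_u3=self.include_u3,
            u2_values=self.rw_belief if self.u2_is_rw_belief else None,
            center=True,
        )

    def build_model(self, design, dt_s, bold=None, behavior=None, **kwargs) -> BDCMModel:
        return BDCMModel(
            self.structure,
            self.build_streams(design, dt_s),
            bold=bold,
            behavior=behavior,
            estimate_behavior=self.estimate_behavior,
            prior_overrides=self.prior_overrides,
            **kwargs,
        )


def build_model_variant(
    variant: str,
    base: Optional[NetworkStructure] = None,
    rw_predictions: Optional[np.ndarray] = None,
    rw_belief: Optional[np.ndarray] = None,
) -> ModelVariant:
    """Construct one of the named candidate models.

    ``output-<REGION>`` variants set the behavioral readout to the bilateral
    region (or all regions for ``output-all``); ``classical-DCM`` fixes every
    behavioral parameter at zero; ``bDCM+RW`` adds a third input stream of
    per-trial learning-model RT predictions routed only through the direct
    behavioral gain (never the neural matrices); ``bDCMxRW`` replaces the
    binary invalid-trial stream with the learner's predicted cue invalidity
    ``v_{t-1}`` (``rw_belief``).
    """
    if base is None:
        base = default_posner_structure()
    if variant.startswith("output-"):
        area = variant.removeprefix("output-")
        if area == "all":
            return ModelVariant(variant, base.with_output_regions(base.region_labels))
        labels = [lab for lab in base.region_labels if lab.startswith(area + "-")]
        if not labels:
            raise ValueError(f"unknown output region {area!r} in {variant!r}")
        return ModelVariant(variant, base.with_output_regions(labels))
    if variant == "classical-DCM":
        return ModelVariant(variant, base, estimate_behavior=False)
    if variant == "bDCM+RW":
        if rw_predictions is None:
            raise ValueError("bDCM+RW requires per-trial rw_predictions")
        st = base.with_n_inputs(base.n_inputs + 1)
        cr = st.Cr_mask.copy()
        cr[-1] = True  # u3 gated straight to the behavioral state
        st = replace(st, Cr_mask=cr)
        return ModelVariant(
            variant,
            st,
            include_u3=True,
            rw_predictions=np.asarray(rw_predictions, dtype=float),
        )
    if variant == "bDCMxRW":
        if rw_belief is None:
            raise ValueError("bDCMxRW requires per-trial rw_belief values")
        return ModelVariant(
            variant,
            base,
            u2_is_rw_belief=True,
            rw_belief=np.asarray(rw_belief, dtype=float),
        )
    raise ValueError(f"unknown variant {variant!r}; known: {_ALL_VARIANTS}")


@dataclass
class ModelEvidenceTable:
    """Subjects x models log-evidence (free-energy) matrix."""

    log_evidence: np.ndarray
    model_labels: Sequence[str]
    subject_labels: Optional[Sequence[str]] = None
    condition: Optional[str] = None  # e.g. run axis

    def __post_init__(self) -> None:
        self.log_evidence = np.atleast_2d(np.asarray(self.log_evidence, dtype=float))
        if not np.all(np.isfinite(self.log_evidence)):
            raise ValueError("log evidence must be finite")
        if self.log_evidence.shape[1] != len(self.model_labels):
            raise ValueError("model_labels length must match columns")
        if self.log_evidence.shape[1] < 2:
            raise ValueError("need at least 2 models for comparison")
        if self.subject_labels is None:
            self.subject_labels = [
                f"sub-{i + 1:02d}" for i in range(self.log_evidence.shape[0])
            ]


@dataclass
class FFXResult:
    """Fixed-effects selection: summed evidence and posterior model probability."""

    model_labels: Sequence[str]
    total_log_evidence: np.ndarray
    posterior_prob: np.ndarray

    @property
    def best_model(self) -> str:
        return self.model_labels[int(np.argmax(self.total_log_evidence))]


@dataclass
class RFXResult:
    """Random-effects selection: Dirichlet posterior over model frequencies."""

    model_labels: Sequence[str]
    alpha: np.ndarray  # Dirichlet concentrations
    expected_frequency: np.ndarray
    exceedance_probability: np.ndarray
    converged: bool
    ep_method: str  # "beta-exact" (2 models) or "monte-carlo"

    @property
    def best_model(self) -> str:
        return self.model_labels[int(np.argmax(self.exceedance_probability))]


def ffx_bms(table: ModelEvidenceTable) -> FFXResult:
    """Sum log evidence over subjects; softmax under a uniform model prior."""
    total = table.log_evidence.sum(axis=0)
    prob = np.exp(total - logsumexp(total))
    return FFXResult(
        model_labels=list(table.model_labels),
        total_log_evidence=total,
        posterior_prob=prob,
    )


def rfx_bms(
    table: ModelEvidenceTable,
    n_samples: int = 100_000,
    seed: int = 0,
    alpha0: float = 1.0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> RFXResult:
    """Variational Dirichlet-multinomial random-effects model selection.

    Iterates per-subject model posteriors and Dirichlet concentrations to
    convergence from a uniform Dirichlet prior.  Exceedance probabilities
    use the closed-form Beta tail for two models and otherwise seeded
    sampling from the Dirichlet posterior.
    """
    lnE = table.log_evidence
    n_sub, n_mod = lnE.shape
    alpha = np.full(n_mod, alpha0)
    converged = False
    for _ in range(max_iter):
        w = lnE + (digamma(alpha) - digamma(alpha.sum()))
        u = np.exp(w - logsumexp(w, axis=1, keepdims=True))
        alpha_new = alpha0 + u.sum(axis=0)
        if np.abs(alpha_new - alpha).max() < tol:
            alpha = alpha_new
            converged = True
            break
        alpha = alpha_new

    if n_mod == 2:
        ep1 = float(beta_dist.sf(0.5, alpha[0], alpha[1]))
        ep = np.array([ep1, 1.0 - ep1])
        method = "beta-exact"
    else:
        rng = np.random.default_rng(seed)
        draws = rng.dirichlet(alpha, size=n_samples)
        winners = np.argmax(draws, axis=1)
        ep = np.bincount(winners, minlength=n_mod) / n_samples
        method = "monte-carlo"

    return RFXResult(
        model_labels=list(table.model_labels),
        alpha=alpha,
        expected_frequency=alpha / alpha.sum(),
        exceedance_probability=ep,
        converged=converged,
        ep_method=method,
    )
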