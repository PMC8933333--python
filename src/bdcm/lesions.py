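"""In-silico lesions: silence a region's afferents and re-simulate behavior.

An artificial lesion zeroes every incoming fixed (A) and modulatory (B)
connection of one region — and, by default, its driving inputs (C) — in a
fitted model, leaving all other parameters and the trial timing untouched.
Re-simulating the lesioned model noiselessly shows how behavior would
change without that region's contribution.  Because the steep bounded
readout can pin simulated reaction times at the sigmoid's floor or
ceiling, each simulation is screened for numerical degeneracy: runs whose
RT variance after the 10th trial falls below a flatline tolerance, or that
produce non-finite values, are flagged unstable and excluded from
summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .design import InputStreams, TaskDesign
from .evaluation import validity_effect
from .forward import DEFAULT_OVERSAMPLE, integrate, rt_read_bins
from .network import BDCMParams, NetworkStructure

__all__ = ["LesionResult", "apply_lesion", "simulate_lesion", "run_lesion_battery"]

FLATLINE_VARIANCE_S2 = 1e-6  # RT variance after trial 10 below this -> flatline


@dataclass
class LesionResult:
    """Simulated behavior of one (possibly intact) lesioned model."""

    lesioned_region: Optional[str]  # None for the intact model
    subject: Optional[str]
    simulated_rts: np.ndarray
    validity_effect_by_location: dict[str, Optional[float]]
    validity_effect_overall: Optional[float]
    stable: bool
    instability_reason: str  # {"none", "flatline", "nonfinite"}


def apply_lesion(
    params: BDCMParams,
    region: str,
    structure: NetworkStructure,
    zero_driving: bool = True,
) -> BDCMParams:
    """Return a copy of ``params`` with the region's afferents set to 0.

    The region's incoming row in A (except its self-connection, which keeps
    the state dissipative) and in every B matrix is zeroed; with
    ``zero_driving`` its C entries are zeroed too, so the silenced region
    receives nothing at all.  The original parameters are not modified, and
    lesioning the same region twice is a no-op the second time.
    """
    i = structure.region_index(region)
    out = params.copy()
    keep_self = out.A[i, i]
    out.A[i, :] = 0.0
    out.A[i, i] = keep_self
    out.B[:, i, :] = 0.0
    if zero_driving:
        out.C[i, :] = 0.0
    return out


def simulate_lesion(
    params: BDCMParams,
    structure: NetworkStructure,
    design: TaskDesign,
    streams: InputStreams,
    region: Optional[str] = None,
    subject: Optional[str] = None,
    zero_driving: bool = True,
    oversample: int = DEFAULT_OVERSAMPLE,
) -> LesionResult:
    """Noiselessly simulate (lesioned) behavior and screen for stability."""
    p = (
        params.copy()
        if region is None
        else apply_lesion(params, region, structure, zero_driving)
    )
    rt_bins = rt_read_bins(streams.onset_bins, oversample, streams.n_bins)
    try:
        traj = integrate(None, p, streams, np.arange(0), rt_bins, oversample)
        rts = traj.s_pred
        nonfinite = not np.all(np.isfinite(rts))
    except FloatingPointError:
        rts = np.full(design.n_trials, np.nan)
        nonfinite = True

    if nonfinite:
        stable, reason = False, "nonfinite"
    elif len(rts) > 10 and float(np.var(rts[10:])) < FLATLINE_VARIANCE_S2:
        stable, reason = False, "flatline"
    else:
        stable, reason = True, "none"

    validity = design.invalid01
    locations = np.asarray(design.locations)
    by_loc: dict[str, Optional[float]] = {}
    if stable:
        for loc in dict.fromkeys(design.locations):
            sel = locations == loc
            by_loc[loc] = validity_effect(rts[sel], validity[sel])
        overall = validity_effect(rts, validity)
    else:
        by_loc = {loc: None for loc in dict.fromkeys(design.locations)}
        overall = None
    return LesionResult(
        lesioned_region=region,
        subject=subject,
        simulated_rts=rts,
        validity_effect_by_location=by_loc,
        validity_effect_overall=overall,
        stable=stable,
        instability_reason=reason,
    )


def run_lesion_battery(
    fitted_params: Sequence[BDCMParams],
    structure: NetworkStructure,
    design: TaskDesign,
    streams: InputStreams,
    regions: Optional[Sequence[str]] = None,
    subjects: Optional[Sequence[str]] = None,
    zero_driving: bool = True,
    include_intact: bool = True,
    oversample: int = DEFAULT_OVERSAMPLE,
) -> list[LesionResult]:
    """Lesion every region in every fitted model; instability is data.

    Returns one result per (subject, lesion) pair — plus the intact model
    per subject when ``include_intact`` — mirroring a per-target-location
    validity-effect summary over subjects.
    """
    if not len(fitted_params):
        raise ValueError("need at least one fitted model")
    if regions is None:
        regions = structure.region_labels
    if subjects is None:
        subjects = [f"sub-{i + 1:02d}" for i in range(len(fitted_params))]
    results = []
    for sub, params in zip(subjects, fitted_params):
        targets: list[Optional[str]] = (
            [None] if include_intact else []
        ) + list(regions)
        for region in targets:
            results.append(
                simulate_lesion(
                    params,
                    structure,
                    design,
                    streams,
                    region=region,
                    subject=sub,
                    zero_driving=zero_driving,
                    oversample=oversample,
                )
            )
    return results
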