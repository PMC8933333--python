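"""Synthetic datasets from a known ground-truth generative model.

The simulator integrates the joint generative model on a task design,
samples BOLD at the scanner TR and reaction times at (one resampled grid
step after) the target onsets, and adds seeded Gaussian observation noise.
BOLD noise is specified as a signal-to-noise ratio (signal variance over
noise variance, per region); RT noise as a standard deviation in seconds.

``default_ground_truth`` provides a calibrated parameterization of the
six-region attention network in which the invalid-trial modulation routes
through IPS (the output region), producing reaction times of roughly
0.4-0.8 s with a validity effect of about 0.1 s — the magnitudes a typical
cueing experiment shows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .design import InputStreams, TaskDesign, build_input_streams
from .forward import DEFAULT_OVERSAMPLE, integrate, rt_read_bins
from .network import BDCMParams, NetworkStructure, default_posner_structure
from .preprocess import BehavioralSeries, BOLDSeries

__all__ = [
    "NoiseSpec",
    "SimulatedDataset",
    "simulate_dataset",
    "default_ground_truth",
]


@dataclass
class NoiseSpec:
    """Observation-noise levels: per-region BOLD SNR and RT noise sd (s)."""

    bold_snr: Optional[float] = 10.0  # None -> noiseless BOLD
    rt_noise_sd: float = 0.02


@dataclass
class SimulatedDataset:
    """A simulated run plus everything needed to score recovery."""

    bold: BOLDSeries  # noisy BOLD at the acquisition TR (all samples observed)
    behavior: BehavioralSeries  # noisy RTs, all trials included
    streams: InputStreams
    params: BDCMParams  # ground truth
    y_clean: np.ndarray  # noiseless BOLD, regions x volumes
    rt_clean: np.ndarray  # noiseless RTs per trial
    seed: int


def simulate_dataset(
    structure: NetworkStructure,
    params: BDCMParams,
    design: TaskDesign,
    noise: Optional[NoiseSpec] = None,
    seed: int = 0,
    tr_s: float = 2.2,
    target_dt_s: float = 1.1,
    oversample: int = DEFAULT_OVERSAMPLE,
) -> SimulatedDataset:
    """Simulate one run of joint BOLD + reaction-time data.

    The input streams are centered, as they are at inversion time, so the
    simulated subject and the fitted model share the same input convention.
    """
    if noise is None:
        noise = NoiseSpec()
    params.validate(structure)
    dt = target_dt_s / oversample
    streams = build_input_streams(design, dt, center=True)
    grid_step = int(round(tr_s / target_dt_s))
    n_grid = streams.n_bins // oversample
    vol_bins = np.arange(0, n_grid + 1, grid_step) * oversample
    rt_bins = rt_read_bins(streams.onset_bins, oversample, streams.n_bins)

    traj = integrate(structure, params, streams, vol_bins, rt_bins, oversample)
    y_clean = traj.y_pred
    rt_clean = traj.s_pred

    rng = np.random.default_rng(seed)
    y = y_clean.copy()
    if noise.bold_snr is not None and np.isfinite(noise.bold_snr):
        sd = np.sqrt(y_clean.var(axis=1) / noise.bold_snr)
        y = y + rng.normal(size=y.shape) * sd[:, None]
    rts = rt_clean.copy()
    if noise.rt_noise_sd:
        rts = rts + rng.normal(0.0, noise.rt_noise_sd, size=rts.shape)

    bold = BOLDSeries(
        values=y,
        tr_s=tr_s,
        region_labels=structure.region_labels,
        observed_mask=np.ones(y.shape[1], dtype=bool),
    )
    behavior = BehavioralSeries(
        rt_s=rts,
        include_mask=np.ones(len(rts), dtype=bool),
        exclusion_reason=np.full(len(rts), "none", dtype=object),
    )
    return SimulatedDataset(
        bold=bold,
        behavior=behavior,
        streams=streams,
        params=params.copy(),
        y_clean=y_clean,
        rt_clean=rt_clean,
        seed=seed,
    )


def default_ground_truth(
    structure: Optional[NetworkStructure] = None,
    carrier: str = "IPS",
) -> tuple[NetworkStructure, BDCMParams]:
    """Calibrated six-region ground truth with IPS driving behavior.

    The invalid-trial input strengthens the connections into the bilateral
    ``carrier`` regions (default IPS), whose neural states alone feed the
    response state, so invalid trials slow the simulated responses.  The
    readout bias places baseline reaction times near 0.5 s.
    """
    if structure is None:
        structure = default_posner_structure(
            output_regions=(f"{carrier}-L", f"{carrier}-R")
        )
    p = BDCMParams.zeros(structure)
    labels = structure.region_labels
    np.fill_diagonal(p.A, -0.6)
    # heterogeneous coupling and drive: feedforward and feedback routes
    # differ and ventral drive is weaker — regions must differ for the
    # output-region question to be well posed.  Magnitudes keep the system
    # comfortably dissipative (max eigenvalue well below 0) so moderate
    # between-subject variation cannot destabilize it.
    coupling = {
        ("IPS", "FEF"): 0.05, ("FEF", "IPS"): 0.15,
        ("TPJ", "IPS"): 0.05, ("IPS", "TPJ"): 0.15,
        ("TPJ", "FEF"): 0.05, ("FEF", "TPJ"): 0.10,
    }
    drive = {"IPS": 0.9, "FEF": 0.6, "TPJ": 0.4}
    off_diag = structure.A_mask & ~np.eye(structure.n_regions, dtype=bool)
    for i, tgt in enumerate(labels):
        for j, src in enumerate(labels):
            if not off_diag[i, j]:
                continue
            a_tgt, a_src = tgt.rsplit("-", 1)[0], src.rsplit("-", 1)[0]
            p.A[i, j] = 0.1 if a_tgt == a_src else coupling.get((a_src, a_tgt), 0.1)
        if structure.C_mask[i, 0]:
            p.C[i, 0] = drive.get(tgt.rsplit("-", 1)[0], 0.7)
    # invalid trials transiently boost the modulated connections, most
    # strongly those into the carrier; the readout weight is negative
    # because neural states sit below their (zero) temporal mean just
    # before each target under centered inputs
    for j in range(structure.n_inputs):
        for i, tgt in enumerate(labels):
            row = structure.B_masks[j, i]
            if row.any():
                p.B[j, i, row] = 10.0 if tgt.startswith(carrier) else 1.0
    p.ar[structure.Ar_mask] = -0.04
    p.decay = 0.3
    p.rho = -0.0161  # baseline RT near 0.5 s when r is at rest
    return structure, p
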