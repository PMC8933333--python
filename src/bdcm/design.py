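"""Posner spatial-cueing task designs and model input streams.

The experiment emulated here is a probabilistic spatial-cueing paradigm: a
central cue indicates the upcoming target location with 80% validity; on the
remaining 20% of trials the target appears at the opposite location and
attention must be reoriented.  A run consists of blocks of trials in which
target location (two per run axis), target orientation, and cue-target SOA are
fully crossed and presented in random order.

Input streams are the micro-time driving/modulatory vectors of the network
model: ``u1`` carries a unit impulse at every target onset, ``u2`` carries
impulses at invalidly cued targets only (or, in the learning-infused variant,
the learner's predicted cue invalidity), and an optional ``u3`` carries
trial-wise reaction-time predictions from a behavioral learning model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import product
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Trial",
    "TaskDesign",
    "InputStreams",
    "generate_task_design",
    "build_input_streams",
    "DEFAULT_SOAS",
    "DEFAULT_ITIS",
]

DEFAULT_SOAS = (0.4, 0.6)
DEFAULT_ITIS = (2.0, 2.7, 3.2, 3.9, 4.5)
ORIENTATIONS = ("horizontal", "vertical")
AXIS_LOCATIONS = {"horizontal": ("left", "right"), "vertical": ("down", "up")}

# Trial timing (seconds): trial start -> cue onset, then cue -> target = SOA,
# then a fixed response window before the inter-trial interval begins.
CUE_DELAY_S = 1.0
RESPONSE_WINDOW_S = 1.5
DEFAULT_BLOCK_BREAK_S = 11.5  # midpoint of the 10-13 s inter-block break


@dataclass
class Trial:
    """One cueing trial; ``onset_s`` is the target onset from run start."""

    index: int
    onset_s: float
    validity: str  # "valid" | "invalid"
    target_location: str
    target_orientation: str
    soa_s: float
    iti_s: float
    block: int
    response_correct: bool = True
    rt_s: Optional[float] = None  # None until simulated or measured


@dataclass
class TaskDesign:
    """An ordered set of trials for one run of the cueing task."""

    trials: list[Trial]
    run_axis: str
    n_blocks: int
    trials_per_block: int

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def onsets(self) -> np.ndarray:
        return np.array([t.onset_s for t in self.trials], dtype=float)

    @property
    def invalid01(self) -> np.ndarray:
        """Per-trial cue invalidity: 1 on invalid, 0 on valid trials."""
        return np.array(
            [1.0 if t.validity == "invalid" else 0.0 for t in self.trials]
        )

    @property
    def locations(self) -> list[str]:
        return [t.target_location for t in self.trials]

    @property
    def duration_s(self) -> float:
        if not self.trials:
            return 0.0
        last = self.trials[-1]
        return last.onset_s + RESPONSE_WINDOW_S + last.iti_s


def generate_task_design(
    n_blocks: int = 5,
    trials_per_block: int = 40,
    invalid_fraction: float = 0.2,
    soas: Sequence[float] = DEFAULT_SOAS,
    itis: Sequence[float] = DEFAULT_ITIS,
    run_axis: str = "horizontal",
    seed: int = 0,
    block_break_s: float = DEFAULT_BLOCK_BREAK_S,
) -> TaskDesign:
    """Generate a randomized, balanced cueing-task design.

    Within each block the location x orientation x SOA cells are repeated as
    evenly as the trial count allows, the per-block invalid-trial count is
    exactly ``round(trials_per_block * invalid_fraction)`` (which must be an
    integer number of trials), invalid trials are spread over cells as evenly
    as possible, and trial order is shuffled.  Defaults reproduce a 5-block,
    40-trial (32 valid / 8 invalid) run with SOAs {0.4, 0.6} s and ITIs drawn
    from {2.0, 2.7, 3.2, 3.9, 4.5} s.
    """
    if n_blocks < 0:
        raise ValueError("n_blocks must be >= 0")
    if trials_per_block <= 0:
        raise ValueError("trials_per_block must be positive")
    if not soas or not itis:
        raise ValueError("soas and itis must be non-empty")
    if run_axis not in AXIS_LOCATIONS:
        raise ValueError(f"unknown run_axis {run_axis!r}")
    n_invalid_f = trials_per_block * invalid_fraction
    n_invalid = int(round(n_invalid_f))
    if abs(n_invalid_f - n_invalid) > 1e-9:
        raise ValueError(
            f"trials_per_block * invalid_fraction = {n_invalid_f} is not an "
            "integer; choose a fraction yielding a whole number of invalid "
            "trials per block"
        )

    rng = np.random.default_rng(seed)
    locations = AXIS_LOCATIONS[run_axis]
    cells = list(product(locations, ORIENTATIONS, tuple(soas)))
    n_cells = len(cells)

    trials: list[Trial] = []
    t_cursor = 0.0
    index = 0
    for block in range(n_blocks):
        # Balanced cell repetitions; remainder cells chosen by seed.
        reps = trials_per_block // n_cells
        rem = trials_per_block % n_cells
        cell_ids = np.repeat(np.arange(n_cells), reps)
        if rem:
            cell_ids = np.concatenate(
                [cell_ids, rng.choice(n_cells, size=rem, replace=False)]
            )
        # Spread invalid trials over cells as evenly as possible.
        counts = np.bincount(cell_ids, minlength=n_cells)
        inv_per_cell = np.minimum(n_invalid // n_cells, counts)
        leftover = n_invalid - int(inv_per_cell.sum())
        order = rng.permutation(n_cells)
        for c in order:
            if leftover == 0:
                break
            if inv_per_cell[c] < counts[c]:
                inv_per_cell[c] += 1
                leftover -= 1
        if leftover:
            raise ValueError("invalid count exceeds trials per block")

        block_rows = []
        for c, cell in enumerate(cells):
            ids = np.flatnonzero(cell_ids == c)
            for k in range(len(ids)):
                block_rows.append((cell, k < inv_per_cell[c]))
        rng.shuffle(block_rows)

        for (loc, orient, soa), is_invalid in block_rows:
            iti = float(rng.choice(np.asarray(itis, dtype=float)))
            onset = t_cursor + CUE_DELAY_S + soa
            trials.append(
                Trial(
                    index=index,
                    onset_s=round(onset, 6),
                    validity="invalid" if is_invalid else "valid",
                    target_location=loc,
                    target_orientation=orient,
                    soa_s=float(soa),
                    iti_s=iti,
                    block=block,
                    )
            )
            t_cursor = onset + RESPONSE_WINDOW_S + iti
            index += 1
        if block < n_blocks - 1:
            t_cursor += block_break_s

    return TaskDesign(
        trials=trials,
        run_axis=run_axis,
        n_blocks=n_blocks,
        trials_per_block=trials_per_block,
    )


@dataclass
class InputStreams:
    """Micro-time input streams driving the network model."""

    dt_s: float
    u: np.ndarray  # streams x micro-time bins
    centered: bool
    onset_bins: np.ndarray  # per-trial micro-time bin of target onset
    names: tuple[str, ...] = ("u1",)

    @property
    def n_bins(self) -> int:
        return self.u.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_bins * self.dt_s

    def center(self) -> "InputStreams":
        """Return a copy with each stream's mean subtracted."""
        u = self.u - self.u.mean(axis=1, keepdims=True)
        return replace(self, u=u, centered=True)


def build_input_streams(
    design: TaskDesign,
    dt_s: float,
    rw_prediction: Optional[np.ndarray] = None,
    include_u3: bool = False,
    center: bool = True,
    u2_values: Optional[np.ndarray] = None,
    duration_s: Optional[float] = None,
    tail_s: float = 30.0,
) -> InputStreams:
    """Construct driving and modulatory input streams from a task design.

    ``u1`` receives a unit impulse at every target onset; ``u2`` receives
    impulses at invalid-target onsets, unless ``u2_values`` supplies per-trial
    values (the learning-infused variant routes the learner's predicted cue
    invalidity of the previous trial here).  If ``include_u3``,
    ``rw_prediction`` (one value per trial, e.g. model-predicted RTs) is
    placed at the onset bins as a third stream.  With ``center`` each stream
    has its mean subtracted, as the streams are mean-centered before model
    inversion.
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    n_trials = design.n_trials
    if include_u3:
        if rw_prediction is None or len(rw_prediction) != n_trials:
            raise ValueError("include_u3 requires one rw_prediction per trial")
    if u2_values is not None and len(u2_values) != n_trials:
        raise ValueError("u2_values must supply one value per trial")

    if duration_s is None:
        duration_s = design.duration_s + tail_s
    n_bins = int(np.ceil(duration_s / dt_s))
    onsets = design.onsets
    onset_bins = np.round(onsets / dt_s).astype(int)
    if n_trials and onset_bins.max(initial=0) >= n_bins:
        raise ValueError(
            f"trial onset at {onsets.max():.3f}s falls beyond the stream "
            f"duration of {duration_s:.3f}s"
        )
    if n_trials and len(np.unique(onset_bins)) != n_trials:
        raise ValueError("two trial onsets fall into the same micro-time bin")

    n_streams = 3 if include_u3 else 2
    u = np.zeros((n_streams, n_bins))
    names = ("u1", "u2", "u3")[:n_streams]
    u[0, onset_bins] = 1.0
    if u2_values is not None:
        u[1, onset_bins] = np.asarray(u2_values, dtype=float)
    else:
        u[1, onset_bins] = design.invalid01
    if include_u3:
        u[2, onset_bins] = np.asarray(rw_prediction, dtype=float)

    streams = InputStreams(
        dt_s=dt_s,
        u=u,
        centered=False,
        onset_bins=onset_bins,
        names=names,
    )
    return streams.center() if center else streams
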