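"""File formats, configuration, and reproducibility plumbing.

Trial tables travel as tab-separated BIDS-style events files (UTF-8,
``n/a`` for missing values, onsets in seconds from run start, 1-based trial
indices in files).  Regional BOLD series travel as tab-separated tables
with one header-labelled column per region and one row per volume; the TR
comes from the configuration.  Configuration is YAML with nested sections
(design / model / noise / integration / inversion / evaluation) and is
fully round-trippable.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .design import AXIS_LOCATIONS, TaskDesign, Trial
from .network import BDCMParams, HemodynamicParams
from .preprocess import BOLDSeries

__all__ = [
    "EVENT_COLUMNS",
    "read_events",
    "write_events",
    "behavior_frame",
    "read_bold",
    "write_bold",
    "default_config",
    "load_config",
    "save_config",
    "params_to_dict",
    "params_from_dict",
    "write_manifest",
]

EVENT_COLUMNS = [
    "onset",
    "duration",
    "trial_type",
    "validity",
    "location",
    "orientation",
    "soa",
    "response_time",
    "correct",
]
TARGET_DURATION_S = 0.25
NA = "n/a"


def write_events(
    design: TaskDesign,
    path: Union[str, Path],
    rts: Optional[np.ndarray] = None,
) -> None:
    """Write a task design (optionally with measured/simulated RTs) as TSV."""
    rows = []
    for t in design.trials:
        rt = rts[t.index] if rts is not None else t.rt_s
        rows.append(
            {
                "onset": t.onset_s,
                "duration": TARGET_DURATION_S,
                "trial_type": "target",
                "validity": t.validity,
                "location": t.target_location,
                "orientation": t.target_orientation,
                "soa": t.soa_s,
                "response_time": np.nan if rt is None else rt,
                "correct": int(t.response_correct),
            }
        )
    frame = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    frame.to_csv(path, sep="\t", index=False, na_rep=NA)


def read_events(path: Union[str, Path]) -> TaskDesign:
    """Read a BIDS-style events TSV back into a task design.

    Rows are re-sorted by onset (with a warning) if the file is out of
    order; missing reaction times stay missing.  Block membership and ITIs
    are not stored in the events dialect, so blocks read back as one run
    and ITIs are reconstructed from the onset gaps.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)
    missing = [c for c in EVENT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"events file {path} is missing column(s): {missing}")
    for i, row in frame.iterrows():
        try:
            float(row["onset"])
            float(row["soa"])
        except (TypeError, ValueError) as err:
            raise ValueError(f"malformed row at line {i + 2} of {path}: {err}") from None
    onsets = frame["onset"].to_numpy(dtype=float)
    if np.any(np.diff(onsets) < 0):
        warnings.warn(f"events in {path} were not sorted by onset; re-sorting", stacklevel=2)
        frame = frame.sort_values("onset", kind="stable").reset_index(drop=True)

    locations = set(frame["location"].astype(str)) - {NA}
    run_axis = "horizontal"
    for axis, locs in AXIS_LOCATIONS.items():
        if locations and locations <= set(locs):
            run_axis = axis
            break

    trials = []
    onsets = frame["onset"].to_numpy(dtype=float)
    gaps = np.diff(onsets)
    for i, row in frame.iterrows():
        rt = row["response_time"]
        rt = None if pd.isna(rt) else float(rt)
        soa = float(row["soa"])
        iti = float(gaps[i]) - soa if i < len(gaps) else 3.0
        trials.append(
            Trial(
                index=int(i),
                onset_s=float(row["onset"]),
                validity=str(row["validity"]),
                target_location=str(row["location"]),
                target_orientation=str(row["orientation"]),
                soa_s=soa,
                iti_s=max(iti, 0.0),
                block=0,
                response_correct=bool(int(row["correct"])),
                rt_s=rt,
            )
        )
    return TaskDesign(
        trials=trials,
        run_axis=run_axis,
        n_blocks=1 if trials else 0,
        trials_per_block=len(trials) or 1,
    )


def behavior_frame(design: TaskDesign) -> pd.DataFrame:
    """Per-trial RT/correctness table in the layout RT screening expects."""
    return pd.DataFrame(
        {
            "rt_s": [np.nan if t.rt_s is None else t.rt_s for t in design.trials],
            "response_correct": [t.response_correct for t in design.trials],
        }
    )


def write_bold(series: BOLDSeries, path: Union[str, Path]) -> None:
    """One column per region, one row per (observed) sample."""
    frame = pd.DataFrame(series.observed.T, columns=list(series.region_labels))
    frame.to_csv(path, sep="\t", index=False, na_rep=NA)


def read_bold(
    path: Union[str, Path],
    tr_s: float,
    region_labels: Optional[Sequence[str]] = None,
) -> BOLDSeries:
    """Read a raw regional BOLD table; columns realigned by header name."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)
    if region_labels is not None:
        missing = [r for r in region_labels if r not in frame.columns]
        if missing:
            raise ValueError(f"BOLD file {path} is missing region column(s): {missing}")
        frame = frame[list(region_labels)]
    for col in frame.columns:
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.isna() & frame[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"non-numeric value in {path} at row {row + 2}, column {col!r}: "
                f"{frame[col].iloc[row]!r}"
            )
        frame[col] = converted
    values = frame.to_numpy(dtype=float).T
    return BOLDSeries(
        values=values,
        tr_s=tr_s,
        region_labels=tuple(frame.columns),
        observed_mask=np.ones(values.shape[1], dtype=bool),
    )


def default_config() -> dict:
    """Baseline configuration reproducing the default study conditions."""
    return {
        "seed": 0,
        "design": {
            "n_blocks": 5,
            "trials_per_block": 40,
            "invalid_fraction": 0.2,
            "soas": [0.4, 0.6],
            "itis": [2.0, 2.7, 3.2, 3.9, 4.5],
            "run_axis": "horizontal",
        },
        "model": {
            "regions": ["IPS-L", "IPS-R", "FEF-L", "FEF-R", "TPJ-L", "TPJ-R"],
            "output_regions": ["IPS-L", "IPS-R"],
        },
        "noise": {"bold_snr": 10.0, "rt_noise_sd": 0.02},
        "integration": {"tr_s": 2.2, "target_dt_s": 1.1, "oversample": 8},
        "inversion": {
            "max_iter": 64,
            "f_tol": 0.01,
            "explained_variance": [0.1, 0.9],
        },
        "evaluation": {"n_perm": 10000},
    }


def load_config(path: Union[str, Path, None]) -> dict:
    """Defaults overlaid with the (possibly partial) YAML file at ``path``."""
    config = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(config.get(key), dict):
                config[key].update(val)
            else:
                config[key] = val
    return config


def save_config(config: dict, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)


def params_to_dict(params: BDCMParams) -> dict:
    return {
        "A": params.A.tolist(),
        "B": params.B.tolist(),
        "C": params.C.tolist(),
        "ar": params.ar.tolist(),
        "br": params.br.tolist(),
        "cr": params.cr.tolist(),
        "decay": float(params.decay),
        "rho": float(params.rho),
        "phi": {k: float(v) for k, v in asdict(params.phi).items()},
    }


def params_from_dict(d: dict) -> BDCMParams:
    return BDCMParams(
        A=np.asarray(d["A"], dtype=float),
        B=np.asarray(d["B"], dtype=float),
        C=np.asarray(d["C"], dtype=float),
        ar=np.asarray(d["ar"], dtype=float),
        br=np.asarray(d["br"], dtype=float),
        cr=np.asarray(d["cr"], dtype=float),
        decay=float(d["decay"]),
        rho=float(d["rho"]),
        phi=HemodynamicParams(**d["phi"]),
    )


def write_manifest(
    out_dir: Union[str, Path],
    config: dict,
    files: Sequence[Union[str, Path]],
    status: str = "complete",
) -> Path:
    """Record config hash, seeds, and per-file checksums for reproducibility."""
    out_dir = Path(out_dir)
    entries = []
    for f in files:
        f = Path(f)
        digest = hashlib.sha256(f.read_bytes()).hexdigest() if f.exists() else None
        entries.append({"file": f.name, "sha256": digest})
    manifest = {
        "status": status,
        "seed": config.get("seed"),
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(config, sort_keys=True).encode()
        ).hexdigest(),
        "files": entries,
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return path
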