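"""Plain-text file formats: trials as CSV + JSON sidecar, cohort manifests,
model and report serialization.

A trial is stored as one CSV (``sample_index`` column followed by one column
per channel, written with 17 significant digits so float64 values round-trip
bit-exactly) plus a JSON sidecar carrying subject, task, state, sampling
rate, channel specifications and event indices.  A cohort manifest lists all
trials of a cohort.  Processed kinematic channels — not motion-capture
markers — are the pipeline's input, so no C3D handling is needed; a C3D
importer would slot in beside :func:`read_trial`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ChannelSpec, GaitEvents, KinematicTrial

_FLOAT_FMT = "%.17g"


def write_trial(trial: KinematicTrial, csv_path, sidecar_path) -> None:
    """Write one trial as CSV + JSON sidecar (lossless round-trip)."""
    df = pd.DataFrame(trial.signal, columns=trial.channel_names)
    df.insert(0, "sample_index", np.arange(trial.n_samples))
    df.to_csv(csv_path, index=False, float_format=_FLOAT_FMT)
    sidecar = {
        "subject_id": trial.subject_id,
        "task": trial.task,
        "state": trial.state,
        "fs": trial.fs,
        "trial_id": trial.trial_id,
        "events": trial.events.as_dict(),
        "channels": [
            {"name": c.name, "source": c.source, "quantity": c.quantity, "axis": c.axis}
            for c in trial.channels
        ],
    }
    with open(sidecar_path, "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)


def read_trial(csv_path, sidecar_path) -> KinematicTrial:
    """Read one trial back; validation errors name the file and field."""
    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    channels = [ChannelSpec(**c) for c in sidecar["channels"]]
    try:
        events = GaitEvents.from_dict(sidecar["events"])
    except (KeyError, ValueError) as exc:
        raise ValueError(f"{sidecar_path}: invalid events: {exc}") from exc
    df = pd.read_csv(csv_path, float_precision="round_trip")
    expected = ["sample_index"] + [c.name for c in channels]
    extra = [c for c in df.columns if c not in expected]
    if extra:
        raise ValueError(
            f"{csv_path}: column(s) {extra} are not declared in the sidecar "
            f"channel list"
        )
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"{csv_path}: missing column(s) {missing}")
    signal = df[[c.name for c in channels]].to_numpy(dtype=float)
    if not np.isfinite(signal).all():
        r, c = np.argwhere(~np.isfinite(signal))[0]
        raise ValueError(
            f"{csv_path}: non-finite value at line {r + 2}, field {channels[c].name!r}"
        )
    try:
        return KinematicTrial(
            subject_id=sidecar["subject_id"],
            task=sidecar["task"],
            state=sidecar["state"],
            fs=float(sidecar["fs"]),
            signal=signal,
            channels=channels,
            events=events,
            trial_id=sidecar.get("trial_id", ""),
        )
    except ValueError as exc:
        raise ValueError(f"{sidecar_path}: {exc}") from exc


def write_cohort(trials: list[KinematicTrial], out_dir) -> Path:
    """Write every trial plus a manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for t in trials:
        csv_name = f"{t.trial_id}.csv"
        sidecar_name = f"{t.trial_id}.json"
        write_trial(t, out / csv_name, out / sidecar_name)
        entries.append(
            {
                "trial_id": t.trial_id,
                "subject_id": t.subject_id,
                "task": t.task,
                "state": t.state,
                "csv": csv_name,
                "sidecar": sidecar_name,
            }
        )
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump({"n_trials": len(entries), "trials": entries}, fh, indent=1, sort_keys=True)
    return manifest_path


def read_cohort(manifest_path) -> list[KinematicTrial]:
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(
            f"cohort manifest not found: {manifest_path}; run `locomode simulate` "
            "first or point --cohort at a directory containing manifest.json"
        )
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    base = manifest_path.parent
    return [
        read_trial(base / e["csv"], base / e["sidecar"]) for e in manifest["trials"]
    ]
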