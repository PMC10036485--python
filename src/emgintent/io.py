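"""Dataset bundle I/O: JSON-lines manifest + one CSV of samples per trial.

Plain-text formats are used throughout (diff-able, language-portable):
``manifest.jsonl`` holds one metadata record per trial; ``trials/<id>.csv``
holds the sample table (time_s, emg_ch1..emg_chK, joystick_x) written with
10 significant digits, so a read/write round trip reproduces amplitudes to
~1e-9 relative and metadata exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .synth import TrialRecording

__all__ = ["write_dataset", "read_dataset"]

_FLOAT_FMT = "%.10g"


def write_dataset(trials: Sequence[TrialRecording], path) -> Path:
    """Write trials under ``path``; returns the manifest path."""
    root = Path(path)
    (root / "trials").mkdir(parents=True, exist_ok=True)
    seen = set()
    records = []
    for k, trial in enumerate(trials):
        trial_id = trial.trial_id or f"{trial.subject_id}_t{k + 1:03d}"
        if trial_id in seen:
            raise ValueError(f"duplicate trial_id {trial_id!r}")
        seen.add(trial_id)
        n = trial.n_samples
        frame = pd.DataFrame(
            np.column_stack([np.arange(n) / trial.sampling_rate,
                             trial.emg, trial.joystick_x]),
            columns=(["time_s"]
                     + [f"emg_ch{c + 1}" for c in range(trial.emg.shape[1])]
                     + ["joystick_x"]),
        )
        rel = f"trials/{trial_id}.csv"
        frame.to_csv(root / rel, index=False, float_format=_FLOAT_FMT)
        records.append({
            "trial_id": trial_id,
            "subject_id": trial.subject_id,
            "idle_label": trial.idle_label,
            "motion_label": trial.motion_label,
            "cue_time_s": trial.cue_time,
            "onset_time_s": trial.onset_time,
            "valid": trial.valid,
            "sampling_rate_hz": trial.sampling_rate,
            "n_samples": n,
            "samples_file": rel,
        })
    manifest = root / "manifest.jsonl"
    with open(manifest, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec) + "\n")
    return manifest


def read_dataset(path) -> list[TrialRecording]:
    """Read a dataset bundle; validates manifest/sample-file consistency
    and the uniform time grid, naming the offending trial on failure."""
    root = Path(path)
    manifest = root / "manifest.jsonl"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest.jsonl under {root}")
    records = [json.loads(line) for line in manifest.read_text().splitlines()
               if line.strip()]
    ids = [r["trial_id"] for r in records]
    if len(ids) != len(set(ids)):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate trial_id(s) in manifest: {dup}")
    expected_files = {r["samples_file"] for r in records}
    actual_files = {f"trials/{p.name}" for p in (root / "trials").glob("*.csv")}
    orphans = actual_files - expected_files
    if orphans:
        names = sorted(Path(o).stem for o in orphans)
        raise ValueError(f"sample files without manifest rows: {names}")
    trials = []
    for rec in records:
        tid = rec["trial_id"]
        sample_path = root / rec["samples_file"]
        if not sample_path.exists():
            raise FileNotFoundError(f"missing sample file for trial {tid!r}")
        frame = pd.read_csv(sample_path)
        emg_cols = [c for c in frame.columns if c.startswith("emg_ch")]
        if "time_s" not in frame.columns or not emg_cols \
                or "joystick_x" not in frame.columns:
            raise ValueError(f"malformed sample header for trial {tid!r}")
        fs = float(rec["sampling_rate_hz"])
        t = frame["time_s"].to_numpy()
        dt = np.diff(t)
        if np.any(dt <= 0) or np.any(np.abs(dt - 1.0 / fs) > 1e-6):
            raise ValueError(
                f"time column of trial {tid!r} is not a strictly increasing "
                f"1/fs grid")
        trials.append(TrialRecording(
            subject_id=rec["subject_id"],
            idle_label=rec["idle_label"],
            motion_label=rec["motion_label"],
            emg=frame[emg_cols].to_numpy(),
            joystick_x=frame["joystick_x"].to_numpy(),
            cue_time=float(rec["cue_time_s"]),
            onset_time=(None if rec["onset_time_s"] is None
                        else float(rec["onset_time_s"])),
            sampling_rate=fs,
            trial_id=tid,
            valid=bool(rec.get("valid", True)),
        ))
    return trials
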