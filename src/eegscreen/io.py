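"""Plain-text persistence: cohorts as per-trial CSV matrices plus a manifest,
feature tables as CSV, models and selection results as JSON."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import EpochedRecording, FEATURE_NAMES

MANIFEST_NAME = "manifest.csv"


def write_cohort(cohort: list[EpochedRecording], out_dir: str | Path) -> Path:
    """One channels x samples CSV per trial, plus a cohort manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in cohort:
        subj_dir = out / rec.subject_id
        subj_dir.mkdir(exist_ok=True)
        for t in range(rec.n_trials):
            np.savetxt(subj_dir / f"trial{t:04d}.csv", rec.data[t],
                       delimiter=",", fmt="%.8g")
        rows.append({"subject_id": rec.subject_id, "group": rec.group,
                     "fs": rec.fs, "n_trials": rec.n_trials,
                     "channels": "|".join(rec.channel_names)})
    pd.DataFrame(rows).to_csv(out / MANIFEST_NAME, index=False)
    return out / MANIFEST_NAME


def read_cohort(in_dir: str | Path) -> list[EpochedRecording]:
    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / MANIFEST_NAME)
    cohort = []
    for row in manifest.itertuples():
        subj_dir = in_dir / row.subject_id
        trials = sorted(subj_dir.glob("trial*.csv"))
        data = np.stack([np.loadtxt(p, delimiter=",", ndmin=2) for p in trials])
        cohort.append(EpochedRecording(
            subject_id=row.subject_id, group=row.group, fs=float(row.fs),
            data=data, channel_names=str(row.channels).split("|")))
    return cohort


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in FEATURE_NAMES if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing column(s): {missing}")
    return table


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
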