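"""Assemble the trials x 14-feature table from epoched recordings.

Every feature is computed per epoch and channel and then averaged over
channels, yielding one row per trial with subject ID and group label.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .core import DegenerateInputError, EpochedRecording, FEATURE_NAMES
from .nonlinear import NonlinearParams, nonlinear_features
from .spectral import compute_psdn, spectral_features


def trial_features(epochs_2d: np.ndarray, fs: float, params: NonlinearParams,
                   psd_method: str = "welch") -> dict[str, float]:
    """Channel-averaged feature values of one (channels x samples) trial.

    Channels on which a feature is undefined (e.g. no SampEn template
    matches) are excluded from that feature's average with a warning.
    """
    acc: dict[str, list[float]] = {name: [] for name in FEATURE_NAMES}
    for ch in range(epochs_2d.shape[0]):
        x = epochs_2d[ch]
        try:
            for k, v in spectral_features(compute_psdn(x, fs, psd_method)).items():
                acc[k].append(v)
        except DegenerateInputError as err:
            warnings.warn(f"channel {ch}: spectral features skipped ({err})")
        try:
            for k, v in nonlinear_features(x, fs, params).items():
                acc[k].append(v)
        except DegenerateInputError as err:
            warnings.warn(f"channel {ch}: nonlinear features skipped ({err})")
    out = {}
    for name, vals in acc.items():
        if not vals:
            raise DegenerateInputError(f"feature {name} undefined on all channels")
        out[name] = float(np.mean(vals))
    return out


def feature_table(recordings: list[EpochedRecording],
                  params: NonlinearParams | None = None,
                  psd_method: str = "welch") -> pd.DataFrame:
    """FeatureTable: one row per trial, 14 feature columns + subject_id, group."""
    params = params or NonlinearParams()
    rows = []
    for rec in recordings:
        for t in range(rec.n_trials):
            row = trial_features(rec.data[t], rec.fs, params, psd_method)
            row["subject_id"] = rec.subject_id
            row["group"] = rec.group
            rows.append(row)
    df = pd.DataFrame(rows)
    return df[list(FEATURE_NAMES) + ["subject_id", "group"]]
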