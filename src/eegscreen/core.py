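"""Shared data containers and constants for the EEG screening pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Diagnostic classes in canonical order (used everywhere a class axis appears).
GROUPS: tuple[str, ...] = ("HC", "MCI", "AD")

#: Conventional EEG frequency bands, half-open [low, high) in Hz.  The six
#: bands tile the analysis range [1, 70); the top edge of gamma is treated as
#: closed so the 70 Hz grid point is not orphaned.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta1": (13.0, 19.0),
    "beta2": (19.0, 30.0),
    "gamma": (30.0, 70.0),
}

#: Analysis band edges (Hz) to which every PSD is restricted.
FREQ_RANGE: tuple[float, float] = (1.0, 70.0)

#: The 14 feature columns of a FeatureTable, fixed order.
FEATURE_NAMES: tuple[str, ...] = (
    "RP_delta", "RP_theta", "RP_alpha", "RP_beta1", "RP_beta2", "RP_gamma",
    "MF", "IAF", "SE",
    "LZC", "CTM", "SampEn", "FuzzyEn", "AMI",
)

#: Standard 10-20 labels of the 19-channel montage.
CHANNELS_10_20: tuple[str, ...] = (
    "Fp1", "Fp2", "Fz", "F3", "F4", "F7", "F8", "Cz", "C3", "C4",
    "T3", "T4", "T5", "T6", "Pz", "P3", "P4", "O1", "O2",
)


class ConfigurationError(ValueError):
    """Invalid parameter or configuration value."""


class DegenerateInputError(ValueError):
    """Input on which the requested quantity is mathematically undefined."""


class UndefinedEntropyError(DegenerateInputError):
    """No template matches: the conditional probability (and entropy) is undefined."""


@dataclass
class EpochedRecording:
    """One subject's artifact-free trials.

    data is a (n_trials, n_channels, n_samples) float array in µV at a fixed
    sampling rate.  samples must equal ``fs * epoch_seconds``.
    """

    subject_id: str
    group: str
    fs: float
    data: np.ndarray
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.group not in GROUPS:
            raise ConfigurationError(f"unknown group {self.group!r}")
        if self.data.ndim != 3:
            raise ConfigurationError("data must be trials x channels x samples")
        if not np.isfinite(self.data).all():
            raise ConfigurationError("data contains non-finite values")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[1])]
        if len(self.channel_names) != self.data.shape[1]:
            raise ConfigurationError("channel_names length mismatch")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]
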