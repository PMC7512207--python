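"""Synthetic three-group EEG cohort generator.

Each channel is a weighted sum of narrowband oscillators (one per
conventional frequency band, the alpha oscillator centred at the group's
alpha-peak frequency) plus band-limited 1/f Gaussian background noise.  The
noise fraction controls signal irregularity, which gives the groups their
complexity gradient; the alpha-peak frequency and band weights give them
their spectral gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import (
    BANDS,
    CHANNELS_10_20,
    ConfigurationError,
    EpochedRecording,
    FREQ_RANGE,
    GROUPS,
)

#: Centre frequency (Hz) of each band's oscillator.  Alpha is overridden by
#: the profile's alpha_peak_hz.
_BAND_CENTRES = {
    "delta": 2.5, "theta": 6.0, "alpha": 10.0,
    "beta1": 16.0, "beta2": 24.0, "gamma": 40.0,
}
#: Spectral half-width (Hz, Gaussian sd) of each oscillator.
_BAND_WIDTHS = {
    "delta": 0.8, "theta": 1.0, "alpha": 0.8,
    "beta1": 1.5, "beta2": 2.5, "gamma": 5.0,
}

_RMS_UV = 30.0          # target channel RMS amplitude, µV
_COMMON_SOURCE_VAR = 0.6  # variance fraction shared across channels


@dataclass(frozen=True)
class GroupProfile:
    """Generative parameters of one diagnostic group."""

    group_label: str
    alpha_peak_hz: float
    band_power_weights: dict[str, float]
    noise_fraction: float
    alpha_bandwidth_hz: float = 0.8

    def __post_init__(self) -> None:
        if self.group_label not in GROUPS:
            raise ConfigurationError(f"unknown group {self.group_label!r}")
        if set(self.band_power_weights) != set(BANDS):
            raise ConfigurationError("band_power_weights must cover the six bands")
        total = sum(self.band_power_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"band weights sum to {total}, expected 1")
        if any(w < 0 for w in self.band_power_weights.values()):
            raise ConfigurationError("band weights must be non-negative")
        if not 0.0 <= self.noise_fraction < 1.0:
            raise ConfigurationError("noise_fraction must lie in [0, 1)")
        if not 4.0 <= self.alpha_peak_hz <= 15.0:
            raise ConfigurationError("alpha_peak_hz must lie in [4, 15] Hz")
        if self.alpha_bandwidth_hz <= 0:
            raise ConfigurationError("alpha_bandwidth_hz must be positive")


def default_profiles() -> dict[str, GroupProfile]:
    """Profiles giving the expected group gradients.

    Alpha peaks slow and the background-noise share shrinks from HC to AD, so
    downstream medians are ordered: IAF and entropies decrease, theta power
    and the central tendency measure increase.  Weights are chosen so the
    measured relative powers (oscillators plus the 1/f background) sit near
    plausible resting-EEG values while keeping group overlap.
    """

    def _w(delta, theta, alpha, beta1, beta2, gamma):
        w = dict(delta=delta, theta=theta, alpha=alpha,
                 beta1=beta1, beta2=beta2, gamma=gamma)
        s = sum(w.values())
        w = {k: v / s for k, v in w.items()}
        # exact unit sum despite float division
        w["gamma"] += 1.0 - sum(w.values())
        return w

    return {
        "HC": GroupProfile("HC", 9.5, _w(.10, .03, .62, .13, .10, .02), 0.66),
        "MCI": GroupProfile("MCI", 9.4, _w(.09, .08, .60, .11, .09, .03), 0.53),
        "AD": GroupProfile("AD", 8.8, _w(.08, .15, .58, .09, .07, .03), 0.40),
    }


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generation settings."""

    n_subjects_per_group: int = 37
    trials_per_subject_mean: float = 46.0
    trials_per_subject_sd: float = 8.9
    fs: float = 200.0
    epoch_seconds: float = 5.0
    n_channels: int = 19
    rng_seed: int = 0
    profiles: dict[str, GroupProfile] = field(default_factory=default_profiles)
    subject_jitter: float = 1.0  # scale of per-subject parameter jitter
    #: lognormal amplitude-burst depth of the broadband noise (0 = Gaussian).
    #: A cohort-level noise-model property, identical for all groups.
    noise_burst_depth: float = 0.0

    def __post_init__(self) -> None:
        n = self.fs * self.epoch_seconds
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError("fs * epoch_seconds must be an integer")
        if self.n_subjects_per_group < 1 or self.n_channels < 1:
            raise ConfigurationError("counts must be >= 1")
        if set(self.profiles) != set(GROUPS):
            raise ConfigurationError("profiles must cover HC, MCI and AD")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.epoch_seconds))


def _spectral_shaper(n_samples: int, fs: float) -> np.ndarray:
    """rfft frequency grid for epoch synthesis."""
    return np.fft.rfftfreq(n_samples, d=1.0 / fs)


def _coloured_component(rng: np.random.Generator, amplitude: np.ndarray,
                        n_samples: int, size: int) -> np.ndarray:
    """size x n_samples unit-variance signals with the given rfft amplitude."""
    nf = amplitude.shape[0]
    coef = (rng.standard_normal((size, nf)) + 1j * rng.standard_normal((size, nf)))
    coef *= amplitude
    coef[:, 0] = 0.0
    x = np.fft.irfft(coef, n=n_samples, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _jittered_profile(profile: GroupProfile, rng: np.random.Generator,
                      scale: float) -> GroupProfile:
    """Per-subject variation of the group profile."""
    peak = float(np.clip(profile.alpha_peak_hz + scale * rng.normal(0.0, 0.3),
                         4.0, 15.0))
    w = {k: v * float(np.exp(scale * rng.normal(0.0, 0.18)))
         for k, v in profile.band_power_weights.items()}
    s = sum(w.values())
    w = {k: v / s for k, v in w.items()}
    w["gamma"] += 1.0 - sum(w.values())
    nf = float(np.clip(profile.noise_fraction + scale * rng.normal(0.0, 0.05),
                       0.05, 0.95))
    return replace(profile, alpha_peak_hz=peak, band_power_weights=w,
                   noise_fraction=nf)


def generate_subject(profile: GroupProfile, config: CohortConfig,
                     subject_seed: int, subject_id: str | None = None,
                     n_trials: int | None = None) -> EpochedRecording:
    """Generate one subject's epoched recording, deterministic in subject_seed."""
    rng = np.random.default_rng(subject_seed)
    n_samples = config.n_samples
    freqs = _spectral_shaper(n_samples, config.fs)
    subj = _jittered_profile(profile, rng, config.subject_jitter)

    if n_trials is None:
        n_trials = max(1, int(round(rng.normal(config.trials_per_subject_mean,
                                               config.trials_per_subject_sd))))

    lo, hi = FREQ_RANGE
    in_band = (freqs >= lo) & (freqs <= hi)
    noise_amp = np.zeros_like(freqs)
    with np.errstate(divide="ignore"):
        noise_amp[in_band] = freqs[in_band] ** -0.5  # 1/f power spectrum
    env_amp = np.zeros_like(freqs)
    env_amp[(freqs > 0) & (freqs <= 2.0)] = 1.0  # slow burst envelope

    osc_amps = {}
    for band in BANDS:
        centre = subj.alpha_peak_hz if band == "alpha" else _BAND_CENTRES[band]
        width = (subj.alpha_bandwidth_hz if band == "alpha"
                 else _BAND_WIDTHS[band])
        amp = np.exp(-0.5 * ((freqs - centre) / width) ** 2)
        amp[~in_band] = 0.0
        osc_amps[band] = amp

    size = n_trials * config.n_channels

    def _signal_block(block_rng: np.random.Generator, n: int) -> np.ndarray:
        osc = np.zeros((n, n_samples))
        for band, amp in osc_amps.items():
            osc += np.sqrt(subj.band_power_weights[band]) * _coloured_component(
                block_rng, amp, n_samples, n)
        noise = _coloured_component(block_rng, noise_amp, n_samples, n)
        if config.noise_burst_depth > 0:
            env = np.exp(config.noise_burst_depth
                         * _coloured_component(block_rng, env_amp, n_samples, n))
            noise = noise * env
            noise /= noise.std(axis=1, keepdims=True)
        return (np.sqrt(1.0 - subj.noise_fraction) * osc
                + np.sqrt(subj.noise_fraction) * noise)

    common = _signal_block(rng, n_trials)                      # shared source
    indep = _signal_block(rng, size).reshape(n_trials, config.n_channels,
                                             n_samples)
    data = (np.sqrt(_COMMON_SOURCE_VAR) * common[:, None, :]
            + np.sqrt(1.0 - _COMMON_SOURCE_VAR) * indep)
    data *= _RMS_UV

    names = list(CHANNELS_10_20[:config.n_channels])
    if config.n_channels > len(CHANNELS_10_20):
        names += [f"ch{i}" for i in range(len(CHANNELS_10_20), config.n_channels)]
    sid = subject_id or f"{profile.group_label}_{subject_seed}"
    return EpochedRecording(subject_id=sid, group=profile.group_label,
                            fs=config.fs, data=data, channel_names=names)


def generate_cohort(config: CohortConfig) -> list[EpochedRecording]:
    """Generate n_subjects_per_group recordings per group, reproducibly."""
    root = np.random.SeedSequence(config.rng_seed)
    seeds = root.generate_state(3 * config.n_subjects_per_group * 2)
    cohort: list[EpochedRecording] = []
    i = 0
    for group in GROUPS:
        profile = config.profiles[group]
        for k in range(config.n_subjects_per_group):
            sid = f"{group}{k:03d}"
            cohort.append(generate_subject(profile, config,
                                           subject_seed=int(seeds[i]),
                                           subject_id=sid))
            i += 1
    return cohort
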