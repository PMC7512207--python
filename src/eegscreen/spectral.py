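"""Normalized PSD and the four spectral features (RP, MF, IAF, SE).

Features are computed per epoch and channel on the PSD restricted to
1-70 Hz and renormalized to unit sum.  Band sums use half-open [f1, f2)
intervals so the six conventional bands partition the grid exactly; the
topmost edge (70 Hz) is closed so the last grid point is not orphaned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import (
    BANDS,
    ConfigurationError,
    DegenerateInputError,
    FREQ_RANGE,
)

_ALPHA_EXT = (4.0, 15.0)  # extended alpha band for the IAF


@dataclass(frozen=True)
class NormalizedPSD:
    """Unit-sum PSD on a uniform frequency grid restricted to 1-70 Hz."""

    freqs: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        f, v = np.asarray(self.freqs, float), np.asarray(self.values, float)
        if f.shape != v.shape or f.ndim != 1:
            raise ConfigurationError("freqs and values must be 1-D and congruent")
        if np.any(np.diff(f) <= 0):
            raise ConfigurationError("frequency grid must be strictly increasing")
        if np.any(v < 0):
            raise ConfigurationError("PSD values must be non-negative")
        if abs(v.sum() - 1.0) > 1e-9:
            raise ConfigurationError("PSD values must sum to 1")
        object.__setattr__(self, "freqs", f)
        object.__setattr__(self, "values", v)

    @property
    def bin_width(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


def compute_psdn(epoch: np.ndarray, fs: float, method: str = "welch",
                 window_seconds: float = 2.0) -> NormalizedPSD:
    """Estimate the PSD of one epoch and normalize it on the 1-70 Hz grid.

    Welch's method (2-s Hamming segments, 50% overlap) is the default: on a
    5-s epoch it averages 4 segments and yields a 0.5 Hz grid, fine enough to
    resolve alpha-peak differences below 1 Hz.  A plain periodogram is
    available for comparison.
    """
    epoch = np.asarray(epoch, dtype=float)
    if epoch.ndim != 1:
        raise ConfigurationError("epoch must be a 1-D series")
    if epoch.shape[-1] < 2 * fs:
        raise ValueError("epoch shorter than 2 s")
    if not np.any(epoch != epoch[0]):
        raise DegenerateInputError("constant epoch: normalized PSD undefined")
    if method == "welch":
        nper = int(round(window_seconds * fs))
        freqs, psd = signal.welch(epoch, fs=fs, window="hamming",
                                  nperseg=nper, noverlap=nper // 2)
    elif method == "periodogram":
        freqs, psd = signal.periodogram(epoch, fs=fs)
    else:
        raise ConfigurationError(f"unknown PSD method {method!r}")
    lo, hi = FREQ_RANGE
    mask = (freqs >= lo) & (freqs <= hi)
    vals = psd[mask]
    total = vals.sum()
    if total <= 0:
        raise DegenerateInputError("no spectral mass in the 1-70 Hz band")
    return NormalizedPSD(freqs=freqs[mask], values=vals / total)


def _band_mask(psd: NormalizedPSD, f1: float, f2: float) -> np.ndarray:
    # half-open [f1, f2); the right edge is included when it is the grid top,
    # so the six bands tile the full grid.
    closed_top = f2 >= psd.freqs[-1]
    if closed_top:
        return (psd.freqs >= f1) & (psd.freqs <= f2)
    return (psd.freqs >= f1) & (psd.freqs < f2)


def relative_power(psd: NormalizedPSD, f1: float, f2: float) -> float:
    """Fraction of normalized spectral mass in [f1, f2)."""
    lo, hi = FREQ_RANGE
    if not (lo <= f1 < f2 <= hi):
        raise ConfigurationError(f"band ({f1}, {f2}) outside {FREQ_RANGE}")
    return float(psd.values[_band_mask(psd, f1, f2)].sum())


def _median_of_mass(freqs: np.ndarray, mass: np.ndarray) -> float:
    """Smallest grid frequency whose cumulative mass reaches half the total."""
    total = mass.sum()
    if total <= 0:
        raise DegenerateInputError("zero spectral mass")
    idx = int(np.searchsorted(np.cumsum(mass), 0.5 * total - 1e-15))
    return float(freqs[min(idx, len(freqs) - 1)])


def median_frequency(psd: NormalizedPSD) -> float:
    """Frequency comprising 50% of the normalized spectral power."""
    return _median_of_mass(psd.freqs, psd.values)


def individual_alpha_frequency(psd: NormalizedPSD) -> float:
    """Median-frequency rule applied within the extended alpha band (4-15 Hz)."""
    lo, hi = _ALPHA_EXT
    mask = (psd.freqs >= lo) & (psd.freqs <= hi)
    if not np.any(psd.values[mask] > 0):
        raise DegenerateInputError("no spectral mass in the 4-15 Hz band")
    return _median_of_mass(psd.freqs[mask], psd.values[mask])


def spectral_entropy(psd: NormalizedPSD) -> float:
    """Shannon entropy of the normalized PSD, scaled to [0, 1] by log(bins)."""
    p = psd.values[psd.values > 0]
    h = float(-(p * np.log(p)).sum())
    return h / np.log(psd.values.size)


def spectral_features(psd: NormalizedPSD) -> dict[str, float]:
    """The nine spectral feature values of one epoch/channel."""
    out = {f"RP_{band}": relative_power(psd, lo, hi)
           for band, (lo, hi) in BANDS.items()}
    out["MF"] = median_frequency(psd)
    out["IAF"] = individual_alpha_frequency(psd)
    out["SE"] = spectral_entropy(psd)
    return out
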