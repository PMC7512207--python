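"""Signal conditioning: band-pass / notch filtering and epoch segmentation.

Filters are applied forward-backward (zero phase) so epoch-relative timing is
preserved.  The band-pass is a Hamming-window FIR with a ~1 Hz transition
width; the notch is a 2nd-order Butterworth band-stop with a 2 Hz bandwidth.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .core import ConfigurationError

_PASSBAND = (1.0, 70.0)


def _fir_taps(fs: float, transition_hz: float = 1.0) -> int:
    # Hamming-window design: transition width ~ 3.3 / numtaps cycles/sample.
    taps = int(np.ceil(3.3 * fs / transition_hz))
    return taps + 1 if taps % 2 == 0 else taps  # odd length, type-I linear phase


def design_bandpass(fs: float, low: float = _PASSBAND[0],
                    high: float = _PASSBAND[1]) -> np.ndarray:
    if fs <= 2 * high:
        raise ConfigurationError(
            f"fs={fs} too low: Nyquist must exceed the {high} Hz band edge")
    taps = _fir_taps(fs)
    return signal.firwin(taps, [low, high], pass_zero=False,
                         window="hamming", fs=fs)


def bandpass_filter(x: np.ndarray, fs: float, low: float = _PASSBAND[0],
                    high: float = _PASSBAND[1]) -> np.ndarray:
    """Zero-phase 1-70 Hz FIR band-pass along the last axis."""
    x = np.asarray(x, dtype=float)
    b = design_bandpass(fs, low, high)
    padlen = len(b)
    if x.shape[-1] <= padlen:
        raise ValueError(
            f"series of length {x.shape[-1]} shorter than filter order "
            f"({len(b) - 1}); filter continuous data, not single epochs")
    return signal.filtfilt(b, [1.0], x, axis=-1, padlen=padlen)


def notch_filter(x: np.ndarray, fs: float, f0: float = 50.0,
                 bandwidth: float = 2.0) -> np.ndarray:
    """Zero-phase Butterworth band-stop around the mains frequency."""
    x = np.asarray(x, dtype=float)
    if f0 >= fs / 2:
        raise ConfigurationError(f"notch frequency {f0} >= Nyquist {fs / 2}")
    sos = signal.butter(2, [f0 - bandwidth / 2, f0 + bandwidth / 2],
                        btype="bandstop", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


def segment_epochs(continuous: np.ndarray, fs: float,
                   epoch_seconds: float = 5.0) -> np.ndarray:
    """Cut a (channels, samples) record into non-overlapping epochs.

    Returns (n_epochs, channels, epoch_samples); the trailing remainder is
    discarded.
    """
    continuous = np.atleast_2d(np.asarray(continuous, dtype=float))
    epoch_len = int(round(fs * epoch_seconds))
    if abs(fs * epoch_seconds - epoch_len) > 1e-9:
        raise ConfigurationError("fs * epoch_seconds must be an integer")
    n_channels, n_samples = continuous.shape
    n_epochs = n_samples // epoch_len
    if n_epochs == 0:
        raise ValueError(
            f"recording of {n_samples} samples shorter than one "
            f"{epoch_len}-sample epoch")
    trimmed = continuous[:, : n_epochs * epoch_len]
    return trimmed.reshape(n_channels, n_epochs, epoch_len).transpose(1, 0, 2)


def preprocess_continuous(continuous: np.ndarray, fs: float,
                          epoch_seconds: float = 5.0,
                          notch_hz: float | None = 50.0) -> np.ndarray:
    """Filter a continuous multichannel record, then segment it."""
    x = bandpass_filter(continuous, fs)
    if notch_hz is not None:
        x = notch_filter(x, fs, notch_hz)
    return segment_epochs(x, fs, epoch_seconds)
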