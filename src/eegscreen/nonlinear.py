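"""Nonlinear per-epoch features: LZC, CTM, SampEn, FuzzyEn and AMI.

The entropy kernels are numba-compiled O(N^2) pair scans; they are checked
against plain-Python brute-force oracles in the test suite.  Parameter
selection picks, per feature, the grid point whose trial-level values best
separate the three groups under a Kruskal-Wallis test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import stats

from .core import (
    ConfigurationError,
    DegenerateInputError,
    UndefinedEntropyError,
)


# --------------------------------------------------------------------------
# Lempel-Ziv complexity
# --------------------------------------------------------------------------

@njit(cache=True)
def _lz76_count(s: np.ndarray) -> int:
    """Number of distinct production components of a binary sequence
    (Lempel-Ziv 1976, Kaspar-Schuster scanning algorithm)."""
    n = s.shape[0]
    c = 1
    l = 1
    i = 0
    k = 1
    kmax = 1
    while True:
        if s[i + k - 1] == s[l + k - 1]:
            k += 1
            if l + k > n:
                c += 1
                break
        else:
            if k > kmax:
                kmax = k
            i += 1
            if i == l:
                c += 1
                l += kmax
                if l + 1 > n:
                    break
                i = 0
                k = 1
                kmax = 1
            else:
                k = 1
    return c


def binarize_by_median(x: np.ndarray) -> np.ndarray:
    """0-1 conversion: samples at or above the median map to 1."""
    x = np.asarray(x, dtype=float)
    med = np.median(x)
    if np.all(x == x[0]):
        raise DegenerateInputError("constant series: median split undefined")
    return (x >= med).astype(np.uint8)


def lempel_ziv_complexity(x: np.ndarray) -> float:
    """Normalized LZ complexity of the median-binarized series."""
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("series too short for LZ complexity")
    s = binarize_by_median(x)
    c = _lz76_count(s)
    n = s.size
    return float(c * np.log2(n) / n)


# --------------------------------------------------------------------------
# Central tendency measure
# --------------------------------------------------------------------------

def central_tendency_measure(x: np.ndarray, rho: float,
                             normalize: bool = True) -> float:
    """Fraction of first-difference scatter points within radius rho.

    With normalize=True the epoch is z-scored first, so a single rho value is
    comparable across subjects and channels.
    """
    x = np.asarray(x, dtype=float)
    if rho <= 0:
        raise ConfigurationError("rho must be positive")
    if x.size < 3:
        raise ValueError("need at least 3 samples for the difference plot")
    if normalize:
        sd = x.std()
        x = (x - x.mean()) / sd if sd > 0 else x - x.mean()
    d = np.diff(x)
    radii = np.hypot(d[1:], d[:-1])
    return float(np.mean(radii < rho))


# --------------------------------------------------------------------------
# Sample entropy
# --------------------------------------------------------------------------

@njit(cache=True)
def _sampen_counts(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """Pairs of templates matching at length m and at length m+1
    (Chebyshev distance < r, self-matches excluded)."""
    nvec = x.shape[0] - m  # templates of length m that also have a successor
    bm = 0
    bm1 = 0
    for i in range(nvec - 1):
        for j in range(i + 1, nvec):
            d = 0.0
            for k in range(m):
                t = abs(x[i + k] - x[j + k])
                if t > d:
                    d = t
            if d < r:
                bm += 1
                t = abs(x[i + m] - x[j + m])
                if t > d:
                    d = t
                if d < r:
                    bm1 += 1
    return bm, bm1


def sample_entropy(x: np.ndarray, m: int = 1, r: float | None = None) -> float:
    """-ln(B^{m+1} / B^m) with tolerance r in the units of x."""
    x = np.asarray(x, dtype=float)
    if m < 1:
        raise ConfigurationError("m must be >= 1")
    if x.size <= m + 1:
        raise ValueError("series too short for the requested m")
    if r is None or r <= 0:
        raise ConfigurationError("tolerance r must be positive")
    bm, bm1 = _sampen_counts(x, m, r)
    if bm == 0 or bm1 == 0:
        raise UndefinedEntropyError(
            f"no template matches at m={m} (B^m={bm}, B^m+1={bm1})")
    return float(-np.log(bm1 / bm))


# --------------------------------------------------------------------------
# Fuzzy entropy
# --------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _fuzzy_phi(x: np.ndarray, m: int, nvec: int, r: float, n: float) -> float:
    """phi at template length m over the first nvec templates (nvec = N - m0
    at both lengths m0 and m0+1, mirroring the SampEn convention).

    D_ij is symmetric, so each unordered pair is evaluated once.
    """
    tm = np.empty((nvec, m))
    for i in range(nvec):
        mu = 0.0
        for k in range(m):
            mu += x[i + k]
        mu /= m
        for k in range(m):
            tm[i, k] = x[i + k] - mu
    rowsum = np.zeros(nvec)
    for i in range(nvec - 1):
        for j in range(i + 1, nvec):
            d = 0.0
            for k in range(m):
                t = abs(tm[i, k] - tm[j, k])
                if t > d:
                    d = t
            sim = np.exp(-(d ** n) / r)
            rowsum[i] += sim
            rowsum[j] += sim
    return rowsum.mean() / (nvec - 1)


@njit(cache=True, fastmath=True)
def _fuzzy_phi2_centered(a: np.ndarray, r: float, n: float) -> float:
    """phi^2 when m+1 = 2: mean-centred pair templates are (-a_i, +a_i) with
    a_i = (x(i+1) - x(i)) / 2, so the Chebyshev distance is just |a_i - a_j|."""
    nvec = a.shape[0]
    rowsum = np.zeros(nvec)
    for i in range(nvec - 1):
        for j in range(i + 1, nvec):
            sim = np.exp(-(abs(a[i] - a[j]) ** n) / r)
            rowsum[i] += sim
            rowsum[j] += sim
    return rowsum.mean() / (nvec - 1)


def fuzzy_entropy(x: np.ndarray, m: int = 1, r: float | None = None,
                  n: float = 3.0) -> float:
    """ln(phi^m) - ln(phi^{m+1}) with exponential similarity exp(-d^n / r)."""
    x = np.asarray(x, dtype=float)
    if m < 1 or n < 1:
        raise ConfigurationError("m and n must be >= 1")
    if x.size <= m + 1:
        raise ValueError("series too short for the requested m")
    if r is None or r <= 0:
        raise ConfigurationError("tolerance r must be positive")
    nvec = x.size - m  # templates carried at both lengths
    # mean-centred length-1 templates are identically zero, so phi^1 == 1
    phi_m = 1.0 if m == 1 else _fuzzy_phi(x, m, nvec, r, float(n))
    if m == 1:
        a = 0.5 * (x[1:] - x[:-1])  # nvec = N - 1 pair templates
        phi_m1 = _fuzzy_phi2_centered(a, r, float(n))
    else:
        phi_m1 = _fuzzy_phi(x, m + 1, nvec, r, float(n))
    return float(np.log(phi_m) - np.log(phi_m1))


# --------------------------------------------------------------------------
# Auto-mutual information
# --------------------------------------------------------------------------

@njit(cache=True)
def _ami_profile_bits(codes: np.ndarray, n_bins: int, max_lag: int) -> np.ndarray:
    """Mutual information (bits) between the series and its lagged copy,
    for lags 0..max_lag, from a 2-D equal-width histogram."""
    n = codes.shape[0]
    out = np.empty(max_lag + 1)
    joint = np.empty((n_bins, n_bins))
    for lag in range(max_lag + 1):
        npairs = n - lag
        joint[:, :] = 0.0
        for t in range(npairs):
            joint[codes[t], codes[t + lag]] += 1.0
        mi = 0.0
        for a in range(n_bins):
            pa = 0.0
            for b in range(n_bins):
                pa += joint[a, b]
            for b in range(n_bins):
                pb = 0.0
                for a2 in range(n_bins):
                    pb += joint[a2, b]
                pj = joint[a, b]
                if pj > 0.0:
                    mi += (pj / npairs) * np.log2(pj * npairs / (pa * pb))
        out[lag] = mi
    return out


def auto_mutual_information(
    x: np.ndarray, fs: float, max_lag_s: float = 0.5, bins: int = 16,
    summary: str = "mean",
) -> tuple[np.ndarray, float]:
    """Normalized AMI-vs-lag profile (AMI(0) = 1) and a scalar summary.

    summary="mean": mean of the normalized profile over lags >= 1.
    summary="slope": least-squares slope of the profile vs lag in seconds.
    """
    x = np.asarray(x, dtype=float)
    if bins < 2:
        raise ConfigurationError("need at least 2 histogram bins")
    max_lag = int(round(max_lag_s * fs))
    if abs(max_lag_s * fs - max_lag) > 1e-9:
        raise ConfigurationError("max_lag_s * fs must be an integer lag count")
    if x.size <= max_lag:
        raise ValueError("series shorter than the maximum lag")
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise DegenerateInputError("constant series: AMI(0) = 0")
    codes = np.minimum(((x - lo) / (hi - lo) * bins).astype(np.int64), bins - 1)
    profile = _ami_profile_bits(codes, bins, max_lag)
    if profile[0] <= 0:
        raise DegenerateInputError("zero entropy at lag 0")
    profile = profile / profile[0]
    if summary == "mean":
        value = float(profile[1:].mean())
    elif summary == "slope":
        lags_s = np.arange(max_lag + 1) / fs
        value = float(np.polyfit(lags_s, profile, 1)[0])
    else:
        raise ConfigurationError(f"unknown AMI summary {summary!r}")
    return profile, value


# --------------------------------------------------------------------------
# Parameter container and grid selection
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NonlinearParams:
    """Nonlinear feature parameters; tolerances are multiples of epoch SD."""

    ctm_rho: float = 0.075
    sampen_m: int = 1
    sampen_r: float = 0.1
    fuzzyen_m: int = 1
    fuzzyen_r: float = 0.1
    fuzzyen_n: float = 3.0
    ami_max_lag_s: float = 0.5
    ami_bins: int = 16
    ami_summary: str = "mean"
    ctm_normalize: bool = True

    def __post_init__(self) -> None:
        if self.ctm_rho <= 0 or self.sampen_r <= 0 or self.fuzzyen_r <= 0:
            raise ConfigurationError("tolerances must be positive")
        if self.sampen_m < 1 or self.fuzzyen_m < 1 or self.fuzzyen_n < 1:
            raise ConfigurationError("m and n must be >= 1")
        if self.ami_bins < 2:
            raise ConfigurationError("ami_bins must be >= 2")


def nonlinear_features(epoch: np.ndarray, fs: float,
                       params: NonlinearParams) -> dict[str, float]:
    """The five nonlinear feature values of one epoch/channel.

    SampEn may be undefined (no matches); the caller handles the raised
    UndefinedEntropyError by excluding the epoch/channel from averaging.
    """
    epoch = np.asarray(epoch, dtype=float)
    sd = epoch.std()
    if sd == 0:
        raise DegenerateInputError("constant epoch")
    out = {
        "LZC": lempel_ziv_complexity(epoch),
        "CTM": central_tendency_measure(epoch, params.ctm_rho,
                                        params.ctm_normalize),
        "SampEn": sample_entropy(epoch, params.sampen_m, params.sampen_r * sd),
        "FuzzyEn": fuzzy_entropy(epoch, params.fuzzyen_m,
                                 params.fuzzyen_r * sd, params.fuzzyen_n),
    }
    _, ami = auto_mutual_information(epoch, fs, params.ami_max_lag_s,
                                     params.ami_bins, params.ami_summary)
    out["AMI"] = ami
    return out


def default_grids() -> dict[str, list]:
    """Full parameter grids for the selection procedure."""
    return {
        "ctm": [round(r, 3) for r in np.arange(0.01, 0.5 + 1e-9, 0.005)],
        "sampen": [(m, round(r, 2)) for m in (1, 2)
                   for r in np.arange(0.1, 0.25 + 1e-9, 0.05)],
        "fuzzyen": [(m, round(r, 2), n) for m in (1, 2)
                    for r in np.arange(0.1, 0.25 + 1e-9, 0.05)
                    for n in (1, 2, 3)],
    }


def _kw_pvalue(values: np.ndarray, groups: np.ndarray) -> float:
    samples = [values[groups == g] for g in np.unique(groups)]
    if any(len(s) == 0 for s in samples) or len(samples) < 2:
        raise ValueError("every group needs at least one observation")
    if all(np.all(s == samples[0][0]) for s in samples):
        return 1.0  # identical constant samples: no separation
    return float(stats.kruskal(*samples).pvalue)


def select_nonlinear_params(recordings, grids: dict[str, list] | None = None,
                            base: NonlinearParams | None = None) -> NonlinearParams:
    """Pick, per feature, the grid point minimizing the Kruskal-Wallis p-value
    of trial-level (channel-averaged) values across the three groups.

    Ties are broken toward smaller parameter values (lexicographic order).
    Only pass training-set recordings here.
    """
    grids = grids if grids is not None else default_grids()
    base = base or NonlinearParams()
    if not recordings:
        raise ValueError("no recordings given")

    groups = np.concatenate([[rec.group] * rec.n_trials for rec in recordings])
    if len(np.unique(groups)) < 2:
        raise ValueError("need at least two groups for selection")

    def trial_values(fn) -> np.ndarray:
        vals = []
        for rec in recordings:
            for t in range(rec.n_trials):
                per_ch = []
                for c in range(rec.n_channels):
                    try:
                        per_ch.append(fn(rec.data[t, c], rec.fs))
                    except (DegenerateInputError, ValueError):
                        continue
                vals.append(np.mean(per_ch) if per_ch else np.nan)
        return np.asarray(vals)

    def best(grid, fn):
        scored = []
        for point in grid:
            v = trial_values(lambda x, fs, p=point: fn(x, fs, p))
            ok = ~np.isnan(v)
            scored.append((_kw_pvalue(v[ok], groups[ok]), point))
        pmin = min(p for p, _ in scored)
        return min(pt for p, pt in scored if p == pmin)

    rho = best(sorted(grids["ctm"]),
               lambda x, fs, p: central_tendency_measure(x, p, base.ctm_normalize))
    sm, sr = best(sorted(grids["sampen"]),
                  lambda x, fs, p: sample_entropy(x, p[0], p[1] * x.std()))
    fm, fr, fn_ = best(sorted(grids["fuzzyen"]),
                       lambda x, fs, p: fuzzy_entropy(x, p[0], p[1] * x.std(), p[2]))
    return NonlinearParams(ctm_rho=rho, sampen_m=sm, sampen_r=sr,
                           fuzzyen_m=fm, fuzzyen_r=fr, fuzzyen_n=fn_,
                           ami_max_lag_s=base.ami_max_lag_s,
                           ami_bins=base.ami_bins, ami_summary=base.ami_summary,
                           ctm_normalize=base.ctm_normalize)
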