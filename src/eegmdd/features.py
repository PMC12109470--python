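"""Per-epoch EEG feature schema: spectral, temporal, nonlinear, time-frequency.

Nineteen features are computed per channel and averaged over each scalp
region's channels, giving ``n_regions x 19`` columns (95 under the default
five-region map):

* spectral (9): spectral centroid, PSD-argmax frequency, six absolute band
  powers (Simpson-integrated Welch PSD) and total power;
* temporal (3): skewness, kurtosis (Fisher), peak absolute amplitude;
* nonlinear (5): sample entropy, Higuchi fractal dimension, R/S Hurst
  exponent, Shannon entropy of the amplitude histogram, C0 complexity;
* time-frequency (2): mean and max spectrogram energy.

The sample-entropy pair count is numba-compiled; everything else is
numpy/scipy.  All estimators are deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from numba import njit
from scipy import signal as sps
from scipy import stats as spstats
from scipy.integrate import simpson

from .core import (
    BANDS_STANDARD,
    BandScheme,
    DEFAULT_REGION_MAP,
    EpochSet,
    FeatureTable,
    RegionMap,
)

__all__ = [
    "PSDEstimate",
    "FeatureParams",
    "FEATURE_NAMES",
    "FEATURE_CATEGORIES",
    "welch_psd",
    "band_powers",
    "center_frequencies",
    "temporal_stats",
    "sample_entropy",
    "higuchi_fd",
    "higuchi_curve_lengths",
    "hurst_rs",
    "shannon_entropy",
    "c0_complexity",
    "tf_energy",
    "feature_vector",
    "build_feature_table",
]

#: Column order of the per-region feature block.
FEATURE_NAMES = [
    "center_freq_relative",
    "center_freq_absolute",
    "delta_power",
    "theta_power",
    "alpha_power",
    "beta1_power",
    "beta2_power",
    "gamma_power",
    "total_power",
    "skewness",
    "kurtosis",
    "peak",
    "sample_entropy",
    "higuchi_fd",
    "hurst",
    "shannon_entropy",
    "c0_complexity",
    "mean_tf_energy",
    "max_tf_energy",
]

FEATURE_CATEGORIES = {
    "spectral": FEATURE_NAMES[0:9],
    "temporal": FEATURE_NAMES[9:12],
    "nonlinear": FEATURE_NAMES[12:17],
    "time_frequency": FEATURE_NAMES[17:19],
}


@dataclass
class PSDEstimate:
    """Segment-averaged (Welch) power spectral density, µV²/Hz."""

    freqs: np.ndarray
    power: np.ndarray
    segment_length: int
    hop: int
    n_segments: int
    window: str = "hann"

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape:
            raise ValueError("freqs and power must have matching shapes")
        if np.any(self.power < 0):
            raise ValueError("PSD must be non-negative")


@dataclass
class FeatureParams:
    """Tunable knobs of the feature extractors (field-standard defaults)."""

    welch_segment_seconds: float = 4.0
    welch_overlap_fraction: float = 0.5
    sampen_m: int = 2
    sampen_r_factor: float = 0.2  # tolerance = factor × epoch SD
    higuchi_kmax: int = 10
    shannon_bins: int = 128
    stft_window_seconds: float = 1.0
    stft_overlap_fraction: float = 0.5
    c0_mode: str = "paper_literal"


# ---------------------------------------------------------------------------
# Spectral
# ---------------------------------------------------------------------------

def welch_psd(
    x: np.ndarray,
    fs: float,
    segment_seconds: float = 4.0,
    overlap_fraction: float = 0.5,
) -> PSDEstimate:
    """Welch PSD: mean of windowed per-segment periodograms.

    Density scaling — Simpson-integrating the estimate over the full range
    recovers the signal variance (white-noise Parseval consistency).
    """
    x = np.asarray(x, dtype=float)
    nperseg = int(round(segment_seconds * fs))
    if x.size < nperseg:
        raise ValueError(
            f"signal of {x.size} samples shorter than one "
            f"{nperseg}-sample Welch segment"
        )
    noverlap = int(round(nperseg * overlap_fraction))
    freqs, power = sps.welch(
        x, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap,
        detrend="constant", scaling="density",
    )
    hop = nperseg - noverlap
    n_segments = (x.size - noverlap) // hop
    return PSDEstimate(freqs=freqs, power=power, segment_length=nperseg,
                       hop=hop, n_segments=n_segments)


def band_powers(
    psd: PSDEstimate, bands: BandScheme = BANDS_STANDARD
) -> tuple[dict[str, float], float, dict[str, float]]:
    """Simpson-integrated absolute, total, and relative band powers.

    Absolute power integrates the PSD over ``[f_lo, f_hi)`` on the
    frequency grid; total power integrates the full estimated range;
    relative = absolute / total.
    """
    f, p = psd.freqs, psd.power
    if bands.f_hi > f[-1] + 1e-9:
        raise ValueError(
            f"band edge {bands.f_hi} Hz outside PSD range (max {f[-1]:.2f} Hz)"
        )
    total = float(simpson(p, x=f))
    absolute: dict[str, float] = {}
    for name, (lo, hi) in bands:
        mask = (f >= lo) & (f < hi)
        if mask.sum() < 2:
            raise ValueError(
                f"band {name!r} covers fewer than 2 PSD grid points"
            )
        absolute[name] = float(simpson(p[mask], x=f[mask]))
    if total <= 0:
        raise ValueError("total power is zero; degenerate PSD")
    relative = {k: v / total for k, v in absolute.items()}
    return absolute, total, relative


def center_frequencies(psd: PSDEstimate) -> tuple[float, float]:
    """(spectral centroid, PSD-argmax frequency); ties go to the lower bin."""
    f, p = psd.freqs, psd.power
    denom = simpson(p, x=f)
    if denom <= 0:
        raise ValueError("all-zero PSD has no center frequency")
    centroid = float(simpson(f * p, x=f) / denom)
    argmax = float(f[int(np.argmax(p))])  # first max = lowest frequency
    return centroid, argmax


# ---------------------------------------------------------------------------
# Temporal
# ---------------------------------------------------------------------------

def temporal_stats(x: np.ndarray) -> tuple[float, float, float, bool]:
    """(skewness, Fisher kurtosis, peak |amplitude|, degenerate flag).

    A zero-variance series reports (0, 0, peak) with the flag set.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("temporal stats need at least 2 samples")
    peak = float(np.abs(x).max())
    if np.ptp(x) == 0:
        return 0.0, 0.0, peak, True
    return (
        float(spstats.skew(x)),
        float(spstats.kurtosis(x, fisher=True)),
        peak,
        False,
    )


# ---------------------------------------------------------------------------
# Nonlinear
# ---------------------------------------------------------------------------

@njit(cache=True)
def _sampen_pair_counts(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """Chebyshev template matches at lengths m (B) and m+1 (A); no self-matches."""
    n = x.shape[0]
    nvec = n - m
    A = 0
    B = 0
    for i in range(nvec - 1):
        for j in range(i + 1, nvec):
            ok = True
            for k in range(m):
                if abs(x[i + k] - x[j + k]) > r:
                    ok = False
                    break
            if ok:
                B += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    A += 1
    return A, B


def sample_entropy(
    x: np.ndarray,
    m: int = 2,
    r: float | None = None,
) -> float:
    """Sample entropy −ln(A/B) with Chebyshev distance.

    ``r`` defaults to 0.2 × SD of the series.  B = 0 (no template pairs
    match at length m) returns +inf; A = 0 with B > 0 is capped at
    ln(B) + ln(N − m) so downstream tables stay finite.
    """
    x = np.ascontiguousarray(x, dtype=np.float64)
    n = x.size
    if n <= m + 1:
        raise ValueError(f"series of {n} samples too short for m={m}")
    if r is None:
        r = 0.2 * float(x.std())
    if r < 0:
        raise ValueError("tolerance r must be non-negative")
    if np.ptp(x) == 0:
        return 0.0  # every template matches: A/B = 1
    A, B = _sampen_pair_counts(x, m, float(r))
    if B == 0:
        return math.inf
    if A == 0:
        return math.log(B) + math.log(n - m)
    return -math.log(A / B)


def higuchi_curve_lengths(x: np.ndarray, kmax: int = 10) -> np.ndarray:
    """Mean curve length L(k) for scale factors k = 1..kmax.

    L(m, k) is the normalized length of the decimated series starting at
    offset m with step k; L(k) averages over the k offsets.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2 * kmax:
        raise ValueError(f"need at least {2 * kmax} samples for kmax={kmax}")
    L = np.empty(kmax)
    for k in range(1, kmax + 1):
        lm = np.empty(k)
        for m in range(k):
            idx = np.arange(m, n, k)
            nseg = idx.size - 1
            if nseg < 1:
                lm[m] = 0.0
                continue
            dist = np.abs(np.diff(x[idx])).sum()
            norm = (n - 1) / (nseg * k)
            lm[m] = dist * norm / k
        L[k - 1] = lm.mean()
    return L


def higuchi_fd(x: np.ndarray, kmax: int = 10, clip: bool = True) -> float:
    """Higuchi fractal dimension from the log L(k) – log k slope.

    D is 1 for a smooth curve and approaches 2 for white noise.  The
    reported value is clipped to [1, 2] unless ``clip=False``.  A constant
    series reports D = 1 (degenerate).
    """
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        return 1.0
    L = higuchi_curve_lengths(x, kmax)
    if np.any(L <= 0):
        return 1.0
    k = np.arange(1, kmax + 1)
    slope = np.polyfit(np.log(k), np.log(L), 1)[0]
    d = -float(slope)
    return float(np.clip(d, 1.0, 2.0)) if clip else d


def hurst_rs(x: np.ndarray, min_window: int = 16,
             n_scales: int = 10) -> float:
    """Rescaled-range Hurst exponent.

    For log-spaced window sizes n the series is partitioned into disjoint
    windows (from both ends, so reversal leaves the estimate unchanged);
    each window contributes (range of cumulative mean deviation) / SD, and
    H is the slope of log(R/S) against log(n).  ≈0.5 for uncorrelated
    noise, >0.5 for persistent series.  Constant input reports 0.5.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 64:
        raise ValueError("Hurst estimation needs at least 64 samples")
    if np.ptp(x) == 0:
        return 0.5
    sizes = np.unique(
        np.geomspace(min_window, n // 2, num=n_scales).astype(int)
    )
    log_n, log_rs = [], []
    for w in sizes:
        rs_vals = []
        n_win = n // w
        for rev in (False, True):
            xx = x[::-1] if rev else x
            for i in range(n_win):
                seg = xx[i * w : (i + 1) * w]
                s = seg.std()
                if s == 0:
                    continue
                y = np.cumsum(seg - seg.mean())
                rs_vals.append((y.max() - y.min()) / s)
        if rs_vals:
            log_n.append(math.log(w))
            log_rs.append(math.log(np.mean(rs_vals)))
    if len(log_n) < 2:
        return 0.5
    return float(np.polyfit(log_n, log_rs, 1)[0])


def shannon_entropy(x: np.ndarray, n_bins: int = 128) -> float:
    """Shannon entropy (nats) of the equal-width amplitude histogram.

    Bins span [min, max]; a constant series has zero entropy.
    """
    x = np.asarray(x, dtype=float)
    if x.size < n_bins:
        raise ValueError(f"need at least {n_bins} samples for {n_bins} bins")
    if np.ptp(x) == 0:
        return 0.0
    counts, _ = np.histogram(x, bins=n_bins, range=(x.min(), x.max()))
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def c0_complexity(x: np.ndarray, mode: str = "paper_literal") -> float:
    """C0 complexity of a series.

    ``paper_literal`` (default): the maximum single-sided FFT amplitude,
    2·|X_k|/N — 1.0 for a unit-amplitude grid-frequency sinusoid.
    ``standard``: fraction of total spectral power carried by components at
    or below the mean spectral power (irregularity ratio in [0, 1]).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 8:
        raise ValueError("C0 complexity needs at least 8 samples")
    spec = np.fft.rfft(x)
    if mode == "paper_literal":
        return float(np.abs(spec).max() * 2.0 / n)
    if mode == "standard":
        power = np.abs(spec) ** 2
        total = power.sum()
        if total == 0:
            return 0.0
        mean_p = power.mean()
        return float(power[power <= mean_p].sum() / total)
    raise ValueError(f"unknown C0 mode {mode!r}")


# ---------------------------------------------------------------------------
# Time-frequency
# ---------------------------------------------------------------------------

def tf_energy(
    x: np.ndarray,
    fs: float,
    stft_window_seconds: float = 1.0,
    stft_overlap_fraction: float = 0.5,
) -> tuple[float, float]:
    """Mean and max magnitude-squared spectrogram energy over all bins."""
    x = np.asarray(x, dtype=float)
    nperseg = int(round(stft_window_seconds * fs))
    if x.size < nperseg:
        raise ValueError("signal shorter than one STFT window")
    noverlap = int(round(nperseg * stft_overlap_fraction))
    _, _, sxx = sps.spectrogram(
        x, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap,
        detrend=False, scaling="density", mode="psd",
    )
    return float(sxx.mean()), float(sxx.max())


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def feature_vector(
    x: np.ndarray,
    fs: float,
    bands: BandScheme = BANDS_STANDARD,
    params: FeatureParams | None = None,
) -> dict[str, float]:
    """All 19 features of one channel-epoch, keyed by feature name."""
    params = params or FeatureParams()
    x = np.asarray(x, dtype=float)

    psd = welch_psd(x, fs, params.welch_segment_seconds,
                    params.welch_overlap_fraction)
    absolute, total, _ = band_powers(psd, bands)
    centroid, argmax_f = center_frequencies(psd)
    skew, kurt, peak, _ = temporal_stats(x)
    se = sample_entropy(x, m=params.sampen_m,
                        r=params.sampen_r_factor * float(x.std()))
    if not math.isfinite(se):
        se = math.log(max(x.size - params.sampen_m, 2))  # B = 0 saturation
    mean_tf, max_tf = tf_energy(x, fs, params.stft_window_seconds,
                                params.stft_overlap_fraction)

    out = {
        "center_freq_relative": centroid,
        "center_freq_absolute": argmax_f,
        "total_power": total,
        "skewness": skew,
        "kurtosis": kurt,
        "peak": peak,
        "sample_entropy": se,
        "higuchi_fd": higuchi_fd(x, params.higuchi_kmax),
        "hurst": hurst_rs(x),
        "shannon_entropy": shannon_entropy(x, params.shannon_bins),
        "c0_complexity": c0_complexity(x, params.c0_mode),
        "mean_tf_energy": mean_tf,
        "max_tf_energy": max_tf,
    }
    for band in bands.band_names:
        out[f"{band}_power"] = absolute[band]
    return {name: out[name] for name in FEATURE_NAMES}


def build_feature_table(
    epoch_sets: Iterable[EpochSet],
    regions: RegionMap = DEFAULT_REGION_MAP,
    bands: BandScheme = BANDS_STANDARD,
    params: FeatureParams | None = None,
) -> FeatureTable:
    """One row per retained epoch; features averaged over region channels.

    Each of the 19 features is computed per channel and then arithmetically
    averaged across the region's channels; columns are
    ``"<region>__<feature>"`` (5 × 19 = 95 under the defaults).
    """
    params = params or FeatureParams()
    epoch_sets = list(epoch_sets)
    if not epoch_sets:
        raise ValueError("no epoch sets supplied")

    columns = [
        f"{region}__{feat}"
        for region, _ in regions
        for feat in FEATURE_NAMES
    ]
    rows: list[list[float]] = []
    labels: list[str] = []
    subjects: list[str] = []

    for eps in epoch_sets:
        # map region channels to data rows once per epoch set
        lower = {c.lower(): i for i, c in enumerate(eps.channel_names)}
        region_idx: dict[str, list[int]] = {}
        for region, chans in regions:
            idx = []
            for ch in chans:
                if ch.lower() not in lower:
                    raise ValueError(
                        f"region {region!r} channel {ch!r} missing from "
                        f"recording {eps.subject_id!r}"
                    )
                idx.append(lower[ch.lower()])
            region_idx[region] = idx

        for e in range(eps.n_epochs):
            if not eps.retained[e]:
                continue
            per_channel = {}
            needed = sorted({i for idx in region_idx.values() for i in idx})
            for ci in needed:
                per_channel[ci] = feature_vector(
                    eps.epochs[e, ci], eps.fs, bands, params
                )
            row: list[float] = []
            for region, _ in regions:
                idx = region_idx[region]
                for feat in FEATURE_NAMES:
                    row.append(
                        float(np.mean([per_channel[i][feat] for i in idx]))
                    )
            rows.append(row)
            labels.append(eps.group)
            subjects.append(eps.subject_id)

    if not rows:
        raise ValueError("no retained epochs across the supplied epoch sets")
    values = pd.DataFrame(rows, columns=columns)
    return FeatureTable(values, labels, subjects)
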