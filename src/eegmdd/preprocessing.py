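"""Continuous-signal cleaning: re-referencing, filtering, ICA artifact removal.

The chain mirrors standard resting-EEG practice: average reference to unify
the baseline, a zero-phase FIR band-pass (0.5–50 Hz) plus a 49–51 Hz FIR
band-stop against mains interference, and ICA-based suppression of
components that track a frontal (Fp1/Fp2) eye-movement proxy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import Recording

__all__ = [
    "ArtifactReport",
    "apply_average_reference",
    "filter_recording",
    "remove_artifact_components",
]


@dataclass
class ArtifactReport:
    """What the ICA stage removed and why."""

    n_components: int
    removed_indices: list[int]
    correlation_with_frontal_proxy: list[float]
    threshold: float = 0.7
    converged: bool = True

    def __post_init__(self) -> None:
        for i in self.removed_indices:
            if not 0 <= i < self.n_components:
                raise ValueError(f"removed index {i} outside [0, {self.n_components})")


def apply_average_reference(rec: Recording) -> Recording:
    """Subtract the instantaneous cross-channel mean from every channel.

    After re-referencing the per-sample mean across channels is zero (to
    numerical tolerance).  Requires at least two channels.
    """
    if rec.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    out = rec.copy_with(data=data)
    out.annotations["reference"] = "average"
    return out


def _design_bandpass(fs: float, low: float, high: float,
                     transition: float = 0.5) -> np.ndarray:
    """Hamming-window FIR band-pass; transition width set by the low edge."""
    # Hamming transition width ~ 3.3 / numtaps (normalized); odd tap count.
    numtaps = int(np.ceil(3.3 * fs / transition))
    numtaps += 1 - numtaps % 2
    return signal.firwin(numtaps, [low, high], pass_zero=False,
                         window="hamming", fs=fs)


def _design_bandstop(fs: float, notch: float, half_width: float = 1.0,
                     transition: float = 0.5) -> np.ndarray:
    numtaps = int(np.ceil(3.3 * fs / transition))
    numtaps += 1 - numtaps % 2
    return signal.firwin(numtaps, [notch - half_width, notch + half_width],
                         pass_zero=True, window="hamming", fs=fs)


def _zero_phase_fir(data: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Forward-backward FIR filtering along the last axis (zero phase).

    Uses FFT convolution with reflected-edge padding, so it stays fast for
    the multi-thousand-tap kernels a 0.5 Hz transition demands.
    """
    n = data.shape[-1]
    pad = min(3 * taps.size, n - 1)
    if pad > 0:
        left = data[..., 1 : pad + 1][..., ::-1]
        right = data[..., -pad - 1 : -1][..., ::-1]
        ext = np.concatenate([2 * data[..., :1] - left, data,
                              2 * data[..., -1:] - right], axis=-1)
    else:
        ext = data
    fwd = signal.fftconvolve(ext, taps[None, :] if data.ndim == 2 else taps,
                             mode="same", axes=-1)
    bwd = signal.fftconvolve(fwd[..., ::-1],
                             taps[None, :] if data.ndim == 2 else taps,
                             mode="same", axes=-1)[..., ::-1]
    return bwd[..., pad : pad + n] if pad > 0 else bwd


def filter_recording(
    rec: Recording,
    band: tuple[float, float] = (0.5, 50.0),
    notch: float | None = 50.0,
) -> Recording:
    """Zero-phase FIR band-pass plus optional mains band-stop.

    Signal length is preserved; the notch attenuates the mains line by well
    over 20 dB (forward-backward filtering squares the magnitude response).
    """
    low, high = band
    if not 0 < low < high:
        raise ValueError(f"invalid band edges {band}")
    if rec.fs <= 2 * high:
        raise ValueError(
            f"sampling rate {rec.fs} Hz cannot represent a {high} Hz band edge"
        )
    data = _zero_phase_fir(rec.data, _design_bandpass(rec.fs, low, high))
    if notch is not None:
        if notch >= rec.fs / 2:
            raise ValueError(f"notch {notch} Hz above Nyquist")
        data = _zero_phase_fir(data, _design_bandstop(rec.fs, notch))
    out = rec.copy_with(data=data)
    out.annotations["filter"] = {"band": [low, high], "notch": notch,
                                 "design": "hamming-fir-zerophase"}
    return out


def remove_artifact_components(
    rec: Recording,
    threshold: float = 0.7,
    seed: int = 0,
    max_iter: int = 500,
) -> tuple[Recording, ArtifactReport]:
    """Suppress ICA components correlated with frontal eye activity.

    The decomposition (FastICA) is deterministic given ``seed``.  The
    component count equals the channel count capped at the data's numerical
    rank — average-referenced data lose one degree of freedom, and a
    singular whitening matrix wrecks both convergence and reconstruction.
    The unmixing is estimated on a decimated copy of the signal (enough to
    keep ≥ 20 k samples) and applied to the full-rate data.  Components
    whose time course has absolute Pearson correlation >= ``threshold``
    with the frontal proxy — the mean of Fp1 and Fp2 *before*
    decomposition — are zeroed and the signal reconstructed from the
    remainder.
    """
    from sklearn.decomposition import FastICA
    from sklearn.exceptions import ConvergenceWarning
    import warnings

    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    if rec.n_channels < 3:
        raise ValueError("ICA needs at least 3 channels")
    if rec.duration < 10.0:
        raise ValueError("ICA needs at least 10 s of signal")
    try:
        proxy = (rec.data[rec.channel_index("Fp1")] +
                 rec.data[rec.channel_index("Fp2")]) / 2.0
    except KeyError as e:
        raise ValueError("frontal proxy needs Fp1 and Fp2 channels") from e

    X = rec.data.T  # samples × channels
    sv = np.linalg.svd(X - X.mean(axis=0), compute_uv=False)
    rank = int((sv > sv[0] * 1e-8).sum())
    n_comp = min(rec.n_channels, rank)
    decim = max(1, X.shape[0] // 20000)
    ica = FastICA(n_components=n_comp, random_state=seed,
                  whiten="unit-variance", max_iter=max_iter, tol=1e-3)
    # Full rotational convergence is unattainable when most sources are
    # near-Gaussian (background EEG); the spiky artifact components are
    # still identified, so non-convergence is flagged, not fatal.
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        ica.fit(X[::decim])
        converged = not any(
            issubclass(w.category, ConvergenceWarning) for w in caught
        )
    S = ica.transform(X)

    proxy_sd = proxy.std()
    corrs = []
    for k in range(S.shape[1]):
        s = S[:, k]
        sd = s.std()
        if proxy_sd == 0 or sd == 0:
            corrs.append(0.0)
        else:
            corrs.append(float(np.corrcoef(s, proxy)[0, 1]))
    removed = [k for k, c in enumerate(corrs) if abs(c) >= threshold]

    S_clean = S.copy()
    S_clean[:, removed] = 0.0
    cleaned = ica.inverse_transform(S_clean).T

    report = ArtifactReport(
        n_components=S.shape[1],
        removed_indices=removed,
        correlation_with_frontal_proxy=corrs,
        threshold=threshold,
        converged=converged,
    )
    out = rec.copy_with(data=cleaned)
    out.annotations["ica"] = {
        "seed": seed,
        "threshold": threshold,
        "removed": removed,
        "converged": converged,
    }
    return out, report
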