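"""Cropping, overlapping epoch extraction, and amplitude quality control.

Defaults follow the study protocol: keep 30–155 s of each recording, cut
32 s epochs with 1 s overlap (four per subject at those defaults), then
drop epochs whose absolute amplitude exceeds 100 µV on any channel or whose
peak-to-peak amplitude falls below 1 µV on any channel.
"""

from __future__ import annotations

import numpy as np

from .core import EpochSet, Recording

__all__ = ["crop_recording", "epoch_recording", "qc_epochs"]


def crop_recording(rec: Recording, t_start: float = 30.0,
                   t_end: float = 155.0) -> Recording:
    """Keep the [t_start, t_end) stretch of the recording (seconds).

    The output holds exactly ``round((t_end - t_start) * fs)`` samples.
    """
    if not 0 <= t_start < t_end:
        raise ValueError(f"invalid crop window [{t_start}, {t_end})")
    if rec.duration + 1e-9 < t_end:
        raise ValueError(
            f"recording lasts {rec.duration:.2f} s, cannot crop to {t_end} s"
        )
    i0 = int(round(t_start * rec.fs))
    n_out = int(round((t_end - t_start) * rec.fs))
    out = rec.copy_with(data=rec.data[:, i0 : i0 + n_out].copy())
    out.annotations["crop"] = [t_start, t_end]
    return out


def epoch_recording(rec: Recording, window_seconds: float = 32.0,
                    overlap_seconds: float = 1.0) -> EpochSet:
    """Cut fixed-length overlapping epochs starting at multiples of the stride.

    Epoch k starts at ``k * (window - overlap)`` seconds; the count is
    ``floor((T - window) / (window - overlap)) + 1``.
    """
    if overlap_seconds >= window_seconds:
        raise ValueError("overlap must be shorter than the window")
    if rec.duration + 1e-9 < window_seconds:
        raise ValueError(
            f"recording lasts {rec.duration:.2f} s, shorter than one "
            f"{window_seconds} s window"
        )
    win = int(round(window_seconds * rec.fs))
    stride = int(round((window_seconds - overlap_seconds) * rec.fs))
    starts = list(range(0, rec.n_samples - win + 1, stride))
    epochs = np.stack([rec.data[:, s : s + win] for s in starts])
    return EpochSet(
        epochs=epochs,
        fs=rec.fs,
        window_seconds=window_seconds,
        overlap_seconds=overlap_seconds,
        retained=np.ones(len(starts), dtype=bool),
        subject_id=rec.subject_id,
        group=rec.group,
        channel_names=list(rec.channel_names),
        starts=np.asarray(starts, dtype=float) / rec.fs,
    )


def qc_epochs(eps: EpochSet, reject: float = 100.0,
              flat: float = 1.0) -> EpochSet:
    """Amplitude quality control on top of the current retention mask.

    An epoch stays retained iff every channel's max absolute amplitude is
    <= ``reject`` µV *and* every channel's peak-to-peak amplitude is >=
    ``flat`` µV.  Data are untouched; only the mask changes.  Idempotent.
    """
    if eps.n_epochs == 0:
        raise ValueError("no epochs to quality-control")
    peak = np.abs(eps.epochs).max(axis=2)  # epochs × channels
    ptp = eps.epochs.max(axis=2) - eps.epochs.min(axis=2)
    ok = (peak <= reject).all(axis=1) & (ptp >= flat).all(axis=1)
    return EpochSet(
        epochs=eps.epochs,
        fs=eps.fs,
        window_seconds=eps.window_seconds,
        overlap_seconds=eps.overlap_seconds,
        retained=eps.retained & ok,
        subject_id=eps.subject_id,
        group=eps.group,
        channel_names=list(eps.channel_names),
        starts=eps.starts,
    )
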