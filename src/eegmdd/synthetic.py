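"""Synthetic two-group resting-EEG cohorts.

Each recording is a sum of band-limited oscillatory carriers (filtered white
noise, one per canonical band), a 1/f^beta broadband background, frontal
blink transients, and 50 Hz mains contamination — the ingredients the
downstream pipeline must separate.  Patient-group (MDD) recordings have each
band's carrier amplitude multiplied by a configurable effect factor,
optionally restricted to a subset of scalp regions, so group differences in
relative band power are planted with known location and sign.

Default effect directions: theta, alpha and beta relative power elevated in
the patient group, gamma reduced, delta untouched.  Carriers are noise, not
pure tones, so entropy/fractal features stay non-degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import (
    BANDS_STANDARD,
    BandScheme,
    DEFAULT_REGION_MAP,
    Recording,
    RegionMap,
    STANDARD_CHANNELS,
)

__all__ = [
    "EffectMap",
    "CohortSpec",
    "generate_recording",
    "generate_cohort",
    "write_edf_fixture",
]

#: Per-band carrier RMS amplitudes (µV) of the healthy-control baseline.
#: Posterior-dominant alpha, strong slow activity, weak gamma — the usual
#: eyes-closed resting profile.
DEFAULT_BAND_AMPLITUDES = {
    "delta": 10.0,
    "theta": 6.0,
    "alpha": 8.0,
    "beta1": 3.0,
    "beta2": 2.0,
    "gamma": 1.0,
}

#: Patient-group amplitude factors (1.0 = no group difference).
DEFAULT_EFFECT_FACTORS = {
    "delta": 1.0,
    "theta": 1.3,
    "alpha": 1.3,
    "beta1": 1.2,
    "beta2": 1.2,
    "gamma": 0.8,
}

#: Blink spatial falloff: full on Fp1/Fp2, 0.3 on F3/F4, 0.05 elsewhere.
_BLINK_TOPO = {"fp1": 1.0, "fp2": 1.0, "f3": 0.3, "f4": 0.3}


@dataclass
class EffectMap:
    """Group-difference and nuisance parameters of the generator.

    ``band_factors`` multiply the patient group's per-band carrier
    amplitude (power scales with the square); ``region_scope`` restricts
    the effect to the named regions' channels (None = whole scalp).
    """

    band_factors: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_FACTORS)
    )
    blink_rate: float = 10.0  # events per minute
    line_noise_amplitude: float = 2.0  # µV, 50 Hz
    background_exponent: float = 1.0  # 1/f^beta slope
    background_amplitude: float = 5.0  # µV RMS over the passband
    base_band_amplitudes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_AMPLITUDES)
    )
    region_scope: list[str] | None = None

    def __post_init__(self) -> None:
        for band, f in self.band_factors.items():
            if f <= 0:
                raise ValueError(f"effect factor for {band!r} must be > 0")
        if self.blink_rate < 0:
            raise ValueError("blink_rate must be >= 0")

    @classmethod
    def null(cls, **kwargs) -> "EffectMap":
        """No group difference (all factors 1.0)."""
        factors = {b: 1.0 for b in DEFAULT_EFFECT_FACTORS}
        return cls(band_factors=factors, **kwargs)


@dataclass
class CohortSpec:
    """Cohort-level generation parameters."""

    n_mdd: int = 34
    n_hc: int = 30
    duration_seconds: float = 160.0
    fs: float = 256.0
    effect: EffectMap = field(default_factory=EffectMap)
    seed: int = 0
    bands: BandScheme = field(default_factory=lambda: BANDS_STANDARD)
    channels: list[str] = field(default_factory=lambda: list(STANDARD_CHANNELS))
    region_map: RegionMap = field(default_factory=lambda: DEFAULT_REGION_MAP)

    def __post_init__(self) -> None:
        if self.duration_seconds <= 0 or self.fs <= 0:
            raise ValueError("duration and fs must be positive")


def _band_limited_noise(
    rng: np.random.Generator, n: int, fs: float, f_lo: float, f_hi: float
) -> np.ndarray:
    """Unit-RMS noise whose spectrum is confined to [f_lo, f_hi]."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= f_lo) & (freqs <= f_hi)
    spec[~mask] = 0.0
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _pink_background(
    rng: np.random.Generator, n: int, fs: float, exponent: float,
    f_lo: float = 0.5, f_hi: float = 48.0,
) -> np.ndarray:
    """Unit-RMS 1/f^exponent noise band-limited to the analysis range."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    gain = np.zeros_like(freqs)
    band = (freqs >= f_lo) & (freqs <= f_hi)
    gain[band] = freqs[band] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * gain, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _blink_template(fs: float, width_s: float) -> np.ndarray:
    """Half-cosine (raised) pulse of the given width."""
    n = max(int(round(width_s * fs)), 2)
    t = np.linspace(0.0, np.pi, n)
    return np.sin(t)


def generate_recording(
    subject_id: str,
    group: str,
    spec: CohortSpec,
    seed: int | np.random.SeedSequence,
) -> Recording:
    """Generate one subject's recording; bit-deterministic given ``seed``."""
    if spec.duration_seconds < 1.0:
        raise ValueError("recording too short to epoch")
    rng = np.random.default_rng(seed)
    n = int(round(spec.duration_seconds * spec.fs))
    fs = spec.fs
    channels = list(spec.channels)
    n_ch = len(channels)
    eff = spec.effect

    if eff.region_scope is None:
        scoped = {c.lower() for c in channels}
    else:
        scoped = set()
        for region in eff.region_scope:
            scoped |= {c.lower() for c in spec.region_map[region]}

    data = np.zeros((n_ch, n))
    for ci, ch in enumerate(channels):
        x = eff.background_amplitude * _pink_background(
            rng, n, fs, eff.background_exponent
        )
        for band, (lo, hi) in spec.bands:
            amp = eff.base_band_amplitudes.get(band, 0.0)
            if amp <= 0:
                continue
            if group == "MDD" and ch.lower() in scoped:
                amp *= eff.band_factors.get(band, 1.0)
            x += amp * _band_limited_noise(rng, n, fs, lo, hi)
        data[ci] = x

    blink_times: list[float] = []
    if eff.blink_rate > 0:
        n_blinks = rng.poisson(eff.blink_rate * spec.duration_seconds / 60.0)
        starts = np.sort(rng.uniform(0, spec.duration_seconds, size=n_blinks))
        topo = np.array(
            [_BLINK_TOPO.get(c.lower(), 0.05) for c in channels]
        )
        for t0 in starts:
            width = rng.uniform(0.3, 2.0)
            amp = rng.uniform(80.0, 150.0)
            pulse = amp * _blink_template(fs, width)
            i0 = int(round(t0 * fs))
            i1 = min(i0 + pulse.size, n)
            if i1 <= i0:
                continue
            data[:, i0:i1] += topo[:, None] * pulse[: i1 - i0][None, :]
            blink_times.append(float(t0))

    if eff.line_noise_amplitude > 0:
        t = np.arange(n) / fs
        phase = rng.uniform(0, 2 * np.pi)
        data += eff.line_noise_amplitude * np.sin(2 * np.pi * 50.0 * t + phase)

    return Recording(
        subject_id=subject_id,
        group=group,
        fs=fs,
        channel_names=channels,
        data=data,
        annotations={
            "blink_times": blink_times,
            "seed": str(seed),
            "generator": "eegmdd.synthetic",
        },
    )


def generate_cohort(spec: CohortSpec) -> list[Recording]:
    """Generate the full two-group cohort.

    Per-subject seeds are spawned deterministically from ``spec.seed``, so
    cohorts are reproducible and subjects mutually independent.
    """
    if spec.n_mdd + spec.n_hc < 2:
        raise ValueError("cohort needs at least two subjects")
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(spec.n_mdd + spec.n_hc)
    out: list[Recording] = []
    k = 0
    for i in range(spec.n_mdd):
        out.append(generate_recording(f"mdd{i + 1:03d}", "MDD", spec, children[k]))
        k += 1
    for i in range(spec.n_hc):
        out.append(generate_recording(f"hc{i + 1:03d}", "HC", spec, children[k]))
        k += 1
    return out


# ---------------------------------------------------------------------------
# EDF fixture writer
# ---------------------------------------------------------------------------

def write_edf_fixture(
    rec: Recording,
    path: str | Path,
    physical_range: tuple[float, float] = (-500.0, 500.0),
    physical_dimension: str = "uV",
) -> Path:
    """Write a recording as a plain EDF file (16-bit samples).

    A minimal, self-contained EDF+-free writer: fixed-format ASCII header
    plus little-endian int16 data records of one second each.  Quantization
    error is bounded by (range span)/2^16 — under 0.1 µV for a ±500 µV
    range.  ``physical_dimension`` lets tests exercise unit conversion on
    read (e.g. write millivolt-scaled data with ``"mV"``).
    """
    if not np.all(np.isfinite(rec.data)):
        raise ValueError("recording contains non-finite samples")
    pmin, pmax = physical_range
    if rec.data.min() < pmin or rec.data.max() > pmax:
        raise ValueError(
            f"signal range [{rec.data.min():.1f}, {rec.data.max():.1f}] exceeds "
            f"declared physical range [{pmin}, {pmax}]"
        )
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per record (1 s records)
    n_records = rec.n_samples // spr
    if n_records == 0:
        raise ValueError("recording shorter than one EDF data record")
    n_ch = rec.n_channels
    dmin, dmax = -32768, 32767

    def pad(s: str, width: int) -> bytes:
        b = s.encode("ascii", errors="replace")[:width]
        return b + b" " * (width - len(b))

    header = b"".join(
        [
            pad("0", 8),  # version
            pad(f"subject {rec.subject_id}", 80),
            pad("eegmdd synthetic fixture", 80),
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(256 + 256 * n_ch), 8),
            pad("", 44),
            pad(str(n_records), 8),
            pad("1", 8),  # record duration, seconds
            pad(str(n_ch), 4),
        ]
    )
    fields = [
        (16, [ch for ch in rec.channel_names]),  # label
        (80, ["" for _ in range(n_ch)]),  # transducer
        (8, [physical_dimension for _ in range(n_ch)]),
        (8, [f"{pmin:g}" for _ in range(n_ch)]),
        (8, [f"{pmax:g}" for _ in range(n_ch)]),
        (8, [str(dmin) for _ in range(n_ch)]),
        (8, [str(dmax) for _ in range(n_ch)]),
        (80, ["" for _ in range(n_ch)]),  # prefiltering
        (8, [str(spr) for _ in range(n_ch)]),
        (32, ["" for _ in range(n_ch)]),  # reserved
    ]
    for width, vals in fields:
        header += b"".join(pad(v, width) for v in vals)

    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.round((rec.data - pmin) * scale + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    out = Path(path)
    out.parent.mkdir(parents=True, exist_ok=True)
    with open(out, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            seg = digital[:, r * spr : (r + 1) * spr]
            fh.write(seg.tobytes())  # channel-sequential within record
    return out
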