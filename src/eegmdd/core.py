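"""Domain types shared by every pipeline stage, plus artifact readers/writers.

Amplitudes are microvolts (µV) everywhere inside the package; EDF physical
units are converted on read.  The canonical montage is the 19-channel
international 10–20 layout sampled at 256 Hz, grouped into the five scalp
regions used throughout (frontal, left/right temporal, parietal–occipital,
central).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "RegionMap",
    "BandScheme",
    "EpochSet",
    "FeatureTable",
    "ConfusionCounts",
    "DEFAULT_REGION_MAP",
    "BANDS_STANDARD",
    "BANDS_NARROW",
    "STANDARD_CHANNELS",
    "DEFAULT_DROP_CHANNELS",
    "read_recording",
    "write_recording_bundle",
    "standardize_channels",
    "region_channels",
]

#: The 19 scalp electrodes of the 10–20 system used by the montage.
STANDARD_CHANNELS = [
    "Fp1", "Fp2", "F3", "F4", "F7", "F8", "T3", "T4", "T5", "T6",
    "C3", "C4", "P3", "P4", "O1", "O2", "Fz", "Cz", "Pz",
]

#: Non-EEG / reference bookkeeping channels dropped by default.
DEFAULT_DROP_CHANNELS = ["EEG A2-A1", "EEG 23A-23R", "EEG 24A-24R"]

GROUPS = ("MDD", "HC", "unknown")


def _canonical_channel(name: str) -> str:
    """Reduce a dataset-dialect channel label to its bare 10–20 name.

    ``'EEG Fp1-LE' -> 'Fp1'``; matching is case-insensitive and strips the
    ``EEG `` prefix and reference suffixes (``-LE``, ``-A1`` ...).
    """
    s = name.strip()
    s = re.sub(r"^EEG[ _]+", "", s, flags=re.IGNORECASE)
    s = re.sub(r"-(LE|RE|A1|A2|REF|AVG|IR)$", "", s, flags=re.IGNORECASE)
    s = s.strip()
    for std in STANDARD_CHANNELS:
        if s.lower() == std.lower():
            return std
    return s


@dataclass
class Recording:
    """A continuous multichannel EEG recording in microvolts.

    ``data`` is channels × samples; row ``i`` belongs to
    ``channel_names[i]``.
    """

    subject_id: str
    group: str
    fs: float
    channel_names: list[str]
    data: np.ndarray
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels × samples array")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but "
                f"{len(self.channel_names)} channel names"
            )
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def channel_index(self, name: str) -> int:
        """Index of a channel, matching case-insensitively on bare labels."""
        want = _canonical_channel(name).lower()
        for i, ch in enumerate(self.channel_names):
            if _canonical_channel(ch).lower() == want:
                return i
        raise KeyError(f"channel {name!r} not present in {self.channel_names}")

    def copy_with(self, **kwargs) -> "Recording":
        base = dict(
            subject_id=self.subject_id,
            group=self.group,
            fs=self.fs,
            channel_names=list(self.channel_names),
            data=self.data.copy(),
            annotations=dict(self.annotations),
        )
        base.update(kwargs)
        return Recording(**base)


class RegionMap:
    """Ordered mapping from scalp-region name to its channel list.

    Region channel sets must be pairwise disjoint.  The default map groups
    the 19 standard channels into five regions (frontal, left temporal,
    parietal–occipital, right temporal, central).
    """

    def __init__(self, regions: Mapping[str, Sequence[str]]):
        self._regions: dict[str, list[str]] = {
            str(k): [str(c) for c in v] for k, v in regions.items()
        }
        seen: set[str] = set()
        for name, chans in self._regions.items():
            low = {c.lower() for c in chans}
            if low & seen:
                dup = sorted(low & seen)
                raise ValueError(f"region {name!r} repeats channels {dup}")
            seen |= low

    @property
    def region_names(self) -> list[str]:
        return list(self._regions)

    @property
    def all_channels(self) -> list[str]:
        out: list[str] = []
        for chans in self._regions.values():
            out.extend(chans)
        return out

    def __iter__(self):
        return iter(self._regions.items())

    def __len__(self) -> int:
        return len(self._regions)

    def __getitem__(self, region: str) -> list[str]:
        return region_channels(self, region)

    def as_dict(self) -> dict[str, list[str]]:
        return {k: list(v) for k, v in self._regions.items()}


def region_channels(region_map: RegionMap, region: str) -> list[str]:
    """The ordered channel list of ``region``.

    Raises ``KeyError`` naming the valid regions if ``region`` is unknown.
    """
    regions = region_map.as_dict()
    if region not in regions:
        raise KeyError(
            f"unknown region {region!r}; valid regions: {sorted(regions)}"
        )
    return list(regions[region])


#: Five-region scalp grouping of the 19-channel 10–20 montage.
DEFAULT_REGION_MAP = RegionMap(
    {
        "Frontal": ["Fp1", "Fp2", "F3", "F4"],
        "Left Temporal": ["F7", "T3", "T5"],
        "Parietal-Occipital": ["P3", "P4", "O1", "O2"],
        "Right Temporal": ["F8", "T4", "T6"],
        "Central": ["C3", "C4", "Fz", "Cz", "Pz"],
    }
)


class BandScheme:
    """Ordered, non-overlapping frequency bands (Hz)."""

    def __init__(self, bands: Mapping[str, tuple[float, float]]):
        items = list(bands.items())
        prev_hi = -np.inf
        for name, (lo, hi) in items:
            if not (0 <= lo < hi):
                raise ValueError(f"band {name!r} has invalid edges ({lo}, {hi})")
            if lo < prev_hi:
                raise ValueError(f"band {name!r} overlaps the previous band")
            prev_hi = hi
        self._bands = {str(k): (float(lo), float(hi)) for k, (lo, hi) in items}

    @property
    def band_names(self) -> list[str]:
        return list(self._bands)

    def __iter__(self):
        return iter(self._bands.items())

    def __len__(self) -> int:
        return len(self._bands)

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self._bands[name]

    def as_dict(self) -> dict[str, tuple[float, float]]:
        return dict(self._bands)

    @property
    def f_lo(self) -> float:
        return min(lo for lo, _ in self._bands.values())

    @property
    def f_hi(self) -> float:
        return max(hi for _, hi in self._bands.values())


#: Canonical six-band split of the 0.5–48 Hz range.
BANDS_STANDARD = BandScheme(
    {
        "delta": (0.5, 4.0),
        "theta": (4.0, 8.0),
        "alpha": (8.0, 13.0),
        "beta1": (13.0, 21.0),
        "beta2": (21.0, 30.0),
        "gamma": (30.0, 48.0),
    }
)

#: Narrow-edge preset (gaps between bands); shipped for comparison runs.
BANDS_NARROW = BandScheme(
    {
        "delta": (1.0, 3.0),
        "theta": (4.0, 7.0),
        "alpha": (8.0, 11.0),
        "beta1": (12.0, 20.0),
        "beta2": (21.0, 29.0),
        "gamma": (30.0, 48.0),
    }
)

BAND_PRESETS = {"standard": BANDS_STANDARD, "narrow": BANDS_NARROW}


@dataclass
class EpochSet:
    """Fixed-length epochs cut from one subject's recording.

    ``epochs`` is epochs × channels × samples (µV).  ``retained`` marks the
    epochs that survived amplitude quality control; ``starts`` records each
    epoch's onset (seconds) in the source recording.
    """

    epochs: np.ndarray
    fs: float
    window_seconds: float
    overlap_seconds: float
    retained: np.ndarray
    subject_id: str
    group: str
    channel_names: list[str]
    starts: np.ndarray

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=np.float64)
        self.retained = np.asarray(self.retained, dtype=bool)
        self.starts = np.asarray(self.starts, dtype=np.float64)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be a 3-D tensor")
        n = self.epochs.shape[0]
        if self.retained.shape != (n,) or self.starts.shape != (n,):
            raise ValueError("retained/starts must have one entry per epoch")
        expect = int(round(self.window_seconds * self.fs))
        if self.epochs.shape[2] != expect:
            raise ValueError(
                f"epochs carry {self.epochs.shape[2]} samples, expected {expect}"
            )

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())


class FeatureTable:
    """Epoch-by-feature matrix with region-qualified column names.

    Columns are ``"<region>__<feature>"``; each row is one retained epoch,
    carrying its subject id and group label.  Backed by a pandas DataFrame.
    """

    LABEL_COL = "label"
    SUBJECT_COL = "subject_id"

    def __init__(
        self,
        values: pd.DataFrame,
        labels: Sequence[str],
        subject_ids: Sequence[str],
    ):
        values = values.reset_index(drop=True)
        if values.isna().any().any():
            bad = values.columns[values.isna().any()].tolist()
            raise ValueError(f"feature table contains NaN in columns {bad}")
        if len(labels) != len(values) or len(subject_ids) != len(values):
            raise ValueError("labels/subject_ids must match row count")
        self.values = values
        self.labels = pd.Series(list(labels), name=self.LABEL_COL)
        self.subject_ids = pd.Series(list(subject_ids), name=self.SUBJECT_COL)

    @property
    def column_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_rows(self) -> int:
        return len(self.values)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def X(self) -> np.ndarray:
        return self.values.to_numpy(dtype=np.float64)

    def y(self, positive: str = "MDD") -> np.ndarray:
        """Binary labels: 1 for the positive (patient) class."""
        return (self.labels.to_numpy() == positive).astype(int)

    def groups(self) -> np.ndarray:
        return self.subject_ids.to_numpy()

    def subset_columns(self, columns: Sequence[str]) -> "FeatureTable":
        missing = [c for c in columns if c not in self.values.columns]
        if missing:
            raise KeyError(f"columns not in table: {missing}")
        return FeatureTable(self.values[list(columns)], self.labels, self.subject_ids)

    def region_columns(self, region: str) -> list[str]:
        prefix = f"{region}__"
        return [c for c in self.values.columns if c.startswith(prefix)]

    def to_frame(self) -> pd.DataFrame:
        out = self.values.copy()
        out[self.LABEL_COL] = self.labels.to_numpy()
        out[self.SUBJECT_COL] = self.subject_ids.to_numpy()
        return out

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FeatureTable":
        if cls.LABEL_COL not in frame or cls.SUBJECT_COL not in frame:
            raise ValueError(
                f"frame must carry {cls.LABEL_COL!r} and {cls.SUBJECT_COL!r} columns"
            )
        meta = [cls.LABEL_COL, cls.SUBJECT_COL]
        return cls(
            frame.drop(columns=meta),
            frame[cls.LABEL_COL].tolist(),
            frame[cls.SUBJECT_COL].astype(str).tolist(),
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        return cls.from_frame(pd.read_csv(path))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"FeatureTable({self.n_rows} rows × {self.n_features} features, "
            f"groups={sorted(set(self.labels))})"
        )


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion-matrix counts; MDD is the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def write_recording_bundle(rec: Recording, path: str | Path) -> Path:
    """Write a recording as a raw float64 array + JSON sidecar.

    ``path`` is the stem; ``<stem>.npy`` holds the channels × samples array
    and ``<stem>.json`` the sampling rate, channel names and labels.  The
    round trip is bit-exact.
    """
    stem = Path(path)
    stem.parent.mkdir(parents=True, exist_ok=True)
    np.save(stem.with_suffix(".npy"), rec.data.astype(np.float64))
    sidecar = {
        "subject_id": rec.subject_id,
        "group": rec.group,
        "fs": rec.fs,
        "channel_names": rec.channel_names,
        "unit": "uV",
        "annotations": _jsonable(rec.annotations),
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return stem


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _read_bundle(path: Path) -> Recording:
    stem = path
    if stem.suffix in {".npy", ".json"}:
        stem = stem.with_suffix("")
    npy, sidecar = stem.with_suffix(".npy"), stem.with_suffix(".json")
    if not npy.exists() or not sidecar.exists():
        raise IOError(f"array bundle incomplete: need {npy} and {sidecar}")
    meta = json.loads(sidecar.read_text())
    data = np.load(npy)
    if data.ndim != 2 or data.shape[0] != len(meta["channel_names"]):
        raise ValueError(
            f"bundle {stem}: array shape {data.shape} inconsistent with "
            f"{len(meta['channel_names'])} channel names"
        )
    return Recording(
        subject_id=meta["subject_id"],
        group=meta.get("group", "unknown"),
        fs=float(meta["fs"]),
        channel_names=list(meta["channel_names"]),
        data=data,
        annotations=meta.get("annotations", {}),
    )


def _read_edf(path: Path) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6  # mne returns volts
    sid = Path(path).stem
    return Recording(
        subject_id=sid,
        group="unknown",
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        data=data_uv,
    )


def read_recording(path: str | Path, format: str = "auto") -> Recording:
    """Read a recording from EDF or an array bundle.

    EDF physical values are converted to microvolts.  ``format='auto'``
    dispatches on the file suffix (.edf vs .npy/.json/stem).
    """
    p = Path(path)
    if format == "auto":
        format = "edf" if p.suffix.lower() == ".edf" else "bundle"
    if format == "edf":
        if not p.exists():
            raise IOError(f"no such file: {p}")
        return _read_edf(p)
    if format == "bundle":
        return _read_bundle(p)
    raise ValueError(f"unknown format {format!r}; use 'edf' or 'bundle'")


def standardize_channels(
    rec: Recording,
    drop_list: Sequence[str] | None = None,
    rename_map: Mapping[str, str] | None = None,
) -> Recording:
    """Drop non-EEG channels and map labels to bare 10–20 names.

    Channels in ``drop_list`` (default: linked-ear/bookkeeping channels)
    are removed; survivors are renamed via ``rename_map`` first, then
    canonicalized (``'EEG Fp1-LE' -> 'Fp1'``).  Channel order is preserved.
    """
    drop = {c.strip().lower() for c in (drop_list if drop_list is not None
                                        else DEFAULT_DROP_CHANNELS)}
    rename = dict(rename_map or {})
    keep_idx, names = [], []
    for i, ch in enumerate(rec.channel_names):
        if ch.strip().lower() in drop:
            continue
        keep_idx.append(i)
        names.append(_canonical_channel(rename.get(ch, ch)))
    if not keep_idx:
        raise ValueError("standardize_channels removed every channel")
    return rec.copy_with(channel_names=names, data=rec.data[keep_idx].copy())
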