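"""Multichannel recording container, HDF5/text I/O, sensor layouts, filtering.

A :class:`Recording` holds one subject's continuous multichannel time series
(channels x samples) at a fixed sampling rate, together with the subject id,
channel names and an optional class label (``"TD"`` / ``"ASD"``).  A
:class:`SensorLayout` assigns every channel to the left hemisphere, the
midline, or the right hemisphere; the bundled default montage reproduces the
70 left + 11 midline + 70 right split of a 151-sensor whole-head child MEG
system (the true sensor geometry is not public, so the assignment here is
synthetic and only the left/midline/right partition is meaningful).

Filtering is always zero-phase (forward-backward), because downstream phase
features must not be corrupted by filter group delay.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "Recording",
    "SensorLayout",
    "default_montage",
    "make_layout",
    "load_recording",
    "save_recording",
    "load_layout",
    "save_layout",
    "bandpass_filter",
    "notch_filter",
    "select_channels",
]

CLASS_LABELS = ("TD", "ASD")
HEMISPHERES = ("left", "midline", "right")


@dataclass
class Recording:
    """One subject's channels-x-samples signal with metadata.

    Parameters
    ----------
    subject_id : str
        Unique subject identifier.
    data : ndarray, shape (n_channels, n_samples)
        Signal matrix in arbitrary (tesla-like) units; must be finite.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
        Unique channel names, one per data row.
    label : str or None
        Class label, ``"TD"`` or ``"ASD"``, or None if unknown.
    """

    subject_id: str
    data: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)
    label: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (channels x samples) matrix")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not self.channel_names:
            self.channel_names = [f"ch{i:03d}" for i in range(self.data.shape[0])]
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if not np.isfinite(self.data).all():
            raise ValueError("data contains non-finite samples")
        if self.label is not None and self.label not in CLASS_LABELS:
            raise ValueError(f"label must be one of {CLASS_LABELS} or None")

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

    def with_data(self, data: np.ndarray) -> "Recording":
        """Copy of this recording with a replacement data matrix."""
        return replace(self, data=data)


@dataclass(frozen=True)
class SensorLayout:
    """Exhaustive, disjoint assignment of channels to left/midline/right."""

    channel_names: tuple[str, ...]
    hemisphere: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.channel_names) != len(self.hemisphere):
            raise ValueError("channel_names and hemisphere must have equal length")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("layout channel names must be unique")
        bad = set(self.hemisphere) - set(HEMISPHERES)
        if bad:
            raise ValueError(f"unknown hemisphere tags: {sorted(bad)}")

    def channels(self, side: str) -> list[str]:
        """Channel names tagged with ``side`` (left/midline/right), in order."""
        if side not in HEMISPHERES:
            raise ValueError(f"side must be one of {HEMISPHERES}, got {side!r}")
        return [c for c, h in zip(self.channel_names, self.hemisphere) if h == side]

    def __len__(self) -> int:
        return len(self.channel_names)


def make_layout(n_left: int, n_midline: int, n_right: int, prefix: str = "AG") -> SensorLayout:
    """Build a synthetic layout with the given left/midline/right counts.

    Channels are named ``{prefix}001`` ... in order: left block, midline
    block, right block.  Only the partition is meaningful; no spatial
    coordinates are implied.
    """
    n = n_left + n_midline + n_right
    names = tuple(f"{prefix}{i + 1:03d}" for i in range(n))
    hemi = ("left",) * n_left + ("midline",) * n_midline + ("right",) * n_right
    return SensorLayout(names, hemi)


def default_montage() -> SensorLayout:
    """The 151-channel default montage: 70 left, 11 midline, 70 right."""
    return make_layout(70, 11, 70)


def load_layout(path: str | Path) -> SensorLayout:
    """Read a layout from CSV with columns ``channel,hemisphere``."""
    df = pd.read_csv(path)
    return SensorLayout(tuple(df["channel"].astype(str)), tuple(df["hemisphere"].astype(str)))


def save_layout(layout: SensorLayout, path: str | Path) -> None:
    pd.DataFrame(
        {"channel": layout.channel_names, "hemisphere": layout.hemisphere}
    ).to_csv(path, index=False)


def save_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording to an HDF5 container.

    Layout: dataset ``data`` (channels x samples), attributes ``fs``,
    ``subject_id``, ``label`` (empty string if unknown) and
    ``channel_names``.
    """
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data)
        f.attrs["fs"] = float(rec.fs)
        f.attrs["subject_id"] = rec.subject_id
        f.attrs["label"] = rec.label or ""
        f.attrs["channel_names"] = [str(c) for c in rec.channel_names]


def load_recording(path: str | Path, layout: SensorLayout | None = None) -> Recording:
    """Load a recording from HDF5 (or delimited text) and validate it.

    Text files (``.csv``/``.tsv``) hold channels as columns with names in the
    header; the sampling rate must then be supplied by a ``# fs=<Hz>`` first
    line.  If ``layout`` is given, the file's channel set must match it
    exactly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".csv", ".tsv"}:
        rec = _load_text_recording(path)
    else:
        with h5py.File(path, "r") as f:
            data = np.asarray(f["data"])
            fs = float(f.attrs["fs"])
            subject_id = str(f.attrs.get("subject_id", path.stem))
            label = str(f.attrs.get("label", "")) or None
            names = [str(c) for c in f.attrs.get("channel_names", [])]
        rec = Recording(subject_id, data, fs, names, label)
    if layout is not None and list(rec.channel_names) != list(layout.channel_names):
        raise ValueError("recording channels do not match the supplied layout")
    return rec


def _load_text_recording(path: Path) -> Recording:
    with open(path) as fh:
        first = fh.readline().strip()
    if not first.startswith("# fs="):
        raise ValueError("text recording must begin with a '# fs=<Hz>' line")
    fs = float(first.split("=", 1)[1])
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    df = pd.read_csv(path, skiprows=1, sep=sep)
    return Recording(path.stem, df.to_numpy().T, fs, list(df.columns))


def _validate_band(lo: float, hi: float, fs: float) -> None:
    if not (0 < lo < hi < fs / 2):
        raise ValueError(f"require 0 < lo < hi < fs/2; got lo={lo}, hi={hi}, fs={fs}")


def bandpass_filter(rec: Recording, lo: float, hi: float, order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass between ``lo`` and ``hi`` Hz.

    Forward-backward application (``sosfiltfilt``) guarantees no group-delay
    shift, so spectral phase estimates downstream are unaffected by the
    filter.
    """
    _validate_band(lo, hi, rec.fs)
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    return rec.with_data(signal.sosfiltfilt(sos, rec.data, axis=-1))


def notch_filter(rec: Recording, f0: float = 50.0, quality: float = 30.0) -> Recording:
    """Zero-phase IIR notch at ``f0`` Hz (power-line removal)."""
    if not (0 < f0 < rec.fs / 2):
        raise ValueError(f"require 0 < f0 < fs/2; got f0={f0}, fs={rec.fs}")
    b, a = signal.iirnotch(f0, quality, fs=rec.fs)
    return rec.with_data(signal.filtfilt(b, a, rec.data, axis=-1))


def select_channels(rec: Recording, layout: SensorLayout, subset: str = "all") -> Recording:
    """Restrict a recording to one hemisphere (midline always dropped).

    ``subset`` is ``"all"`` (unchanged), ``"left"`` or ``"right"``.  Retained
    channels keep their original order.
    """
    if subset == "all":
        return rec
    if subset not in ("left", "right"):
        raise ValueError(f"subset must be 'all', 'left' or 'right', got {subset!r}")
    if list(rec.channel_names) != list(layout.channel_names):
        raise ValueError("recording channels do not match the layout")
    keep = layout.channels(subset)
    idx = [rec.channel_names.index(c) for c in keep]
    return replace(rec, data=rec.data[idx], channel_names=keep)
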