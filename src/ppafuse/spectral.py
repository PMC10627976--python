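"""Spectral features: Welch band power (dB) and preferred phase angle.

Two subject-level feature families are computed per channel and canonical
frequency band on the integer 1-100 Hz grid:

* ``PSD_fb`` — decibels of the arithmetic mean of the Welch power spectral
  density over the band's integer-frequency bins,
  ``10 log10( mean_{f in fb} S_xx(f) )``.

* ``PPA_fb`` — the preferred phase angle: the argument of the mean of the
  unit phasors ``exp(i theta(f))`` over the band's bins, where ``theta(f)``
  is the phase of the full-length DFT at integer frequency ``f``.  The
  modulus of the same mean vector is the *phase consistency* in [0, 1]
  (1 = all bins in phase, 0 = uniformly dispersed).

Band edges are inclusive on both sides (alpha = {8,...,13}, six bins), so
boundary bins belong to both adjacent bands.  Phases come from one DFT of
the whole recording; recordings whose duration is not an integer number of
seconds are rejected rather than interpolated, so that every integer
frequency is an exact DFT bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .signal_io import Recording, SensorLayout, select_channels

__all__ = [
    "BandScheme",
    "SpectrumSet",
    "FeatureMatrix",
    "DEFAULT_BANDS",
    "FREQ_GRID",
    "welch_segment_length",
    "welch_spectrum",
    "band_psd_features",
    "fft_phases",
    "preferred_phase_angle",
    "extract_feature_matrix",
]

#: Integer frequency grid (Hz) on which all spectra are evaluated.
FREQ_GRID = np.arange(1, 101)

DEGENERATE_CONSISTENCY = 1e-12


@dataclass(frozen=True)
class BandScheme:
    """Ordered named frequency bands with inclusive integer edges."""

    bands: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        for name, lo, hi in self.bands:
            if lo != int(lo) or hi != int(hi):
                raise ValueError(f"band {name}: edges must be integers")
            if not lo < hi:
                raise ValueError(f"band {name}: require fb_min < fb_max")

    @property
    def names(self) -> list[str]:
        return [b[0] for b in self.bands]

    def bins(self, name: str) -> np.ndarray:
        """Inclusive integer bins of the named band."""
        for n, lo, hi in self.bands:
            if n == name:
                return np.arange(lo, hi + 1)
        raise KeyError(name)

    def n_bins(self, name: str) -> int:
        return len(self.bins(name))

    def __len__(self) -> int:
        return len(self.bands)


#: The six canonical bands: delta through high gamma, inclusive edges.
DEFAULT_BANDS = BandScheme(
    (
        ("delta", 1, 4),
        ("theta", 4, 8),
        ("alpha", 8, 13),
        ("beta", 13, 30),
        ("low_gamma", 30, 50),
        ("high_gamma", 50, 100),
    )
)


@dataclass
class SpectrumSet:
    """Per-channel power and/or phase on the integer 1-100 Hz grid."""

    power: np.ndarray | None = None  # (n_channels, 100), S_xx(f) >= 0
    phase: np.ndarray | None = None  # (n_channels, 100), radians in (-pi, pi]

    def __post_init__(self) -> None:
        for name, arr in (("power", self.power), ("phase", self.phase)):
            if arr is None:
                continue
            arr = np.asarray(arr, dtype=np.float64)
            if arr.ndim != 2 or arr.shape[1] != len(FREQ_GRID):
                raise ValueError(f"{name} must be (n_channels, {len(FREQ_GRID)})")
            if not np.isfinite(arr).all():
                raise ValueError(f"{name} contains non-finite values")
            setattr(self, name, arr)
        if self.power is not None and (self.power < 0).any():
            raise ValueError("power must be non-negative")


@dataclass
class FeatureMatrix:
    """Subjects-x-features matrix with per-feature descriptors and labels.

    ``descriptors`` has one row per column of ``values`` with fields
    ``channel``, ``band`` and ``kind`` (``PSD`` or ``PPA``); ``kind_tag``
    labels the matrix as a whole (``PSD``, ``PPA`` or ``fused``).
    """

    values: np.ndarray
    descriptors: pd.DataFrame
    labels: np.ndarray
    subject_ids: list[str] = field(default_factory=list)
    kind_tag: str = "PSD"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if len(self.descriptors) != self.values.shape[1]:
            raise ValueError("one descriptor row per feature column required")
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("one label per subject row required")
        if not self.subject_ids:
            self.subject_ids = [f"s{i:03d}" for i in range(self.values.shape[0])]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: subject, label, then ``channel.band.kind`` columns."""
        cols = [
            f"{c}.{b}.{k}"
            for c, b, k in zip(
                self.descriptors["channel"],
                self.descriptors["band"],
                self.descriptors["kind"],
            )
        ]
        df = pd.DataFrame(self.values, columns=cols)
        df.insert(0, "label", self.labels)
        df.insert(0, "subject", self.subject_ids)
        return df


def welch_segment_length(duration_s: float, n_segments: int = 8, overlap: float = 0.5) -> float:
    """Segment length (s) for equal segments with the given overlap.

    With ``r = overlap``, ``n`` segments of length ``L`` tile a record of
    length ``T`` when ``L (1 + (n-1)(1-r)) = T``; at 50% overlap this is
    ``L = 2 T / (n + 1)`` (180 s in 8 half-overlapping segments -> 40 s).
    """
    if not 0 <= overlap < 1:
        raise ValueError("overlap must lie in [0, 1)")
    return duration_s / (1 + (n_segments - 1) * (1 - overlap))


def welch_spectrum(
    rec: Recording,
    n_segments: int = 8,
    overlap: float = 0.5,
    window: str = "hamming",
) -> SpectrumSet:
    """Welch power spectral density sampled at integer 1-100 Hz.

    The recording is divided into ``n_segments`` equal segments with the
    given fractional overlap, each windowed and periodogram-averaged
    (one-sided density normalisation).  Power at integer frequency ``f`` is
    taken from the DFT bin nearest to ``f``; when the segment length is an
    integer number of seconds the integer frequencies are exact bins.
    """
    seg_s = welch_segment_length(rec.duration, n_segments, overlap)
    if seg_s < 1.0:
        raise ValueError(
            f"recording too short: segment length {seg_s:.3f} s < 1 s"
        )
    nperseg = int(round(seg_s * rec.fs))
    noverlap = int(round(nperseg * overlap))
    freqs, pxx = signal.welch(
        rec.data,
        fs=rec.fs,
        window=window,
        nperseg=nperseg,
        noverlap=noverlap,
        detrend=False,
        scaling="density",
        axis=-1,
    )
    if freqs[-1] < FREQ_GRID[-1]:
        raise ValueError("sampling rate too low to cover the 1-100 Hz grid")
    idx = np.argmin(np.abs(freqs[None, :] - FREQ_GRID[:, None]), axis=1)
    return SpectrumSet(power=pxx[:, idx])


def fft_phases(rec: Recording) -> SpectrumSet:
    """Phase angles of the full-length DFT at integer 1-100 Hz.

    ``theta(f)`` is the argument of the DFT coefficient at bin ``f * T``
    (``T`` the duration in seconds), mapped to (-pi, pi]; a cosine at
    frequency ``f`` has ``theta(f) = 0``, a sine ``-pi/2``.
    """
    T = rec.duration
    if abs(T - round(T)) > 1e-9:
        raise ValueError(
            f"duration must be an integer number of seconds (got {T:.6f} s) "
            "so that integer frequencies are exact DFT bins"
        )
    T = int(round(T))
    if rec.fs / 2 <= FREQ_GRID[-1]:
        raise ValueError("sampling rate too low to cover the 1-100 Hz grid")
    spec = np.fft.rfft(rec.data, axis=-1)
    bins = FREQ_GRID * T
    theta = np.angle(spec[:, bins])
    # np.angle returns [-pi, pi]; fold -pi onto +pi for the (-pi, pi] contract
    theta[theta <= -np.pi] = np.pi
    return SpectrumSet(phase=theta)


def band_psd_features(spec: SpectrumSet, scheme: BandScheme = DEFAULT_BANDS) -> np.ndarray:
    """Band-averaged power in dB, shape (n_channels, n_bands).

    For each band, dB of the arithmetic mean of ``S_xx`` over the inclusive
    integer bins.  Any fixed positive spectral scaling only shifts these
    values by a constant dB offset, which per-feature z-scoring later
    removes.
    """
    if spec.power is None:
        raise ValueError("SpectrumSet has no power")
    out = np.empty((spec.power.shape[0], len(scheme)))
    for j, name in enumerate(scheme.names):
        bins = scheme.bins(name)
        if bins[0] < FREQ_GRID[0] or bins[-1] > FREQ_GRID[-1]:
            raise ValueError(f"band {name} lies outside the 1-100 Hz grid")
        out[:, j] = 10 * np.log10(spec.power[:, bins - 1].mean(axis=1))
    return out


def preferred_phase_angle(
    phases: np.ndarray, band: tuple[int, int] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Preferred phase angle and phase consistency of a set of phases.

    Parameters
    ----------
    phases : ndarray
        Phase angles in radians.  Either a 1-D array of band-bin phases, or
        a (n_channels, 100) full-grid phase matrix together with ``band``.
    band : (fb_min, fb_max), optional
        Inclusive integer band edges selecting columns of a full-grid
        matrix.

    Returns
    -------
    ppa : ndarray or float
        Argument of the mean unit phasor over the band bins, in (-pi, pi].
        A degenerate resultant (consistency below 1e-12, e.g. phases
        uniformly spread around the circle) yields 0 rather than an error:
        downstream z-scoring tolerates the arbitrary value.
    consistency : ndarray or float
        Modulus of the same mean vector, in [0, 1].
    """
    phases = np.asarray(phases, dtype=np.float64)
    if band is not None:
        lo, hi = band
        phases = phases[..., lo - 1 : hi]
    resultant = np.exp(1j * phases).mean(axis=-1)
    consistency = np.abs(resultant)
    ppa = np.where(consistency < DEGENERATE_CONSISTENCY, 0.0, np.angle(resultant))
    if ppa.ndim == 0:
        return float(ppa), float(consistency)
    return ppa, consistency


def _band_ppa_features(spec: SpectrumSet, scheme: BandScheme) -> np.ndarray:
    if spec.phase is None:
        raise ValueError("SpectrumSet has no phase")
    out = np.empty((spec.phase.shape[0], len(scheme)))
    for j, (name, lo, hi) in enumerate(scheme.bands):
        ppa, _ = preferred_phase_angle(spec.phase, band=(lo, hi))
        out[:, j] = ppa
    return out


def extract_feature_matrix(
    cohort: list[Recording],
    kind: str,
    scheme: BandScheme = DEFAULT_BANDS,
    layout: SensorLayout | None = None,
    subset: str = "all",
    n_segments: int = 8,
    overlap: float = 0.5,
) -> FeatureMatrix:
    """Assemble the subjects-x-features matrix for one feature kind.

    Columns are channel-major, band-minor: with the default six-band scheme
    a 151-channel whole-head recording yields 906 features per subject, a
    70-channel hemisphere 420.

    Parameters
    ----------
    cohort : list of Recording
        Recordings sharing sampling rate, duration and channel set.
    kind : {"PSD", "PPA"}
        Power (Welch, dB) or preferred-phase-angle features.
    layout, subset
        Optional hemisphere restriction before extraction.
    """
    if kind not in ("PSD", "PPA"):
        raise ValueError(f"kind must be 'PSD' or 'PPA', got {kind!r}")
    if not cohort:
        raise ValueError("empty cohort")
    ref = cohort[0]
    for rec in cohort[1:]:
        if (
            rec.fs != ref.fs
            or rec.n_samples != ref.n_samples
            or rec.channel_names != ref.channel_names
        ):
            raise ValueError("cohort recordings must share fs, duration and channels")
    rows = []
    for rec in cohort:
        if layout is not None and subset != "all":
            rec = select_channels(rec, layout, subset)
        if kind == "PSD":
            spec = welch_spectrum(rec, n_segments=n_segments, overlap=overlap)
            feats = band_psd_features(spec, scheme)
        else:
            spec = fft_phases(rec)
            feats = _band_ppa_features(spec, scheme)
        rows.append(feats.reshape(-1))  # channel-major, band-minor
    channels = cohort[0].channel_names
    if layout is not None and subset != "all":
        channels = layout.channels(subset)
    desc = pd.DataFrame(
        {
            "channel": np.repeat(channels, len(scheme)),
            "band": np.tile(scheme.names, len(channels)),
            "kind": kind,
        }
    )
    labels = np.array([rec.label or "unknown" for rec in cohort])
    return FeatureMatrix(
        values=np.vstack(rows),
        descriptors=desc,
        labels=labels,
        subject_ids=[rec.subject_id for rec in cohort],
        kind_tag=kind,
    )
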