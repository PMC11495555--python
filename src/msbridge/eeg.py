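"""EEG input, preprocessing, global field power, and GFP-peak extraction.

The microstate pipeline starts from a multichannel EEG recording. This
module provides the recording container, zero-phase bandpass filtering and
anti-aliased downsampling, the global field power (GFP) time series, strict
local-maximum peak detection, and reproducible random subsampling of peak
topographies for clustering.

Conventions
-----------
* Maps are average-referenced (channel mean removed per time point) before
  GFP and before clustering; GFP is the population (divide-by-N) standard
  deviation across channels.
* Annotation intervals are 0-based, half-open ``[onset, onset + duration)``
  in samples of the recording they belong to.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .exceptions import InsufficientDataError, InvalidParameterError

__all__ = [
    "Annotation",
    "EEGRecording",
    "GFPSeries",
    "preprocess",
    "global_field_power",
    "detect_gfp_peaks",
    "sample_peak_maps",
    "average_reference",
    "read_recording_csv",
    "write_recording_csv",
    "read_recording_edf",
]


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class Annotation:
    """A labeled half-open interval ``[onset, onset + duration)`` in samples."""

    onset: int
    duration: int
    label: str


@dataclass
class EEGRecording:
    """Channels x samples EEG matrix with sampling rate and annotations.

    Parameters
    ----------
    data
        Real matrix of shape ``(n_channels, n_samples)`` in microvolts.
    srate
        Sampling rate in Hz; must be positive.
    channel_names
        One name per channel.
    annotations
        Condition intervals; each must lie inside ``[0, n_samples)``.
    """

    data: np.ndarray
    srate: float
    channel_names: list[str] = field(default_factory=list)
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InvalidParameterError("data must be a 2-D channels x samples matrix")
        if self.srate <= 0:
            raise InvalidParameterError(f"srate must be positive, got {self.srate}")
        if not self.channel_names:
            self.channel_names = [f"ch{i:03d}" for i in range(self.data.shape[0])]
        if len(self.channel_names) != self.data.shape[0]:
            raise InvalidParameterError(
                "channel_names length does not match number of rows"
            )
        for ann in self.annotations:
            if ann.onset < 0 or ann.duration < 0 or ann.onset + ann.duration > self.n_samples:
                raise InvalidParameterError(
                    f"annotation {ann} outside [0, {self.n_samples})"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class GFPSeries:
    """Global field power per sample plus indices of detected peaks."""

    values: np.ndarray
    peak_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.peak_indices = np.asarray(self.peak_indices, dtype=int)

    @property
    def n_peaks(self) -> int:
        return int(self.peak_indices.size)


# ---------------------------------------------------------------------------
# preprocessing


def average_reference(maps: np.ndarray) -> np.ndarray:
    """Remove the channel mean from each map (rows of an n x channels array,
    or each column of a channels x samples matrix when ``axis`` semantics
    are handled by the caller)."""
    maps = np.asarray(maps, dtype=float)
    return maps - maps.mean(axis=-1, keepdims=True)


def preprocess(
    rec: EEGRecording,
    low_hz: float = 1.0,
    high_hz: float = 40.0,
    target_srate: float = 250.0,
) -> EEGRecording:
    """Zero-phase bandpass filter then downsample a recording.

    A 4th-order Butterworth bandpass is applied forward-backward
    (``sosfiltfilt``, zero phase); resampling uses an anti-aliased polyphase
    filter at the rational ratio ``target_srate / srate`` and the output is
    truncated to ``floor(n_samples * target_srate / srate)`` samples.
    Annotation sample indices are rescaled to the new rate (half-open
    intervals, floor rounding).

    Raises
    ------
    InvalidParameterError
        If the band does not satisfy ``0 < low < high < srate / 2`` or the
        target rate is not positive.
    """
    if not (0.0 < low_hz < high_hz < rec.srate / 2.0):
        raise InvalidParameterError(
            f"band ({low_hz}, {high_hz}) Hz must satisfy 0 < low < high < "
            f"Nyquist ({rec.srate / 2:g} Hz)"
        )
    if target_srate <= 0 or target_srate > rec.srate:
        raise InvalidParameterError(
            f"target_srate {target_srate} must be in (0, {rec.srate}]"
        )

    sos = signal.butter(
        4, [low_hz, high_hz], btype="bandpass", fs=rec.srate, output="sos"
    )
    filtered = signal.sosfiltfilt(sos, rec.data, axis=1)

    ratio = Fraction(target_srate / rec.srate).limit_denominator(10_000)
    if ratio != 1:
        filtered = signal.resample_poly(filtered, ratio.numerator, ratio.denominator, axis=1)
    n_out = int(np.floor(rec.n_samples * target_srate / rec.srate))
    filtered = filtered[:, :n_out]

    scale = target_srate / rec.srate
    new_annotations = []
    for ann in rec.annotations:
        onset = int(np.floor(ann.onset * scale))
        end = min(int(np.floor((ann.onset + ann.duration) * scale)), n_out)
        if end > onset:
            new_annotations.append(Annotation(onset, end - onset, ann.label))
    return EEGRecording(
        data=filtered,
        srate=target_srate,
        channel_names=list(rec.channel_names),
        annotations=new_annotations,
    )


# ---------------------------------------------------------------------------
# global field power


def global_field_power(rec: EEGRecording) -> GFPSeries:
    """Population standard deviation of the average-referenced map per sample.

    Raises
    ------
    InsufficientDataError
        For single-channel recordings (GFP is undefined).
    """
    if rec.n_channels < 2:
        raise InsufficientDataError("GFP requires at least 2 channels")
    centered = rec.data - rec.data.mean(axis=0, keepdims=True)
    values = np.sqrt(np.mean(centered**2, axis=0))
    return GFPSeries(values=values)


def detect_gfp_peaks(g: GFPSeries, min_separation: int = 1) -> GFPSeries:
    """Mark strict interior local maxima of the GFP series.

    A peak is a sample whose value strictly exceeds both neighbours. When
    two peaks fall closer than ``min_separation`` samples, the larger one is
    kept (ties break to the earlier index).
    """
    if min_separation < 1:
        raise InvalidParameterError("min_separation must be >= 1")
    v = g.values
    if v.size < 3:
        return GFPSeries(values=v, peak_indices=np.empty(0, dtype=int))
    interior = np.arange(1, v.size - 1)
    mask = (v[interior] > v[interior - 1]) & (v[interior] > v[interior + 1])
    peaks = interior[mask]
    if min_separation > 1 and peaks.size > 1:
        # greedy by descending value, earlier index wins ties
        order = np.lexsort((peaks, -v[peaks]))
        kept: list[int] = []
        for idx in peaks[order]:
            if all(abs(idx - k) >= min_separation for k in kept):
                kept.append(int(idx))
        peaks = np.array(sorted(kept), dtype=int)
    return GFPSeries(values=v, peak_indices=peaks)


def sample_peak_maps(
    rec: EEGRecording, g: GFPSeries, n: int, seed: int
) -> np.ndarray:
    """Uniform sample of ``n`` GFP-peak topographies without replacement.

    Returns an ``n x channels`` array of average-referenced maps, in
    ascending peak-index order for reproducibility. The study design draws
    10000 peaks per subject.

    Raises
    ------
    InsufficientDataError
        If fewer than ``n`` peaks are available.
    """
    if n < 0:
        raise InvalidParameterError("n must be nonnegative")
    if n > g.n_peaks:
        raise InsufficientDataError(
            f"requested {n} peak maps but only {g.n_peaks} peaks available"
        )
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(g.peak_indices, size=n, replace=False))
    maps = rec.data[:, chosen].T
    return average_reference(maps)


# ---------------------------------------------------------------------------
# file formats: CSV + JSON sidecar, EDF, GFP export


def write_recording_csv(rec: EEGRecording, csv_path: str | Path) -> None:
    """Write a recording as a samples x channels CSV (header = channel
    names) plus a ``.json`` sidecar holding srate and annotations."""
    csv_path = Path(csv_path)
    pd.DataFrame(rec.data.T, columns=rec.channel_names).to_csv(csv_path, index=False)
    sidecar = {
        "srate": rec.srate,
        "annotations": [
            {"onset": a.onset, "duration": a.duration, "label": a.label}
            for a in rec.annotations
        ],
    }
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_recording_csv(csv_path: str | Path) -> EEGRecording:
    """Read a recording written by :func:`write_recording_csv`."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    sidecar = json.loads(csv_path.with_suffix(".json").read_text())
    annotations = [
        Annotation(int(a["onset"]), int(a["duration"]), str(a["label"]))
        for a in sidecar.get("annotations", [])
    ]
    return EEGRecording(
        data=df.to_numpy().T,
        srate=float(sidecar["srate"]),
        channel_names=list(df.columns),
        annotations=annotations,
    )


def read_recording_edf(path: str | Path) -> EEGRecording:
    """Read an EDF file via MNE. Annotations become sample-index intervals."""
    import mne  # deferred: only needed for EDF input

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    srate = float(raw.info["sfreq"])
    annotations = [
        Annotation(int(round(on * srate)), int(round(dur * srate)), desc)
        for on, dur, desc in zip(
            raw.annotations.onset, raw.annotations.duration, raw.annotations.description
        )
    ]
    return EEGRecording(
        data=raw.get_data() * 1e6,  # volts -> microvolts
        srate=srate,
        channel_names=list(raw.ch_names),
        annotations=annotations,
    )


def write_gfp_csv(g: GFPSeries, path: str | Path) -> None:
    """Export GFP values and a peak indicator column as CSV."""
    is_peak = np.zeros(g.values.size, dtype=int)
    is_peak[g.peak_indices] = 1
    pd.DataFrame({"gfp": g.values, "is_peak": is_peak}).to_csv(path, index_label="sample")
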