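"""Filtering, resampling, epoching and epoch labelling.

The pipeline order is fixed: band-pass filter (0.5-32 Hz by default), then
down-sample (25 Hz by default, with an anti-alias low-pass at 0.45x the
target rate applied before decimation), then cut into overlapping epochs
(10 s length, 5 s stride).  Epoch coordinates are half-open ``[start, end)``
seconds; sample indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np
from scipy import signal as sps

from .synthetic import EEGRecording

__all__ = [
    "EpochGrid",
    "EpochLabels",
    "bandpass",
    "resample",
    "make_epochs",
    "label_epochs",
    "preprocess_recording",
    "DEFAULT_BAND",
    "DEFAULT_TARGET_HZ",
    "DEFAULT_EPOCH_S",
    "DEFAULT_STRIDE_S",
]

DEFAULT_BAND = (0.5, 32.0)
DEFAULT_TARGET_HZ = 25.0
DEFAULT_EPOCH_S = 10.0
DEFAULT_STRIDE_S = 5.0


@dataclass(frozen=True)
class EpochGrid:
    """Regular overlapping epoch grid over one recording."""

    epoch_length_s: float
    stride_s: float
    n_epochs: int

    def __post_init__(self) -> None:
        if self.stride_s > self.epoch_length_s:
            raise ValueError("stride_s must be <= epoch_length_s")
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")

    @property
    def epoch_starts_s(self) -> np.ndarray:
        return np.arange(self.n_epochs) * self.stride_s

    def epoch_interval(self, i: int) -> tuple[float, float]:
        start = i * self.stride_s
        return start, start + self.epoch_length_s

    def slices(self, sample_rate_hz: float) -> list[slice]:
        n_len = int(round(self.epoch_length_s * sample_rate_hz))
        out = []
        for i in range(self.n_epochs):
            i0 = int(round(i * self.stride_s * sample_rate_hz))
            out.append(slice(i0, i0 + n_len))
        return out


@dataclass(frozen=True)
class EpochLabels:
    """Per-epoch binary seizure labels (1 = seizure)."""

    labels: np.ndarray
    overlap_fraction_rule: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.overlap_fraction_rule <= 1):
            raise ValueError("overlap_fraction_rule must be in (0, 1]")


def bandpass(recording: EEGRecording, low_hz: float = DEFAULT_BAND[0],
             high_hz: float = DEFAULT_BAND[1], order: int = 4) -> EEGRecording:
    """Zero-phase Butterworth band-pass, applied per channel."""
    nyq = recording.sample_rate_hz / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) invalid for Nyquist {nyq}")
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass",
                     fs=recording.sample_rate_hz, output="sos")
    filtered = sps.sosfiltfilt(sos, recording.signal, axis=1)
    return _dc_replace(recording, signal=filtered)


def resample(recording: EEGRecording, target_hz: float = DEFAULT_TARGET_HZ,
             antialias: bool = True) -> EEGRecording:
    """Down-sample with an optional anti-alias low-pass at 0.45*target_hz.

    Annotations are in seconds and are unchanged.  The anti-alias stage can
    be disabled to reproduce a bare decimation of an already band-limited
    signal.
    """
    fs = recording.sample_rate_hz
    if target_hz > fs:
        raise ValueError("upsampling is not supported")
    if target_hz == fs:
        return recording
    x = recording.signal
    if antialias:
        sos = sps.butter(8, 0.45 * target_hz, btype="lowpass", fs=fs,
                         output="sos")
        x = sps.sosfiltfilt(sos, x, axis=1)
    n_out = int(round(x.shape[1] * target_hz / fs))
    # polyphase resampling on the already low-passed signal
    from fractions import Fraction
    frac = Fraction(target_hz / fs).limit_denominator(1000)
    y = sps.resample_poly(x, frac.numerator, frac.denominator, axis=1)
    y = y[:, :n_out]
    return _dc_replace(recording, signal=y, sample_rate_hz=target_hz)


def make_epochs(recording: EEGRecording, epoch_length_s: float = DEFAULT_EPOCH_S,
                stride_s: float = DEFAULT_STRIDE_S) -> EpochGrid:
    """Overlapping epoch grid: n = floor((duration - length)/stride) + 1."""
    duration = recording.duration_s
    if duration < epoch_length_s:
        raise ValueError(
            f"recording of {duration:.1f} s shorter than one "
            f"{epoch_length_s:.0f} s epoch")
    n_epochs = int(np.floor((duration - epoch_length_s) / stride_s + 1e-9)) + 1
    return EpochGrid(epoch_length_s=epoch_length_s, stride_s=stride_s,
                     n_epochs=n_epochs)


def _overlap_with_union(start: float, end: float,
                        intervals: list[tuple[float, float]]) -> float:
    total = 0.0
    for a, b in intervals:
        total += max(0.0, min(end, b) - max(start, a))
    return total


def label_epochs(grid: EpochGrid, annotations: list[tuple[float, float]],
                 overlap_fraction_rule: float = 0.5) -> EpochLabels:
    """Label an epoch seizure iff its overlap with the annotated seizure
    intervals is >= rule * epoch_length (inclusive)."""
    if not (0 < overlap_fraction_rule <= 1):
        raise ValueError("overlap_fraction_rule must be in (0, 1]")
    need = overlap_fraction_rule * grid.epoch_length_s
    labels = np.zeros(grid.n_epochs, dtype=np.int8)
    for i in range(grid.n_epochs):
        s, e = grid.epoch_interval(i)
        # tolerance keeps the boundary case (overlap exactly == need) inclusive
        if _overlap_with_union(s, e, annotations) >= need - 1e-9:
            labels[i] = 1
    return EpochLabels(labels=labels,
                       overlap_fraction_rule=overlap_fraction_rule)


def preprocess_recording(recording: EEGRecording,
                         band: tuple[float, float] = DEFAULT_BAND,
                         target_hz: float = DEFAULT_TARGET_HZ,
                         antialias: bool = True) -> EEGRecording:
    """Standard chain: band-pass then down-sample."""
    return resample(bandpass(recording, *band), target_hz, antialias=antialias)
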