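"""Signal cleaning, sliding-window segmentation, and normal/preFOG labeling.

The cleaning chain is percentile outlier replacement followed by
zero-phase high-pass detrending.  Segmentation then slices the cleaned
recording into overlapping windows, discards any window that touches a
freeze (FOG data are excluded from training altogether), and labels the
survivors: a window is *prefog* when its most recent sample falls inside
the labeling zone of ``prefog_duration`` samples immediately before a
FOG onset, otherwise *normal*.  Anchoring the label at the last sample
keeps the task causal — the label reflects the newest instant the
classifier could have seen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import signal as sps

from .synth import EventAnnotation, IMURecording

__all__ = [
    "SegmentationParams",
    "Window",
    "WindowSet",
    "replace_outliers",
    "highpass_detrend",
    "segment_and_label",
]

logger = logging.getLogger(__name__)

LABEL_NORMAL = "normal"
LABEL_PREFOG = "prefog"


@dataclass(frozen=True)
class SegmentationParams:
    """Windowing hyperparameters, in sampling points (1 point = 10 ms at 100 Hz)."""

    window_size: int
    step: int
    prefog_duration: int

    def __post_init__(self) -> None:
        if self.window_size < 2:
            raise ValueError("window_size must be >= 2")
        if self.step < 1:
            raise ValueError("step must be positive")
        if self.step > self.window_size:
            raise ValueError("step must not exceed window_size")
        if self.prefog_duration < 1:
            raise ValueError("prefog_duration must be positive")

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.window_size, self.step, self.prefog_duration)


@dataclass(frozen=True)
class Window:
    patient_id: str
    start: int
    end: int  # half-open
    label: str


@dataclass
class WindowSet:
    """Labeled windows of one recording plus the parameters that produced them."""

    windows: list[Window]
    params: SegmentationParams
    recording: IMURecording | None = None

    def __len__(self) -> int:
        return len(self.windows)

    def labels(self) -> np.ndarray:
        return np.array([w.label for w in self.windows])

    def slices(self) -> Iterable[np.ndarray]:
        if self.recording is None:
            raise ValueError("WindowSet carries no recording")
        for w in self.windows:
            yield self.recording.signals[w.start : w.end]


def replace_outliers(rec: IMURecording) -> IMURecording:
    """Replace burst outliers with the channel median.

    Per channel, over the whole recording: samples strictly above the
    97.5th percentile or strictly below the 2.5th percentile are
    replaced by the median of the original series.  Percentiles use
    linear interpolation; a constant channel passes through unchanged.
    """
    if rec.n_samples < 40:
        raise ValueError("need >= 40 samples for stable percentile estimates")
    out = rec.copy()
    x = out.signals
    lo = np.percentile(x, 2.5, axis=0)
    hi = np.percentile(x, 97.5, axis=0)
    med = np.median(x, axis=0)
    mask = (x > hi) | (x < lo)
    out.signals = np.where(mask, med, x)
    return out


def highpass_detrend(
    rec: IMURecording, cutoff_hz: float = 0.3, order: int = 4
) -> IMURecording:
    """Zero-phase Butterworth high-pass to remove drift and DC offset."""
    nyq = rec.sampling_rate_hz / 2.0
    if not 0 < cutoff_hz < nyq:
        raise ValueError(f"cutoff_hz must lie in (0, {nyq}) Hz")
    sos = sps.butter(order, cutoff_hz, btype="highpass", fs=rec.sampling_rate_hz, output="sos")
    out = rec.copy()
    out.signals = sps.sosfiltfilt(sos, out.signals, axis=0)
    return out


def segment_and_label(
    rec: IMURecording, ann: EventAnnotation, p: SegmentationParams
) -> WindowSet:
    """Slice the recording into labeled windows, excluding FOG data.

    Candidate windows start at ``0, step, 2*step, ...`` while they fit.
    Any window overlapping a FOG event by at least one sample is
    discarded.  A surviving window is *prefog* iff its final sample lies
    in ``[onset - prefog_duration, onset)`` for some FOG onset (zones
    are clipped at sample 0), else *normal*.
    """
    if ann.patient_id != rec.patient_id:
        raise ValueError("recording and annotation patient_id differ")
    n = rec.n_samples
    windows: list[Window] = []
    if n < p.window_size:
        logger.warning(
            "recording %s shorter than window (%d < %d): empty WindowSet",
            rec.patient_id, n, p.window_size,
        )
        return WindowSet(windows, p, rec)

    fog = ann.fog_events
    zones = [(max(0, s - p.prefog_duration), s) for s, _ in fog]
    starts = np.arange(0, n - p.window_size + 1, p.step)
    for start in starts:
        end = start + p.window_size
        if any(start < fe and fs < end for fs, fe in fog):
            continue  # window touches a freeze
        last = end - 1
        label = (
            LABEL_PREFOG
            if any(zs <= last < ze for zs, ze in zones)
            else LABEL_NORMAL
        )
        windows.append(Window(rec.patient_id, int(start), int(end), label))
    return WindowSet(windows, p, rec)
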