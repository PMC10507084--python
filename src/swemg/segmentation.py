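"""Sliding-window segmentation, the 30 %-of-maximum activity rule, and
classifier-input normalization.

A 2 s epoch at 1000 Hz windowed at 125 ms with 62.5 ms overlap yields 31
segments of 125 points, i.e. the 16 x 31 x 125 tensor fed to the CNN.
The half-window step is fractional in samples (62.5); segment i starts at
round(i * step), the only convention that tiles 2000 samples into exactly
31 windows of 125 points without resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from swemg.simulate import Recording

__all__ = ["SegmentTensor", "segment", "activity_mask", "to_model_input"]


@dataclass
class SegmentTensor:
    """channels x segments x points view of one epoch, plus metadata."""

    data: np.ndarray  # (channels, segments, points), uV
    starts: np.ndarray  # sample index of each segment start
    window_ms: float
    overlap_ms: float
    fs: float
    label: object = None
    subject: str | None = None
    activity: np.ndarray | None = None  # boolean per segment, set by activity_mask

    @property
    def n_segments(self) -> int:
        return self.data.shape[1]


def segment(rec: Recording, window_ms: float = 125.0, overlap_ms: float = 62.5) -> SegmentTensor:
    """Window the recording into overlapping segments (a copy-view; samples
    are never modified).

    Segment starts are round(i * step) with step = window - overlap in
    (possibly fractional) samples; the count is
    floor((n_samples - window) / step) + 1.
    """
    if not 0 <= overlap_ms < window_ms:
        raise ValueError(f"need 0 <= overlap < window, got {overlap_ms}, {window_ms}")
    win = int(round(window_ms * rec.fs / 1000.0))
    step = (window_ms - overlap_ms) * rec.fs / 1000.0
    if win > rec.n_samples:
        raise ValueError(f"recording of {rec.n_samples} samples shorter than one {win}-sample window")
    n_seg = int(np.floor((rec.n_samples - win) / step)) + 1
    # the rounded-start convention decides boundary cases, not float division
    while int(round(n_seg * step)) + win <= rec.n_samples:
        n_seg += 1
    while int(round((n_seg - 1) * step)) + win > rec.n_samples:
        n_seg -= 1
    starts = np.array([int(round(i * step)) for i in range(n_seg)])
    data = np.stack([rec.data[:, s : s + win] for s in starts], axis=1)
    return SegmentTensor(
        data=data, starts=starts, window_ms=window_ms, overlap_ms=overlap_ms,
        fs=rec.fs, label=rec.label, subject=rec.subject,
    )


def activity_mask(t: SegmentTensor, threshold_frac: float = 0.30) -> np.ndarray:
    """Flag active segments by the 30 %-of-maximum rule.

    A segment is active when its averaged amplitude (mean |x| over all
    channels and points) exceeds ``threshold_frac`` times the maximum of
    that statistic over the epoch's segments.  The maximal segment is
    always active; an all-zero epoch is all-inactive.  The mask is stored
    on the tensor and returned.
    """
    if not 0 <= threshold_frac < 1:
        raise ValueError(f"threshold_frac must lie in [0, 1), got {threshold_frac}")
    amp = np.abs(t.data).mean(axis=(0, 2))  # per-segment averaged amplitude
    peak = amp.max()
    mask = amp > threshold_frac * peak if peak > 0 else np.zeros(t.n_segments, dtype=bool)
    t.activity = mask
    return mask


def to_model_input(t: SegmentTensor) -> np.ndarray:
    """Per-recording z-score of the full tensor (shape preserved).

    Normalizing over all elements at once keeps inter-channel amplitude
    ratios intact — they carry the left/right laterality information the
    classifier needs.  A constant tensor maps to all zeros.
    """
    x = np.asarray(t.data, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("tensor contains non-finite values")
    mean, sd = x.mean(), x.std()
    if sd <= 1e-12 * (abs(mean) + 1.0):  # constant up to rounding
        return np.zeros_like(x)
    return (x - mean) / sd
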