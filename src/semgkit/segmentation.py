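"""Active-segment detection by short-term energy and variance thresholds.

A gesture repetition shows up as a burst of broadband activity on every
channel. Detection runs on the *channel-mean* signal: the mean trace is cut
into sliding frames, each frame's short-term energy

    E = (1/l) * sum_{n=0}^{l-1} x(n)^2

and variance

    Var = (1/l) * sum_{n=0}^{l-1} (x(n) - mean(x))^2

are compared against thresholds, and maximal runs of supra-threshold frames
become active segments. Segment boundaries are then mapped back onto the
original multichannel recording and every segment is linearly interpolated
to a common length so that downstream tensors are rectangular.

Conventions: sample indices are 0-based; intervals are half-open
``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_io import Recording

__all__ = [
    "SegmentationParams",
    "ActiveSegment",
    "mean_signal",
    "frame_series",
    "short_term_energy",
    "frame_variance",
    "detect_active_segments",
    "extract_segments",
    "resample_to_length",
    "segment_recording",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Detection parameters.

    ``energy_threshold`` / ``var_threshold`` of ``None`` select the adaptive
    rule: statistics are computed over the first ``rest_frames`` frames
    (assumed rest) and the threshold is ``rest_mean + threshold_sigma *
    rest_std``. ``mode`` chooses whether a frame must exceed both thresholds
    ("and", default) or either ("or"). When ``expected_segments`` is set and
    more runs survive the minimum-duration filter, the runs with highest
    total energy are kept (in temporal order).
    """

    frame_len: int = 100
    hop: int = 50
    energy_threshold: float | None = None
    var_threshold: float | None = None
    min_segment_frames: int = 2
    expected_segments: int | None = None
    rest_frames: int = 10
    threshold_sigma: float = 6.0
    mode: str = "and"

    def __post_init__(self) -> None:
        if self.frame_len < 1 or not (1 <= self.hop <= self.frame_len):
            raise ValueError(
                f"need 1 <= hop <= frame_len, got hop={self.hop}, frame_len={self.frame_len}"
            )
        for name in ("energy_threshold", "var_threshold"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.min_segment_frames < 1:
            raise ValueError("min_segment_frames must be >= 1")
        if self.mode not in ("and", "or"):
            raise ValueError(f"mode must be 'and' or 'or', got {self.mode!r}")


@dataclass
class ActiveSegment:
    """One detected gesture repetition: interval plus the multichannel slice."""

    start: int
    end: int
    data: np.ndarray  # (n_channels, end - start) before resampling

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"need 0 <= start < end, got ({self.start}, {self.end})")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def mean_signal(recording: Recording) -> np.ndarray:
    """Arithmetic mean across channels, per time sample."""
    return recording.data.mean(axis=0)


def frame_series(series: np.ndarray, frame_len: int, hop: int) -> np.ndarray:
    """Slice a 1-D series into sliding frames.

    Frame ``i`` covers samples ``[i*hop, i*hop + frame_len)``; a trailing
    remainder shorter than ``frame_len`` is dropped. Returns a view of shape
    ``(n_frames, frame_len)`` with ``n_frames = (L - frame_len)//hop + 1``.
    """
    series = np.asarray(series)
    length = series.shape[-1]
    if frame_len > length:
        raise ValueError(f"frame_len {frame_len} exceeds series length {length}")
    n_frames = (length - frame_len) // hop + 1
    windows = np.lib.stride_tricks.sliding_window_view(series, frame_len, axis=-1)
    return windows[..., ::hop, :][..., :n_frames, :]


def short_term_energy(frame: np.ndarray) -> float:
    """Mean squared amplitude of one frame."""
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise ValueError("empty frame")
    return float(np.mean(frame**2))


def frame_variance(frame: np.ndarray) -> float:
    """Population variance (divide-by-l) of one frame."""
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise ValueError("empty frame")
    return float(np.mean((frame - frame.mean()) ** 2))


def _resolve_thresholds(
    energy: np.ndarray, var: np.ndarray, params: SegmentationParams
) -> tuple[float, float]:
    thr_e, thr_v = params.energy_threshold, params.var_threshold
    if thr_e is None or thr_v is None:
        rest = slice(0, min(params.rest_frames, len(energy)))
        if thr_e is None:
            thr_e = float(energy[rest].mean() + params.threshold_sigma * energy[rest].std())
        if thr_v is None:
            thr_v = float(var[rest].mean() + params.threshold_sigma * var[rest].std())
    return thr_e, thr_v


def detect_active_segments(
    series: np.ndarray, params: SegmentationParams = SegmentationParams()
) -> list[tuple[int, int]]:
    """Detect active intervals on a single-channel series.

    Returns sorted, non-overlapping half-open sample intervals. A segment
    starts at the first sample of the first frame of a maximal active run and
    ends after the last sample of the run's final frame.
    """
    series = np.asarray(series, dtype=float)
    frames = frame_series(series, params.frame_len, params.hop)
    energy = np.mean(frames**2, axis=1)
    var = np.mean((frames - frames.mean(axis=1, keepdims=True)) ** 2, axis=1)
    thr_e, thr_v = _resolve_thresholds(energy, var, params)
    if params.mode == "and":
        active = (energy > thr_e) & (var > thr_v)
    else:
        active = (energy > thr_e) | (var > thr_v)

    # maximal runs of active frames
    padded = np.r_[False, active, False]
    starts = np.flatnonzero(padded[1:] & ~padded[:-1])
    ends = np.flatnonzero(~padded[1:] & padded[:-1])  # exclusive frame index
    runs = [(s, e) for s, e in zip(starts, ends) if e - s >= params.min_segment_frames]

    if params.expected_segments is not None and len(runs) > params.expected_segments:
        totals = np.array([energy[s:e].sum() for s, e in runs])
        keep = np.sort(np.argsort(totals)[::-1][: params.expected_segments])
        runs = [runs[i] for i in keep]

    n = series.shape[-1]
    return [
        (int(s) * params.hop, min((int(e) - 1) * params.hop + params.frame_len, n))
        for s, e in runs
    ]


def extract_segments(
    recording: Recording, intervals: list[tuple[int, int]]
) -> list[ActiveSegment]:
    """Slice each interval out of the full multichannel recording."""
    segments = []
    for start, end in intervals:
        if not (0 <= start < end <= recording.n_samples):
            raise IndexError(
                f"interval ({start}, {end}) outside recording of "
                f"{recording.n_samples} samples"
            )
        segments.append(
            ActiveSegment(start=start, end=end, data=recording.data[:, start:end].copy())
        )
    return segments


def resample_to_length(segment: ActiveSegment, target_len: int) -> ActiveSegment:
    """Per-channel linear interpolation onto ``target_len`` equally spaced
    points over the original support. End samples are preserved exactly."""
    if target_len < 2:
        raise ValueError(f"target_len must be >= 2, got {target_len}")
    n = segment.n_samples
    if n < 2:
        raise ValueError("segment must hold >= 2 samples to interpolate")
    old_grid = np.arange(n, dtype=float)
    new_grid = np.linspace(0.0, n - 1, target_len)
    data = np.vstack([np.interp(new_grid, old_grid, ch) for ch in segment.data])
    return ActiveSegment(start=segment.start, end=segment.end, data=data)


def segment_recording(
    recording: Recording,
    params: SegmentationParams = SegmentationParams(),
    target_len: int | None = None,
) -> list[ActiveSegment]:
    """Detect on the channel mean, extract all channels, optionally
    length-normalize. Convenience wrapper over the individual steps."""
    intervals = detect_active_segments(mean_signal(recording), params)
    segments = extract_segments(recording, intervals)
    if target_len is not None:
        segments = [resample_to_length(s, target_len) for s in segments]
    return segments
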