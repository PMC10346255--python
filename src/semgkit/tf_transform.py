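"""Sliding-window DFT: time-domain segments to time-frequency tensors.

Each channel is cut into frames (default 50 ms with 40% overlap, i.e. the
hop is 60% of the frame), every frame is transformed by the 1-D DFT

    X(k) = sum_{n=0}^{N-1} x(n) * exp(-j 2 pi n k / N),

and the complex spectrum is decomposed into real part, imaginary part,
magnitude sqrt(re^2 + im^2), and full-quadrant phase atan2(im, re). For real
input the spectrum is Hermitian, so only the one-sided half
(bins 0..floor(N/2)) is kept. Frames are rectangular (no taper) by default;
a Hann taper is available but off, since the classifier consumes relative
spectral shape rather than calibrated band power.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segmentation import ActiveSegment

__all__ = [
    "SpectrumFrame",
    "TimeFrequencyTensor",
    "dft_frame",
    "spectrum_components",
    "stft_tensor",
    "flatten_for_model",
    "unflatten_from_model",
]

COMPONENTS = ("real", "imag", "magnitude", "phase", "stacked")


@dataclass
class SpectrumFrame:
    """One-sided spectral decomposition of a single windowed frame."""

    x_real: np.ndarray
    x_imag: np.ndarray
    x_mag: np.ndarray
    x_phase: np.ndarray  # radians; phase of a zero bin is defined as 0
    N: int
    fs: float

    @property
    def n_bins(self) -> int:
        return self.N // 2 + 1

    @property
    def freqs(self) -> np.ndarray:
        return np.arange(self.n_bins) * self.fs / self.N


@dataclass
class TimeFrequencyTensor:
    """Stack of per-channel, per-frame spectra.

    ``values`` has shape (n_channels, n_frames, n_bins); for the ``stacked``
    component the four decompositions are concatenated as channel groups,
    giving 4*n_channels leading entries ordered real/imag/magnitude/phase.
    """

    values: np.ndarray
    component: str
    frame_ms: float
    overlap_frac: float
    fs: float

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def n_bins(self) -> int:
        return self.values.shape[2]


def frame_hop(frame_len: int, overlap_frac: float) -> int:
    """Hop in samples: the frame length minus the overlapped fraction."""
    hop = int(round(frame_len * (1.0 - overlap_frac)))
    return max(hop, 1)


def dft_frame(frame: np.ndarray) -> np.ndarray:
    """Full two-sided complex DFT of one frame (all N bins)."""
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise ValueError("empty frame")
    return np.fft.fft(frame)


def spectrum_components(X: np.ndarray, N: int, fs: float) -> SpectrumFrame:
    """Decompose a complex spectrum and truncate to the one-sided half."""
    X = np.asarray(X)
    half = X[: N // 2 + 1]
    re = half.real.copy()
    im = half.imag.copy()
    mag = np.hypot(re, im)
    phase = np.arctan2(im, re)
    phase[mag == 0] = 0.0
    return SpectrumFrame(x_real=re, x_imag=im, x_mag=mag, x_phase=phase, N=N, fs=fs)


def _component_stack(frames: np.ndarray, component: str) -> np.ndarray:
    """frames: (..., n_frames, N) real -> (..., n_frames, n_bins) or stacked."""
    N = frames.shape[-1]
    spectra = np.fft.fft(frames, axis=-1)[..., : N // 2 + 1]
    re, im = spectra.real, spectra.imag
    if component == "real":
        return re
    if component == "imag":
        return im
    mag = np.hypot(re, im)
    if component == "magnitude":
        return mag
    phase = np.arctan2(im, re)
    phase[mag == 0] = 0.0
    if component == "phase":
        return phase
    if component == "stacked":
        return np.concatenate([re, im, mag, phase], axis=0)
    raise ValueError(f"unknown component {component!r}; expected one of {COMPONENTS}")


def stft_tensor(
    segment: ActiveSegment | np.ndarray,
    fs: float,
    frame_ms: float = 50.0,
    overlap_frac: float = 0.4,
    component: str = "magnitude",
    window: str = "rectangular",
) -> TimeFrequencyTensor:
    """Transform a multichannel segment into a time-frequency tensor.

    Parameters
    ----------
    segment : ActiveSegment or ndarray (n_channels, n_samples)
    fs : sampling rate in Hz.
    frame_ms : frame length in milliseconds (paper protocol sweeps 20/50/100).
    overlap_frac : overlapped fraction of the frame length (default 0.4).
    component : which spectral decomposition to keep.
    """
    data = segment.data if isinstance(segment, ActiveSegment) else np.asarray(segment)
    if data.ndim != 2:
        raise ValueError("segment data must be 2-D (channels x samples)")
    if not 0 <= overlap_frac < 1:
        raise ValueError(f"overlap_frac must be in [0, 1), got {overlap_frac}")
    frame_len = int(round(frame_ms * fs / 1000.0))
    if frame_len < 1 or frame_len > data.shape[1]:
        raise ValueError(
            f"frame of {frame_len} samples invalid for segment of {data.shape[1]}"
        )
    hop = frame_hop(frame_len, overlap_frac)
    n_frames = (data.shape[1] - frame_len) // hop + 1
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = data[:, idx]  # (C, n_frames, frame_len)
    if window == "hann":
        frames = frames * np.hanning(frame_len)
    elif window != "rectangular":
        raise ValueError(f"unknown window {window!r}")
    values = _component_stack(frames, component)
    return TimeFrequencyTensor(
        values=values, component=component, frame_ms=frame_ms,
        overlap_frac=overlap_frac, fs=fs,
    )


def flatten_for_model(tensor: TimeFrequencyTensor) -> np.ndarray:
    """Lay the tensor out as model input: (n_channels, n_frames * n_bins).

    Per channel, frames are concatenated in temporal order with bins in
    ascending frequency inside each frame. The inverse is
    :func:`unflatten_from_model`.
    """
    c, f, b = tensor.values.shape
    return tensor.values.reshape(c, f * b)


def unflatten_from_model(
    flat: np.ndarray, n_frames: int, n_bins: int
) -> np.ndarray:
    """Inverse of :func:`flatten_for_model` (returns the raw value array)."""
    c, fb = flat.shape
    if fb != n_frames * n_bins:
        raise ValueError(f"{fb} features cannot split into {n_frames}x{n_bins}")
    return flat.reshape(c, n_frames, n_bins)
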