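"""Denoising of raw sEMG: Butterworth bandpass and power-line notch.

Motion artifact and baseline drift live below ~20 Hz and surface EMG carries
little power above ~450 Hz, so the standard cleanup is a 20-450 Hz bandpass
followed by a 50 Hz notch against mains interference. Both filters are
applied forward-backward (zero phase) so that gesture onset times, which the
segmentation stage thresholds on, are not delayed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .signal_io import Recording

__all__ = ["FilterSpec", "bandpass", "notch", "denoise"]


@dataclass(frozen=True)
class FilterSpec:
    """Filter parameters. Defaults: 20-450 Hz order-4 Butterworth bandpass
    and a 50 Hz IIR notch with 2 Hz 3-dB bandwidth (Q = 25)."""

    band_low: float = 20.0
    band_high: float = 450.0
    notch_freq: float = 50.0
    butter_order: int = 4
    notch_bandwidth: float = 2.0

    def validate(self, fs: float) -> None:
        nyq = fs / 2.0
        if not 0 < self.band_low < self.band_high:
            raise ValueError(
                f"need 0 < band_low < band_high, got {self.band_low}, {self.band_high}"
            )
        if self.band_high >= nyq:
            raise ValueError(
                f"band edge {self.band_high} Hz >= Nyquist {nyq} Hz at fs={fs} Hz"
            )
        if not 0 < self.notch_freq < nyq:
            raise ValueError(
                f"notch frequency {self.notch_freq} Hz outside (0, {nyq}) at fs={fs} Hz"
            )
        if self.butter_order < 1:
            raise ValueError("butter_order must be >= 1")
        if self.notch_bandwidth <= 0:
            raise ValueError("notch_bandwidth must be positive")


def _bandpass_sos(spec: FilterSpec, fs: float) -> np.ndarray:
    return signal.butter(
        spec.butter_order, [spec.band_low, spec.band_high],
        btype="bandpass", fs=fs, output="sos",
    )


def _notch_ba(spec: FilterSpec, fs: float) -> tuple[np.ndarray, np.ndarray]:
    q = spec.notch_freq / spec.notch_bandwidth
    return signal.iirnotch(spec.notch_freq, q, fs=fs)


def bandpass(recording: Recording, spec: FilterSpec = FilterSpec()) -> Recording:
    """Zero-phase Butterworth bandpass, applied independently per channel."""
    spec.validate(recording.fs)
    sos = _bandpass_sos(spec, recording.fs)
    filtered = signal.sosfiltfilt(sos, recording.data, axis=-1)
    return replace(recording, data=filtered)


def notch(recording: Recording, spec: FilterSpec = FilterSpec()) -> Recording:
    """Zero-phase IIR notch at ``spec.notch_freq`` (mains interference)."""
    spec.validate(recording.fs)
    b, a = _notch_ba(spec, recording.fs)
    filtered = signal.filtfilt(b, a, recording.data, axis=-1)
    return replace(recording, data=filtered)


def denoise(recording: Recording, spec: FilterSpec = FilterSpec()) -> Recording:
    """Bandpass then notch — the standard preprocessing chain."""
    return notch(bandpass(recording, spec), spec)


def bandpass_response(spec: FilterSpec, fs: float, freqs: np.ndarray) -> np.ndarray:
    """|H(f)| of one forward pass of the designed bandpass at ``freqs`` (Hz).

    Zero-phase application squares this magnitude. Exposed so callers (and
    tests) can predict steady-state sinusoid gain analytically.
    """
    sos = _bandpass_sos(spec, fs)
    _, h = signal.sosfreqz(sos, worN=np.atleast_1d(freqs), fs=fs)
    return np.abs(h)


def notch_response(spec: FilterSpec, fs: float, freqs: np.ndarray) -> np.ndarray:
    """|H(f)| of one forward pass of the designed notch at ``freqs`` (Hz)."""
    b, a = _notch_ba(spec, fs)
    _, h = signal.freqz(b, a, worN=np.atleast_1d(freqs), fs=fs)
    return np.abs(h)
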