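"""Reading and writing multichannel sEMG recordings.

Two on-disk layouts are supported:

* comma-delimited text: one row per time sample, one column per channel,
  with an optional header row of channel names;
* a single-file ``.npz`` array container holding the data matrix, the
  sampling rate and optional metadata (label, subject, annotations).

The sampling rate is always supplied by the caller (CSV) or stored in the
container; it is never inferred from the data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Recording", "read_recording", "write_recording", "load_ninapro_db1"]


class FormatError(ValueError):
    """Raised when an on-disk recording violates the expected layout."""


@dataclass
class Recording:
    """One multichannel surface-EMG recording.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal amplitudes (nominally millivolts).
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
        One name per channel; defaults to ``ch0..chN``.
    label : str or None
        Optional gesture-class identifier.
    subject_id : str or None
    annotations : list of (int, int)
        Ground-truth active segments as half-open sample intervals
        ``[start, end)``, sorted and non-overlapping.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)
    label: str | None = None
    subject_id: str | None = None
    annotations: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"data must be 2-D (channels x samples), got shape {self.data.shape}")
        n_ch, n_s = self.data.shape
        if n_ch < 1 or n_s < 1:
            raise ValueError(f"recording must have >=1 channel and >=1 sample, got {n_ch}x{n_s}")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(n_ch)]
        if len(self.channel_names) != n_ch:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {n_ch} channels"
            )
        self.annotations = [(int(a), int(b)) for a, b in self.annotations]
        prev_end = 0
        for start, end in self.annotations:
            if not (0 <= start < end <= n_s):
                raise ValueError(f"annotation ({start}, {end}) outside [0, {n_s}]")
            if start < prev_end:
                raise ValueError("annotations must be sorted and non-overlapping")
            prev_end = end

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


def _looks_numeric(cell: str) -> bool:
    try:
        float(cell)
        return True
    except ValueError:
        return False


def _read_csv(path: Path, fs: float) -> Recording:
    with open(path, newline="") as fh:
        rows = [row for row in csv.reader(fh) if row]
    if not rows:
        raise FormatError(f"{path}: empty file")
    channel_names: list[str] = []
    start = 0
    if not all(_looks_numeric(c) for c in rows[0]):
        channel_names = [c.strip() for c in rows[0]]
        start = 1
        if start == len(rows):
            raise FormatError(f"{path}: header but no data rows")
    n_cols = len(rows[start])
    columns: list[list[float]] = [[] for _ in range(n_cols)]
    for i, row in enumerate(rows[start:], start=start + 1):
        if len(row) != n_cols:
            raise FormatError(
                f"{path}: row {i} has {len(row)} columns, expected {n_cols}"
            )
        for j, cell in enumerate(row):
            try:
                columns[j].append(float(cell))
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric cell at row {i}, column {j + 1}: {cell!r}"
                ) from None
    data = np.asarray(columns, dtype=float)  # channel-major: column j -> channel j
    return Recording(data=data, fs=fs, channel_names=channel_names)


def _read_npz(path: Path) -> Recording:
    with np.load(path, allow_pickle=False) as npz:
        if "data" not in npz or "fs" not in npz:
            raise FormatError(f"{path}: container must hold 'data' and 'fs'")
        data = npz["data"]
        fs = float(npz["fs"])
        names = [str(c) for c in npz["channel_names"]] if "channel_names" in npz else []
        label = str(npz["label"]) if "label" in npz else None
        subject = str(npz["subject_id"]) if "subject_id" in npz else None
        ann = (
            [(int(a), int(b)) for a, b in npz["annotations"]]
            if "annotations" in npz and npz["annotations"].size
            else []
        )
    return Recording(
        data=data, fs=fs, channel_names=names, label=label,
        subject_id=subject, annotations=ann,
    )


def read_recording(path: str | Path, fs: float | None = None) -> Recording:
    """Read a recording from CSV (requires ``fs``) or an ``.npz`` container.

    CSV layout is one row per time sample and one column per channel, so
    channel ``j`` of the returned recording is column ``j`` of the file.
    Values are returned exactly as stored, with no scaling.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such recording file: {path}")
    if path.suffix == ".npz":
        return _read_npz(path)
    if fs is None:
        raise ValueError("fs is required when reading delimited text")
    return _read_csv(path, fs)


def write_recording(recording: Recording, path: str | Path) -> None:
    """Write a recording to CSV or ``.npz``, chosen by the file extension.

    CSV numbers are printed with ``%.17g`` so the write/read round trip is
    exact for float64 (well below the documented 1e-12 tolerance).
    """
    path = Path(path)
    if not path.parent.is_dir():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    if path.suffix == ".npz":
        extra = {}
        if recording.label is not None:
            extra["label"] = np.asarray(recording.label)
        if recording.subject_id is not None:
            extra["subject_id"] = np.asarray(recording.subject_id)
        np.savez(
            path,
            data=recording.data,
            fs=np.asarray(recording.fs),
            channel_names=np.asarray(recording.channel_names),
            annotations=np.asarray(recording.annotations, dtype=int).reshape(-1, 2),
            **extra,
        )
        return
    header = ",".join(recording.channel_names)
    np.savetxt(path, recording.data.T, fmt="%.17g", delimiter=",",
               header=header, comments="")


def load_ninapro_db1(path: str | Path, fs: float = 100.0) -> list[Recording]:
    """Adapter for a Ninapro-DB1-style MATLAB container.

    Expects arrays ``emg`` (samples x channels), ``stimulus`` (gesture id per
    sample, 0 = rest) and ``repetition``. One :class:`Recording` is returned
    per (stimulus, repetition) run of non-zero stimulus, labelled with the
    gesture id. Optional; not required by the synthetic pipeline.
    """
    from scipy.io import loadmat

    mat = loadmat(str(path))
    for key in ("emg", "stimulus", "repetition"):
        if key not in mat:
            raise FormatError(f"{path}: missing array {key!r}")
    emg = np.asarray(mat["emg"], dtype=float)
    stim = np.asarray(mat["stimulus"]).ravel().astype(int)
    rep = np.asarray(mat["repetition"]).ravel().astype(int)
    if emg.shape[0] != stim.size:
        raise FormatError(f"{path}: emg and stimulus lengths differ")
    recordings: list[Recording] = []
    boundaries = np.flatnonzero(np.diff(stim) != 0) + 1
    for start, end in zip(np.r_[0, boundaries], np.r_[boundaries, stim.size]):
        gesture = stim[start]
        if gesture == 0:
            continue
        recordings.append(
            Recording(
                data=emg[start:end].T,
                fs=fs,
                label=str(gesture),
                subject_id=f"rep{rep[start]}",
            )
        )
    return recordings
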