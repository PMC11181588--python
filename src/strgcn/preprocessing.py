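"""EEG input/output and preprocessing.

Recordings are channel-by-sample matrices in microvolts with a sampling rate
and ordered 10-20 electrode labels.  This module reads EDF files (via mne) and
a plain-text matrix format, band-pass filters with zero-phase Butterworth
filters, decomposes into the canonical delta/theta/alpha/beta sub-bands,
selects/reorders channels, optionally decimates to a working rate, and cuts
recordings into fixed-length, possibly overlapping epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import signal


@dataclass(frozen=True)
class Band:
    """A named frequency band with edges in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not 0 < self.lo < self.hi:
            raise ValueError(f"invalid band edges {self.lo}-{self.hi} Hz")


#: Canonical EEG analysis bands.
BANDS: dict[str, Band] = {
    "delta": Band("delta", 0.5, 4.0),
    "theta": Band("theta", 4.0, 8.0),
    "alpha": Band("alpha", 8.0, 13.0),
    "beta": Band("beta", 13.0, 30.0),
    "full": Band("full", 0.5, 30.0),
}

SUBBANDS = ("delta", "theta", "alpha", "beta")


class FormatError(ValueError):
    """Raised when a file does not conform to the expected on-disk format."""


@dataclass
class EEGRecording:
    """A multichannel EEG recording.

    Parameters
    ----------
    data
        ``(n_channels, n_samples)`` array, microvolts.
    fs
        Sampling rate in Hz.
    channel_names
        Ordered electrode labels (10-20 system), one per row of ``data``.
    subject_id
        Opaque identifier, optional.
    label
        Optional class tag (e.g. ``"SZ"`` or ``"HC"``).
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    subject_id: str | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_names):
            raise FormatError(
                f"{len(self.channel_names)} channel names but "
                f"{self.data.shape[0]} data rows"
            )
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EpochSet:
    """Fixed-length windows cut from one or more recordings.

    ``epochs`` is ``(n_epochs, n_channels, window_len)``; ``labels`` holds one
    class tag per epoch.
    """

    epochs: np.ndarray
    labels: list
    fs: float
    channel_names: list[str]
    window_len: int
    step: int
    subject_ids: list | None = None

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (epoch, channel, sample)")
        if len(self.labels) != len(self.epochs):
            raise ValueError("one label per epoch required")

    def __len__(self) -> int:
        return len(self.epochs)


def read_recording(path: str | Path, format: str | None = None) -> EEGRecording:
    """Read an EEG recording from disk.

    ``format`` is ``"edf"`` or ``"matrix"``; when omitted it is inferred from
    the file extension (``.edf`` vs anything else).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "matrix"
    if format == "edf":
        return _read_edf(path)
    if format == "matrix":
        return _read_matrix(path)
    raise ValueError(f"unknown format {format!r}")


def _read_edf(path: Path) -> EEGRecording:
    import mne  # deferred: only needed for EDF input

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    return EEGRecording(
        data=data,
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        subject_id=path.stem,
    )


def _read_matrix(path: Path) -> EEGRecording:
    """Plain matrix format: ``fs=<Hz>`` line, channel-name CSV line, then one
    sample per row with one column per channel."""
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("fs="):
            raise FormatError(f"{path}: first line must be 'fs=<Hz>'")
        try:
            fs = float(header[3:])
        except ValueError as exc:
            raise FormatError(f"{path}: unparseable sampling rate") from exc
        names = [n.strip() for n in fh.readline().strip().split(",") if n.strip()]
        if not names:
            raise FormatError(f"{path}: missing channel-name line")
        body = np.loadtxt(fh, ndmin=2)
    if body.shape[1] != len(names):
        raise FormatError(
            f"{path}: header names {len(names)} channels but matrix has "
            f"{body.shape[1]} columns"
        )
    return EEGRecording(data=body.T, fs=fs, channel_names=names,
                        subject_id=path.stem)


def write_matrix(rec: EEGRecording, path: str | Path) -> None:
    """Write a recording in the plain matrix text format (samples as rows)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"fs={rec.fs:g}\n")
        fh.write(",".join(rec.channel_names) + "\n")
        np.savetxt(fh, rec.data.T, fmt="%.10g")


def _bandpass_sos(band: Band, fs: float, order: int = 5) -> np.ndarray:
    if band.hi >= fs / 2:
        raise ValueError(
            f"band edge {band.hi} Hz is at or above Nyquist ({fs / 2} Hz)"
        )
    return signal.butter(order, [band.lo, band.hi], btype="bandpass",
                         fs=fs, output="sos")


def bandpass_filter(rec: EEGRecording, band: Band | str,
                    order: int = 5) -> EEGRecording:
    """Zero-phase band-pass filter (forward-backward Butterworth).

    Zero-phase filtering preserves relative timing across channels, which the
    downstream coherence estimates depend on.  The default order keeps the
    double-pass transition bands narrow enough that the canonical sub-bands
    approximately partition in-band energy.
    """
    if isinstance(band, str):
        band = BANDS[band]
    sos = _bandpass_sos(band, rec.fs, order)
    filtered = signal.sosfiltfilt(sos, rec.data, axis=-1)
    return replace(rec, data=filtered)


def subband_decompose(rec: EEGRecording) -> dict[str, EEGRecording]:
    """Split a recording into the four canonical sub-bands.

    Returns a dict keyed ``delta``/``theta``/``alpha``/``beta``, each entry a
    filtered copy with the same shape as the input.
    """
    if rec.fs / 2 <= 30:
        raise ValueError("sampling rate too low for the 13-30 Hz beta band")
    return {name: bandpass_filter(rec, BANDS[name]) for name in SUBBANDS}


def select_channels(rec: EEGRecording, names: list[str]) -> EEGRecording:
    """Subset/reorder channels by label (case-insensitive)."""
    lookup = {n.lower(): i for i, n in enumerate(rec.channel_names)}
    missing = [n for n in names if n.lower() not in lookup]
    if missing:
        raise KeyError(f"channels not present in recording: {missing}")
    idx = [lookup[n.lower()] for n in names]
    return replace(rec, data=rec.data[idx],
                   channel_names=[rec.channel_names[i] for i in idx])


def resample_recording(rec: EEGRecording, fs_new: float) -> EEGRecording:
    """Resample to a working rate with polyphase anti-alias filtering."""
    if fs_new == rec.fs:
        return rec
    from fractions import Fraction

    frac = Fraction(fs_new / rec.fs).limit_denominator(1000)
    data = signal.resample_poly(rec.data, frac.numerator, frac.denominator,
                                axis=-1)
    return replace(rec, data=data, fs=fs_new)


def segment_epochs(rec: EEGRecording, window_len: int, step: int) -> EpochSet:
    """Cut a recording into half-open windows ``[t, t + window_len)``.

    Windows start at offsets ``0, step, 2*step, ...`` while they fit; the
    count is ``floor((n_samples - window_len) / step) + 1``.  Each epoch
    inherits the recording's label.
    """
    if not 0 < window_len <= rec.n_samples:
        raise ValueError(
            f"window_len {window_len} outside (0, {rec.n_samples}]"
        )
    if step <= 0:
        raise ValueError("step must be positive")
    n = (rec.n_samples - window_len) // step + 1
    epochs = np.stack(
        [rec.data[:, i * step: i * step + window_len] for i in range(n)]
    )
    return EpochSet(
        epochs=epochs,
        labels=[rec.label] * n,
        fs=rec.fs,
        channel_names=list(rec.channel_names),
        window_len=window_len,
        step=step,
        subject_ids=[rec.subject_id] * n,
    )


def save_epochs(es: EpochSet, path: str | Path) -> None:
    """Persist an epoch set to an ``.npz`` archive."""
    np.savez(
        path,
        epochs=es.epochs,
        labels=np.asarray(es.labels, dtype=object),
        fs=es.fs,
        channel_names=np.asarray(es.channel_names, dtype=object),
        window_len=es.window_len,
        step=es.step,
        subject_ids=np.asarray(
            es.subject_ids if es.subject_ids is not None else [], dtype=object
        ),
    )


def load_epochs(path: str | Path) -> EpochSet:
    with np.load(path, allow_pickle=True) as z:
        subj = list(z["subject_ids"]) or None
        return EpochSet(
            epochs=z["epochs"],
            labels=list(z["labels"]),
            fs=float(z["fs"]),
            channel_names=[str(c) for c in z["channel_names"]],
            window_len=int(z["window_len"]),
            step=int(z["step"]),
            subject_ids=subj,
        )
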