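"""Readers and writers for DEAP-dialect per-subject EEG recordings.

The public DEAP preprocessed distribution ships one file per subject: a
serialized mapping with a ``"data"`` block of shape (trials, channels,
samples) and a ``"labels"`` block of shape (trials, 4) holding the 1-9
self-assessment ratings in the order (valence, arousal, dominance, liking).
This module reads/writes that dialect plus a portable HDF5 dialect, and
implements the 1-based channel selection used throughout the pipeline.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

__all__ = [
    "EEGRecording",
    "DEFAULT_CHANNEL_SELECTION",
    "load_recording",
    "save_recording",
    "select_channels",
]

#: The 14-channel selection (1-based indices into the 40-channel DEAP block)
#: conventionally used for frequency-band emotion decoding.
DEFAULT_CHANNEL_SELECTION: tuple[int, ...] = (
    1, 2, 3, 4, 6, 11, 13, 17, 19, 20, 21, 25, 29, 31,
)

RATING_DIMENSIONS: tuple[str, ...] = ("valence", "arousal", "dominance", "liking")


class ValidationError(ValueError):
    """Raised when data violates a structural contract."""


@dataclass
class EEGRecording:
    """A per-subject block of trials x channels x samples EEG plus ratings.

    Parameters
    ----------
    subject_id
        Identifier of the subject the recording belongs to.
    signals
        Real-valued array of shape ``(n_trials, n_channels, n_samples)``,
        microvolt-scale arbitrary units.
    fs
        Sampling rate in Hz; the DEAP preprocessed distribution is 128 Hz.
    ratings
        Array of shape ``(n_trials, 4)`` with self-assessment ratings on the
        1-9 scale, columns ordered (valence, arousal, dominance, liking).
    channel_names
        Optional channel labels of length ``n_channels``.
    """

    subject_id: str
    signals: np.ndarray
    fs: float
    ratings: np.ndarray
    channel_names: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=np.float64)
        self.ratings = np.asarray(self.ratings, dtype=np.float64)
        self.fs = float(self.fs)
        self.validate()

    # -- structural contract -------------------------------------------------
    def validate(self) -> None:
        if self.signals.ndim != 3:
            raise ValidationError(
                f"signals must be 3-D (trials, channels, samples); "
                f"got shape {self.signals.shape}"
            )
        n_trials, n_channels, n_samples = self.signals.shape
        if n_trials < 1 or n_channels < 1 or n_samples < 1:
            raise ValidationError(
                f"signals must be non-empty in every axis; got {self.signals.shape}"
            )
        if not np.all(np.isfinite(self.signals)):
            raise ValidationError("signals contain non-finite values")
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive; got {self.fs}")
        if self.ratings.shape != (n_trials, 4):
            raise ValidationError(
                f"ratings must have shape ({n_trials}, 4); got {self.ratings.shape}"
            )
        if np.any(self.ratings < 1.0) or np.any(self.ratings > 9.0):
            bad = self.ratings[(self.ratings < 1.0) | (self.ratings > 9.0)]
            raise ValidationError(
                f"ratings must lie in [1, 9]; offending values include {bad[:3]}"
            )
        if self.channel_names is not None and len(self.channel_names) != n_channels:
            raise ValidationError(
                f"channel_names has length {len(self.channel_names)}, "
                f"expected {n_channels}"
            )

    # -- convenience ---------------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.signals.shape[0]

    @property
    def n_channels(self) -> int:
        return self.signals.shape[1]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[2]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EEGRecording):
            return NotImplemented
        return (
            self.subject_id == other.subject_id
            and self.fs == other.fs
            and self.signals.shape == other.signals.shape
            and np.array_equal(self.signals, other.signals)
            and np.array_equal(self.ratings, other.ratings)
            and (self.channel_names or None) == (other.channel_names or None)
        )


def _infer_dialect(path: Path) -> str:
    if path.suffix in {".h5", ".hdf5"}:
        return "hdf5"
    return "deap-pickle"


def load_recording(path: str | Path, dialect: str | None = None) -> EEGRecording:
    """Load a per-subject recording.

    Parameters
    ----------
    path
        File to read.
    dialect
        ``"deap-pickle"`` (the public DEAP preprocessed serialization: a
        pickled dict with keys ``"data"`` and ``"labels"``) or ``"hdf5"``.
        Inferred from the extension when omitted (.h5/.hdf5 -> hdf5).

    Returns
    -------
    EEGRecording
        Validated recording; ``fs`` defaults to 128 Hz for the deap-pickle
        dialect, which carries no rate metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "deap-pickle":
        with open(path, "rb") as fh:
            try:
                payload = pickle.load(fh, encoding="latin1")
            except Exception as exc:  # malformed pickle stream
                raise ValidationError(f"cannot unpickle {path}: {exc}") from exc
        if not isinstance(payload, dict):
            raise ValidationError(
                f"deap-pickle file must hold a mapping; got {type(payload).__name__}"
            )
        for key in ("data", "labels"):
            if key not in payload:
                raise ValidationError(f"deap-pickle mapping is missing key '{key}'")
        data = np.asarray(payload["data"], dtype=np.float64)
        labels = np.asarray(payload["labels"], dtype=np.float64)
        if data.ndim != 3:
            raise ValidationError(
                f"'data' must be trials x channels x samples; got shape {data.shape}"
            )
        if labels.ndim != 2 or labels.shape[1] != 4:
            raise ValidationError(
                f"'labels' must be trials x 4; got shape {labels.shape}"
            )
        return EEGRecording(
            subject_id=str(payload.get("subject_id", path.stem)),
            signals=data,
            fs=float(payload.get("fs", 128.0)),
            ratings=labels,
            channel_names=payload.get("channel_names"),
        )
    if dialect == "hdf5":
        with h5py.File(path, "r") as fh:
            for key in ("signals", "ratings"):
                if key not in fh:
                    raise ValidationError(f"HDF5 file is missing dataset '/{key}'")
            signals = fh["signals"][()]
            ratings = fh["ratings"][()]
            fs = float(fh.attrs.get("fs", 128.0))
            subject_id = fh.attrs.get("subject_id", path.stem)
            if isinstance(subject_id, bytes):
                subject_id = subject_id.decode()
            names = None
            if "channel_names" in fh.attrs:
                names = [
                    n.decode() if isinstance(n, bytes) else str(n)
                    for n in fh.attrs["channel_names"]
                ]
        return EEGRecording(
            subject_id=str(subject_id),
            signals=signals,
            fs=fs,
            ratings=ratings,
            channel_names=names,
        )
    raise ValidationError(f"unknown dialect '{dialect}'")


def save_recording(
    rec: EEGRecording, path: str | Path, dialect: str | None = None
) -> None:
    """Write ``rec`` so that :func:`load_recording` reproduces it exactly."""
    rec.validate()
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "deap-pickle":
        payload = {
            "data": rec.signals,
            "labels": rec.ratings,
            "fs": rec.fs,
            "subject_id": rec.subject_id,
        }
        if rec.channel_names is not None:
            payload["channel_names"] = list(rec.channel_names)
        with open(path, "wb") as fh:
            pickle.dump(payload, fh)
    elif dialect == "hdf5":
        with h5py.File(path, "w") as fh:
            fh.create_dataset("signals", data=rec.signals)
            fh.create_dataset("ratings", data=rec.ratings)
            fh.attrs["fs"] = rec.fs
            fh.attrs["subject_id"] = rec.subject_id
            if rec.channel_names is not None:
                fh.attrs["channel_names"] = [str(n) for n in rec.channel_names]
    else:
        raise ValidationError(f"unknown dialect '{dialect}'")


def select_channels(rec: EEGRecording, indices: Sequence[int]) -> EEGRecording:
    """Subset channels by 1-based index, preserving the given order.

    Channel indices are 1-based to match the conventional published channel
    tables; they are converted internally.
    """
    indices = list(indices)
    if len(indices) == 0:
        raise ValidationError("channel selection must not be empty")
    if len(set(indices)) != len(indices):
        raise ValidationError(f"duplicate channel indices in {indices}")
    for idx in indices:
        if not (1 <= idx <= rec.n_channels):
            raise ValidationError(
                f"channel index {idx} out of range [1, {rec.n_channels}]"
            )
    zero_based = [i - 1 for i in indices]
    names = None
    if rec.channel_names is not None:
        names = [rec.channel_names[i] for i in zero_based]
    return replace(
        rec,
        signals=rec.signals[:, zero_based, :].copy(),
        channel_names=names,
    )
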