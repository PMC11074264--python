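"""Windowed FFT band-power features and rating binarization.

Raw multichannel EEG is cut into fixed-length windows per trial; each window
and channel is transformed with the DFT

    X_k = sum_{i=0}^{N-1} x_i exp(-j 2 pi i k / N),  k = 0..N-1,

and summarised as the mean squared spectral magnitude over five canonical
frequency bands (theta 4-8, alpha 8-12, low-beta 12-16, high-beta 16-25,
gamma 25-45 Hz). Short windows are zero-padded to a minimum FFT length so
every band contains at least one bin even for windows of a few samples.
The per-trial 1-9 ratings are thresholded into binary high/low labels that
every window of the trial inherits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps

from .io_deap import EEGRecording, ValidationError, select_channels

__all__ = [
    "Spectrum",
    "BandDefinition",
    "FeatureMatrix",
    "DEFAULT_BANDS",
    "dft",
    "band_power",
    "extract_features",
    "binarize_ratings",
]


@dataclass(frozen=True)
class BandDefinition:
    """A half-open frequency interval [lo, hi) in Hz.

    Half-open intervals avoid double-counting the shared band edges
    (e.g. 8 Hz belongs to alpha, not theta).
    """

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 <= self.lo < self.hi):
            raise ValidationError(
                f"band '{self.name}' must satisfy 0 <= lo < hi; "
                f"got [{self.lo}, {self.hi})"
            )


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta_low", 12.0, 16.0),
    BandDefinition("beta_high", 16.0, 25.0),
    BandDefinition("gamma", 25.0, 45.0),
)


@dataclass
class Spectrum:
    """Two-sided DFT coefficients X_k, k = 0..N-1, of a real signal."""

    coefficients: np.ndarray
    N: int
    fs: float

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=complex)
        if self.coefficients.shape != (self.N,):
            raise ValidationError(
                f"expected {self.N} coefficients; got {self.coefficients.shape}"
            )
        if self.fs <= 0:
            raise ValidationError("fs must be positive")

    @property
    def frequencies(self) -> np.ndarray:
        """Bin centre frequencies k * fs / N for k = 0..N-1."""
        return np.arange(self.N) * self.fs / self.N


def dft(x: Sequence[float] | np.ndarray, fs: float = 1.0) -> Spectrum:
    """Discrete Fourier transform of a real sequence.

    Computed with the FFT; the result is the unnormalised two-sided DFT, so
    the inverse transform divides by N and Parseval's identity reads
    ``sum |x_i|^2 = (1/N) sum |X_k|^2``.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size < 1:
        raise ValidationError(f"input must be a non-empty 1-D sequence; got shape {x.shape}")
    return Spectrum(coefficients=np.fft.fft(x), N=x.size, fs=fs)


def band_power(spec: Spectrum, band: BandDefinition) -> float:
    """Mean |X_k|^2 over bins whose frequency lies in [band.lo, band.hi).

    Only the non-negative-frequency half of the two-sided spectrum is
    scanned (the magnitude spectrum of a real signal is symmetric). Returns
    0 when no bin falls inside the band.
    """
    nyquist = spec.fs / 2
    if band.hi > nyquist + 1e-12:
        raise ValidationError(
            f"band [{band.lo}, {band.hi}) exceeds the Nyquist frequency {nyquist}"
        )
    k = np.arange(spec.N // 2 + 1)
    freqs = k * spec.fs / spec.N
    mask = (freqs >= band.lo) & (freqs < band.hi)
    if not mask.any():
        return 0.0
    return float(np.mean(np.abs(spec.coefficients[k[mask]]) ** 2))


def binarize_ratings(
    ratings: np.ndarray, dimension: str, threshold: float = 5.0
) -> np.ndarray:
    """Threshold 1-9 ratings into binary labels: 1 ("high") iff rating >= threshold."""
    columns = {"valence": 0, "arousal": 1, "dominance": 2, "liking": 3}
    if dimension not in columns:
        raise ValidationError(
            f"unknown dimension '{dimension}'; expected one of {sorted(columns)}"
        )
    if not (1.0 < threshold < 9.0):
        raise ValidationError(f"threshold must lie in (1, 9); got {threshold}")
    ratings = np.asarray(ratings, dtype=np.float64)
    if ratings.ndim != 2 or ratings.shape[1] != 4:
        raise ValidationError(f"ratings must be n_trials x 4; got {ratings.shape}")
    return (ratings[:, columns[dimension]] >= threshold).astype(np.int64)


@dataclass
class FeatureMatrix:
    """Windows x band-power features with inherited binary labels.

    ``values[w, c * n_bands + b]`` is the power of band ``b`` on (selected)
    channel ``c`` in window ``w`` (channel-major, band-minor). ``provenance``
    records (subject, trial, window start sample) per row.
    """

    values: np.ndarray
    feature_names: list[str]
    labels_valence: np.ndarray
    labels_arousal: np.ndarray
    provenance: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = self.values.shape[0]
        if self.values.ndim != 2:
            raise ValidationError("values must be 2-D (windows x features)")
        if len(self.feature_names) != self.values.shape[1]:
            raise ValidationError("feature_names length must match n_features")
        for name, arr in (
            ("labels_valence", self.labels_valence),
            ("labels_arousal", self.labels_arousal),
        ):
            arr = np.asarray(arr)
            if arr.shape != (n,):
                raise ValidationError(f"{name} must have shape ({n},)")
            if not np.isin(arr, (0, 1)).all():
                raise ValidationError(f"{name} must be binary")
        if len(self.provenance) != n:
            raise ValidationError("provenance must have one row per window")
        if np.any(self.values < 0):
            raise ValidationError("band powers must be non-negative")

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def labels(self, dimension: str) -> np.ndarray:
        if dimension == "valence":
            return self.labels_valence
        if dimension == "arousal":
            return self.labels_arousal
        raise ValidationError(f"unknown dimension '{dimension}'")

    # -- interchange ---------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df["valence"] = self.labels_valence
        df["arousal"] = self.labels_arousal
        for col in self.provenance.columns:
            df[col] = self.provenance[col].to_numpy()
        return df

    def save(self, path: str | Path) -> None:
        """Write as CSV (default) or HDF5 (.h5/.hdf5)."""
        path = Path(path)
        if path.suffix in {".h5", ".hdf5"}:
            with h5py.File(path, "w") as fh:
                fh.create_dataset("values", data=self.values)
                fh.create_dataset("labels_valence", data=self.labels_valence)
                fh.create_dataset("labels_arousal", data=self.labels_arousal)
                fh.attrs["feature_names"] = self.feature_names
                for col in self.provenance.columns:
                    data = self.provenance[col].to_numpy()
                    if data.dtype == object:
                        data = data.astype("S")
                    fh.create_dataset(f"provenance/{col}", data=data)
        else:
            self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def load(cls, path: str | Path) -> "FeatureMatrix":
        path = Path(path)
        if path.suffix in {".h5", ".hdf5"}:
            with h5py.File(path, "r") as fh:
                values = fh["values"][()]
                names = [
                    n.decode() if isinstance(n, bytes) else str(n)
                    for n in fh.attrs["feature_names"]
                ]
                lv = fh["labels_valence"][()]
                la = fh["labels_arousal"][()]
                prov = {}
                for col in fh["provenance"]:
                    data = fh[f"provenance/{col}"][()]
                    if data.dtype.kind == "S":
                        data = np.char.decode(data)
                    prov[col] = data
            return cls(values, names, lv, la, pd.DataFrame(prov))
        df = pd.read_csv(path)
        meta = {"valence", "arousal", "subject", "trial", "window_start"}
        names = [c for c in df.columns if c not in meta]
        return cls(
            values=df[names].to_numpy(dtype=np.float64),
            feature_names=names,
            labels_valence=df["valence"].to_numpy(dtype=np.int64),
            labels_arousal=df["arousal"].to_numpy(dtype=np.int64),
            provenance=df[["subject", "trial", "window_start"]].copy(),
        )


def n_windows_per_trial(n_samples: int, window_size: int, step: int) -> int:
    """Number of windows starting at 0, step, 2*step, ... that fully fit."""
    if window_size > n_samples:
        return 0
    return (n_samples - window_size) // step + 1


def extract_features(
    rec: EEGRecording,
    window_size: int,
    step: int | None = None,
    channels: Sequence[int] | None = None,
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
    min_fft_len: int = 256,
    threshold: float = 5.0,
    pre_filter: bool = False,
    pre_filter_band: tuple[float, float] = (4.0, 45.0),
) -> FeatureMatrix:
    """Slice trials into windows and compute per-channel band powers.

    Parameters
    ----------
    rec
        Input recording.
    window_size
        Window length in samples (the published sweeps use 4..128 at 128 Hz).
    step
        Hop between window starts in samples; defaults to ``window_size // 2``
        (50% overlap), or 1 when the window is a single sample.
    channels
        1-based channel indices to keep, in order; all channels when omitted.
    bands
        Frequency bands to summarise.
    min_fft_len
        Windows shorter than this are zero-padded to this FFT length before
        band binning, so narrow bands keep a non-empty bin set for tiny
        windows. Set to 0/1 to disable padding.
    threshold
        Rating cut for label binarization (label 1 iff rating >= threshold).
    pre_filter
        When true, apply a zero-phase 4-45 Hz band-pass (4th-order
        Butterworth, forward-backward) before windowing. Off by default:
        distributed DEAP data is already filtered.

    Returns
    -------
    FeatureMatrix
        One row per (trial, window), ``len(channels) * len(bands)`` columns
        in channel-major, band-minor order.
    """
    if window_size < 1:
        raise ValidationError("window_size must be >= 1")
    if window_size > rec.n_samples:
        raise ValidationError(
            f"window_size {window_size} exceeds trial length {rec.n_samples}"
        )
    if step is None:
        step = max(window_size // 2, 1)
    if step < 1:
        raise ValidationError("step must be >= 1")

    selected = list(channels) if channels is not None else list(range(1, rec.n_channels + 1))
    sub = select_channels(rec, selected)
    signals = sub.signals  # (trials, channels, samples)

    if pre_filter:
        lo, hi = pre_filter_band
        sos = sps.butter(4, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
        signals = sps.sosfiltfilt(sos, signals, axis=2)

    n_fft = max(window_size, int(min_fft_len) if min_fft_len else 1)
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / rec.fs)
    masks = []
    for band in bands:
        if band.hi > rec.fs / 2 + 1e-12:
            raise ValidationError(
                f"band [{band.lo}, {band.hi}) exceeds Nyquist {rec.fs / 2}"
            )
        masks.append((freqs >= band.lo) & (freqs < band.hi))

    # (trials, channels, windows, window_size) view, hop = step
    windows = sliding_window_view(signals, window_size, axis=2)[:, :, ::step, :]
    spectra = np.fft.rfft(windows, n=n_fft, axis=3)
    power = np.abs(spectra) ** 2
    band_vals = np.stack(
        [
            power[..., m].mean(axis=3) if m.any() else np.zeros(power.shape[:3])
            for m in masks
        ],
        axis=3,
    )  # (trials, channels, windows, bands)

    n_trials, n_ch, n_win, n_bands = band_vals.shape
    # rows ordered by (trial, window); columns channel-major, band-minor
    values = band_vals.transpose(0, 2, 1, 3).reshape(n_trials * n_win, n_ch * n_bands)

    lab_v = np.repeat(binarize_ratings(rec.ratings, "valence", threshold), n_win)
    lab_a = np.repeat(binarize_ratings(rec.ratings, "arousal", threshold), n_win)
    starts = np.arange(n_win) * step
    provenance = pd.DataFrame(
        {
            "subject": np.repeat(rec.subject_id, n_trials * n_win),
            "trial": np.repeat(np.arange(n_trials), n_win),
            "window_start": np.tile(starts, n_trials),
        }
    )
    feature_names = [f"ch{c}_{b.name}" for c in selected for b in bands]
    return FeatureMatrix(
        values=values,
        feature_names=feature_names,
        labels_valence=lab_v,
        labels_arousal=lab_a,
        provenance=provenance,
    )
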