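"""Synthetic DEAP-shaped EEG with class-dependent spectral band power.

The generator emulates the structure of a preprocessed per-subject DEAP file
(trials x channels x samples at a fixed rate, plus 1-9 ratings) while giving
full control over the spectral content: each trial belongs to a binary class
per emotion dimension, and each class has a band-power profile realised as a
sum of band-limited sinusoids over a 1/f-shaped noise floor. Ratings are
drawn so that thresholding them recovers the class assignment exactly, which
makes every downstream stage (feature extraction, label binarization,
training, evaluation) testable without the external DEAP download.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .features import DEFAULT_BANDS, BandDefinition
from .io_deap import EEGRecording, ValidationError

__all__ = ["SyntheticSpec", "generate_dataset"]

#: Band-power gain per class used when the caller does not supply profiles:
#: class 0 ("low") is alpha-dominant, class 1 ("high") is gamma-dominant.
#: The bands are disjoint, so the classes are separable in band power.
DEFAULT_BAND_PROFILES: dict[int, dict[str, float]] = {
    0: {"alpha": 1.0},
    1: {"gamma": 1.0},
}


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic per-subject recording.

    Defaults are sized so the full pipeline (generate -> extract -> train ->
    evaluate) runs in seconds: 8 trials x 16 channels x 8 s at 128 Hz.

    Parameters
    ----------
    n_trials, n_channels
        Shape of the recording block.
    fs
        Sampling rate in Hz.
    duration
        Trial length in seconds; ``duration * fs`` must be an integer >= 2.
    class_assignment
        Per-trial binary class, shape ``(n_trials,)`` (shared by valence and
        arousal) or ``(n_trials, 2)`` with columns (valence, arousal). The
        *valence* column drives the spectral profile. ``None`` alternates
        0, 1, 0, 1, ... for an exactly balanced design.
    band_profiles
        Mapping class -> {band name: relative power gain}; bands absent from
        a profile get gain 0. Gains are dimensionless amplitudes applied to
        the band's sinusoids.
    noise_sd
        Standard deviation of the 1/f-shaped background noise (same
        arbitrary units as the sinusoid amplitudes).
    threshold
        Rating cut separating "low" from "high"; class-1 trials draw their
        rating uniformly from (threshold, 9], class-0 from [1, threshold),
        so binarizing at ``threshold`` inverts the assignment exactly.
    n_tones
        Number of random-frequency sinusoids per active band per channel.
    seed
        Seed for all randomness; a fixed seed gives bit-identical output.
    """

    n_trials: int = 8
    n_channels: int = 16
    fs: float = 128.0
    duration: float = 8.0
    class_assignment: np.ndarray | None = None
    band_profiles: Mapping[int, Mapping[str, float]] | None = None
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    noise_sd: float = 0.1
    threshold: float = 5.0
    n_tones: int = 3
    seed: int = 0
    subject_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_trials < 1 or self.n_channels < 1:
            raise ValidationError("n_trials and n_channels must be >= 1")
        n_samples = self.fs * self.duration
        if abs(n_samples - round(n_samples)) > 1e-9 or round(n_samples) < 2:
            raise ValidationError(
                f"duration * fs must be an integer >= 2; got {n_samples}"
            )
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not (1.0 < self.threshold < 9.0):
            raise ValidationError("threshold must lie in (1, 9)")
        for profile in (self.band_profiles or {}).values():
            for name, gain in profile.items():
                if gain < 0:
                    raise ValidationError(
                        f"band gain must be >= 0; got {name}={gain}"
                    )

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))

    def resolved_classes(self) -> np.ndarray:
        """Per-trial classes as an (n_trials, 2) int array (valence, arousal)."""
        if self.class_assignment is None:
            col = np.arange(self.n_trials) % 2
            return np.stack([col, col], axis=1)
        arr = np.asarray(self.class_assignment, dtype=int)
        if arr.ndim == 1:
            arr = np.stack([arr, arr], axis=1)
        if arr.shape != (self.n_trials, 2):
            raise ValidationError(
                f"class_assignment must have shape ({self.n_trials},) or "
                f"({self.n_trials}, 2); got {arr.shape}"
            )
        if not np.isin(arr, (0, 1)).all():
            raise ValidationError("class_assignment entries must be 0 or 1")
        return arr


def _pink_noise(rng: np.random.Generator, n_samples: int, fs: float) -> np.ndarray:
    """Unit-variance 1/f-shaped noise via spectral shaping of white noise."""
    white = rng.standard_normal(n_samples)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    shaped = np.fft.irfft(spectrum * scale, n=n_samples)
    sd = shaped.std()
    return shaped / sd if sd > 0 else shaped


def generate_dataset(spec: SyntheticSpec) -> tuple[EEGRecording, pd.DataFrame]:
    """Generate a recording plus its ground-truth class table.

    Each trial's channel signals are sums of band-limited sinusoids (random
    frequencies within the active bands, random phases) scaled by the trial
    class's band profile, plus 1/f noise of scale ``noise_sd``. Ratings are
    drawn on the side of ``spec.threshold`` matching the class, so
    thresholding recovers the assignment exactly.

    Returns
    -------
    (EEGRecording, DataFrame)
        The recording and a table with columns ``trial``,
        ``class_valence``, ``class_arousal``.
    """
    rng = np.random.default_rng(spec.seed)
    classes = spec.resolved_classes()
    profiles = {
        int(k): dict(v)
        for k, v in (spec.band_profiles or DEFAULT_BAND_PROFILES).items()
    }
    band_by_name = {b.name: b for b in spec.bands}
    for profile in profiles.values():
        for name in profile:
            if name not in band_by_name:
                raise ValidationError(f"unknown band '{name}' in band_profiles")

    n_samples = spec.n_samples
    t = np.arange(n_samples) / spec.fs
    signals = np.zeros((spec.n_trials, spec.n_channels, n_samples))

    for trial in range(spec.n_trials):
        profile = profiles.get(int(classes[trial, 0]), {})
        for ch in range(spec.n_channels):
            x = np.zeros(n_samples)
            for name, gain in profile.items():
                if gain == 0:
                    continue
                band = band_by_name[name]
                hi = min(band.hi, spec.fs / 2)  # stay below Nyquist
                freqs = rng.uniform(band.lo, hi, size=spec.n_tones)
                phases = rng.uniform(0.0, 2.0 * np.pi, size=spec.n_tones)
                x += gain * np.sin(
                    2.0 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]
                ).sum(axis=0)
            if spec.noise_sd > 0:
                x += spec.noise_sd * _pink_noise(rng, n_samples, spec.fs)
            signals[trial, ch] = x

    ratings = np.empty((spec.n_trials, 4))
    for col in range(2):  # valence, arousal tied to the class assignment
        high = classes[:, col] == 1
        ratings[high, col] = rng.uniform(
            np.nextafter(spec.threshold, 9.0), 9.0, size=int(high.sum())
        )
        ratings[~high, col] = rng.uniform(
            1.0, spec.threshold, size=int((~high).sum())
        )
    ratings[:, 2:] = rng.uniform(1.0, 9.0, size=(spec.n_trials, 2))

    rec = EEGRecording(
        subject_id=spec.subject_id,
        signals=signals,
        fs=spec.fs,
        ratings=ratings,
    )
    truth = pd.DataFrame(
        {
            "trial": np.arange(spec.n_trials),
            "class_valence": classes[:, 0],
            "class_arousal": classes[:, 1],
        }
    )
    return rec, truth
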