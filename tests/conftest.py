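import numpy as np
import pytest

from cfnn import EEGRecording, SyntheticSpec, extract_features, generate_dataset


@pytest.fixture(scope="session")
def small_recording() -> EEGRecording:
    """A tiny alpha-vs-gamma synthetic recording (4 trials, 6 channels, 2 s)."""
    spec = SyntheticSpec(
        n_trials=4, n_channels=6, fs=128.0, duration=2.0, noise_sd=0.05, seed=42
    )
    rec, _ = generate_dataset(spec)
    return rec


@pytest.fixture(scope="session")
def default_recording() -> EEGRecording:
    """The default-sized synthetic recording (8 trials, 16 channels, 8 s)."""
    rec, _ = generate_dataset(SyntheticSpec(seed=11))
    return rec


@pytest.fixture(scope="session")
def default_features(default_recording):
    """Band-power features of the default recording, 14 channels x 5 bands."""
    return extract_features(
        default_recording, window_size=32, channels=list(range(1, 15))
    )


@pytest.fixture
def random_recording() -> EEGRecording:
    """A recording with white-noise signals and random valid ratings."""
    rng = np.random.default_rng(7)
    return EEGRecording(
        subject_id="s01",
        signals=rng.standard_normal((3, 5, 64)),
        fs=128.0,
        ratings=rng.uniform(1, 9, (3, 4)),
        channel_names=[f"ch{i}" for i in range(5)],
    )
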