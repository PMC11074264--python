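"""Model/Results interface over the convolutional fuzzy network.

``EmotionCFNN`` is constructed from data (a feature matrix, a raw
recording, or a labelled array) plus a configuration; ``fit()`` trains the
network under a hold-out or k-fold protocol and returns a
:class:`CFNNResults` carrying the trained network, the per-epoch history,
the evaluation report with confidence intervals, and a ``summary()``
parameter ledger.
"""

from __future__ import annotations

from dataclasses import asdict

import numpy as np
import pandas as pd

from .evaluation import EvalReport, run_experiment
from .features import FeatureMatrix, extract_features
from .io_deap import EEGRecording, ValidationError
from .network import (
    CFNNConfig,
    CFNNNetwork,
    ModelSummary,
    build_model,
    summarize,
    train,
)

__all__ = ["EmotionCFNN", "CFNNResults"]


class EmotionCFNN:
    """Binary valence/arousal classifier on EEG band-power features.

    Parameters
    ----------
    features
        A :class:`FeatureMatrix` with binary labels per emotion dimension.
    dimension
        ``"valence"`` or ``"arousal"``: which label column to model.
    config
        Architecture/optimisation settings; defaults reproduce the
        reference 73-input architecture.

    Examples
    --------
    >>> from cfnn import EmotionCFNN, SyntheticSpec, generate_dataset
    >>> rec, _ = generate_dataset(SyntheticSpec(seed=7))
    >>> model = EmotionCFNN.from_recording(rec, dimension="valence",
    ...                                    extract_kwargs={"window_size": 32})
    >>> results = model.fit(test_fraction=0.25)
    >>> 0.0 <= results.accuracy <= 1.0
    True
    """

    def __init__(
        self,
        features: FeatureMatrix,
        dimension: str = "valence",
        config: CFNNConfig | None = None,
    ) -> None:
        if dimension not in ("valence", "arousal"):
            raise ValidationError(f"unknown dimension '{dimension}'")
        self.features = features
        self.dimension = dimension
        self.config = config or CFNNConfig()

    # -- alternative constructors -------------------------------------------
    @classmethod
    def from_recording(
        cls,
        rec: EEGRecording,
        dimension: str = "valence",
        config: CFNNConfig | None = None,
        extract_kwargs: dict | None = None,
    ) -> "EmotionCFNN":
        """Build from a raw recording; features are extracted on the fly."""
        features = extract_features(rec, **(extract_kwargs or {"window_size": 32}))
        return cls(features, dimension=dimension, config=config)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        dimension: str = "valence",
        config: CFNNConfig | None = None,
    ) -> "EmotionCFNN":
        """Build from a flat feature table with `valence`/`arousal` columns."""
        meta = {"valence", "arousal", "subject", "trial", "window_start"}
        names = [c for c in df.columns if c not in meta]
        provenance = pd.DataFrame(
            {
                "subject": df.get("subject", pd.Series(["?"] * len(df))),
                "trial": df.get("trial", pd.Series(np.zeros(len(df), dtype=int))),
                "window_start": df.get(
                    "window_start", pd.Series(np.zeros(len(df), dtype=int))
                ),
            }
        )
        features = FeatureMatrix(
            values=df[names].to_numpy(dtype=np.float64),
            feature_names=names,
            labels_valence=df["valence"].to_numpy(dtype=np.int64),
            labels_arousal=df["arousal"].to_numpy(dtype=np.int64),
            provenance=provenance,
        )
        return cls(features, dimension=dimension, config=config)

    # -- fitting -------------------------------------------------------------
    def fit(
        self,
        test_fraction: float = 0.25,
        kfold: int | None = None,
        seed: int | None = None,
    ) -> "CFNNResults":
        """Train under a hold-out (default 75:25) or k-fold protocol."""
        protocol = {"kfold": kfold} if kfold else {"holdout": test_fraction}
        cfg = self.config
        if seed is not None:
            cfg = CFNNConfig(**{**asdict(cfg), "seed": seed})
        report = run_experiment(
            self.features, protocol, cfg=cfg, dimension=self.dimension
        )
        # refit on the full hold-out training split to expose a usable
        # network (run_experiment trains internally per fold)
        from .evaluation import holdout_split  # local import avoids cycle noise

        network = build_model(cfg)
        if kfold:
            history = train(
                network, self.features, dimension=self.dimension, cfg=cfg
            )
        else:
            train_idx, _ = holdout_split(
                self.features.n_windows,
                test_fraction,
                stratify_on=self.features.labels(self.dimension),
                seed=cfg.seed,
            )
            history = train(
                network,
                self.features,
                dimension=self.dimension,
                cfg=cfg,
                train_idx=train_idx,
            )
        return CFNNResults(self, network, history, report, cfg)


class CFNNResults:
    """Fit results: trained network, history, evaluation report, ledger."""

    def __init__(
        self,
        model: EmotionCFNN,
        network: CFNNNetwork,
        history: dict,
        report: EvalReport,
        config: CFNNConfig,
    ) -> None:
        self.model = model
        self.network = network
        self.history = history
        self.report = report
        self.config = config

    # -- point estimates ------------------------------------------------------
    @property
    def accuracy(self) -> float:
        return self.report.accuracy

    @property
    def f1(self) -> float:
        return self.report.f1

    @property
    def conf_int(self) -> tuple[float, float]:
        """Binomial normal-approximation CI on the test accuracy."""
        return self.report.ci

    def predict(self, X: np.ndarray | FeatureMatrix) -> np.ndarray:
        if isinstance(X, FeatureMatrix):
            X = X.values
        return self.network.predict(X)

    def predict_proba(self, X: np.ndarray | FeatureMatrix) -> np.ndarray:
        if isinstance(X, FeatureMatrix):
            X = X.values
        return self.network.predict_proba(X)

    def summary(self) -> ModelSummary:
        """The per-layer shape/parameter ledger of the fitted network."""
        return summarize(self.network)

    def plot_history(self, ax=None):
        """Plot per-epoch training loss and accuracy (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        epochs = np.arange(1, len(self.history["loss"]) + 1)
        ax.plot(epochs, self.history["loss"], label="loss")
        ax.set_xlabel("epoch")
        ax.set_ylabel("training loss")
        twin = ax.twinx()
        twin.plot(epochs, self.history["accuracy"], color="C1", label="accuracy")
        twin.set_ylabel("training accuracy")
        ax.set_title(f"{self.report.dimension} training history")
        return ax

    def __str__(self) -> str:
        r = self.report
        lines = [
            f"EmotionCFNN results ({r.dimension}, protocol={r.protocol})",
            f"  test examples : {r.n_test}",
            f"  accuracy      : {r.accuracy:.4f}  "
            f"({r.ci[0]:.4f}-{r.ci[1]:.4f} at {r.ci_level:.0%})",
            f"  precision     : {r.precision:.4f}",
            f"  recall        : {r.recall:.4f}",
            f"  F1            : {r.f1:.4f}",
            f"  seed/config   : {r.seed} / {r.config_hash}",
        ]
        return "\n".join(lines)
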