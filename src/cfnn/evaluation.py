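"""Metrics, split protocols, confidence intervals and experiment reports.

Binary classification is summarised by the confusion counts and the four
standard ratios

    accuracy  = (TP + TN) / (TP + FP + TN + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

with zero-denominator ratios reported as 0 and flagged. Uncertainty on a
proportion uses the normal-approximation binomial interval
p +- z * sqrt(p(1-p)/n) clipped to [0, 1]. Hold-out and k-fold protocols
are stratified on the binarized label and fully seeded, so a report is
reproducible byte for byte from (seed, config, input).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import stats
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold, train_test_split

from .features import FeatureMatrix, extract_features
from .io_deap import EEGRecording, ValidationError
from .network import CFNNConfig, build_model, train

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "confusion",
    "metrics",
    "holdout_split",
    "kfold",
    "confidence_interval",
    "run_experiment",
]


@dataclass
class ConfusionCounts:
    """Binary confusion counts; the positive class is label 1 ("high")."""

    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    """Count TP/TN/FP/FN for binary label vectors."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or y_true.size < 1:
        raise ValidationError(
            f"label vectors must be equal-length and non-empty; "
            f"got {y_true.shape} vs {y_pred.shape}"
        )
    cm = confusion_matrix(y_true, y_pred, labels=[0, 1])
    return ConfusionCounts(
        TP=int(cm[1, 1]), TN=int(cm[0, 0]), FP=int(cm[0, 1]), FN=int(cm[1, 0])
    )


def metrics(counts: ConfusionCounts) -> dict:
    """Accuracy, precision, recall and F1 from confusion counts.

    Ratios with a zero denominator are reported as 0.0 and listed under
    ``"undefined"`` rather than raising.
    """
    if counts.total < 1:
        raise ValidationError("counts must cover at least one example")
    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    accuracy = (counts.TP + counts.TN) / counts.total
    precision = ratio(counts.TP, counts.TP + counts.FP, "precision")
    recall = ratio(counts.TP, counts.TP + counts.FN, "recall")
    if precision + recall == 0:
        undefined.append("f1")
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return {
        "accuracy": accuracy,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "undefined": undefined,
    }


def holdout_split(
    n: int,
    test_fraction: float,
    stratify_on: np.ndarray,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded stratified train/test index split.

    Test class proportions match the global proportions within rounding
    (one member per class).
    """
    if not (0.0 < test_fraction < 1.0):
        raise ValidationError("test_fraction must lie in (0, 1)")
    stratify_on = np.asarray(stratify_on)
    if stratify_on.shape != (n,):
        raise ValidationError("stratify_on must have one label per example")
    _, counts = np.unique(stratify_on, return_counts=True)
    if counts.min() < 2:
        raise ValidationError(
            "every class needs >= 2 members to appear on both sides of the split"
        )
    train_idx, test_idx = train_test_split(
        np.arange(n),
        test_size=test_fraction,
        stratify=stratify_on,
        random_state=seed,
        shuffle=True,
    )
    return np.sort(train_idx), np.sort(test_idx)


def kfold(
    n: int, k: int, stratify_on: np.ndarray, seed: int = 0
) -> list[np.ndarray]:
    """Seeded stratified k-fold partition; fold sizes differ by at most 1."""
    if k < 2:
        raise ValidationError("k must be >= 2")
    if k > n:
        raise ValidationError(f"k={k} exceeds the number of examples n={n}")
    stratify_on = np.asarray(stratify_on)
    if stratify_on.shape != (n,):
        raise ValidationError("stratify_on must have one label per example")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [
        np.sort(test_idx)
        for _, test_idx in splitter.split(np.zeros(n), stratify_on)
    ]


def confidence_interval(
    p_hat: float, n: int, level: float = 0.95
) -> tuple[float, float]:
    """Normal-approximation binomial interval for a proportion, clipped to [0, 1]."""
    if not (0.0 < level < 1.0):
        raise ValidationError("level must lie in (0, 1)")
    if not (0.0 <= p_hat <= 1.0) or n < 1:
        raise ValidationError("need 0 <= p_hat <= 1 and n >= 1")
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    half = z * np.sqrt(p_hat * (1.0 - p_hat) / n)
    return (max(0.0, p_hat - half), min(1.0, p_hat + half))


@dataclass
class EvalReport:
    """Evaluation result for one emotion dimension under one protocol."""

    dimension: str
    counts: ConfusionCounts
    accuracy: float
    precision: float
    recall: float
    f1: float
    ci: tuple[float, float]
    ci_level: float
    protocol: dict
    seed: int
    config_hash: str
    n_test: int
    per_fold: list[dict] | None = None

    def to_json(self) -> str:
        payload = asdict(self)
        payload["ci"] = list(self.ci)
        return json.dumps(payload, sort_keys=True, indent=2)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def _fit_and_score(
    features: FeatureMatrix,
    dimension: str,
    cfg: CFNNConfig,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
) -> tuple[ConfusionCounts, dict]:
    model = build_model(cfg)
    train(model, features, dimension=dimension, cfg=cfg, train_idx=train_idx)
    y_pred = model.predict(features.values[test_idx])
    y_true = features.labels(dimension)[test_idx]
    counts = confusion(y_true, y_pred)
    return counts, metrics(counts)


def run_experiment(
    dataset: EEGRecording | FeatureMatrix,
    protocol: dict,
    cfg: CFNNConfig | None = None,
    dimension: str = "valence",
    seed: int | None = None,
    ci_level: float = 0.95,
    extract_kwargs: dict | None = None,
) -> EvalReport:
    """Run extract (if raw) -> split -> train -> predict -> metrics -> CI.

    Parameters
    ----------
    dataset
        A raw recording (features are extracted with ``extract_kwargs``) or
        an existing feature matrix.
    protocol
        ``{"holdout": test_fraction}`` or ``{"kfold": k}``. K-fold reports
        the unweighted mean of per-fold metrics with pooled confusion
        counts, and lists per-fold metrics.
    cfg
        Model configuration; a reseeded copy is used per fold.
    dimension
        ``"valence"`` or ``"arousal"``.
    seed
        Overrides ``cfg.seed`` for both the split and the model when given.
    """
    cfg = cfg or CFNNConfig()
    if seed is not None:
        cfg = CFNNConfig(**{**asdict(cfg), "seed": seed})
    if isinstance(dataset, EEGRecording):
        features = extract_features(dataset, **(extract_kwargs or {"window_size": 32}))
    else:
        features = dataset
    y = features.labels(dimension)
    n = features.n_windows

    if "holdout" in protocol:
        train_idx, test_idx = holdout_split(
            n, protocol["holdout"], stratify_on=y, seed=cfg.seed
        )
        counts, m = _fit_and_score(features, dimension, cfg, train_idx, test_idx)
        ci = confidence_interval(m["accuracy"], counts.total, ci_level)
        per_fold = None
        protocol_desc = {"holdout": protocol["holdout"]}
    elif "kfold" in protocol:
        k = protocol["kfold"]
        folds = kfold(n, k, stratify_on=y, seed=cfg.seed)
        all_idx = np.arange(n)
        per_fold = []
        pooled = ConfusionCounts(0, 0, 0, 0)
        for fold_idx, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(all_idx, test_idx)
            counts_f, m_f = _fit_and_score(
                features, dimension, cfg, train_idx, test_idx
            )
            pooled = ConfusionCounts(
                pooled.TP + counts_f.TP,
                pooled.TN + counts_f.TN,
                pooled.FP + counts_f.FP,
                pooled.FN + counts_f.FN,
            )
            per_fold.append(
                {"fold": fold_idx, "counts": asdict(counts_f), **m_f}
            )
        counts = pooled
        m = {
            key: float(np.mean([f[key] for f in per_fold]))
            for key in ("accuracy", "precision", "recall", "f1")
        }
        m["undefined"] = sorted(
            {name for f in per_fold for name in f["undefined"]}
        )
        ci = confidence_interval(m["accuracy"], counts.total, ci_level)
        protocol_desc = {"kfold": k}
    else:
        raise ValidationError("protocol must contain 'holdout' or 'kfold'")

    return EvalReport(
        dimension=dimension,
        counts=counts,
        accuracy=m["accuracy"],
        precision=m["precision"],
        recall=m["recall"],
        f1=m["f1"],
        ci=ci,
        ci_level=ci_level,
        protocol=protocol_desc,
        seed=cfg.seed,
        config_hash=cfg.hash(),
        n_test=counts.total,
        per_fold=per_fold,
    )
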