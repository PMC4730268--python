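"""Performance measures and stratified cross-validation.

Metrics follow the standard confusion-matrix definitions with +1 meaning
"interacting":

    accuracy    = (TP + TN) / (TP + FP + TN + FN)
    sensitivity = TP / (TP + FN)
    precision   = TP / (TP + FP)
    MCC         = (TP*TN - FP*FN) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN))

A metric whose denominator vanishes is reported as 0 and flagged with a
warning.  ROC/AUC sweeps all distinct score thresholds (ties grouped) and
integrates with the trapezoid rule.  Cross-validation is stratified with
seeded shuffling; aggregate rows report mean +/- sample (n-1) standard
deviation across folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .rotation_forest import RFConfig, train

__all__ = [
    "ConfusionCounts",
    "BinaryMetrics",
    "FoldMetrics",
    "MetricsReport",
    "DegenerateMetricWarning",
    "confusion",
    "metrics",
    "roc_auc",
    "aggregate",
    "cross_validate",
]

METRIC_NAMES = ("sensitivity", "precision", "accuracy", "mcc", "auc")


class DegenerateMetricWarning(UserWarning):
    """A metric's denominator was zero; the metric was reported as 0."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Tally the four confusion counts for +/-1 label vectors."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError(
            f"label vectors must be 1-D and equal length, "
            f"got {y_true.shape} and {y_pred.shape}"
        )
    if y_true.size == 0:
        raise ValueError("empty label vectors")
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        bad = set(np.unique(arr).tolist()) - {-1, 1}
        if bad:
            raise ValueError(f"{name} contains non +/-1 labels: {sorted(bad)}")
    pos = y_true == 1
    pred_pos = y_pred == 1
    return ConfusionCounts(
        tp=int(np.sum(pos & pred_pos)),
        fp=int(np.sum(~pos & pred_pos)),
        tn=int(np.sum(~pos & ~pred_pos)),
        fn=int(np.sum(pos & ~pred_pos)),
    )


@dataclass(frozen=True)
class BinaryMetrics:
    sensitivity: float
    precision: float
    accuracy: float
    mcc: float
    degenerate: tuple[str, ...] = ()


def _safe_ratio(num: float, den: float, name: str, flagged: list[str]) -> float:
    if den == 0:
        warnings.warn(
            f"{name} denominator is zero; reporting 0", DegenerateMetricWarning
        )
        flagged.append(name)
        return 0.0
    return num / den


def metrics(counts: ConfusionCounts) -> BinaryMetrics:
    """Sensitivity, precision, accuracy and MCC from confusion counts."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    if counts.total == 0:
        raise ValueError("all confusion counts are zero")
    flagged: list[str] = []
    accuracy = (tp + tn) / counts.total
    sensitivity = _safe_ratio(tp, tp + fn, "sensitivity", flagged)
    precision = _safe_ratio(tp, tp + fp, "precision", flagged)
    mcc_den = float(tp + fn) * (tn + fp) * (tp + fp) * (tn + fn)
    mcc = _safe_ratio(tp * tn - fp * fn, np.sqrt(mcc_den), "mcc", flagged)
    return BinaryMetrics(
        sensitivity=sensitivity,
        precision=precision,
        accuracy=accuracy,
        mcc=mcc,
        degenerate=tuple(flagged),
    )


def roc_auc(scores, y_true) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus the ROC curve points (fpr, tpr).

    Scores are positive-class confidences; both classes must be present.
    """
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true)
    if scores.shape != y_true.shape:
        raise ValueError("scores and labels must have equal length")
    if len(set(np.unique(y_true).tolist())) < 2:
        raise ValueError("both classes must be present to build a ROC curve")
    fpr, tpr, _ = roc_curve(y_true, scores, pos_label=1)
    auc = float(np.trapezoid(tpr, fpr))
    return auc, fpr, tpr


def aggregate(values) -> tuple[float, float]:
    """Mean and sample (ddof=1) standard deviation across folds."""
    values = np.asarray(values, dtype=float)
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return mean, sd


@dataclass(frozen=True)
class FoldMetrics:
    fold: int
    sensitivity: float
    precision: float
    accuracy: float
    mcc: float
    auc: float
    degenerate: tuple[str, ...] = ()


@dataclass
class MetricsReport:
    """Per-fold metrics plus mean +/- sample sd of each measure."""

    folds: list[FoldMetrics]
    roc_points: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    def values(self, name: str) -> np.ndarray:
        return np.array([getattr(f, name) for f in self.folds])

    def mean(self, name: str) -> float:
        return aggregate(self.values(name))[0]

    def sd(self, name: str) -> float:
        return aggregate(self.values(name))[1]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {k: v for k, v in asdict(f).items() if k != "degenerate"}
            for f in self.folds
        ]
        frame = pd.DataFrame(rows).set_index("fold")
        frame.loc["mean"] = [self.mean(n) for n in METRIC_NAMES]
        frame.loc["sd"] = [self.sd(n) for n in METRIC_NAMES]
        return frame

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.6f")

    def write_roc(self, directory: str | Path) -> list[Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written = []
        for i, (fpr, tpr) in enumerate(self.roc_points, start=1):
            path = directory / f"roc_fold{i}.tsv"
            pd.DataFrame({"fpr": fpr, "tpr": tpr}).to_csv(path, sep="\t", index=False)
            written.append(path)
        return written


def _fold_seed(seed: int, fold: int) -> int:
    ss = np.random.SeedSequence(seed, spawn_key=(fold,))
    return int(ss.generate_state(1)[0] % (2**31))


def cross_validate(
    features: np.ndarray,
    labels: np.ndarray,
    config: RFConfig,
    k: int = 5,
    seed: int = 0,
) -> MetricsReport:
    """Stratified k-fold cross-validation of the Rotation Forest.

    Each fold trains a fresh model on the other k-1 folds (with a
    deterministic per-fold sub-seed) and scores the held-out fold; ROC
    scores are the ensemble's positive-class probabilities.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    for cls in (-1, 1):
        if int(np.sum(labels == cls)) < k:
            raise ValueError(f"class {cls:+d} has fewer than k={k} members")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds: list[FoldMetrics] = []
    rocs = []
    for fold_idx, (train_idx, test_idx) in enumerate(
        splitter.split(features, labels)
    ):
        fold_config = replace(config, seed=_fold_seed(seed, fold_idx))
        model = train(features[train_idx], labels[train_idx], fold_config)
        proba = model.predict_proba(features[test_idx])
        scores = proba[:, 1]
        preds = np.where(scores >= 0.5, 1, -1)
        m = metrics(confusion(labels[test_idx], preds))
        auc, fpr, tpr = roc_auc(scores, labels[test_idx])
        folds.append(
            FoldMetrics(
                fold=fold_idx + 1,
                sensitivity=m.sensitivity,
                precision=m.precision,
                accuracy=m.accuracy,
                mcc=m.mcc,
                auc=auc,
                degenerate=m.degenerate,
            )
        )
        rocs.append((fpr, tpr))
    return MetricsReport(folds=folds, roc_points=rocs)
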