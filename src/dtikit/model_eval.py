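"""RBF-SVM training, grid search, evaluation metrics and the benchmark loop.

The classifier is a C-SVM with RBF kernel (libsvm via scikit-learn), the
published defaults being C=4 and gamma=0.25 obtained by a base-2 grid
search with exponents -10..10. Evaluation uses the six standard binary
metrics:

    Acc  = (TP+TN) / (TP+TN+FP+FN)
    Rec  = TP / (TP+FN)
    Prec = TP / (TP+FP)
    F1   = 2 * Prec * Rec / (Prec + Rec)
    MCC  = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
    AUC  = rank-based (Mann-Whitney) estimate with midranks for ties

Any metric with a zero denominator is reported as 0 with a warning, so
long repeated benchmarks survive degenerate folds.

The benchmark loop mirrors the repeated-evaluation protocol: per
repetition, negatives are sampled from the unlabeled pair space (balanced
to the positive count), the balanced set is split by stratified 5-fold CV,
one SVM is trained per fold, and the six metrics are computed on each test
fold. Fold-level values are pooled across repetitions into mean +/- SD.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .dataset import (
    PairFeatureMatrix,
    SamplingPlan,
    assemble_pairs,
    positive_center,
    sample_negatives,
    split_cv,
)
from .io import InteractionTable

__all__ = [
    "SVMConfig",
    "ConfusionCounts",
    "MetricSet",
    "EvaluationReport",
    "TrainedSVM",
    "train_svm",
    "default_grid",
    "grid_search",
    "confusion_counts",
    "metrics",
    "auc",
    "run_benchmark",
]

METRIC_NAMES = ("acc", "rec", "prec", "f1", "mcc", "auc")


@dataclass(frozen=True)
class SVMConfig:
    """RBF-SVM hyperparameters; kernel is fixed to RBF."""

    c: float = 4.0
    gamma: float = 0.25

    def __post_init__(self) -> None:
        if self.c <= 0 or self.gamma <= 0:
            raise ValueError("c and gamma must be positive")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    """The six evaluation metrics; ``auc`` is None when only counts exist."""

    acc: float
    rec: float
    prec: float
    f1: float
    mcc: float
    auc: float | None = None

    def as_dict(self) -> dict[str, float]:
        d = asdict(self)
        return {k: v for k, v in d.items() if v is not None}


class TrainedSVM:
    """A fitted RBF-SVM exposing continuous decision values and labels.

    Decision values are the signed distances to the separating surface
    (positive side = predicted interaction); predictions threshold at 0.
    Training is deterministic given identical inputs.
    """

    def __init__(self, model: SVC, config: SVMConfig):
        self._model = model
        self.config = config

    def decision_values(self, x: np.ndarray) -> np.ndarray:
        return self._model.decision_function(x)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.decision_values(x) > 0


def train_svm(
    train_features: np.ndarray, labels: np.ndarray, config: SVMConfig | None = None
) -> TrainedSVM:
    """Fit an RBF-SVM on a binary-labeled feature matrix.

    ``labels`` is boolean (True = interaction). Raises on a single-class
    training set.
    """
    config = config or SVMConfig()
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("training set contains a single class")
    model = SVC(kernel="rbf", C=config.c, gamma=config.gamma)
    model.fit(train_features, labels)
    return TrainedSVM(model, config)


def default_grid() -> list[tuple[float, float]]:
    """The 21 x 21 base-2 grid: (2^i, 2^j) for i, j in -10..10."""
    exps = range(-10, 11)
    return [(float(2.0**i), float(2.0**j)) for i in exps for j in exps]


def grid_search(
    train_features: np.ndarray,
    labels: np.ndarray,
    grid: Sequence[tuple[float, float]] | None = None,
    folds: int = 5,
    seed: int = 0,
) -> tuple[float, float]:
    """Pick (c, gamma) maximizing internal cross-validated AUC.

    The default grid is the full 441-point base-2 grid. Candidates are
    scanned in (c, gamma) order and ties resolved toward the smaller c,
    then the smaller gamma.
    """
    labels = np.asarray(labels, dtype=bool)
    grid = sorted(default_grid() if grid is None else grid)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(train_features, labels))
    best: tuple[float, float] | None = None
    best_score = -np.inf
    for c, gamma in grid:
        scores = []
        for train_idx, test_idx in splits:
            svm = train_svm(train_features[train_idx], labels[train_idx], SVMConfig(c, gamma))
            scores.append(auc(labels[test_idx], svm.decision_values(train_features[test_idx])))
        mean_score = float(np.mean(scores))
        if mean_score > best_score:
            best, best_score = (c, gamma), mean_score
    assert best is not None
    return best


def confusion_counts(labels: np.ndarray, predictions: np.ndarray) -> ConfusionCounts:
    """Tally TP/FP/TN/FN from boolean truth and prediction vectors."""
    labels = np.asarray(labels, dtype=bool)
    predictions = np.asarray(predictions, dtype=bool)
    return ConfusionCounts(
        tp=int((labels & predictions).sum()),
        fp=int((~labels & predictions).sum()),
        tn=int((~labels & ~predictions).sum()),
        fn=int((labels & ~predictions).sum()),
    )


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name}: zero denominator, reporting 0", stacklevel=3)
        return 0.0
    return num / den


def metrics(counts: ConfusionCounts) -> MetricSet:
    """Accuracy, recall, precision, F1 and MCC from confusion counts.

    AUC needs a score ranking, not counts, so it is left unset here; any
    zero-denominator metric is reported as 0 with a warning.
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    acc = _safe_div(tp + tn, counts.total, "accuracy")
    rec = _safe_div(tp, tp + fn, "recall")
    prec = _safe_div(tp, tp + fp, "precision")
    f1 = _safe_div(2 * prec * rec, prec + rec, "f1")
    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _safe_div(tp * tn - fp * fn, mcc_den, "mcc")
    return MetricSet(acc=acc, rec=rec, prec=prec, f1=f1, mcc=mcc)


def auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC estimate; ties get midranks.

    Equals the probability that a random positive outscores a random
    negative (ties counting half); 0.5 for label-independent scores.
    """
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(np.asarray(scores, dtype=float))
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class EvaluationReport:
    """Mean +/- SD of each metric over all evaluated folds, plus raw values."""

    mean: dict[str, float]
    std: dict[str, float]
    repetitions: int
    folds: int
    n_evaluations: int
    config: dict = field(default_factory=dict)
    raw: list[dict] = field(default_factory=list)

    @classmethod
    def from_values(
        cls,
        values: list[dict],
        repetitions: int,
        folds: int,
        config: dict,
        aggregate: Literal["fold", "repetition"] = "fold",
    ) -> "EvaluationReport":
        frame = pd.DataFrame(values)
        if aggregate == "repetition":
            frame = frame.groupby("repetition")[list(METRIC_NAMES)].mean().reset_index()
        cols = [c for c in METRIC_NAMES if c in frame.columns]
        return cls(
            mean={m: float(frame[m].mean()) for m in cols},
            std={m: float(frame[m].std(ddof=1)) if len(frame) > 1 else 0.0 for m in cols},
            repetitions=repetitions,
            folds=folds,
            n_evaluations=len(values),
            config=config,
            raw=values,
        )

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, path: str | Path) -> "EvaluationReport":
        data = json.loads(Path(path).read_text())
        return cls(**data)


def evaluate_fold(
    matrix: PairFeatureMatrix,
    train_keys: Sequence[str],
    test_keys: Sequence[str],
    config: SVMConfig,
) -> MetricSet:
    """Train on one fold's training keys and evaluate on its test keys."""
    y_train = matrix.labels(train_keys) == "positive"
    y_test = matrix.labels(test_keys) == "positive"
    svm = train_svm(matrix.features(train_keys), y_train, config)
    scores = svm.decision_values(matrix.features(test_keys))
    m = metrics(confusion_counts(y_test, scores > 0))
    return MetricSet(**{**m.as_dict(), "auc": auc(y_test, scores)})


def run_benchmark(
    interactions: InteractionTable,
    drug_matrix: pd.DataFrame,
    protein_matrix: pd.DataFrame,
    sampling_method: Literal["distance", "random"] = "distance",
    svm_config: SVMConfig | None = None,
    repetitions: int = 100,
    folds: int = 5,
    base_seed: int = 0,
    center_method: Literal["mean", "pca-mean"] = "mean",
    aggregate: Literal["fold", "repetition"] = "fold",
) -> EvaluationReport:
    """Repeated balanced cross-validated evaluation of the full pipeline.

    Per repetition ``r``: sample ``|positives|`` negatives from the
    unlabeled pairs (random sampling reseeds with ``base_seed + r``;
    distance sampling is deterministic given the matrix, so its negative
    set is computed once and reused), split the balanced set with
    stratified ``folds``-fold CV seeded ``base_seed + r``, and record the
    six metrics on every test fold. Fully reproducible given ``base_seed``.
    """
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    svm_config = svm_config or SVMConfig()
    matrix = assemble_pairs(interactions, drug_matrix, protein_matrix)
    center = positive_center(matrix, method=center_method)

    distance_balanced: PairFeatureMatrix | None = None
    if sampling_method == "distance":
        plan = SamplingPlan(method="distance")
        distance_balanced = sample_negatives(matrix, plan, center).balanced()

    values: list[dict] = []
    for rep in range(repetitions):
        seed = base_seed + rep
        if sampling_method == "distance":
            balanced = distance_balanced
        else:
            plan = SamplingPlan(method="random", seed=seed)
            balanced = sample_negatives(matrix, plan).balanced()
        for fold_idx, (train_keys, test_keys) in enumerate(split_cv(balanced, folds, seed)):
            mset = evaluate_fold(balanced, train_keys, test_keys, svm_config)
            values.append({"repetition": rep, "fold": fold_idx, **mset.as_dict()})

    config = {
        "sampling_method": sampling_method,
        "center_method": center_method,
        "svm": {"c": svm_config.c, "gamma": svm_config.gamma, "kernel": "rbf"},
        "repetitions": repetitions,
        "folds": folds,
        "base_seed": base_seed,
        "aggregate": aggregate,
        "n_drugs": len(interactions.drugs),
        "n_targets": len(interactions.targets),
        "n_positive": interactions.n_positive,
    }
    return EvaluationReport.from_values(values, repetitions, folds, config, aggregate)
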