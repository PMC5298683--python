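"""Off-line verification pipeline.

The stored snippets can be classified on a server with ordinary machine
learning: each 1024-sample snippet is reduced to its 129-bin Welch log-PSD
(overlap 192, i.e. 13 averaged segments, near-DC body-movement bins
included), and a binary classifier separates the target species (label 1)
from everything else.  Evaluation repeats a shuffled, stratified 80/20
train/test split ten times and reports mean/std accuracy plus
precision/recall/F1 and the confusion matrix of the final repeat.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, clone
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.svm import SVC, LinearSVC

from . import spectral
from .synth import LabeledSnippet

N_FEATURES = spectral.N_BINS  # 129


@dataclass(frozen=True)
class FeatureMatrix:
    """Rows of 129 log-PSD values with binary labels (1 = target species)."""

    X: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        if self.X.shape[0] != len(self.labels):
            raise ValueError("row count must equal label count")
        if self.X.shape[1] != N_FEATURES:
            raise ValueError(f"expected {N_FEATURES} feature columns")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains non-finite values")

    def to_csv(self, path) -> None:
        freqs = np.arange(N_FEATURES) * spectral.BIN_HZ
        df = pd.DataFrame(self.X, columns=[f"psd_{f:g}hz" for f in freqs])
        df["label"] = self.labels
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        labels = df.pop("label").to_numpy(dtype=int)
        return cls(X=df.to_numpy(dtype=float), labels=labels)


@dataclass(frozen=True)
class SplitScheme:
    """Repeated shuffled holdout: 10 x stratified 80/20 by default."""

    n_repeats: int = 10
    test_fraction: float = 0.2
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.test_fraction < 1):
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts for the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total


UNDEFINED = float("nan")


@dataclass(frozen=True)
class Metrics:
    """Precision, recall and F1 for the positive class.

    A metric whose denominator is zero is undefined and reported as NaN
    with the corresponding flag set, never silently as 0.
    """

    precision: float
    recall: float
    f1: float
    precision_defined: bool = True
    recall_defined: bool = True
    f1_defined: bool = True


@dataclass
class EvaluationResult:
    """Per-repeat accuracies plus final-repeat confusion and metrics."""

    accuracies_pct: list[float]
    confusion: ConfusionMatrix
    metrics: Metrics

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies_pct))

    @property
    def std_accuracy(self) -> float:
        return float(np.std(self.accuracies_pct))


def featurize(
    snippets: Sequence[LabeledSnippet] | Sequence[np.ndarray],
    labels: Sequence[int] | None = None,
    params: spectral.WelchParams | None = None,
) -> FeatureMatrix:
    """Welch log-PSD feature matrix: one 129-value row per snippet.

    Labels default to 1 for target-species :class:`LabeledSnippet` objects
    and must be given explicitly for raw arrays.
    """
    params = params or spectral.WelchParams()
    rows = []
    derived = []
    for s in snippets:
        samples = s.samples if isinstance(s, LabeledSnippet) else np.asarray(s)
        rows.append(spectral.welch_log_psd(samples, params).values)
        if isinstance(s, LabeledSnippet):
            derived.append(1 if s.label == "B. oleae" else 0)
    if labels is None:
        if len(derived) != len(rows):
            raise ValueError("labels must be provided for raw sample arrays")
        labels = derived
    if len(labels) != len(rows):
        raise ValueError("label count does not match snippet count")
    return FeatureMatrix(X=np.asarray(rows), labels=np.asarray(labels, dtype=int))


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionMatrix:
    """Exact confusion counts by direct pair counting (positive class = 1)."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    tp = fp = fn = tn = 0
    for t, p in zip(y_true, y_pred):
        if t == 1 and p == 1:
            tp += 1
        elif t == 0 and p == 1:
            fp += 1
        elif t == 1 and p == 0:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def precision_recall_f1(cm: ConfusionMatrix) -> Metrics:
    """P = Tp/(Tp+Fp), R = Tp/(Tp+Fn), F1 = 2PR/(P+R), applied literally."""
    p_def = (cm.tp + cm.fp) > 0
    r_def = (cm.tp + cm.fn) > 0
    p = cm.tp / (cm.tp + cm.fp) if p_def else UNDEFINED
    r = cm.tp / (cm.tp + cm.fn) if r_def else UNDEFINED
    f_def = p_def and r_def and (p + r) > 0
    f1 = 2 * p * r / (p + r) if f_def else UNDEFINED
    return Metrics(
        precision=p,
        recall=r,
        f1=f1,
        precision_defined=p_def,
        recall_defined=r_def,
        f1_defined=f_def,
    )


# Classifier presets behind a plain fit/predict contract.  Hyperparameters
# follow the published verification study's settings; any sklearn-style
# estimator may be passed instead.
def classifier_presets(random_state: int | None = None) -> dict[str, BaseEstimator]:
    return {
        "linear_svc": LinearSVC(C=0.01, random_state=random_state),
        "rbf_svm": SVC(kernel="rbf", gamma=0.009, C=0.2, random_state=random_state),
        "rf": RandomForestClassifier(
            n_estimators=650,
            min_samples_split=2,
            min_samples_leaf=1,
            random_state=random_state,
        ),
        "rf_small": RandomForestClassifier(n_estimators=100, random_state=random_state),
        "adaboost": AdaBoostClassifier(random_state=random_state),
        "x_tree": ExtraTreesClassifier(
            n_estimators=650,
            min_samples_split=2,
            min_samples_leaf=1,
            random_state=random_state,
        ),
        "gbc": GradientBoostingClassifier(
            min_samples_split=5,
            min_samples_leaf=30,
            max_depth=4,
            random_state=random_state,
        ),
    }


def _resolve_classifier(spec, random_state: int | None) -> BaseEstimator:
    if isinstance(spec, str):
        presets = classifier_presets(random_state)
        if spec not in presets:
            raise ValueError(
                f"unknown classifier {spec!r}; presets: {sorted(presets)}"
            )
        return presets[spec]
    est = clone(spec)
    if "random_state" in est.get_params():
        est.set_params(random_state=random_state)
    return est


def evaluate(
    features: FeatureMatrix | np.ndarray,
    labels: Sequence[int] | None = None,
    classifier: str | BaseEstimator = "rf",
    scheme: SplitScheme = SplitScheme(),
) -> EvaluationResult:
    """Repeated shuffled-holdout evaluation of a binary verifier.

    Each repeat shuffles the corpus, holds out a stratified
    ``test_fraction`` share, fits a fresh classifier and scores it.  The
    result carries per-repeat accuracies (percent) and the final repeat's
    confusion matrix and precision/recall/F1.  Fully reproducible for a
    fixed ``scheme.seed``.
    """
    if isinstance(features, FeatureMatrix):
        X, y = features.X, features.labels
    else:
        X = np.asarray(features, dtype=float)
        y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("evaluation requires at least two classes")

    ss = np.random.SeedSequence(scheme.seed)
    repeat_states = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(scheme.n_repeats)]

    accuracies: list[float] = []
    cm = None
    for state in repeat_states:
        splitter = StratifiedShuffleSplit(
            n_splits=1, test_size=scheme.test_fraction, random_state=state
        )
        if not scheme.stratified:
            rng = np.random.default_rng(state)
            perm = rng.permutation(len(y))
            n_test = int(round(scheme.test_fraction * len(y)))
            test_idx, train_idx = perm[:n_test], perm[n_test:]
        else:
            train_idx, test_idx = next(splitter.split(X, y))
        est = _resolve_classifier(classifier, state)
        est.fit(X[train_idx], y[train_idx])
        y_pred = est.predict(X[test_idx])
        cm = confusion(y[test_idx], y_pred)
        accuracies.append(100.0 * cm.accuracy)

    return EvaluationResult(
        accuracies_pct=accuracies, confusion=cm, metrics=precision_recall_f1(cm)
    )
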