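"""LDA and random-forest classification with repeated stratified evaluation.

Both tasks are framed as supervised classification of per-trial feature
vectors: intention prediction (IP — which of the nine targets, optionally
crossed with the moving arm, 9 or 18 classes) and health-condition detection
(HD — healthy vs left/right hemisphere damage, optionally crossed with the
arm, 3 or 6 classes). Models are ordinary scikit-learn estimators; accuracy
is measured on repeated stratified random trial splits, and the random
forest additionally reports its out-of-bag (OOB) accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import train_test_split

from .features import FeatureRescaler

ALGORITHMS: Tuple[str, ...] = ("LDA", "RF")

#: Random-forest tree counts found adequate for each task.
DEFAULT_TREES_IP = 40
DEFAULT_TREES_HD = 20


@dataclass(frozen=True)
class LabelScheme:
    """Task plus optional left/right-arm distinction.

    IP yields 9 target classes (18 with the arm distinction); HD yields the
    3 conditions (6 with the arm distinction).
    """

    task: str
    lr_distinction: bool

    def __post_init__(self) -> None:
        if self.task not in ("IP", "HD"):
            raise ValueError("task must be 'IP' or 'HD'")

    @property
    def n_classes(self) -> int:
        base = 9 if self.task == "IP" else 3
        return base * 2 if self.lr_distinction else base

    def labels(self, table: pd.DataFrame) -> pd.Series:
        """Build the class label for every row of a feature table."""
        base = table["target"] if self.task == "IP" else table["condition"]
        if self.lr_distinction:
            return base.astype(str) + "/" + table["arm"].astype(str)
        return base.astype(str)


@dataclass
class EvaluationResult:
    """Accuracy of repeated stratified splits (plus OOB for the forest)."""

    algorithm: str
    train_fraction: float
    n_repeats: int
    accuracies: np.ndarray
    confusion: np.ndarray
    class_labels: Tuple[str, ...]
    oob_accuracies: Optional[np.ndarray] = None

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd_accuracy(self) -> float:
        if self.accuracies.size < 2:
            return 0.0
        return float(np.std(self.accuracies, ddof=1))

    @property
    def oob_mean(self) -> Optional[float]:
        if self.oob_accuracies is None:
            return None
        return float(np.mean(self.oob_accuracies))

    @property
    def oob_sd(self) -> Optional[float]:
        if self.oob_accuracies is None:
            return None
        if self.oob_accuracies.size < 2:
            return 0.0
        return float(np.std(self.oob_accuracies, ddof=1))


def _as_matrix(features) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(dtype=float)
    return np.asarray(features, dtype=float)


def _check_classes(y: np.ndarray, min_per_class: int = 2) -> np.ndarray:
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("at least two classes are required")
    if np.any(counts < min_per_class):
        tiny = classes[counts < min_per_class]
        raise ValueError(
            f"every class needs >= {min_per_class} samples; too few for {list(tiny)}"
        )
    return classes


def train_lda(features, labels) -> LinearDiscriminantAnalysis:
    """Fit a linear discriminant model.

    Uses the least-squares solver; when the pooled within-class covariance is
    ill-conditioned (near-singular or more features than samples) automatic
    Ledoit-Wolf shrinkage keeps the fit well defined. Deterministic.
    """
    X = _as_matrix(features)
    y = np.asarray(labels)
    _check_classes(y)
    shrinkage = None
    if X.shape[1] >= X.shape[0]:
        shrinkage = "auto"
    else:
        centred = X - pd.DataFrame(X).groupby(y).transform("mean").to_numpy()
        pooled = centred.T @ centred / max(X.shape[0] - len(np.unique(y)), 1)
        if np.linalg.cond(pooled) > 1e8:
            shrinkage = "auto"
    model = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=shrinkage)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    return model


def train_rf(
    features, labels, n_trees: int, seed: int
) -> Tuple[RandomForestClassifier, float]:
    """Fit a bootstrap-aggregated forest and return its OOB accuracy.

    The OOB accuracy is the fraction of training samples correctly
    classified by the sub-ensemble of trees whose bootstrap did not contain
    them; it is reproducible from ``seed``.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    X = _as_matrix(features)
    y = np.asarray(labels)
    _check_classes(y, min_per_class=1)
    model = RandomForestClassifier(
        n_estimators=int(n_trees),
        oob_score=True,
        bootstrap=True,
        max_features="sqrt",
        random_state=int(seed) % (2**32),
        n_jobs=1,
    )
    with warnings.catch_warnings():
        # Tiny forests can leave some samples with no OOB vote.
        warnings.simplefilter("ignore")
        model.fit(X, y)
    return model, float(model.oob_score_)


@dataclass
class SplitResult:
    accuracy: float
    confusion: np.ndarray
    class_labels: Tuple[str, ...]
    oob_accuracy: Optional[float] = None


def evaluate_split(
    features,
    labels,
    algorithm: str,
    train_fraction: float,
    seed: int,
    *,
    n_trees: Optional[int] = None,
    rescale: bool = True,
) -> SplitResult:
    """One stratified random split: fit on the training part, score the rest.

    Feature rescaling to [-0.80, +0.80] is fitted on the training split only.
    If stratification cannot place every class in both splits the split is
    resampled with a shifted seed, up to 100 attempts.
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"algorithm must be one of {ALGORITHMS}")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    if not isinstance(features, pd.DataFrame):
        features = pd.DataFrame(_as_matrix(features))
    y = np.asarray(labels)
    classes = _check_classes(y)

    last_error: Optional[Exception] = None
    for attempt in range(100):
        try:
            X_tr, X_te, y_tr, y_te = train_test_split(
                features,
                y,
                train_size=train_fraction,
                random_state=(int(seed) + attempt) % (2**32),
                stratify=y,
            )
        except ValueError as exc:
            last_error = exc
            continue
        if set(np.unique(y_tr)) == set(classes) and y_te.size > 0:
            break
        last_error = ValueError("a class is missing from one split")
    else:
        raise ValueError(
            f"could not produce a stratified split in 100 attempts: {last_error}"
        )

    if rescale:
        rescaler = FeatureRescaler().fit(X_tr)
        X_tr = rescaler.transform(X_tr)
        X_te = rescaler.transform(X_te)

    oob = None
    if algorithm == "LDA":
        model = train_lda(X_tr, y_tr)
    else:
        model, oob = train_rf(
            X_tr, y_tr, n_trees if n_trees is not None else DEFAULT_TREES_IP, seed
        )
    predicted = model.predict(X_te.to_numpy(dtype=float))
    cm = confusion_matrix(y_te, predicted, labels=list(classes))
    accuracy = float(np.trace(cm)) / float(cm.sum())
    return SplitResult(
        accuracy=accuracy,
        confusion=cm,
        class_labels=tuple(str(c) for c in classes),
        oob_accuracy=oob,
    )


def repeated_evaluation(
    features,
    labels,
    algorithm: str,
    train_fraction: float,
    n_repeats: int = 200,
    seed: int = 0,
    *,
    n_trees: Optional[int] = None,
    rescale: bool = True,
) -> EvaluationResult:
    """Average accuracy over ``n_repeats`` independent stratified splits.

    Repeat ``i`` uses seed ``seed + i``, so the whole evaluation is
    reproducible from the master seed.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    accuracies = np.empty(n_repeats)
    oobs = np.empty(n_repeats) if algorithm == "RF" else None
    confusion = None
    class_labels: Tuple[str, ...] = ()
    for i in range(n_repeats):
        split = evaluate_split(
            features,
            labels,
            algorithm,
            train_fraction,
            seed=int(seed) + i,
            n_trees=n_trees,
            rescale=rescale,
        )
        accuracies[i] = split.accuracy
        if oobs is not None:
            oobs[i] = split.oob_accuracy
        confusion = split.confusion if confusion is None else confusion + split.confusion
        class_labels = split.class_labels
    return EvaluationResult(
        algorithm=algorithm,
        train_fraction=train_fraction,
        n_repeats=n_repeats,
        accuracies=accuracies,
        confusion=confusion,
        class_labels=class_labels,
        oob_accuracies=oobs,
    )
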