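"""Classification of accelerating vs non-accelerating protrusions.

Given per-window regulator intensity time series and their protrusion
phenotype labels, predicts the binary accelerating class from the z-scored
56-frame intensity vectors.  The majority class is randomly undersampled to
the minority size 10 times; each balanced set is split 67/33 into train and
test, reshuffled 10 times, giving 100 folds per classifier.  Accuracy (Nc/N)
and the Matthews correlation coefficient,

    MCC = (Ntp*Ntn - Nfp*Nfn) / sqrt((Ntp+Nfp)(Ntp+Nfn)(Ntn+Nfp)(Ntn+Nfn)),

are recorded per fold for random forest, RBF-kernel SVM, and a small fully
connected neural network.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

__all__ = ["ClassificationReport", "znormalize_per_window", "balanced_runs", "train_and_score", "mcc"]

N_UNDERSAMPLE = 10
N_SHUFFLE = 10
TRAIN_FRACTION = 0.67


@dataclass
class ClassificationReport:
    classifier: str
    accuracy: list[float] = field(default_factory=list)
    mcc: list[float] = field(default_factory=list)
    confusion: list[tuple[int, int, int, int]] = field(default_factory=list)  # tp, tn, fp, fn
    warnings: list[str] = field(default_factory=list)


def znormalize_per_window(series_set: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-score each series to mean 0 and (population) sd 1.

    Returns the normalized matrix restricted to non-constant series and a
    boolean mask of the rows kept; constant series are excluded with a
    warning.
    """
    X = np.asarray(series_set, dtype=float)
    sd = X.std(axis=1, ddof=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"excluded {int((~keep).sum())} constant series from z-normalization")
    Z = (X[keep] - X[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    return Z, keep


def balanced_runs(
    X: np.ndarray,
    y: np.ndarray,
    n_undersample: int = N_UNDERSAMPLE,
    n_shuffle: int = N_SHUFFLE,
    split: float = TRAIN_FRACTION,
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Build n_undersample x n_shuffle balanced train/test folds.

    The majority class is undersampled without replacement to the minority
    size; each balanced set is split ``split``/(1-``split``) per class after
    shuffling.  Folds are (train_idx, test_idx) into X.
    """
    X = np.asarray(X)
    y = np.asarray(y).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("binary labels required")
    minority_pos = int(np.argmin(counts))
    minority = classes[minority_pos]
    majority = classes[1 - minority_pos]  # the other class (handles equal sizes)
    n_min = counts.min()
    if n_min < 10:
        raise ValueError("minority class has fewer than 10 samples")
    idx_min = np.flatnonzero(y == minority)
    idx_maj = np.flatnonzero(y == majority)
    rng = np.random.default_rng(seed)
    folds = []
    for _ in range(n_undersample):
        maj_sub = rng.choice(idx_maj, size=n_min, replace=False)
        for _ in range(n_shuffle):
            train, test = [], []
            for grp in (idx_min, maj_sub):
                perm = rng.permutation(grp)
                n_train = int(round(split * len(perm)))
                train.append(perm[:n_train])
                test.append(perm[n_train:])
            folds.append((np.concatenate(train), np.concatenate(test)))
    return folds


def mcc(n_tp: int, n_tn: int, n_fp: int, n_fn: int) -> float:
    """Matthews correlation coefficient; 0 (by convention) when undefined."""
    denom = math.sqrt(
        float(n_tp + n_fp) * float(n_tp + n_fn) * float(n_tn + n_fp) * float(n_tn + n_fn)
    )
    if denom == 0:
        return 0.0
    return (n_tp * n_tn - n_fp * n_fn) / denom


def _make_classifier(name: str, seed: int):
    if name == "rf":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if name == "svm":
        return SVC(kernel="rbf", random_state=seed)
    if name == "dnn":
        return MLPClassifier(
            hidden_layer_sizes=(64, 64),
            early_stopping=True,
            max_iter=300,
            random_state=seed,
        )
    raise ValueError(f"unknown classifier {name!r}; expected rf, svm or dnn")


def train_and_score(
    X: np.ndarray,
    y: np.ndarray,
    folds: list[tuple[np.ndarray, np.ndarray]],
    classifier: str,
    positive_label: int = 1,
    seed: int = 0,
) -> ClassificationReport:
    """Fit the named classifier on each fold; record accuracy, MCC, confusion."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    report = ClassificationReport(classifier=classifier)
    for fi, (train, test) in enumerate(folds):
        clf = _make_classifier(classifier, seed + fi)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            clf.fit(X[train], y[train])
            for w in caught:
                report.warnings.append(f"fold {fi}: {w.message}")
        pred = clf.predict(X[test])
        truth = y[test]
        tp = int(np.sum((pred == positive_label) & (truth == positive_label)))
        tn = int(np.sum((pred != positive_label) & (truth != positive_label)))
        fp = int(np.sum((pred == positive_label) & (truth != positive_label)))
        fn = int(np.sum((pred != positive_label) & (truth == positive_label)))
        report.confusion.append((tp, tn, fp, fn))
        report.accuracy.append((tp + tn) / len(truth))
        report.mcc.append(mcc(tp, tn, fp, fn))
    return report
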