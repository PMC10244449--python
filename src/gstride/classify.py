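"""Faller identification from gait features.

A support vector machine (RBF kernel, library-conventional defaults) is
evaluated under repeated random stratified 70/30 train/test splits using
the per-walk means and inter-stride standard deviations of the gait
variables as features.  The baseline is the Timed Up-and-Go (TUG) test
thresholded at the clinical 15 s fall-risk cutoff (or with a
train-optimised threshold), evaluated on the same splits.  Feature
standardisation and any threshold tuning are fitted on the training folds
only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .metrics import MEAN_LABELS, STD_LABELS

__all__ = [
    "FeatureMatrix",
    "ClassificationResult",
    "build_features",
    "make_splits",
    "svm_cross_validate",
    "tug_threshold_baseline",
    "compare_classifiers",
]

log = logging.getLogger(__name__)


@dataclass
class FeatureMatrix:
    """Subjects-by-features matrix of gait variables."""

    values: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] != len(self.names):
            raise ValueError("values must be n_subjects x n_features")


@dataclass
class ClassificationResult:
    """Per-split accuracies of one classifier under a split scheme."""

    accuracies: list[float]
    scheme: str
    seed: int

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def std_accuracy(self) -> float:
        return float(np.std(self.accuracies, ddof=1)) if len(self.accuracies) > 1 else 0.0

    def to_dict(self) -> dict:
        return {"accuracies": [float(a) for a in self.accuracies],
                "mean_accuracy": self.mean_accuracy,
                "std_accuracy": self.std_accuracy,
                "scheme": self.scheme, "seed": self.seed}


def build_features(cohort: pd.DataFrame) -> tuple[FeatureMatrix, np.ndarray]:
    """Gait feature matrix (all walk means and STDs) plus FALLS labels.

    Zero-variance features are dropped with a warning; missing cells must
    have been imputed upstream.
    """
    names = MEAN_LABELS + STD_LABELS
    missing = [n for n in names if n not in cohort.columns]
    if missing:
        raise ValueError(f"cohort lacks walk-summary columns: {missing}")
    bad = cohort[names].isna().any(axis=1)
    if bad.any():
        raise ValueError(
            "incomplete walk summary for subject(s): "
            f"{cohort.loc[bad, 'id'].tolist() if 'id' in cohort else list(cohort.index[bad])}")
    x = cohort[names].to_numpy(float)
    scale = np.maximum(1.0, np.abs(x).max(axis=0))
    keep = x.std(axis=0) > 1e-12 * scale
    if not keep.all():
        dropped = [n for n, k in zip(names, keep) if not k]
        warnings.warn(f"dropping zero-variance feature(s): {dropped}")
        x = x[:, keep]
        names = [n for n, k in zip(names, keep) if k]
    labels = cohort["FALLS"].astype(bool).to_numpy()
    return FeatureMatrix(values=x, names=names), labels


def make_splits(labels: np.ndarray, n_splits: int = 10,
                test_fraction: float = 0.3, seed: int = 0
                ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Repeated random stratified train/test partitions (shared by all
    classifiers so the comparison is paired)."""
    if n_splits < 2:
        raise ValueError("n_splits must be >= 2")
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or (~labels).all():
        raise ValueError("both classes must be present")
    splitter = StratifiedShuffleSplit(n_splits=n_splits, test_size=test_fraction,
                                      random_state=seed)
    return list(splitter.split(np.zeros((len(labels), 1)), labels))


def svm_cross_validate(features: FeatureMatrix, labels: np.ndarray,
                       n_splits: int = 10, test_fraction: float = 0.3,
                       seed: int = 0, c: float = 1.0, gamma="scale",
                       splits: list | None = None) -> ClassificationResult:
    """RBF-kernel SVM accuracy under repeated stratified random splits.

    Standardisation is fitted on the training fold only.  Fully
    reproducible given the seed.
    """
    labels = np.asarray(labels, dtype=bool)
    if splits is None:
        splits = make_splits(labels, n_splits, test_fraction, seed)
    accs = []
    for train, test in splits:
        if labels[train].all() or (~labels[train]).all():
            raise ValueError("single-class training fold; enlarge the groups")
        clf = make_pipeline(StandardScaler(), SVC(C=c, kernel="rbf", gamma=gamma))
        clf.fit(features.values[train], labels[train])
        accs.append(float(clf.score(features.values[test], labels[test])))
    return ClassificationResult(
        accuracies=accs,
        scheme=f"stratified-shuffle n_splits={len(splits)} test_fraction={test_fraction}",
        seed=seed)


def _best_threshold(tug: np.ndarray, y: np.ndarray) -> float:
    """Threshold maximising training accuracy of 'faller iff TUG > thr'."""
    order = np.sort(np.unique(tug))
    candidates = np.concatenate([[order[0] - 1.0],
                                 0.5 * (order[:-1] + order[1:]),
                                 [order[-1] + 1.0]])
    best_thr, best_acc = candidates[0], -1.0
    for thr in candidates:
        acc = float(np.mean((tug > thr) == y))
        if acc > best_acc:
            best_thr, best_acc = float(thr), acc
    return best_thr


def tug_threshold_baseline(tug_values: np.ndarray, labels: np.ndarray,
                           policy: str = "fixed", threshold: float = 15.0,
                           n_splits: int = 10, test_fraction: float = 0.3,
                           seed: int = 0, splits: list | None = None
                           ) -> ClassificationResult:
    """Classify faller iff TUG exceeds a threshold, on the same split scheme.

    ``policy="fixed"`` uses the clinical cutoff (15 s by default);
    ``policy="optimized"`` picks, per split, the threshold maximising
    training accuracy and evaluates it on the test fold.
    """
    tug = np.asarray(tug_values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if np.any(tug <= 0):
        raise ValueError("TUG values must be positive")
    if policy not in ("fixed", "optimized"):
        raise ValueError(f"unknown TUG policy '{policy}'")
    if splits is None:
        splits = make_splits(labels, n_splits, test_fraction, seed)
    accs = []
    for train, test in splits:
        thr = threshold if policy == "fixed" else _best_threshold(tug[train], labels[train])
        accs.append(float(np.mean((tug[test] > thr) == labels[test])))
    return ClassificationResult(
        accuracies=accs,
        scheme=f"stratified-shuffle n_splits={len(splits)} test_fraction={test_fraction}",
        seed=seed)


def compare_classifiers(a: ClassificationResult, b: ClassificationResult) -> dict:
    """Paired per-split comparison of two classifiers.

    Relative improvement is (mean_a - mean_b) / mean_b in percent.
    """
    if len(a.accuracies) != len(b.accuracies):
        raise ValueError("results must share the split scheme")
    if a.scheme != b.scheme:
        raise ValueError("results come from different split schemes")
    diffs = np.asarray(a.accuracies) - np.asarray(b.accuracies)
    return {
        "per_split_difference": diffs.tolist(),
        "mean_difference": float(diffs.mean()),
        "relative_improvement_pct": float(
            (a.mean_accuracy - b.mean_accuracy) / b.mean_accuracy * 100.0),
        "mean_accuracy_a": a.mean_accuracy,
        "mean_accuracy_b": b.mean_accuracy,
    }
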