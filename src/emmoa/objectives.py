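"""Objective backends: map a channel mask to MAR, SAR, and NC.

MAR (motor-imagery accuracy rate) is the mean held-out accuracy of a
CSP + RBF-SVM pipeline under stratified k-fold cross-validation, with the
spatial filters and the classifier fit on training folds only. SAR (SSVEP
accuracy rate) is the fraction of trials whose CCA-based frequency decision
matches the label; CCA needs no training, so it is scored on all trials.
NC = K - C rewards parsimony (K channels in the montage, C selected).

Every distinct (mask, task) computation is charged against a shared
evaluation ledger; cache hits are free. The empty mask is the invalid
solution: accuracy 0 for both tasks, charged nothing.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .data import EpochSet, StimulusSpec
from .features import (bandpass_mi, cca_classify, csp_features, csp_fit,
                       default_pair_count, log_variance_feature)


class BudgetExhausted(RuntimeError):
    """Raised internally when a fresh evaluation would exceed the budget."""


@dataclass
class EvaluationLedger:
    """Counts distinct objective computations against a budget.

    The cache key includes the task, so evaluating one mask for both tasks
    costs two evaluations. budget is mutable so a run can allot part of the
    total to each stage.
    """

    budget: int
    count: int = 0
    cache: dict = field(default_factory=dict)

    def lookup(self, key):
        return self.cache.get(key)

    def can_spend(self) -> bool:
        return self.count < self.budget

    def charge(self, key, value) -> None:
        self.cache[key] = value
        self.count += 1

    def summary(self) -> dict:
        return {"evaluations": self.count, "budget": self.budget,
                "cache_size": len(self.cache)}


def nc_objective(mask: np.ndarray) -> int:
    """Channel-parsimony objective: montage size minus selected count."""
    mask = np.asarray(mask)
    return int(mask.size - mask.sum())


def _median_heuristic_gamma(features: np.ndarray) -> float:
    """RBF kernel width from the median pairwise distance of the training
    features: gamma = 1 / (2 * median^2)."""
    n = len(features)
    if n < 2:
        return 1.0
    d2 = np.sum((features[:, None, :] - features[None, :, :]) ** 2, axis=-1)
    med2 = np.median(d2[np.triu_indices(n, k=1)])
    if med2 <= 0:
        return 1.0
    return 1.0 / (2.0 * med2)


class MIBackend:
    """Cross-validated CSP + RBF-SVM accuracy for a channel subset.

    The 5-30 Hz band-pass is applied once to the full montage at
    construction; per-mask work is channel restriction, fold-wise CSP and
    SVM fits. With a single selected channel CSP is undefined and the
    per-trial log variance is the feature.
    """

    def __init__(self, epochs: EpochSet, n_folds: int = 5, cv_seed: int = 0):
        classes = epochs.classes()
        if len(classes) != 2:
            raise ValueError(f"MI task needs exactly 2 classes, got {list(classes)}")
        counts = [int(np.sum(epochs.labels == c)) for c in classes]
        if min(counts) < 2:
            raise ValueError("MI task needs at least 2 trials per class")
        self.epochs = bandpass_mi(epochs)
        self.n_folds = n_folds
        self.cv_seed = cv_seed
        if min(counts) < n_folds:
            warnings.warn(
                f"only {min(counts)} trials in the smallest class; reducing "
                f"CV folds from {n_folds} to {min(counts)}", RuntimeWarning)
            self.n_folds = min(counts)

    def accuracy(self, mask: np.ndarray) -> float:
        sub = self.epochs.select_mask(mask)
        labels = np.asarray(sub.labels)
        skf = StratifiedKFold(n_splits=self.n_folds, shuffle=True,
                              random_state=self.cv_seed)
        single = sub.n_channels == 1
        scores = []
        for train, test in skf.split(np.zeros(sub.n_trials), labels):
            if single:
                x_train = np.array([log_variance_feature(sub.data[i]) for i in train])
                x_test = np.array([log_variance_feature(sub.data[i]) for i in test])
            else:
                fold = EpochSet(sub.data[train], labels[train], sub.fs,
                                sub.channel_names)
                bank = csp_fit(fold, m=default_pair_count(sub.n_channels))
                x_train = np.array([csp_features(sub.data[i], bank) for i in train])
                x_test = np.array([csp_features(sub.data[i], bank) for i in test])
            clf = SVC(C=1.0, kernel="rbf", gamma=_median_heuristic_gamma(x_train))
            clf.fit(x_train, labels[train])
            scores.append(float(np.mean(clf.predict(x_test) == labels[test])))
        return float(np.mean(scores))


class SSVEPBackend:
    """CCA frequency-decoding accuracy for a channel subset.

    Labels index into the stimulus frequency list; a trial is correct when
    the argmax canonical correlation lands on its label.
    """

    def __init__(self, epochs: EpochSet, stim: StimulusSpec):
        stim.check_nyquist(epochs.fs)
        n_freqs = len(stim.frequencies)
        if np.any((epochs.labels < 0) | (epochs.labels >= n_freqs)):
            raise ValueError("SSVEP labels must index the stimulus frequencies")
        self.epochs = epochs
        self.stim = stim

    def accuracy(self, mask: np.ndarray) -> float:
        sub = self.epochs.select_mask(mask)
        correct = 0
        for trial, label in zip(sub.data, sub.labels):
            correct += cca_classify(trial, self.stim, sub.fs) == int(label)
        return correct / sub.n_trials


class ObjectiveBackend:
    """Ledger-aware facade over both task backends.

    mar/sar return None (not a number) when the mask is fresh and the
    budget is exhausted; callers drop such individuals. The empty mask
    short-circuits to accuracy 0 without touching the ledger.
    """

    def __init__(self, mi_epochs: EpochSet, ssvep_epochs: EpochSet,
                 stim: StimulusSpec, ledger: EvaluationLedger,
                 n_folds: int = 5, cv_seed: int = 0):
        self.mi = MIBackend(mi_epochs, n_folds=n_folds, cv_seed=cv_seed)
        self.ssvep = SSVEPBackend(ssvep_epochs, stim)
        self.ledger = ledger
        self.n_channels = mi_epochs.n_channels

    def nc(self, mask: np.ndarray) -> int:
        return nc_objective(mask)

    def _evaluate(self, mask: np.ndarray, task: str) -> Optional[float]:
        mask = np.asarray(mask, dtype=np.uint8)
        if mask.sum() == 0:
            return 0.0
        key = (mask.tobytes(), task)
        cached = self.ledger.lookup(key)
        if cached is not None:
            return cached
        if not self.ledger.can_spend():
            return None
        value = (self.mi if task == "mi" else self.ssvep).accuracy(mask)
        self.ledger.charge(key, value)
        return value

    def mar(self, mask: np.ndarray) -> Optional[float]:
        """Motor-imagery accuracy of the subset, or None if out of budget."""
        return self._evaluate(mask, "mi")

    def sar(self, mask: np.ndarray) -> Optional[float]:
        """SSVEP accuracy of the subset, or None if out of budget."""
        return self._evaluate(mask, "ssvep")

    def task_accuracy(self, mask: np.ndarray, task_label: int) -> Optional[float]:
        return self.mar(mask) if task_label == 1 else self.sar(mask)
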