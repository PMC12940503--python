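"""Leakage-safe cross-validation scaffolding.

Genomic feature matrices have many correlated observations per subject
(one row per subject-variant combination).  Folding at the observation
level leaks subject identity across the train/test boundary: a model can
memorize a subject from its training rows and recall that subject's label
on its test rows, inflating apparent accuracy.  The remedy is
subject-stratified folding — every observation of a subject shares one
fold — with all metrics computed at the subject level after averaging
observation probabilities per subject.

The reference classifier is a regularized linear probabilistic model
(scikit-learn logistic regression); any object with ``fit(X, y)`` and
``predict_proba(X)`` is pluggable.  Ties at the 0.5 threshold predict
control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold

from .cohort import CohortError

__all__ = [
    "FoldAssignment",
    "CVReport",
    "default_classifier",
    "subject_stratified_folds",
    "observation_naive_folds",
    "run_cv",
    "subject_bootstrap_ci",
    "leakage_gap_experiment",
    "make_leakage_fixture",
    "REPEAT_SEEDS",
]

# Default repeat seeds for 10x repeated cross-validation.
REPEAT_SEEDS = (42, 123, 456, 789, 1011, 1213, 1415, 1617, 1819, 2021)


def default_classifier() -> LogisticRegression:
    return LogisticRegression(C=10.0, max_iter=5000)


@dataclass
class FoldAssignment:
    k: int
    mode: str  # subject_stratified | observation_naive
    seed: int
    subject_fold: dict[str, int] = field(default_factory=dict)
    observation_fold: Optional[np.ndarray] = None  # naive mode only


@dataclass
class CVReport:
    """Subject-level metrics per repeat/fold plus summaries."""

    per_fold: list[dict] = field(default_factory=list)

    METRICS = ("accuracy", "sensitivity", "specificity", "precision",
               "f1", "auc")

    def summary(self) -> dict[str, tuple[float, float]]:
        out = {}
        for m in self.METRICS:
            vals = np.array([f[m] for f in self.per_fold
                             if f[m] is not None and np.isfinite(f[m])])
            out[m] = ((float(vals.mean()), float(vals.std(ddof=1)))
                      if vals.size > 1 else
                      (float(vals.mean()) if vals.size else float("nan"),
                       float("nan")))
        return out


def subject_stratified_folds(
    subject_ids: Sequence[str],
    labels: Sequence[int],
    k: int = 5,
    seed: int = 42,
) -> FoldAssignment:
    """Partition subjects into k label-stratified folds.

    Every observation of a subject inherits the subject's fold, so no
    individual spans the train/test boundary.  Per-fold class balance is
    within one subject of the global balance; a class with fewer than k
    subjects is an error naming the class.
    """
    subject_ids = list(subject_ids)
    y = np.asarray(labels)
    if k < 2:
        raise CohortError("k must be >= 2")
    if len(subject_ids) != len(set(subject_ids)):
        raise CohortError("subject_ids must be unique")
    for cls in np.unique(y):
        if (y == cls).sum() < k:
            raise CohortError(
                f"class {cls!r} has fewer than k={k} subjects")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment: dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(
            skf.split(np.zeros(len(subject_ids)), y)):
        for i in test_idx:
            assignment[subject_ids[i]] = fold
    return FoldAssignment(k=k, mode="subject_stratified", seed=seed,
                          subject_fold=assignment)


def observation_naive_folds(
    n_observations: int, k: int = 5, seed: int = 42
) -> FoldAssignment:
    """Observation-level folds that ignore subject structure (the leaky
    baseline used only for contrast)."""
    if k < 2:
        raise CohortError("k must be >= 2")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    fold_of = np.empty(n_observations, dtype=int)
    for fold, (_, test_idx) in enumerate(kf.split(np.zeros(n_observations))):
        fold_of[test_idx] = fold
    return FoldAssignment(k=k, mode="observation_naive", seed=seed,
                          observation_fold=fold_of)


def _subject_metrics(
    subj_prob: Mapping[str, float],
    subj_label: Mapping[str, int],
) -> dict:
    ids = sorted(subj_prob)
    y = np.array([subj_label[s] for s in ids])
    prob = np.array([subj_prob[s] for s in ids])
    pred = prob > 0.5  # ties predict control
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    n = len(ids)
    metrics = {
        "accuracy": (tp + tn) / n,
        "sensitivity": tp / (tp + fn) if tp + fn else None,
        "specificity": tn / (tn + fp) if tn + fp else None,
        "precision": tp / (tp + fp) if tp + fp else None,
    }
    prec, sens = metrics["precision"], metrics["sensitivity"]
    metrics["f1"] = (2 * prec * sens / (prec + sens)
                     if prec and sens and (prec + sens) > 0 else None)
    metrics["auc"] = (float(roc_auc_score(y, prob))
                      if 0 < y.sum() < n else None)
    return metrics


def _aggregate_probs(
    probs: np.ndarray, subjects: np.ndarray
) -> dict[str, float]:
    agg: dict[str, list[float]] = {}
    for s, p in zip(subjects, probs):
        agg.setdefault(str(s), []).append(float(p))
    return {s: float(np.mean(v)) for s, v in agg.items()}


def run_cv(
    X: np.ndarray,
    observation_subjects: Sequence[str],
    subject_labels: Mapping[str, int],
    classifier_factory: Callable = default_classifier,
    k: int = 5,
    repeat_seeds: Sequence[int] = REPEAT_SEEDS,
    mode: str = "subject_stratified",
) -> CVReport:
    """Repeated k-fold CV with subject-level metric aggregation.

    Observation-level predicted probabilities are averaged per subject,
    thresholded at 0.5 for the hard metrics, and AUC is computed on the
    subject-level mean probabilities.  A fold whose test set contains only
    one class gets ``None`` for the class-conditional metrics.
    """
    X = np.asarray(X, dtype=float)
    obs_subj = np.asarray(observation_subjects)
    if X.shape[0] != obs_subj.shape[0]:
        raise CohortError("feature rows must align with observation subjects")
    unknown = set(obs_subj) - set(subject_labels)
    if unknown:
        raise CohortError(f"observations reference unknown subjects: "
                          f"{sorted(unknown)[:3]}")
    y_obs = np.array([subject_labels[s] for s in obs_subj])
    subjects = sorted(set(obs_subj))
    subj_y = [subject_labels[s] for s in subjects]

    report = CVReport()
    for repeat, seed in enumerate(repeat_seeds):
        if mode == "subject_stratified":
            folds = subject_stratified_folds(subjects, subj_y, k, seed)
            obs_fold = np.array(
                [folds.subject_fold[s] for s in obs_subj])
        elif mode == "observation_naive":
            folds = observation_naive_folds(X.shape[0], k, seed)
            obs_fold = folds.observation_fold
        else:
            raise CohortError(f"unknown CV mode {mode!r}")
        for fold in range(k):
            test = obs_fold == fold
            clf = classifier_factory()
            clf.fit(X[~test], y_obs[~test])
            probs = clf.predict_proba(X[test])[:, 1]
            subj_prob = _aggregate_probs(probs, obs_subj[test])
            metrics = _subject_metrics(
                subj_prob, {s: subject_labels[s] for s in subj_prob})
            metrics.update(repeat=repeat, seed=seed, fold=fold,
                           n_subjects=len(subj_prob))
            report.per_fold.append(metrics)
    return report


def subject_bootstrap_ci(
    subject_probs: Mapping[str, float],
    subject_labels: Mapping[str, int],
    iterations: int = 1000,
    seed: int = 42,
    level: float = 0.95,
) -> dict[str, tuple[float, float]]:
    """Percentile bootstrap CIs for subject-level metrics.

    Resampling is at the subject level, never the observation level.
    Degenerate resamples containing a single class are redrawn (the count
    is reported under ``"n_redrawn"``).
    """
    ids = sorted(subject_probs)
    if len(ids) < 4:
        raise CohortError("bootstrap needs >= 2 subjects per class")
    y = np.array([subject_labels[s] for s in ids])
    prob = np.array([subject_probs[s] for s in ids])
    if y.min() == y.max():
        raise CohortError("bootstrap needs both classes present")
    rng = np.random.default_rng(seed)
    samples: dict[str, list[float]] = {m: [] for m in CVReport.METRICS}
    n_redrawn = 0
    for _ in range(iterations):
        while True:
            idx = rng.integers(len(ids), size=len(ids))
            if 0 < y[idx].sum() < len(ids):
                break
            n_redrawn += 1
        metrics = _subject_metrics(
            {str(i): prob[j] for i, j in enumerate(idx)},
            {str(i): int(y[j]) for i, j in enumerate(idx)},
        )
        for m in samples:
            if metrics[m] is not None:
                samples[m].append(metrics[m])
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    out: dict = {
        m: (float(np.quantile(v, lo_q)), float(np.quantile(v, hi_q)))
        for m, v in samples.items() if v
    }
    out["n_redrawn"] = n_redrawn
    return out


def make_leakage_fixture(
    n_subjects: int = 40,
    obs_per_subject: int = 8,
    n_features: int = 40,
    center_scale: float = 3.0,
    noise_scale: float = 0.5,
    seed: int = 42,
) -> tuple[np.ndarray, np.ndarray, dict[str, int]]:
    """Subject-confounded features with label-independent structure.

    Each subject gets a private Gaussian feature centroid; observations
    scatter tightly around it.  Labels are assigned per subject at random,
    independent of the features, so any above-chance accuracy can only
    come from subject-identity leakage.
    """
    rng = np.random.default_rng(seed)
    centers = rng.normal(0.0, center_scale, (n_subjects, n_features))
    labels = np.zeros(n_subjects, dtype=int)
    labels[: n_subjects // 2] = 1
    rng.shuffle(labels)
    subj_idx = np.repeat(np.arange(n_subjects), obs_per_subject)
    X = centers[subj_idx] + rng.normal(
        0.0, noise_scale, (n_subjects * obs_per_subject, n_features))
    obs_subjects = np.array([f"S{i:03d}" for i in subj_idx])
    subject_labels = {f"S{i:03d}": int(labels[i])
                      for i in range(n_subjects)}
    return X, obs_subjects, subject_labels


def leakage_gap_experiment(
    X: np.ndarray,
    observation_subjects: Sequence[str],
    subject_labels: Mapping[str, int],
    classifier_factory: Callable = default_classifier,
    k: int = 5,
    repeat_seeds: Sequence[int] = REPEAT_SEEDS,
) -> dict:
    """Accuracy of naive observation-level folds vs grouped folds.

    Returns mean subject-level accuracies under both folding modes and
    their gap (naive minus grouped) with across-repeat SDs.
    """
    naive = run_cv(X, observation_subjects, subject_labels,
                   classifier_factory, k, repeat_seeds,
                   mode="observation_naive")
    grouped = run_cv(X, observation_subjects, subject_labels,
                     classifier_factory, k, repeat_seeds,
                     mode="subject_stratified")
    naive_acc, naive_sd = naive.summary()["accuracy"]
    grouped_acc, grouped_sd = grouped.summary()["accuracy"]
    return {
        "naive_accuracy": naive_acc,
        "naive_sd": naive_sd,
        "grouped_accuracy": grouped_acc,
        "grouped_sd": grouped_sd,
        "gap": naive_acc - grouped_acc,
    }
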