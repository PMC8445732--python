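"""Evaluation machinery: stratified folds, confusion matrices, accuracy,
class-size-weighted accuracy aggregation, and Cohen's kappa.

Class order everywhere is (normal, NPDR, PDR); confusion-matrix rows are the
true grade, columns the predicted grade.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .frames import Grade

__all__ = [
    "stratified_kfold",
    "confusion",
    "accuracy",
    "weighted_accuracy",
    "cohen_kappa",
]


def _as_grades(labels: Sequence) -> list:
    return [Grade(g) for g in labels]


def stratified_kfold(grades: Sequence, k: int = 5, seed: int = 0) -> np.ndarray:
    """Per-sample fold ids in {0..k-1}, stratified by grade.

    Within each grade the samples are randomly permuted (seeded) and dealt
    round-robin to the folds, so per-grade counts across folds differ by at
    most one. Every grade must contribute at least ``k`` samples.
    """
    grades = _as_grades(grades)
    if k < 2:
        raise ValueError("k must be at least 2")
    rng = np.random.default_rng(seed)
    assignments = np.full(len(grades), -1, dtype=int)
    for g in sorted(set(grades), key=lambda x: x.ordinal):
        idx = np.array([i for i, gi in enumerate(grades) if gi == g])
        if len(idx) < k:
            raise ValueError(f"grade {g.value} has {len(idx)} samples, fewer than k={k}")
        perm = rng.permutation(len(idx))
        assignments[idx[perm]] = np.arange(len(idx)) % k
    return assignments


def confusion(true: Sequence, pred: Sequence) -> np.ndarray:
    """3x3 confusion matrix of counts, rows = true grade, cols = predicted."""
    true, pred = _as_grades(true), _as_grades(pred)
    if len(true) != len(pred):
        raise ValueError(f"length mismatch: {len(true)} true vs {len(pred)} predicted")
    cm = np.zeros((3, 3), dtype=int)
    for t, p in zip(true, pred):
        cm[t.ordinal, p.ordinal] += 1
    return cm


def accuracy(cm: np.ndarray) -> float:
    """Overall accuracy: trace over total of a confusion matrix."""
    cm = np.asarray(cm)
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm)) / float(total)


def weighted_accuracy(per_class_acc: Sequence[float], class_counts: Sequence[int]) -> float:
    """Class-size-weighted aggregation of per-class accuracies.

    Per-class correct counts are rounded to the nearest integer before
    summing, mirroring how an integer-valued confusion matrix would hold
    them; the result is the overall accuracy implied by per-class figures.
    """
    acc = np.asarray(per_class_acc, dtype=float)
    counts = np.asarray(class_counts, dtype=float)
    if acc.shape != counts.shape:
        raise ValueError("per_class_acc and class_counts must have equal length")
    if counts.sum() <= 0:
        raise ValueError("total class count must be positive")
    if np.any(counts <= 0):
        raise ValueError("all class counts must be positive")
    correct = np.rint(acc * counts)
    return float(correct.sum() / counts.sum())


def cohen_kappa(cm: np.ndarray) -> float:
    """Chance-corrected agreement: kappa = (p_o - p_e) / (1 - p_e).

    p_o is the observed agreement (trace / N) and p_e the agreement expected
    from the row and column margins alone.
    """
    cm = np.asarray(cm, dtype=float)
    n = cm.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(cm) / n
    p_e = float(np.sum(cm.sum(axis=1) * cm.sum(axis=0)) / n**2)
    if abs(1.0 - p_e) < 1e-12:
        raise ValueError("kappa undefined: expected agreement is 1 (degenerate matrix)")
    return float((p_o - p_e) / (1.0 - p_e))
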