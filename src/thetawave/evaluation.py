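"""Repeated random train/test splits and the study's performance metrics.

Each participant contributes 40 trials; 30 are drawn at random for training
and the remaining 10 for testing, and the draw is repeated (four times by
default) to stabilise the estimate.  Metrics follow the study's printed
definitions, with positive emotion as the "positive" class::

    accuracy    = 100 * (TP + TN) / (TP + FP + TN + FN)
    specificity = 100 * TP / (TP + FP)
    sensitivity = 100 * TN / (TN + FN)

Under standard nomenclature these "specificity"/"sensitivity" formulas are
the positive-class precision and the negative predictive value; they are
implemented verbatim, with the textbook definitions available behind
``standard=True``.  Counts are confusion-tallied per repeat and the metric
percentages averaged across repeats (not pooled), which is pinned by tests
because the pooling order changes the result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .classifiers import NEGATIVE, POSITIVE

__all__ = [
    "SplitPlan",
    "ConfusionCounts",
    "MetricSet",
    "make_splits",
    "confusion",
    "metrics",
    "aggregate",
]

logger = logging.getLogger(__name__)


@dataclass
class SplitPlan:
    """A reproducible set of train/test index pairs over one participant."""

    n_repeats: int
    train_size: int
    test_size: int
    stratified: bool
    seed: int | None
    folds: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = self.train_size + self.test_size
        for train, test in self.folds:
            if len(train) != self.train_size or len(test) != self.test_size:
                raise ValueError("fold sizes disagree with the plan")
            if len(np.intersect1d(train, test)) or len(
                np.union1d(train, test)
            ) != n:
                raise ValueError("train/test must partition the trials")


def _stratified_test_counts(
    class_counts: dict[int, int], test_size: int, n: int
) -> dict[int, int]:
    """Largest-remainder allocation of test slots per class (within +/-1)."""
    quotas = {c: test_size * cnt / n for c, cnt in class_counts.items()}
    base = {c: int(q) for c, q in quotas.items()}
    short = test_size - sum(base.values())
    by_frac = sorted(quotas, key=lambda c: quotas[c] - base[c], reverse=True)
    for c in by_frac[:short]:
        base[c] += 1
    return base


def make_splits(
    n_trials: int,
    labels: Sequence[int],
    n_repeats: int = 4,
    train_size: int = 30,
    test_size: int = 10,
    stratified: bool = True,
    seed: int | None = None,
) -> SplitPlan:
    """Draw ``n_repeats`` independent random train/test partitions.

    Stratified draws keep each fold's class proportions within one trial of
    the overall proportions.  A draw whose training fold contains a single
    class is redrawn from the next seed substream (up to 100 attempts, then
    ``RuntimeError``), since a one-class training set cannot train either
    classifier.
    """
    labels = np.asarray(labels)
    if labels.size != n_trials:
        raise ValueError("labels length must equal n_trials")
    if train_size + test_size != n_trials:
        raise ValueError("train_size + test_size must equal n_trials")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")

    folds: list[tuple[np.ndarray, np.ndarray]] = []
    for rep in range(n_repeats):
        for attempt in range(100):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(rep, attempt))
            )
            if stratified:
                counts = {
                    int(c): int((labels == c).sum()) for c in np.unique(labels)
                }
                test_per_class = _stratified_test_counts(
                    counts, test_size, n_trials
                )
                test_parts = []
                for c, n_test_c in test_per_class.items():
                    idx_c = rng.permutation(np.flatnonzero(labels == c))
                    test_parts.append(idx_c[:n_test_c])
                test = np.sort(np.concatenate(test_parts))
            else:
                perm = rng.permutation(n_trials)
                test = np.sort(perm[:test_size])
            train = np.setdiff1d(np.arange(n_trials), test)
            if len(np.unique(labels[train])) > 1:
                folds.append((train, test))
                break
        else:
            raise RuntimeError(
                f"could not draw a two-class training fold in repeat {rep}"
            )
    return SplitPlan(
        n_repeats=n_repeats,
        train_size=train_size,
        test_size=test_size,
        stratified=stratified,
        seed=seed,
        folds=folds,
    )


@dataclass(frozen=True)
class ConfusionCounts:
    """Two-class decision tally with positive emotion as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionCounts:
    """Tally TP/FP/TN/FN; labels are 1 = positive emotion, 0 = negative."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    return ConfusionCounts(
        tp=int(np.sum((y_true == POSITIVE) & (y_pred == POSITIVE))),
        fp=int(np.sum((y_true == NEGATIVE) & (y_pred == POSITIVE))),
        tn=int(np.sum((y_true == NEGATIVE) & (y_pred == NEGATIVE))),
        fn=int(np.sum((y_true == POSITIVE) & (y_pred == NEGATIVE))),
    )


@dataclass(frozen=True)
class MetricSet:
    """Percentages in [0, 100]; ``None`` marks an undefined ratio (0/0)."""

    accuracy: float | None
    specificity: float | None
    sensitivity: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {
            "accuracy": self.accuracy,
            "specificity": self.specificity,
            "sensitivity": self.sensitivity,
        }


def metrics(c: ConfusionCounts, standard: bool = False) -> MetricSet:
    """Accuracy/specificity/sensitivity percentages from a confusion tally.

    With ``standard=False`` (default) the study's printed formulas are used:
    specificity = TP/(TP+FP), sensitivity = TN/(TN+FN).  ``standard=True``
    switches to the textbook definitions (TN/(TN+FP) and TP/(TP+FN)).
    A ratio with zero denominator is reported as ``None`` rather than 0.
    """
    if c.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")
    accuracy = 100.0 * (c.tp + c.tn) / c.total
    if standard:
        spec_num, spec_den = c.tn, c.tn + c.fp
        sens_num, sens_den = c.tp, c.tp + c.fn
    else:
        spec_num, spec_den = c.tp, c.tp + c.fp
        sens_num, sens_den = c.tn, c.tn + c.fn
    specificity = 100.0 * spec_num / spec_den if spec_den else None
    sensitivity = 100.0 * sens_num / sens_den if sens_den else None
    return MetricSet(accuracy=accuracy, specificity=specificity, sensitivity=sensitivity)


def aggregate(metric_sets: Sequence[MetricSet]) -> MetricSet:
    """Unweighted arithmetic mean per metric over repeats or participants.

    Undefined (``None``) entries are excluded from their metric's mean; the
    number excluded is logged.  An empty input raises ``ValueError``.
    """
    if len(metric_sets) == 0:
        raise ValueError("cannot aggregate an empty collection of metric sets")
    means: dict[str, float | None] = {}
    for name in ("accuracy", "specificity", "sensitivity"):
        vals = [getattr(m, name) for m in metric_sets]
        defined = [v for v in vals if v is not None]
        n_undef = len(vals) - len(defined)
        if n_undef:
            logger.info("aggregate: %d undefined %s value(s) excluded", n_undef, name)
        means[name] = float(np.mean(defined)) if defined else None
    return MetricSet(**means)
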