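"""Wrapper channel selection: rank channels by single-channel accuracy.

Every montage channel is evaluated in isolation: its trials are reduced to
the five theta-band statistics, a classifier (an MLP with a 5 x n_hidden x 2
architecture by default, or kNN) is trained and tested on each repeat of a
split plan, and the channel's score is its mean accuracy across repeats.
Channels are ranked by score — ties broken by montage order — and the top
``n_select`` (five by default) form the selected set whose features are
concatenated downstream.

The procedure is univariate by construction: it measures each channel's
standalone separability, not the joint performance of the selected set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import features as feats
from .classifiers import (
    KNNModel,
    knn_predict,
    mlp_predict,
    mlp_train,
    select_k_loo,
    standardize_apply,
    standardize_fit,
)
from .evaluation import SplitPlan, aggregate, confusion, metrics
from .synthdata import ParticipantDataset

__all__ = ["ChannelRanking", "select_channels", "selection_report", "channel_feature_matrix"]


@dataclass
class ChannelRanking:
    """Per-channel mean accuracies, the descending ranking, and the top set."""

    per_channel_accuracy: dict[str, float]
    ranked: list[str]
    selected: list[str]

    def __post_init__(self) -> None:
        if self.selected != self.ranked[: len(self.selected)]:
            raise ValueError("selected must be the leading slice of ranked")
        if sorted(self.ranked) != sorted(self.per_channel_accuracy):
            raise ValueError("ranking must be a permutation of the scored channels")


def channel_feature_matrix(
    dataset: ParticipantDataset, channel: str, levels: int = 4
) -> np.ndarray:
    """n_trials x 5 matrix of single-channel theta features."""
    return np.vstack(
        [
            feats.extract_trial_features(t, [channel], levels=levels).values
            for t in dataset.trials
        ]
    )


def _fold_accuracy(
    X: np.ndarray,
    labels: np.ndarray,
    train: np.ndarray,
    test: np.ndarray,
    classifier: str,
    n_hidden: int,
    learning_rate: float,
    momentum: float,
    max_epochs: int,
    tol: float,
    seed: int,
    k_grid: tuple[int, ...],
) -> float:
    """Train on one fold (z-scored with training statistics) and test it."""
    mean, sd = standardize_fit(X[train])
    Xtr = standardize_apply(X[train], mean, sd)
    Xte = standardize_apply(X[test], mean, sd)
    if classifier == "mlp":
        model = mlp_train(
            Xtr,
            labels[train],
            n_hidden=n_hidden,
            learning_rate=learning_rate,
            momentum=momentum,
            max_epochs=max_epochs,
            tol=tol,
            seed=seed,
        )
        pred = mlp_predict(model, Xte)
    elif classifier == "knn":
        k = select_k_loo(Xtr, labels[train], k_grid)
        pred = knn_predict(KNNModel(exemplars=Xtr, labels=labels[train], k=k), Xte)
    else:
        raise ValueError(f"unknown classifier {classifier!r}")
    m = metrics(confusion(labels[test], pred))
    return float(m.accuracy)


def select_channels(
    dataset: ParticipantDataset,
    splits: SplitPlan,
    classifier: str = "mlp",
    n_hidden: int = 10,
    learning_rate: float = 0.7,
    momentum: float = 0.9,
    max_epochs: int = 1000,
    tol: float = 1e-3,
    k_grid: tuple[int, ...] = (1, 3),
    n_select: int = 5,
    seed: int | None = None,
    levels: int = 4,
) -> ChannelRanking:
    """Score every channel on the split plan and keep the ``n_select`` best.

    Weight initialisation gets an independent substream per (channel,
    repeat) derived from ``seed``, so the ranking is deterministic given
    dataset + seed.
    """
    montage = list(dataset.montage)
    if n_select > len(montage):
        raise ValueError("n_select exceeds the montage size")
    labels = dataset.labels
    scores: dict[str, float] = {}
    for ci, channel in enumerate(montage):
        X = channel_feature_matrix(dataset, channel, levels=levels)
        accs = []
        for rep, (train, test) in enumerate(splits.folds):
            sub = np.random.SeedSequence(entropy=seed, spawn_key=(ci, rep))
            accs.append(
                _fold_accuracy(
                    X,
                    labels,
                    train,
                    test,
                    classifier,
                    n_hidden,
                    learning_rate,
                    momentum,
                    max_epochs,
                    tol,
                    int(sub.generate_state(1)[0] % 2**31),
                    k_grid,
                )
            )
        scores[channel] = float(np.mean(accs))
    ranked = sorted(montage, key=lambda ch: (-scores[ch], montage.index(ch)))
    return ChannelRanking(
        per_channel_accuracy=scores, ranked=ranked, selected=ranked[:n_select]
    )


def selection_report(ranking: ChannelRanking) -> pd.DataFrame:
    """Tabulate a ranking: channel, mean accuracy, rank, selected flag."""
    rows = [
        {
            "channel": ch,
            "mean_accuracy": ranking.per_channel_accuracy[ch],
            "rank": i + 1,
            "selected": ch in ranking.selected,
        }
        for i, ch in enumerate(ranking.ranked)
    ]
    return pd.DataFrame(rows)
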