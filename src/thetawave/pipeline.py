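"""End-to-end orchestration: selection -> final features -> MLP vs kNN.

Per participant the flow is:

1. draw a split plan and rank all channels by single-channel accuracy
   (wrapper selection, MLP ``5 x n x 2`` by default);
2. build the final feature matrix by concatenating the five theta-band
   statistics over the selected channels (25 inputs for five channels);
3. draw an independent split plan for final evaluation — selection and
   final testing never share random streams, which avoids the optimistic
   bias of reusing the selection folds;
4. pick the hidden-layer size on the training folds only (inner
   validation split, default grid {5, 10, 15, 20}, ties to the smallest),
   and kNN's ``k`` in {1, 3} by leave-one-out on the training folds;
5. train and test both classifiers on the *same* final folds, tally
   confusions per repeat, and average the metric percentages.

Every random draw site (data, splits, weights, shuffles, inner splits)
uses a named substream of the master seed, so any stage can be re-run in
isolation and a full rerun is byte-identical.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

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
from .evaluation import MetricSet, SplitPlan, aggregate, confusion, make_splits, metrics
from .selection import ChannelRanking, select_channels, selection_report
from .synthdata import ParticipantDataset, SynthConfig, cohort_configs, generate_participant

__all__ = [
    "RunConfig",
    "ParticipantResult",
    "CohortResult",
    "run_participant",
    "run_cohort",
    "run_synthetic_cohort",
    "write_reports",
]

# named substreams of the master seed (one axis of the spawn key)
_STREAM_SELECTION_SPLITS = 0
_STREAM_SELECTION_WEIGHTS = 1
_STREAM_FINAL_SPLITS = 2
_STREAM_INNER_VALIDATION = 3
_STREAM_FINAL_WEIGHTS = 4


@dataclass(frozen=True)
class RunConfig:
    """Everything the pipeline needs besides the data itself."""

    n_repeats: int = 4
    train_size: int = 30
    test_size: int = 10
    stratified: bool = True
    n_select: int = 5
    selection_classifier: str = "mlp"
    selection_hidden: int = 10
    hidden_grid: tuple[int, ...] = (5, 10, 15, 20)
    k_grid: tuple[int, ...] = (1, 3)
    learning_rate: float = 0.7
    momentum: float = 0.9
    max_epochs: int = 1000
    tol: float = 1e-3
    levels: int = 4
    fixed_channels: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.n_select < 1:
            raise ValueError("n_select must be >= 1")


def _substream(master: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=master, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % 2**31)


def _fold_hash(splits: SplitPlan) -> str:
    h = hashlib.sha256()
    for train, test in splits.folds:
        h.update(np.asarray(train, dtype=np.int64).tobytes())
        h.update(np.asarray(test, dtype=np.int64).tobytes())
    return h.hexdigest()[:16]


@dataclass
class ParticipantResult:
    participant_id: str
    ranking: ChannelRanking
    selected: list[str]
    hidden_size: int
    k: int
    mlp_per_repeat: list[MetricSet]
    knn_per_repeat: list[MetricSet]
    mlp_mean: MetricSet
    knn_mean: MetricSet
    fold_hash_mlp: str
    fold_hash_knn: str


def _final_feature_matrix(
    dataset: ParticipantDataset, channels: Sequence[str], levels: int
) -> np.ndarray:
    return np.vstack(
        [
            feats.extract_trial_features(t, channels, levels=levels).values
            for t in dataset.trials
        ]
    )


def _inner_validation_split(
    train_idx: np.ndarray, labels: np.ndarray, seed: int, frac: float = 0.2
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified split of one training fold into fit and validation parts."""
    rng = np.random.default_rng(seed)
    val_parts = []
    for c in np.unique(labels[train_idx]):
        idx_c = train_idx[labels[train_idx] == c]
        n_val = max(1, round(frac * idx_c.size))
        val_parts.append(rng.permutation(idx_c)[:n_val])
    val = np.sort(np.concatenate(val_parts))
    fit = np.setdiff1d(train_idx, val)
    return fit, val


def _choose_hidden_size(
    X: np.ndarray,
    labels: np.ndarray,
    splits: SplitPlan,
    config: RunConfig,
    master_seed: int,
    participant_index: int,
) -> int:
    """Mean inner-validation accuracy per grid size; ties to the smallest."""
    mean_acc: dict[int, float] = {}
    for n_hidden in config.hidden_grid:
        accs = []
        for rep, (train, _) in enumerate(splits.folds):
            seed = _substream(
                master_seed, _STREAM_INNER_VALIDATION, participant_index, rep, n_hidden
            )
            fit, val = _inner_validation_split(train, labels, seed)
            mean, sd = standardize_fit(X[fit])
            model = mlp_train(
                standardize_apply(X[fit], mean, sd),
                labels[fit],
                n_hidden=n_hidden,
                learning_rate=config.learning_rate,
                momentum=config.momentum,
                max_epochs=config.max_epochs,
                tol=config.tol,
                seed=seed,
            )
            pred = mlp_predict(model, standardize_apply(X[val], mean, sd))
            accs.append(float(np.mean(pred == labels[val])))
        mean_acc[n_hidden] = float(np.mean(accs))
    best = max(mean_acc.values())
    return min(n for n, a in mean_acc.items() if a == best)


def run_participant(
    dataset: ParticipantDataset, config: RunConfig, participant_index: int = 0
) -> ParticipantResult:
    """Run selection, final feature formation and both classifiers.

    ``participant_index`` separates the seed substreams of cohort members.
    With ``config.fixed_channels`` set, selection is skipped in favour of
    that channel set (the ranking is still computed for the report).
    """
    labels = dataset.labels
    n = dataset.n_trials

    sel_splits = make_splits(
        n,
        labels,
        n_repeats=config.n_repeats,
        train_size=config.train_size,
        test_size=config.test_size,
        stratified=config.stratified,
        seed=_substream(config.seed, _STREAM_SELECTION_SPLITS, participant_index),
    )
    ranking = select_channels(
        dataset,
        sel_splits,
        classifier=config.selection_classifier,
        n_hidden=config.selection_hidden,
        learning_rate=config.learning_rate,
        momentum=config.momentum,
        max_epochs=config.max_epochs,
        tol=config.tol,
        k_grid=config.k_grid,
        n_select=config.n_select,
        seed=_substream(config.seed, _STREAM_SELECTION_WEIGHTS, participant_index),
        levels=config.levels,
    )
    channels = (
        list(config.fixed_channels) if config.fixed_channels else ranking.selected
    )

    X = _final_feature_matrix(dataset, channels, config.levels)
    final_splits = make_splits(
        n,
        labels,
        n_repeats=config.n_repeats,
        train_size=config.train_size,
        test_size=config.test_size,
        stratified=config.stratified,
        seed=_substream(config.seed, _STREAM_FINAL_SPLITS, participant_index),
    )

    hidden_size = _choose_hidden_size(
        X, labels, final_splits, config, config.seed, participant_index
    )

    loo_acc = {k: [] for k in config.k_grid}
    mlp_sets: list[MetricSet] = []
    knn_sets: list[MetricSet] = []
    fold_Z: list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = []
    for rep, (train, test) in enumerate(final_splits.folds):
        mean, sd = standardize_fit(X[train])
        Ztr = standardize_apply(X[train], mean, sd)
        Zte = standardize_apply(X[test], mean, sd)
        fold_Z.append((Ztr, Zte, train, test))
        model = mlp_train(
            Ztr,
            labels[train],
            n_hidden=hidden_size,
            learning_rate=config.learning_rate,
            momentum=config.momentum,
            max_epochs=config.max_epochs,
            tol=config.tol,
            seed=_substream(config.seed, _STREAM_FINAL_WEIGHTS, participant_index, rep),
        )
        mlp_sets.append(metrics(confusion(labels[test], mlp_predict(model, Zte))))
        for k in config.k_grid:
            correct = 0
            for i in range(len(train)):
                keep = np.arange(len(train)) != i
                sub = KNNModel(exemplars=Ztr[keep], labels=labels[train][keep], k=k)
                if knn_predict(sub, Ztr[i]) == labels[train][i]:
                    correct += 1
            loo_acc[k].append(correct / len(train))

    best_loo = max(float(np.mean(v)) for v in loo_acc.values())
    k = min(kk for kk, v in loo_acc.items() if float(np.mean(v)) == best_loo)
    for Ztr, Zte, train, test in fold_Z:
        knn = KNNModel(exemplars=Ztr, labels=labels[train], k=k)
        knn_sets.append(metrics(confusion(labels[test], knn_predict(knn, Zte))))

    return ParticipantResult(
        participant_id=dataset.participant_id,
        ranking=ranking,
        selected=channels,
        hidden_size=hidden_size,
        k=k,
        mlp_per_repeat=mlp_sets,
        knn_per_repeat=knn_sets,
        mlp_mean=aggregate(mlp_sets),
        knn_mean=aggregate(knn_sets),
        fold_hash_mlp=_fold_hash(final_splits),
        fold_hash_knn=_fold_hash(final_splits),
    )


@dataclass
class CohortResult:
    participants: list[ParticipantResult]
    mlp_report: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    knn_report: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    summary: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.participants:
            raise ValueError("cohort result needs at least one participant")
        self.mlp_report = _classifier_report(self.participants, "mlp_mean")
        self.knn_report = _classifier_report(self.participants, "knn_mean")
        self.summary = pd.DataFrame(
            [
                {"classifier": "MLPNN", **_average_row(self.mlp_report)},
                {"classifier": "kNN", **_average_row(self.knn_report)},
            ]
        )


def _classifier_report(
    participants: list[ParticipantResult], attr: str
) -> pd.DataFrame:
    rows = []
    for p in participants:
        m: MetricSet = getattr(p, attr)
        rows.append(
            {
                "participant": p.participant_id,
                "accuracy": m.accuracy,
                "specificity": m.specificity,
                "sensitivity": m.sensitivity,
            }
        )
    frame = pd.DataFrame(rows)
    avg = {"participant": "Average", **_average_row(frame)}
    return pd.concat([frame, pd.DataFrame([avg])], ignore_index=True)


def _average_row(frame: pd.DataFrame) -> dict[str, float]:
    body = frame[frame.get("participant", pd.Series(dtype=str)) != "Average"] if "participant" in frame else frame
    return {
        name: float(body[name].mean())
        for name in ("accuracy", "specificity", "sensitivity")
    }


def run_cohort(
    cohort: Iterable[ParticipantDataset], config: RunConfig
) -> CohortResult:
    """Run every participant and assemble per-classifier report tables.

    Each table has one row per participant plus an ``Average`` row that is
    the arithmetic mean of its column.
    """
    results = [
        run_participant(ds, config, participant_index=i)
        for i, ds in enumerate(cohort)
    ]
    if not results:
        raise ValueError("cohort must contain at least one participant")
    return CohortResult(participants=results)


def run_synthetic_cohort(
    synth_config: SynthConfig, n_participants: int, config: RunConfig
) -> CohortResult:
    """Generate and process a synthetic cohort one participant at a time.

    Streaming keeps only one participant's raw EEG in memory; the datasets
    are exactly those :func:`thetawave.synthdata.generate_cohort` yields.
    """
    results = []
    for i, (pid, cfg) in enumerate(
        cohort_configs(synth_config, n_participants)
    ):
        ds = generate_participant(cfg)
        ds.participant_id = pid
        results.append(run_participant(ds, config, participant_index=i))
    return CohortResult(participants=results)


def report_text(frame: pd.DataFrame) -> str:
    """Render a report table as TSV with values rounded to one decimal."""
    out = frame.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].round(1)
    return out.to_csv(sep="\t", index=False)


def write_reports(result: CohortResult, out_dir: str | Path) -> None:
    """Write ranking, per-classifier and summary TSVs under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for p in result.participants:
        selection_report(p.ranking).to_csv(
            out_dir / f"ranking_{p.participant_id}.tsv", sep="\t", index=False
        )
    (out_dir / "mlp_report.tsv").write_text(report_text(result.mlp_report))
    (out_dir / "knn_report.tsv").write_text(report_text(result.knn_report))
    (out_dir / "summary.tsv").write_text(report_text(result.summary))
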