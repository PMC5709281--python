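"""Portable on-disk dataset format: JSON manifest plus per-trial CSV matrices.

A dataset directory contains ``manifest.json`` with the participant id,
sampling rate, montage, ordered trial file names and valence ratings, and
one CSV per trial whose rows are channels (montage order) and columns are
samples.  Values are written with 17 significant digits, so a write/read
cycle reproduces the matrices to double precision.  Labels are never
stored: they are re-derived from the ratings on read (rating < 5 negative,
else positive).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .synthdata import (
    ParticipantDataset,
    TrialRecording,
    label_from_rating,
)

__all__ = ["MANIFEST_NAME", "DatasetManifest", "write_dataset", "read_dataset", "validate_dataset"]

MANIFEST_NAME = "manifest.json"


@dataclass(frozen=True)
class DatasetManifest:
    participant_id: str
    fs: float
    montage: tuple[str, ...]
    trial_files: tuple[str, ...]
    valence_ratings: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.trial_files) != len(self.valence_ratings):
            raise ValueError("trial_files and valence_ratings disagree in length")
        if len(self.trial_files) == 0:
            raise ValueError("a dataset must contain at least one trial")
        for r in self.valence_ratings:
            label_from_rating(r)  # range check


def write_dataset(dataset: ParticipantDataset, directory: str | Path) -> DatasetManifest:
    """Write ``dataset`` to ``directory`` and return the manifest.

    One ``trial_NNN.csv`` per trial plus ``manifest.json``.  The directory
    is created if needed; an unwritable path raises ``OSError``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    trial_files = []
    for i, trial in enumerate(dataset.trials):
        name = f"trial_{i:03d}.csv"
        np.savetxt(directory / name, trial.data, fmt="%.17g", delimiter=",")
        trial_files.append(name)
    manifest = DatasetManifest(
        participant_id=dataset.participant_id,
        fs=dataset.fs,
        montage=tuple(dataset.montage),
        trial_files=tuple(trial_files),
        valence_ratings=tuple(float(r) for r in dataset.ratings),
    )
    with open(directory / MANIFEST_NAME, "w", encoding="utf-8") as fh:
        json.dump(asdict(manifest), fh, indent=1)
    return manifest


def read_manifest(directory: str | Path) -> DatasetManifest:
    directory = Path(directory)
    path = directory / MANIFEST_NAME
    if not path.exists():
        raise FileNotFoundError(f"no {MANIFEST_NAME} in {directory}")
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    return DatasetManifest(
        participant_id=raw["participant_id"],
        fs=float(raw["fs"]),
        montage=tuple(raw["montage"]),
        trial_files=tuple(raw["trial_files"]),
        valence_ratings=tuple(float(r) for r in raw["valence_ratings"]),
    )


def read_dataset(directory: str | Path) -> ParticipantDataset:
    """Read a dataset directory back into memory.

    Labels are derived from the stored ratings by the strict rule (below 5
    negative, else positive).  A trial matrix whose row count disagrees
    with the montage raises ``ValueError``; a rating outside [1, 9] fails
    validation inside the manifest.
    """
    directory = Path(directory)
    manifest = read_manifest(directory)
    trials = []
    for i, (name, rating) in enumerate(
        zip(manifest.trial_files, manifest.valence_ratings)
    ):
        data = np.loadtxt(directory / name, delimiter=",", ndmin=2)
        if data.shape[0] != len(manifest.montage):
            raise ValueError(
                f"{name}: {data.shape[0]} rows but montage has "
                f"{len(manifest.montage)} channels"
            )
        trials.append(
            TrialRecording(
                trial_id=i,
                data=data,
                fs=manifest.fs,
                valence_rating=rating,
                label=label_from_rating(rating),
                montage=manifest.montage,
            )
        )
    return ParticipantDataset(
        participant_id=manifest.participant_id,
        montage=manifest.montage,
        trials=trials,
    )


def validate_dataset(directory: str | Path) -> list[str]:
    """Check a dataset directory; returns a list of problems (empty if valid)."""
    problems: list[str] = []
    try:
        read_dataset(directory)
    except (OSError, ValueError, KeyError, json.JSONDecodeError) as exc:
        problems.append(str(exc))
    return problems
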