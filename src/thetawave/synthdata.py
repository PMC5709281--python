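"""Synthetic multichannel EEG with a class-dependent theta-band effect.

The generator emulates the structure of a preprocessed affective-EEG study:
per participant, 40 fixed-length trials of 32-channel EEG at 128 Hz, each
with a valence rating on a 1-9 scale (rating < 5 labels the trial
negative, otherwise positive).  Every channel carries 1/f-shaped broadband
noise — white noise integrated by cumulative sum, then band-passed to
4-45 Hz, matching the band limits of the emulated recordings — scaled to a
configurable standard deviation.  A chosen subset of "informative" channels
additionally carries a theta oscillation ``A * sin(2*pi*f*t + phi)`` with
``f ~ U(4, 8)`` Hz and random phase, whose amplitude ``A`` depends on the
trial's valence class.  That planted amplitude difference is the only
class signal: channels outside the informative set are exchangeable noise.

Defaults are the strong-effect study condition used throughout the test
suite: positive-trial amplitude 4 uV, negative 1 uV, noise SD 2 uV, with
the effect planted in channels P3, FC2, AF3, O1 and Fp1.

Everything is driven by a single integer seed; identical configurations
produce bit-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .classifiers import NEGATIVE, POSITIVE

__all__ = [
    "MONTAGE_32",
    "SynthConfig",
    "TrialRecording",
    "ParticipantDataset",
    "label_from_rating",
    "generate_participant",
    "generate_cohort",
]

# 32-channel international 10-20 montage (the layout of the emulated
# recordings); only the five default informative channels are significant
# to the method, the remaining names are a configuration default.
MONTAGE_32 = (
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7",
    "CP5", "CP1", "P3", "P7", "PO3", "O1", "Oz", "Pz",
    "Fp2", "AF4", "Fz", "F4", "F8", "FC6", "FC2", "Cz",
    "C4", "T8", "CP6", "CP2", "P4", "P8", "PO4", "O2",
)

RATING_THRESHOLD = 5.0


def label_from_rating(rating: float) -> int:
    """Binarize a valence rating: strictly below 5 is negative, else positive."""
    if not 1.0 <= rating <= 9.0:
        raise ValueError(f"valence rating {rating} outside the 9-point scale [1, 9]")
    return NEGATIVE if rating < RATING_THRESHOLD else POSITIVE


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters; defaults are the strong-effect study condition."""

    n_channels: int = 32
    fs: float = 128.0
    segment_seconds: float = 63.0
    n_trials: int = 40
    montage: tuple[str, ...] = MONTAGE_32
    informative_channels: tuple[str, ...] = ("P3", "FC2", "AF3", "O1", "Fp1")
    theta_amp_pos: float = 4.0
    theta_amp_neg: float = 1.0
    background_sd: float = 2.0
    rating_threshold: float = RATING_THRESHOLD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        n_samples = self.segment_seconds * self.fs
        if abs(n_samples - round(n_samples)) > 1e-9:
            raise ValueError("segment_seconds * fs must be an integer sample count")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.n_channels != len(self.montage):
            raise ValueError("n_channels must equal the montage length")
        if len(set(self.montage)) != len(self.montage):
            raise ValueError("montage names must be unique")
        if self.theta_amp_pos <= 0 or self.theta_amp_neg <= 0:
            raise ValueError("theta amplitudes must be positive")
        if self.background_sd <= 0:
            raise ValueError("background_sd must be positive")
        if self.rating_threshold != RATING_THRESHOLD:
            raise ValueError("the valence cut is fixed at 5")
        missing = set(self.informative_channels) - set(self.montage)
        if missing:
            raise LookupError(f"informative channels not in montage: {sorted(missing)}")

    @property
    def n_samples(self) -> int:
        return round(self.segment_seconds * self.fs)


@dataclass
class TrialRecording:
    """One stimulus presentation: channels x samples (uV) plus its rating.

    ``montage`` names the rows of ``data``; the label follows the strict
    "rating < 5 is negative" rule and is validated against the rating.
    """

    trial_id: int
    data: np.ndarray
    fs: float
    valence_rating: float
    label: int
    montage: tuple[str, ...] = MONTAGE_32

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.montage):
            raise ValueError("data must be a channels x samples matrix")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("trial data contains non-finite values")
        if self.label != label_from_rating(self.valence_rating):
            raise ValueError(
                f"label {self.label} inconsistent with rating {self.valence_rating}"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.data[self.montage.index(name)]
        except ValueError:
            raise LookupError(f"channel {name!r} not in montage") from None


@dataclass
class ParticipantDataset:
    """All trials of one participant, sharing montage and sampling rate."""

    participant_id: str
    montage: tuple[str, ...]
    trials: list[TrialRecording] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.montage)) != len(self.montage):
            raise ValueError("montage names must be unique")
        if not self.trials:
            raise ValueError("a dataset must contain at least one trial")
        fs0 = self.trials[0].fs
        n0 = self.trials[0].n_samples
        for t in self.trials:
            if t.fs != fs0 or t.n_samples != n0:
                raise ValueError("all trials must share fs and n_samples")
            if tuple(t.montage) != tuple(self.montage):
                raise ValueError("all trials must share the dataset montage")

    @property
    def fs(self) -> float:
        return self.trials[0].fs

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def labels(self) -> np.ndarray:
        return np.array([t.label for t in self.trials])

    @property
    def ratings(self) -> np.ndarray:
        return np.array([t.valence_rating for t in self.trials])


def _background_noise(
    rng: np.random.Generator, shape: tuple[int, int], fs: float, sd: float
) -> np.ndarray:
    """1/f-shaped noise: integrated white noise, band-passed to 4-45 Hz.

    The cumulative sum steepens the spectrum toward low frequencies and the
    band-pass removes the drift below 4 Hz, mirroring the band limits of
    the emulated preprocessed recordings.  Each channel is rescaled to the
    requested standard deviation.
    """
    white = rng.standard_normal(shape)
    brown = np.cumsum(white, axis=1)
    sos = sps.butter(4, (4.0, 45.0), btype="bandpass", fs=fs, output="sos")
    shaped = sps.sosfiltfilt(sos, brown, axis=1)
    scale = shaped.std(axis=1, keepdims=True)
    scale[scale == 0.0] = 1.0
    return shaped * (sd / scale)


def generate_participant(config: SynthConfig) -> ParticipantDataset:
    """Generate one participant's dataset from a validated configuration.

    Classes are balanced (n_trials // 2 positive) and shuffled; ratings are
    drawn uniformly from [5.5, 9] for positive trials and [1, 4.5] for
    negative ones, so no rating sits on the ambiguous cut at 5.  The theta
    frequency and phase are redrawn per informative channel and trial,
    preventing a classifier from keying on a single spectral line.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n = config.n_samples
    t = np.arange(n) / config.fs
    informative_rows = [config.montage.index(c) for c in config.informative_channels]

    n_pos = config.n_trials // 2
    classes = np.array(
        [POSITIVE] * n_pos + [NEGATIVE] * (config.n_trials - n_pos)
    )
    rng.shuffle(classes)

    trials: list[TrialRecording] = []
    for trial_id, cls in enumerate(classes):
        rating = (
            rng.uniform(5.5, 9.0) if cls == POSITIVE else rng.uniform(1.0, 4.5)
        )
        data = _background_noise(
            rng, (config.n_channels, n), config.fs, config.background_sd
        )
        amp = config.theta_amp_pos if cls == POSITIVE else config.theta_amp_neg
        for row in informative_rows:
            f = rng.uniform(4.0, 8.0)
            phi = rng.uniform(0.0, 2.0 * np.pi)
            data[row] += amp * np.sin(2.0 * np.pi * f * t + phi)
        trials.append(
            TrialRecording(
                trial_id=trial_id,
                data=data,
                fs=config.fs,
                valence_rating=float(rating),
                label=int(cls),
                montage=config.montage,
            )
        )
    return ParticipantDataset(
        participant_id=f"synthetic-{config.seed}",
        montage=config.montage,
        trials=trials,
    )


def participant_seeds(master_seed: int, n_participants: int) -> np.ndarray:
    """Deterministic per-participant seeds derived from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return ss.generate_state(n_participants, dtype=np.uint32) % np.uint32(2**31)


def generate_cohort(
    config: SynthConfig, n_participants: int, seed: int | None = None
) -> list[ParticipantDataset]:
    """Generate ``n_participants`` independent datasets from a master seed.

    Each participant gets a seed derived deterministically from
    ``seed`` (defaulting to ``config.seed``) and a distinct id ``S01..``.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    master = config.seed if seed is None else seed
    cohort = []
    for i, child_seed in enumerate(participant_seeds(master, n_participants)):
        ds = generate_participant(replace(config, seed=int(child_seed)))
        ds.participant_id = f"S{i + 1:02d}"
        cohort.append(ds)
    return cohort


def cohort_configs(
    config: SynthConfig, n_participants: int, seed: int | None = None
) -> list[tuple[str, SynthConfig]]:
    """(participant_id, per-participant config) pairs without generating data.

    Lets callers stream large cohorts one participant at a time while
    producing exactly the datasets :func:`generate_cohort` would.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    master = config.seed if seed is None else seed
    return [
        (f"S{i + 1:02d}", replace(config, seed=int(child_seed)))
        for i, child_seed in enumerate(participant_seeds(master, n_participants))
    ]
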