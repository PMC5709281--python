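"""Statistical features of theta-band wavelet coefficients.

Each channel's level-4 detail band (cD4, 4-8 Hz at 128 Hz sampling) is
reduced to five statistics, in this fixed order:

1. ``max_abs``   — maximum of the absolute coefficient values
2. ``mean_abs``  — mean of the absolute coefficient values
3. ``std``       — sample standard deviation (n-1 denominator)
4. ``avg_power`` — mean of the squared coefficients
5. ``avg_energy``— sum of the squared coefficients

With a fixed-length coefficient vector, ``avg_energy`` is exactly
``len(coeffs) * avg_power``; both are kept because downstream models use the
full five-statistic set.  Concatenating the five statistics over the five
selected channels gives the 25-dimensional final feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .wavelets import WaveletFilterPair, wavedec

if TYPE_CHECKING:  # pragma: no cover
    from .synthdata import TrialRecording

__all__ = ["FEATURE_NAMES", "FeatureVector", "theta_features", "extract_trial_features"]

FEATURE_NAMES = ("max_abs", "mean_abs", "std", "avg_power", "avg_energy")


@dataclass(frozen=True)
class FeatureVector:
    """Ordered feature values with the channel order that produced them.

    ``values`` holds one 5-block per channel, channels in ``channel_order``;
    permuting the requested channels permutes the 5-blocks accordingly.
    """

    values: np.ndarray
    channel_order: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "channel_order", tuple(self.channel_order))
        if self.values.size != 5 * len(self.channel_order):
            raise ValueError(
                f"expected {5 * len(self.channel_order)} values for "
                f"{len(self.channel_order)} channels, got {self.values.size}"
            )

    def __len__(self) -> int:
        return self.values.size

    def block(self, channel: str) -> np.ndarray:
        """The 5-statistic block belonging to ``channel``."""
        i = self.channel_order.index(channel)
        return self.values[5 * i : 5 * i + 5]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(
            f"{ch}_{stat}" for ch in self.channel_order for stat in FEATURE_NAMES
        )


def theta_features(coeffs: np.ndarray) -> np.ndarray:
    """Reduce one coefficient vector to the five statistics listed above.

    Requires at least two finite coefficients (the sample standard deviation
    needs n >= 2); violations raise ``ValueError``.
    """
    c = np.asarray(coeffs, dtype=float)
    if c.ndim != 1 or c.size < 2:
        raise ValueError("coefficient vector must be 1-D with length >= 2")
    if not np.all(np.isfinite(c)):
        raise ValueError("coefficient vector contains non-finite values")
    absc = np.abs(c)
    sq = c * c
    return np.array(
        [absc.max(), absc.mean(), c.std(ddof=1), sq.mean(), sq.sum()]
    )


def extract_trial_features(
    trial: "TrialRecording",
    channels: Sequence[str],
    levels: int = 4,
    filters: WaveletFilterPair | None = None,
    mode: str = "symmetric",
) -> FeatureVector:
    """Per-channel DWT -> deepest detail band -> five statistics, concatenated.

    ``channels`` are taken in the given order and must be distinct members of
    the trial's montage; duplicates or unknown names raise ``LookupError``.
    One channel yields a length-5 vector, five channels the 25-dimensional
    final feature vector.
    """
    channels = list(channels)
    if len(set(channels)) != len(channels):
        raise LookupError(f"duplicate channels in request: {channels}")
    montage = list(trial.montage)
    blocks = []
    for name in channels:
        try:
            row = montage.index(name)
        except ValueError:
            raise LookupError(f"channel {name!r} not in montage") from None
        dec = wavedec(trial.data[row], filters=filters, levels=levels, mode=mode)
        blocks.append(theta_features(dec.details[-1]))
    return FeatureVector(values=np.concatenate(blocks), channel_order=tuple(channels))
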