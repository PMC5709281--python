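"""Multilevel discrete wavelet transform with the Daubechies-2 (db2) filter pair.

The transform is a dyadic two-channel filter bank: each level convolves the
current approximation with a low-pass filter ``h`` and its quadrature-mirror
high-pass ``g`` and keeps every second output sample, producing an
approximation and a detail sub-band.  Cascading four levels on a 128 Hz
signal places the fourth detail band (cD4) on 4-8 Hz, the EEG theta band.

Two boundary-extension modes are provided:

``symmetric``
    Half-sample symmetric reflection (``... x1 x0 | x0 x1 ...``).  Each level
    maps a length-``L`` input to ``floor((L + 3) / 2)`` coefficients, so an
    8064-sample segment yields 4033, 2018, 1010 and finally 506 cD4
    coefficients.
``periodic``
    Circular extension (periodization).  Each level halves the length
    (odd inputs are padded by repeating the final sample) and the filter
    bank is exactly orthonormal, conserving signal energy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WaveletFilterPair",
    "DecompositionResult",
    "db2_filters",
    "dwt_single_level",
    "idwt_single_level",
    "wavedec",
    "waverec",
    "subband_ranges",
]

_MODES = ("symmetric", "periodic")


@dataclass(frozen=True)
class WaveletFilterPair:
    """Analysis low-pass taps ``h`` and the quadrature-mirror high-pass ``g``.

    The taps satisfy ``g[n] = (-1)^n * h[L-1-n]``, ``sum(h) = sqrt(2)``,
    ``sum(g) = 0`` and ``sum(h**2) = 1`` (orthonormal two-channel bank).
    """

    h: np.ndarray
    g: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "h", np.asarray(self.h, dtype=float))
        object.__setattr__(self, "g", np.asarray(self.g, dtype=float))
        if self.h.shape != self.g.shape or self.h.ndim != 1:
            raise ValueError("h and g must be 1-D arrays of equal length")

    def __len__(self) -> int:
        return self.h.size


def db2_filters() -> WaveletFilterPair:
    """Return the Daubechies order-2 analysis filter pair in natural order.

    ``h = [(1+s3), (3+s3), (3-s3), (1-s3)] / (4*sqrt(2))`` with
    ``s3 = sqrt(3)``; ``g`` follows from the quadrature-mirror relation.
    db2 has two vanishing moments, so detail coefficients of affine signals
    vanish away from the boundaries.
    """
    s2 = math.sqrt(2.0)
    s3 = math.sqrt(3.0)
    h = np.array([1.0 + s3, 3.0 + s3, 3.0 - s3, 1.0 - s3]) / (4.0 * s2)
    g = ((-1.0) ** np.arange(4)) * h[::-1]
    return WaveletFilterPair(h=h, g=g)


@dataclass
class DecompositionResult:
    """Output of :func:`wavedec`: final approximation plus details cD1..cDL.

    ``details[0]`` is cD1, the highest-frequency half band; ``details[-1]``
    is the deepest (lowest-frequency) detail band.
    """

    levels: int
    approx: np.ndarray
    details: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.details) != self.levels:
            raise ValueError(
                f"expected {self.levels} detail bands, got {len(self.details)}"
            )

    @property
    def cD4(self) -> np.ndarray:
        """The level-4 detail band (theta band for 128 Hz input)."""
        if self.levels < 4:
            raise ValueError("decomposition has fewer than 4 levels")
        return self.details[3]


def _check_mode(mode: str) -> None:
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}, got {mode!r}")


def symmetric_output_len(n: int) -> int:
    """Per-level output length in symmetric mode: ``floor((n + 3) / 2)``."""
    return (n + 3) // 2


def periodic_output_len(n: int) -> int:
    """Per-level output length in periodic mode: ``ceil(n / 2)``."""
    return (n + 1) // 2


def dwt_single_level(
    x: np.ndarray,
    filters: WaveletFilterPair | None = None,
    mode: str = "symmetric",
) -> tuple[np.ndarray, np.ndarray]:
    """One analysis step: boundary-extend, filter with (h, g), downsample by 2.

    Returns ``(approx, detail)``.  Raises ``ValueError`` for signals shorter
    than the filter or for an unknown extension mode.
    """
    _check_mode(mode)
    if filters is None:
        filters = db2_filters()
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    flen = len(filters)
    if x.size < flen:
        raise ValueError(f"signal length {x.size} shorter than filter length {flen}")

    if mode == "symmetric":
        ext = np.concatenate([x[: flen - 1][::-1], x, x[-(flen - 1) :][::-1]])
        approx = np.correlate(ext, filters.h, mode="valid")[1::2]
        detail = np.correlate(ext, filters.g, mode="valid")[1::2]
    else:  # periodic
        if x.size % 2:
            x = np.concatenate([x, x[-1:]])
        ext = np.concatenate([x[-1:], x, x[:2]])
        approx = np.correlate(ext, filters.h, mode="valid")[::2]
        detail = np.correlate(ext, filters.g, mode="valid")[::2]
    return approx, detail


def idwt_single_level(
    approx: np.ndarray,
    detail: np.ndarray,
    filters: WaveletFilterPair | None = None,
    mode: str = "symmetric",
    original_length: int | None = None,
) -> np.ndarray:
    """Invert one analysis step (upsample, filter with synthesis pair, sum).

    For orthonormal filters the synthesis pair is (h, g) again.
    ``original_length`` selects among the lengths consistent with the
    coefficient count; a request off by more than one sample raises
    ``ValueError``.
    """
    _check_mode(mode)
    if filters is None:
        filters = db2_filters()
    approx = np.asarray(approx, dtype=float)
    detail = np.asarray(detail, dtype=float)
    if approx.shape != detail.shape or approx.ndim != 1:
        raise ValueError("approx and detail must be 1-D arrays of equal length")
    n = approx.size
    flen = len(filters)
    if n < flen // 2:
        raise ValueError("too few coefficients to invert")

    up_a = np.zeros(2 * n)
    up_a[::2] = approx
    up_d = np.zeros(2 * n)
    up_d[::2] = detail
    full = np.convolve(up_a, filters.h) + np.convolve(up_d, filters.g)

    if mode == "symmetric":
        natural = 2 * n - flen + 2  # length of the untrimmed reconstruction
        if original_length is None:
            original_length = natural
        if not natural - 1 <= original_length <= natural:
            raise ValueError(
                f"original_length {original_length} inconsistent with "
                f"{n} coefficients (expected {natural - 1} or {natural})"
            )
        return full[flen - 2 : flen - 2 + original_length]
    # periodic: wrap the convolution tail and realign
    wrapped = full[: 2 * n].copy()
    wrapped[: flen - 1] += full[2 * n :]
    out = np.roll(wrapped, -1)
    if original_length is None:
        original_length = 2 * n
    if not 2 * n - 1 <= original_length <= 2 * n:
        raise ValueError(
            f"original_length {original_length} inconsistent with "
            f"{n} coefficients (expected {2 * n - 1} or {2 * n})"
        )
    return out[:original_length]


def wavedec(
    x: np.ndarray,
    filters: WaveletFilterPair | None = None,
    levels: int = 4,
    mode: str = "symmetric",
) -> DecompositionResult:
    """Cascade :func:`dwt_single_level` ``levels`` times on the approximation.

    Raises ``ValueError`` if any level would see a signal shorter than the
    filter.
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if filters is None:
        filters = db2_filters()
    approx = np.asarray(x, dtype=float)
    details: list[np.ndarray] = []
    for _ in range(levels):
        approx, detail = dwt_single_level(approx, filters, mode=mode)
        details.append(detail)
    return DecompositionResult(levels=levels, approx=approx, details=details)


def _length_chain(original_length: int, levels: int, mode: str) -> list[int]:
    out_len = symmetric_output_len if mode == "symmetric" else periodic_output_len
    chain = [original_length]
    for _ in range(levels):
        chain.append(out_len(chain[-1]))
    return chain


def waverec(
    result: DecompositionResult,
    filters: WaveletFilterPair | None = None,
    mode: str = "symmetric",
    original_length: int | None = None,
) -> np.ndarray:
    """Reconstruct the signal from a :class:`DecompositionResult`.

    ``original_length`` must be the analysed signal's length; the per-level
    coefficient lengths implied by it are checked against the stored bands
    and any mismatch raises ``ValueError``.
    """
    _check_mode(mode)
    if filters is None:
        filters = db2_filters()
    if original_length is None:
        raise ValueError("original_length is required for reconstruction")
    chain = _length_chain(original_length, result.levels, mode)
    for lvl, detail in enumerate(result.details, start=1):
        if detail.size != chain[lvl]:
            raise ValueError(
                f"cD{lvl} has {detail.size} coefficients, expected {chain[lvl]} "
                f"for original_length {original_length}"
            )
    if result.approx.size != chain[-1]:
        raise ValueError(
            f"approximation has {result.approx.size} coefficients, "
            f"expected {chain[-1]}"
        )
    approx = result.approx
    for lvl in range(result.levels, 0, -1):
        approx = idwt_single_level(
            approx,
            result.details[lvl - 1],
            filters,
            mode=mode,
            original_length=chain[lvl - 1],
        )
    return approx


def subband_ranges(fs: float, levels: int) -> list[tuple[float, float]]:
    """Nominal (low, high) Hz range of each detail band, cD1 first.

    Detail level ``j`` covers ``(fs / 2**(j+1), fs / 2**j)``; at 128 Hz the
    fourth level is the 4-8 Hz theta band.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if levels < 1:
        raise ValueError("levels must be >= 1")
    return [(fs / 2 ** (j + 1), fs / 2**j) for j in range(1, levels + 1)]
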