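"""Hearing-capability inference from endosseous cochlear duct length.

In archosaurs the length of the endosseous cochlear duct (ECD) tracks
hearing sensitivity and frequency range.  The duct length is normalised by
basicranial length (BCL, anterior basisphenoid limit to posterior
occipital-condyle margin) and log-transformed,

    x = log10(ECD / BCL)

and two empirical linear relations map x to frequencies in Hz:

    best hearing range      y = 6104.3 x + 6975
    mean best frequency     y = 3311.3 x + 4000.8

Base-10 logarithms are used throughout; both outputs are strictly
increasing in ECD/BCL, so longer ducts (relative to head size) imply
higher estimated frequencies under these relations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "HearingEstimate",
    "scaled_ecd",
    "best_hearing_range",
    "mean_best_frequency",
    "hearing_estimate",
]

BEST_RANGE_SLOPE = 6104.3
BEST_RANGE_INTERCEPT = 6975.0
MEAN_FREQ_SLOPE = 3311.3
MEAN_FREQ_INTERCEPT = 4000.8


@dataclass(frozen=True)
class HearingEstimate:
    """Hearing-frequency estimates for one inner ear.

    ``x`` is the scaled, log-transformed duct length log10(ECD/BCL);
    frequencies are full-precision Hz (round to integers for reporting).
    """

    ECD: float  # endosseous cochlear duct length, mm
    BCL: float  # basicranial length, mm
    x: float
    best_range_hz: float
    mean_freq_hz: float


def scaled_ecd(ECD: float, BCL: float) -> float:
    """log10 of cochlear duct length over basicranial length (both mm)."""
    if not (ECD > 0 and math.isfinite(ECD)):
        raise ValueError(f"cochlear duct length must be positive, got {ECD!r}")
    if not (BCL > 0 and math.isfinite(BCL)):
        raise ValueError(f"basicranial length must be positive, got {BCL!r}")
    return math.log10(ECD / BCL)


def best_hearing_range(x: float) -> float:
    """Best hearing range (Hz) from the scaled log duct length."""
    if not math.isfinite(x):
        raise ValueError(f"scaled duct length must be finite, got {x!r}")
    return BEST_RANGE_SLOPE * x + BEST_RANGE_INTERCEPT


def mean_best_frequency(x: float) -> float:
    """Mean best hearing frequency (Hz) from the scaled log duct length."""
    if not math.isfinite(x):
        raise ValueError(f"scaled duct length must be finite, got {x!r}")
    return MEAN_FREQ_SLOPE * x + MEAN_FREQ_INTERCEPT


def hearing_estimate(ECD: float, BCL: float) -> HearingEstimate:
    """Compose the scaling and both frequency relations for one specimen."""
    x = scaled_ecd(ECD, BCL)
    return HearingEstimate(
        ECD=ECD,
        BCL=BCL,
        x=x,
        best_range_hz=best_hearing_range(x),
        mean_freq_hz=mean_best_frequency(x),
    )
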