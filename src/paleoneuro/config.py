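"""Pipeline configuration and the single rounding profile.

Every reported quantity rounds through one profile so user-facing output
and test expectations cannot drift apart: frequencies to integer Hz,
REQ to 1 decimal, midbrain ratios to 2 decimals, percentages to 1 decimal,
masses to whole kilograms.  Rounding is half-up (the convention of the
printed comparative tables) and presentation-only -- stored values keep
full precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = ["PipelineConfig", "round_half_up", "DEFAULT_ROUNDING"]

DEFAULT_ROUNDING: dict[str, int] = {
    "hz": 0,
    "req": 1,
    "ratio": 2,
    "percent": 1,
    "mass_kg": 0,
    "volume_cm3": 3,
}


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (matches printed-table convention)."""
    factor = 10.0**ndigits
    value = math.floor(abs(x) * factor + 0.5) / factor
    return math.copysign(value, x)


@dataclass(frozen=True)
class PipelineConfig:
    """Shared configuration for reports and the CLI.

    fill_fractions : endocast fill fractions used for REQ (each in (0, 1])
    rounding : quantity-kind -> decimal places (see DEFAULT_ROUNDING)
    strict_mesh : reject open meshes instead of integrating with a warning
    output_format : one of json | csv | markdown
    """

    fill_fractions: tuple[float, ...] = (0.37, 0.50)
    rounding: dict = field(default_factory=lambda: dict(DEFAULT_ROUNDING))
    strict_mesh: bool = True
    output_format: str = "json"

    def __post_init__(self) -> None:
        if not self.fill_fractions:
            raise ValueError("at least one fill fraction is required")
        for f in self.fill_fractions:
            if not (0.0 < f <= 1.0):
                raise ValueError(f"fill fraction {f!r} outside (0, 1]")
        missing = set(DEFAULT_ROUNDING) - set(self.rounding)
        if missing:
            raise ValueError(f"rounding profile missing kinds: {sorted(missing)}")
        if self.output_format not in {"json", "csv", "markdown"}:
            raise ValueError(f"unknown output format {self.output_format!r}")

    def round(self, kind: str, value: float) -> float:
        """Round ``value`` per the profile entry for quantity ``kind``."""
        nd = self.rounding[kind]
        rounded = round_half_up(value, nd)
        return int(rounded) if nd == 0 else rounded
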