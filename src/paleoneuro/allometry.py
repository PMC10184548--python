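"""Body-mass estimation and the reptile encephalisation quotient (REQ).

Two closed-form allometries drive the encephalisation pipeline:

* **Bipedal body mass from femoral circumference.**  For a biped of
  minimum femoral circumference ``FC`` (mm),

      mass_g = 10 ** (2.749 * log10(FC * sqrt(2)) - 1.104)

  The sqrt(2) factor converts the single femoral circumference to the
  combined stylopodial circumference of the underlying quadruped scaling
  relation.  For Baryonyx (FC = 350 mm) this yields 2011 kg.

* **Reptile encephalisation quotient.**  Observed brain mass over the
  mass predicted for a reptile of the same body mass,

      REQ = M_Br / (0.0155 * M_Bd ** 0.553)

  with both masses in grams and brain mass excluding the olfactory tract
  and bulbs.

Because in non-maniraptoriform dinosaurs the brain did not fill the
endocranial cavity, brain mass is taken as a *fill fraction* (conventionally
37% or 50%) of endocast volume at a brain-tissue density of 1 g/cm**3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "MassEstimate",
    "EncephalizationResult",
    "body_mass_bipedal",
    "femoral_circumference_for_mass",
    "brain_mass_from_endocast",
    "req",
    "encephalization",
]

# Bipedal mass allometry coefficients (log10 grams vs log10 mm).
MASS_SLOPE = 2.749
MASS_INTERCEPT = -1.104
STYLOPODIAL_FACTOR = math.sqrt(2.0)

# REQ reference allometry: predicted reptile brain mass (g) for body mass (g).
REQ_COEFFICIENT = 0.0155
REQ_EXPONENT = 0.553

#: Brain tissue density, g/cm**3: near unity, so volume and mass interchange.
BRAIN_DENSITY_G_PER_CM3 = 1.0

#: Conventional endocast fill fractions for non-maniraptoriform dinosaurs.
DEFAULT_FILL_FRACTIONS = (0.37, 0.50)


@dataclass(frozen=True)
class MassEstimate:
    """Body-mass estimate from minimum femoral circumference."""

    FC: float  # minimum femoral circumference, mm
    mass_g: float
    mass_kg: float


@dataclass(frozen=True)
class EncephalizationResult:
    """Brain mass, body mass, fill fraction and the resulting REQ."""

    MBr: float  # brain mass, g
    MBd: float  # body mass, g
    fill_fraction: float
    REQ: float


def body_mass_bipedal(FC: float) -> MassEstimate:
    """Estimate bipedal body mass from minimum femoral circumference (mm)."""
    if not (FC > 0 and math.isfinite(FC)):
        raise ValueError(f"femoral circumference must be positive, got {FC!r}")
    mass_g = 10.0 ** (
        MASS_SLOPE * math.log10(FC * STYLOPODIAL_FACTOR) + MASS_INTERCEPT
    )
    return MassEstimate(FC=FC, mass_g=mass_g, mass_kg=mass_g / 1000.0)


def femoral_circumference_for_mass(mass_g: float) -> float:
    """Analytic inverse of :func:`body_mass_bipedal` (mm for a target mass in g)."""
    if not (mass_g > 0 and math.isfinite(mass_g)):
        raise ValueError(f"mass must be positive, got {mass_g!r}")
    return 10.0 ** (
        (math.log10(mass_g) - MASS_INTERCEPT) / MASS_SLOPE
    ) / STYLOPODIAL_FACTOR


def brain_mass_from_endocast(EV: float, fill_fraction: float) -> float:
    """Brain mass (g) as a fraction of endocast volume (cm**3).

    ``fill_fraction`` must lie in (0, 1]; the default study conventions
    are 0.37 and 0.50.
    """
    if not (EV > 0 and math.isfinite(EV)):
        raise ValueError(f"endocast volume must be positive, got {EV!r}")
    if not (0.0 < fill_fraction <= 1.0):
        raise ValueError(
            f"fill fraction must be in (0, 1], got {fill_fraction!r}"
        )
    return EV * fill_fraction * BRAIN_DENSITY_G_PER_CM3


def req(MBr: float, MBd: float) -> float:
    """Reptile encephalisation quotient from brain and body mass (both g)."""
    if not (MBr > 0 and math.isfinite(MBr)):
        raise ValueError(f"brain mass must be positive, got {MBr!r}")
    if not (MBd > 0 and math.isfinite(MBd)):
        raise ValueError(f"body mass must be positive, got {MBd!r}")
    return MBr / (REQ_COEFFICIENT * MBd**REQ_EXPONENT)


def encephalization(
    EV: float, body_mass_g: float, fill_fraction: float
) -> EncephalizationResult:
    """Full encephalisation result for one endocast volume and body mass."""
    MBr = brain_mass_from_endocast(EV, fill_fraction)
    return EncephalizationResult(
        MBr=MBr,
        MBd=body_mass_g,
        fill_fraction=fill_fraction,
        REQ=req(MBr, body_mass_g),
    )
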