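"""Comparative records: packaged reference tables, ratios and specimen reports.

Five plain-text reference tables ship with the package, one row per printed
row of the comparative literature compilation this pipeline reproduces:

``metrics``    endocast metric data for the two baryonychine specimens
``midbrain``   midbrain:"medulla" elongation ratios across theropods
``req``        reptile encephalisation quotients across theropods
``hearing``    cochlear-duct-based hearing estimates across saurischians
``olfaction``  olfactory ratios across theropods

Rows are flagged ``recomputable`` only where the table prints every input
needed to re-derive its value; literature rows whose printed derivations
differ in the last digit from re-derivation with the printed (rounded)
inputs are carried as stored values, not recomputed.  Ranges (en-dash in
print) are stored as min/max pairs; thousands separators are stripped at
load.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields
from importlib import resources

import pandas as pd

from . import allometry, audition, olfaction as olf
from .config import PipelineConfig

__all__ = [
    "SpecimenMeasurements",
    "ComparativeRecord",
    "TABLE_NAMES",
    "midbrain_medulla_ratio",
    "load_reference_table",
    "recompute_derived",
    "specimen_report",
    "report_to_markdown",
]

TABLE_NAMES = ("metrics", "midbrain", "req", "hearing", "olfaction")

#: numeric columns per table, parsed as value-or-range
_NUMERIC_COLUMNS = {
    "metrics": (
        "preserved_length_mm",
        "length_excl_olfactory_mm",
        "endocast_volume_cm3",
        "cerebral_width_mm",
        "cephalic_flexure_deg",
        "pontine_flexure_deg",
    ),
    "midbrain": ("midbrain_mm", "medulla_mm", "ratio"),
    "req": ("ev_cm3", "ev37_cm3", "ev50_cm3", "mbd_g", "req37", "req50"),
    "hearing": ("ecd_mm", "bcl_mm", "best_hz", "mean_hz"),
    "olfaction": ("ratio_pct", "bulb_mm", "cerebrum_mm"),
}

_ANGLE_FIELDS = ("cephalic_flexure_deg", "pontine_flexure_deg")


@dataclass
class SpecimenMeasurements:
    """Per-specimen scalar inputs; every field but ``taxon`` is optional.

    Lengths in mm, volumes in cm**3, masses in g, angles in degrees.
    Flexure angles are carried as stored metadata only (no reproducible
    measurement protocol exists for them).  ``body_mass_g`` may be set
    directly -- e.g. borrowed from a closely similar taxon -- in which case
    ``body_mass_source`` records the provenance; otherwise mass is derived
    from femoral circumference where available.
    """

    taxon: str
    specimen_id: str | None = None
    ecd_mm: float | None = None
    bcl_mm: float | None = None
    endocast_volume_cm3: float | None = None
    femoral_circumference_mm: float | None = None
    bulb_length_mm: float | None = None
    cerebrum_diameter_mm: float | None = None
    midbrain_length_mm: float | None = None
    medulla_length_mm: float | None = None
    cephalic_flexure_deg: float | None = None
    pontine_flexure_deg: float | None = None
    endocast_length_mm: float | None = None
    cerebral_width_mm: float | None = None
    body_mass_g: float | None = None
    body_mass_source: str | None = None

    def __post_init__(self) -> None:
        if not self.taxon:
            raise ValueError("taxon is required")
        for f in fields(self):
            if f.name in ("taxon", "specimen_id", "body_mass_source"):
                continue
            value = getattr(self, f.name)
            if value is None:
                continue
            value = float(value)
            setattr(self, f.name, value)
            if not (value > 0 and math.isfinite(value)):
                raise ValueError(f"{f.name} must be positive, got {value!r}")
            if f.name in _ANGLE_FIELDS and not (0.0 < value < 180.0):
                raise ValueError(
                    f"{f.name} must lie in (0, 180) degrees, got {value!r}"
                )


@dataclass(frozen=True)
class ComparativeRecord:
    """One row of a packaged reference table.

    ``values`` maps column -> float or (min, max) tuple (ranges) or None;
    ``printed`` keeps the verbatim cell text so printed precision is
    recoverable; ``recomputable_fields`` lists the derived columns that
    re-derive exactly from this row's printed inputs.
    """

    table: str
    taxon: str
    specimen_id: str | None
    values: dict
    printed: dict
    source: str
    recomputable: bool
    recomputable_fields: tuple = ()
    note: str | None = None


def midbrain_medulla_ratio(midbrain_length: float, medulla_length: float) -> float:
    """Midbrain-region elongation: midbrain length over "medulla" length.

    Midbrain length runs from the anterior floccular-lobe border to the
    peak of the dorsal expansion; "medulla" length from the foramen magnum
    to the trigeminal nerve trunk.
    """
    if not (midbrain_length > 0 and math.isfinite(midbrain_length)):
        raise ValueError(
            f"midbrain length must be positive, got {midbrain_length!r}"
        )
    if not (medulla_length > 0 and math.isfinite(medulla_length)):
        raise ValueError(
            f"medulla length must be positive, got {medulla_length!r}"
        )
    return midbrain_length / medulla_length


def _parse_cell(text: str):
    """Parse a printed numeric cell: value, range 'a-b', or NA -> None."""
    text = text.strip().replace(",", "").replace("–", "-")
    if text in ("", "NA", "n/a"):
        return None
    if "-" in text[1:]:  # range (leading '-' would be a sign; values here are positive)
        lo_s, hi_s = text.split("-", 1)
        lo, hi = float(lo_s), float(hi_s)
        return (min(lo, hi), max(lo, hi))
    return float(text)


def _load_frame(name: str) -> pd.DataFrame:
    path = resources.files("paleoneuro.data").joinpath(f"{name}.csv")
    with resources.as_file(path) as p:
        return pd.read_csv(p, dtype=str, keep_default_na=False)


def load_reference_table(name: str) -> list[ComparativeRecord]:
    """Load one packaged reference table as a list of ComparativeRecord."""
    if name not in TABLE_NAMES:
        raise ValueError(
            f"unknown table {name!r}; valid names: {', '.join(TABLE_NAMES)}"
        )
    frame = _load_frame(name)
    numeric = _NUMERIC_COLUMNS[name]
    records = []
    for _, row in frame.iterrows():
        values = {col: _parse_cell(row[col]) for col in numeric}
        printed = {col: row[col].strip() for col in numeric}
        if name == "hearing":
            recomp_fields = tuple(
                col
                for col, flag in (
                    ("best_hz", row["recomputable_best"]),
                    ("mean_hz", row["recomputable_mean"]),
                )
                if flag == "True"
            )
            recomputable = bool(recomp_fields)
        elif "recomputable" in row:
            recomputable = row["recomputable"] == "True"
            derived = {
                "midbrain": ("ratio",),
                "req": ("req37", "req50"),
                "olfaction": ("ratio_pct",),
            }.get(name, ())
            recomp_fields = derived if recomputable else ()
        else:
            recomputable, recomp_fields = False, ()
        records.append(
            ComparativeRecord(
                table=name,
                taxon=row["taxon"],
                specimen_id=row.get("specimen_id") or None,
                values=values,
                printed=printed,
                source=row["source"],
                recomputable=recomputable,
                recomputable_fields=recomp_fields,
                note=(row.get("note") or None)
                if row.get("note") not in ("NA", "") else None,
            )
        )
    return records


def recompute_derived(record: ComparativeRecord) -> dict:
    """Re-derive a record's recomputable fields from its stored inputs.

    Returns {field: recomputed float} for every field in
    ``recomputable_fields``; the caller compares against the printed value
    at its printed precision.  Ranges are never recomputable.
    """
    out: dict = {}
    v = record.values
    for field_name in record.recomputable_fields:
        if record.table == "hearing":
            x = audition.scaled_ecd(v["ecd_mm"], v["bcl_mm"])
            out[field_name] = (
                audition.best_hearing_range(x)
                if field_name == "best_hz"
                else audition.mean_best_frequency(x)
            )
        elif record.table == "midbrain":
            out[field_name] = midbrain_medulla_ratio(
                v["midbrain_mm"], v["medulla_mm"]
            )
        elif record.table == "req":
            fill = 0.37 if field_name == "req37" else 0.50
            out[field_name] = allometry.encephalization(
                v["ev_cm3"], v["mbd_g"], fill
            ).REQ
        elif record.table == "olfaction":
            out[field_name] = olf.olfactory_ratio(
                v["bulb_mm"], v["cerebrum_mm"]
            )
        else:
            raise ValueError(
                f"table {record.table!r} has no derived fields to recompute"
            )
    return out


def _not_computable(missing: list[str]) -> dict:
    return {"status": "not computable", "missing": sorted(missing)}


def specimen_report(
    m: SpecimenMeasurements, config: PipelineConfig | None = None
) -> dict:
    """Assemble every derivable quantity for one specimen.

    Sections whose inputs are missing are reported as ``not computable``
    rather than omitted; each computed section lists the inputs it used.
    The result is a plain JSON-serialisable dict and is deterministic:
    identical measurements and config give byte-identical JSON.
    """
    config = config or PipelineConfig()
    report: dict = {
        "taxon": m.taxon,
        "specimen_id": m.specimen_id,
        "config": {"fill_fractions": list(config.fill_fractions)},
    }

    # --- body mass ---------------------------------------------------------
    mass_g = None
    if m.body_mass_g is not None:
        mass_g = m.body_mass_g
        report["body_mass"] = {
            "status": "ok",
            "inputs": {"body_mass_g": m.body_mass_g},
            "source": m.body_mass_source or "supplied",
            "mass_g": mass_g,
            "mass_kg": mass_g / 1000.0,
            "mass_kg_rounded": config.round("mass_kg", mass_g / 1000.0),
        }
    elif m.femoral_circumference_mm is not None:
        est = allometry.body_mass_bipedal(m.femoral_circumference_mm)
        mass_g = est.mass_g
        report["body_mass"] = {
            "status": "ok",
            "inputs": {"femoral_circumference_mm": m.femoral_circumference_mm},
            "source": "bipedal femoral-circumference allometry",
            "mass_g": est.mass_g,
            "mass_kg": est.mass_kg,
            "mass_kg_rounded": config.round("mass_kg", est.mass_kg),
        }
    else:
        report["body_mass"] = _not_computable(
            ["femoral_circumference_mm or body_mass_g"]
        )

    # --- encephalisation ---------------------------------------------------
    if m.endocast_volume_cm3 is not None and mass_g is not None:
        per_fill = {}
        for f in config.fill_fractions:
            res = allometry.encephalization(m.endocast_volume_cm3, mass_g, f)
            per_fill[f"{f:g}"] = {
                "brain_mass_g": res.MBr,
                "req": res.REQ,
                "req_rounded": config.round("req", res.REQ),
            }
        report["encephalization"] = {
            "status": "ok",
            "inputs": {
                "endocast_volume_cm3": m.endocast_volume_cm3,
                "body_mass_g": mass_g,
            },
            "per_fill": per_fill,
        }
    else:
        missing = []
        if m.endocast_volume_cm3 is None:
            missing.append("endocast_volume_cm3")
        if mass_g is None:
            missing.append("body_mass")
        report["encephalization"] = _not_computable(missing)

    # --- hearing -----------------------------------------------------------
    if m.ecd_mm is not None and m.bcl_mm is not None:
        est = audition.hearing_estimate(m.ecd_mm, m.bcl_mm)
        report["hearing"] = {
            "status": "ok",
            "inputs": {"ecd_mm": m.ecd_mm, "bcl_mm": m.bcl_mm},
            "x": est.x,
            "best_range_hz": est.best_range_hz,
            "mean_freq_hz": est.mean_freq_hz,
            "best_range_hz_rounded": config.round("hz", est.best_range_hz),
            "mean_freq_hz_rounded": config.round("hz", est.mean_freq_hz),
        }
    else:
        missing = [n for n, v in (("ecd_mm", m.ecd_mm), ("bcl_mm", m.bcl_mm))
                   if v is None]
        report["hearing"] = _not_computable(missing)

    # --- olfaction ---------------------------------------------------------
    if m.bulb_length_mm is not None and m.cerebrum_diameter_mm is not None:
        ratio = olf.olfactory_ratio(m.bulb_length_mm, m.cerebrum_diameter_mm)
        section = {
            "status": "ok",
            "inputs": {
                "bulb_length_mm": m.bulb_length_mm,
                "cerebrum_diameter_mm": m.cerebrum_diameter_mm,
            },
            "ratio_pct": ratio,
            "ratio_pct_rounded": config.round("percent", ratio),
        }
        if mass_g is not None:
            log_ratio, log_mass = olf.log_olfactory_point(ratio, mass_g)
            section["log_ratio"] = log_ratio
            section["log_body_mass"] = log_mass
        report["olfaction"] = section
    else:
        missing = [
            n for n, v in (
                ("bulb_length_mm", m.bulb_length_mm),
                ("cerebrum_diameter_mm", m.cerebrum_diameter_mm),
            ) if v is None
        ]
        report["olfaction"] = _not_computable(missing)

    # --- midbrain elongation ----------------------------------------------
    if m.midbrain_length_mm is not None and m.medulla_length_mm is not None:
        ratio = midbrain_medulla_ratio(m.midbrain_length_mm, m.medulla_length_mm)
        report["midbrain_ratio"] = {
            "status": "ok",
            "inputs": {
                "midbrain_length_mm": m.midbrain_length_mm,
                "medulla_length_mm": m.medulla_length_mm,
            },
            "ratio": ratio,
            "ratio_rounded": config.round("ratio", ratio),
        }
    else:
        missing = [
            n for n, v in (
                ("midbrain_length_mm", m.midbrain_length_mm),
                ("medulla_length_mm", m.medulla_length_mm),
            ) if v is None
        ]
        report["midbrain_ratio"] = _not_computable(missing)

    return report


def report_to_json(report: dict) -> str:
    """Canonical (byte-stable) JSON rendering of a specimen report."""
    return json.dumps(report, sort_keys=True, indent=2)


_SECTION_TITLES = {
    "body_mass": "Body mass",
    "encephalization": "Encephalisation (REQ)",
    "hearing": "Hearing",
    "olfaction": "Olfaction",
    "midbrain_ratio": "Midbrain elongation",
}


def report_to_markdown(report: dict) -> str:
    """Human-readable Markdown rendering of a specimen report."""
    lines = [f"# {report['taxon']}"]
    if report.get("specimen_id"):
        lines.append(f"Specimen: {report['specimen_id']}")
    for key, title in _SECTION_TITLES.items():
        section = report[key]
        lines.append(f"\n## {title}")
        if section["status"] != "ok":
            lines.append(f"not computable (missing: {', '.join(section['missing'])})")
            continue
        if key == "body_mass":
            lines.append(f"- mass: {section['mass_kg_rounded']:g} kg "
                         f"({section['source']})")
        elif key == "encephalization":
            for fill, res in section["per_fill"].items():
                lines.append(
                    f"- fill {fill}: brain mass {res['brain_mass_g']:.1f} g, "
                    f"REQ {res['req_rounded']:g}"
                )
        elif key == "hearing":
            lines.append(
                f"- best hearing range: {section['best_range_hz_rounded']} Hz"
            )
            lines.append(
                f"- mean best frequency: {section['mean_freq_hz_rounded']} Hz"
            )
        elif key == "olfaction":
            lines.append(f"- olfactory ratio: {section['ratio_pct_rounded']}%")
            if "log_ratio" in section:
                lines.append(
                    f"- log10 ratio {section['log_ratio']:.3f} at "
                    f"log10 mass {section['log_body_mass']:.3f}"
                )
        elif key == "midbrain_ratio":
            lines.append(f"- midbrain:\"medulla\" ratio: "
                         f"{section['ratio_rounded']:g}")
    return "\n".join(lines) + "\n"
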