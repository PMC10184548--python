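"""Synthetic meshes and specimen cohorts with ground truth known by construction.

Raw CT-derived endocasts are large binary artefacts; every stage of this
pipeline is instead exercised against synthetic stand-ins whose true
values are analytic:

* ellipsoid "endocasts" (true volume 4/3*pi*a*b*c),
* capped tubes along a polyline (synthetic cochlear-duct stand-ins with a
  known centreline length),
* measurement cohorts drawn log-uniformly over realistic ranges, with
  every derived quantity (body mass, REQ, hearing frequencies, olfactory
  and midbrain ratios) recomputed by an independent straight-line oracle
  at generation time -- never by calling the pipeline under test.

No attempt is made to emulate CT artefacts, taphonomic deformation or
disarticulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .comparative import SpecimenMeasurements
from .mesh import Polyline, TriangleMesh, polyline_length

__all__ = [
    "SyntheticMesh",
    "SyntheticSpecimen",
    "DEFAULT_RANGES",
    "make_ellipsoid_mesh",
    "make_tube_mesh",
    "make_specimen_cohort",
]


@dataclass(frozen=True)
class SyntheticMesh:
    """A generated mesh plus its analytically known measures (mm / mm**3)."""

    mesh: TriangleMesh
    true_volume_mm3: float | None = None
    true_centreline_mm: float | None = None


@dataclass(frozen=True)
class SyntheticSpecimen:
    """Generated measurements plus oracle-derived ground truths."""

    measurements: SpecimenMeasurements
    seed: int
    truth: dict


# Measurement ranges a cohort is drawn from (log-uniform).  Linear spans
# follow the comparative tables: cochlear ducts ~6-20 mm against basicrania
# ~15-110 mm with observed ECD/BCL quotients of ~0.155-0.43, endocast
# volumes ~95-415 cm**3, femora spanning mid-sized to multi-tonne bipeds.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "bcl_mm": (15.0, 110.0),
    "ecd_mm": (6.0, 20.0),
    "ecd_bcl_ratio": (0.155, 0.43),
    "endocast_volume_cm3": (95.0, 415.0),
    "femoral_circumference_mm": (150.0, 600.0),
    "cerebrum_diameter_mm": (25.0, 60.0),
    "olfactory_ratio": (0.27, 0.71),
    "midbrain_length_mm": (15.0, 65.0),
    "medulla_length_mm": (20.0, 55.0),
}


def make_ellipsoid_mesh(
    a: float, b: float, c: float, subdivisions: int = 4, seed: int = 0
) -> SyntheticMesh:
    """Watertight, outward-oriented ellipsoid mesh with semi-axes a, b, c (mm).

    Built by scaling an icosphere.  ``subdivisions`` counts subdivision
    passes over the icosahedron (0 = the bare icosahedron).  Every level is
    an inscribed polyhedron, so the mesh volume is strictly below the
    analytic 4/3*pi*a*b*c; the deficit shrinks with subdivision and is
    about 0.2% at the default ``subdivisions=4``.  The generator is
    deterministic; ``seed`` is accepted for interface uniformity.
    """
    import trimesh

    for name, val in (("a", a), ("b", b), ("c", c)):
        if not (val > 0 and math.isfinite(val)):
            raise ValueError(f"semi-axis {name} must be positive, got {val!r}")
    if subdivisions < 0:
        raise ValueError(f"subdivisions must be >= 0, got {subdivisions!r}")
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    verts = np.asarray(ico.vertices, dtype=float) * np.array([a, b, c])
    mesh = TriangleMesh(verts, np.asarray(ico.faces), name="synthetic ellipsoid")
    return SyntheticMesh(
        mesh=mesh, true_volume_mm3=4.0 / 3.0 * math.pi * a * b * c
    )


def _transport_frames(points: np.ndarray):
    """Parallel-transport orthonormal frames along a polyline."""
    tangents = np.diff(points, axis=0)
    norms = np.linalg.norm(tangents, axis=1)
    if np.any(norms == 0):
        raise ValueError("polyline has zero-length segments (repeated points)")
    tangents = tangents / norms[:, None]
    # per-vertex tangents (average of adjacent segments)
    vt = np.empty_like(points)
    vt[0], vt[-1] = tangents[0], tangents[-1]
    if len(points) > 2:
        mid = tangents[:-1] + tangents[1:]
        mn = np.linalg.norm(mid, axis=1)
        if np.any(mn == 0):
            raise ValueError("polyline reverses direction exactly; cannot frame")
        vt[1:-1] = mid / mn[:, None]
    # initial normal: any vector not parallel to the first tangent
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(ref, vt[0])) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    n = np.cross(vt[0], np.cross(ref, vt[0]))
    n /= np.linalg.norm(n)
    frames = [(n, np.cross(vt[0], n))]
    for i in range(1, len(points)):
        # rotate previous normal into the new tangent plane
        n_prev = frames[-1][0]
        t = vt[i]
        n_new = n_prev - np.dot(n_prev, t) * t
        ln = np.linalg.norm(n_new)
        if ln == 0:
            raise ValueError("degenerate frame transport on polyline")
        n_new /= ln
        frames.append((n_new, np.cross(t, n_new)))
    return frames


def make_tube_mesh(
    path: Polyline | np.ndarray, radius: float, segments: int = 32
) -> SyntheticMesh:
    """Capped, watertight tube of given radius (mm) swept along a polyline.

    Cross-sections are regular ``segments``-gons transported along the
    path; the ends are closed with flat triangle fans, so a straight path
    of length L has exact volume L * (1/2) n r**2 sin(2*pi/n) -- within 1%
    of the cylinder pi r**2 L at the default 32 segments.  Reported
    ``true_centreline_mm`` is the polyline length.  A warning is raised if
    the radius is large relative to the shortest segment, where the swept
    surface may self-intersect.
    """
    if not isinstance(path, Polyline):
        path = Polyline(np.asarray(path))
    if not (radius > 0 and math.isfinite(radius)):
        raise ValueError(f"radius must be positive, got {radius!r}")
    if segments < 3:
        raise ValueError(f"segments must be >= 3, got {segments!r}")
    points = path.points
    seg_lengths = np.linalg.norm(np.diff(points, axis=0), axis=1)
    if np.any(seg_lengths == 0):
        raise ValueError("degenerate path: repeated consecutive points")
    if radius > 0.5 * seg_lengths.min():
        import warnings

        warnings.warn(
            "tube radius exceeds half the shortest path segment; the swept "
            "surface may self-intersect",
            UserWarning,
            stacklevel=2,
        )
    frames = _transport_frames(points)
    angles = 2.0 * math.pi * np.arange(segments) / segments
    rings = []
    for p, (n, b) in zip(points, frames):
        ring = p + radius * (
            np.outer(np.cos(angles), n) + np.outer(np.sin(angles), b)
        )
        rings.append(ring)
    verts = np.concatenate(rings + [points[:1], points[-1:]], axis=0)
    start_centre = len(verts) - 2
    end_centre = len(verts) - 1

    faces = []
    for i in range(len(points) - 1):
        base0, base1 = i * segments, (i + 1) * segments
        for j in range(segments):
            k = (j + 1) % segments
            # outward winding: counter-clockwise rings viewed from the
            # tube's forward direction
            faces.append((base0 + j, base1 + j, base1 + k))
            faces.append((base0 + j, base1 + k, base0 + k))
    last = (len(points) - 1) * segments
    for j in range(segments):
        k = (j + 1) % segments
        faces.append((start_centre, k, j))  # start cap faces backward
        faces.append((end_centre, last + j, last + k))  # end cap
    mesh = TriangleMesh(verts, np.asarray(faces), name="synthetic tube")
    return SyntheticMesh(
        mesh=mesh, true_centreline_mm=polyline_length(path)
    )


# ---------------------------------------------------------------------------
# Cohort generation with an independent oracle
# ---------------------------------------------------------------------------


def _oracle_truths(m: SpecimenMeasurements, fills=(0.37, 0.50)) -> dict:
    """Straight-line re-derivation of every closed form (the oracle).

    Deliberately independent of the pipeline modules: each formula is
    written out in full here so generator and pipeline can disagree.
    """
    truth: dict = {}
    fc = m.femoral_circumference_mm
    mass_g = 10.0 ** (2.749 * math.log10(fc * 2.0**0.5) - 1.104)
    truth["mass_g"] = mass_g
    truth["req"] = {
        f"{f:g}": (m.endocast_volume_cm3 * f * 1.0)
        / (0.0155 * mass_g**0.553)
        for f in fills
    }
    x = math.log10(m.ecd_mm / m.bcl_mm)
    truth["best_range_hz"] = 6104.3 * x + 6975.0
    truth["mean_freq_hz"] = 3311.3 * x + 4000.8
    truth["olfactory_pct"] = 100.0 * m.bulb_length_mm / m.cerebrum_diameter_mm
    truth["midbrain_ratio"] = m.midbrain_length_mm / m.medulla_length_mm
    return truth


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(math.exp(rng.uniform(math.log(lo), math.log(hi))))


def _validate_ranges(ranges: dict) -> None:
    for key, (lo, hi) in ranges.items():
        if not (0 < lo <= hi and math.isfinite(lo) and math.isfinite(hi)):
            raise ValueError(f"invalid range for {key!r}: ({lo!r}, {hi!r})")
    r_lo, r_hi = ranges["ecd_bcl_ratio"]
    e_lo, e_hi = ranges["ecd_mm"]
    b_lo, b_hi = ranges["bcl_mm"]
    if max(e_lo, r_lo * b_lo) > min(e_hi, r_hi * b_lo) or max(
        e_lo, r_lo * b_hi
    ) > min(e_hi, r_hi * b_hi):
        raise ValueError(
            "ecd_mm, bcl_mm and ecd_bcl_ratio ranges are incompatible: no "
            "cochlear duct length satisfies both constraints at a range "
            "endpoint"
        )


def make_specimen_cohort(
    n: int,
    seed: int,
    ranges: dict[str, tuple[float, float]] | None = None,
    fills: tuple[float, ...] = (0.37, 0.50),
) -> list[SyntheticSpecimen]:
    """Draw ``n`` synthetic specimens, reproducibly, from one seeded stream.

    Measurements are log-uniform within ``ranges`` (defaults:
    :data:`DEFAULT_RANGES`).  The cochlear duct length is drawn jointly
    with the basicranium: BCL log-uniform, then ECD log-uniform within the
    intersection of its own range and the allowed ECD/BCL quotient band,
    keeping relative duct lengths inside the span observed across
    saurischians.  Olfactory bulb length is likewise drawn as a quotient of
    the cerebrum diameter.  Ground truths are computed by the independent
    in-module oracle, not by the pipeline.
    """
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n!r}")
    merged = dict(DEFAULT_RANGES)
    if ranges:
        unknown = set(ranges) - set(DEFAULT_RANGES)
        if unknown:
            raise ValueError(f"unknown range keys: {sorted(unknown)}")
        merged.update(ranges)
    _validate_ranges(merged)
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n):
        bcl = _log_uniform(rng, *merged["bcl_mm"])
        r_lo, r_hi = merged["ecd_bcl_ratio"]
        e_lo, e_hi = merged["ecd_mm"]
        lo = max(e_lo, r_lo * bcl)
        hi = min(e_hi, r_hi * bcl)
        ecd = _log_uniform(rng, lo, hi)
        cerebrum = _log_uniform(rng, *merged["cerebrum_diameter_mm"])
        bulb = cerebrum * _log_uniform(rng, *merged["olfactory_ratio"])
        m = SpecimenMeasurements(
            taxon=f"Synthetica specimen {i}",
            specimen_id=f"SYN {seed}-{i}",
            ecd_mm=ecd,
            bcl_mm=bcl,
            endocast_volume_cm3=_log_uniform(
                rng, *merged["endocast_volume_cm3"]
            ),
            femoral_circumference_mm=_log_uniform(
                rng, *merged["femoral_circumference_mm"]
            ),
            bulb_length_mm=bulb,
            cerebrum_diameter_mm=cerebrum,
            midbrain_length_mm=_log_uniform(rng, *merged["midbrain_length_mm"]),
            medulla_length_mm=_log_uniform(rng, *merged["medulla_length_mm"]),
        )
        cohort.append(
            SyntheticSpecimen(
                measurements=m, seed=seed, truth=_oracle_truths(m, fills)
            )
        )
    return cohort
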