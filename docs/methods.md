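# Methods

This note documents the models, conventions and numerical choices behind
`paleoneuro`, and what the synthetic-data tests do and do not establish
about real fossil data.

## Mesh volumetrics

An endocast volume is the signed-tetrahedron sum Σ det(v₀,v₁,v₂)/6 over
the faces of a closed triangle surface (equivalently, the divergence
theorem applied to the position field). The implementation:

- **Welding.** File formats such as STL store three independent vertices
  per facet; vertices closer than 1e-6 mm are merged by deterministic grid
  snapping before any topological check. The tolerance is far below CT
  voxel size (~0.1 mm for the scans this kind of mesh derives from), so
  welding cannot merge genuinely distinct anatomy.
- **Watertightness.** An edge shared by exactly two faces is interior; an
  edge owned by one face is a boundary. Strict mode (default) rejects any
  boundary edge and reports the count; permissive mode integrates anyway
  and emits a warning, because real fossil segmentations often carry small
  holes. Edges shared by more than two faces (non-manifold) are always
  rejected — the enclosed volume is not well defined there.
- **Orientation.** STL carries no guaranteed winding. A breadth-first
  propagation from the lowest-index face of each connected component
  flips faces until every interior edge is traversed in opposite
  directions by its two owners; a contradiction (Möbius-like surface)
  raises. The per-component signed sum is then taken in absolute value, so
  a globally reversed mesh yields the same volume and disjoint closed
  shells are additive. Each closed shell is treated as solid: a shell
  nested inside another is *added*, not subtracted — interior cavities are
  not modelled, consistent with treating the segmented surface as ground
  truth.
- **Units.** Vertices are mm; volume is converted mm³→cm³ exactly once at
  output.

Rigid-motion invariance holds to ~1e-9 relative (floating-point
cancellation in the determinant sum grows with translation distance; the
test translates by tens of mm, typical of re-registered scans).

## Allometries

**Bipedal body mass.** mass_g = 10^(2.749·log₁₀(√2·FC) − 1.104) with FC
the minimum femoral circumference in mm. The √2 factor maps the single
femoral circumference onto the combined stylopodial circumference of the
underlying quadrupedal scaling relation. The function is an exact power
law (mass ∝ FC^2.749) with an analytic inverse, both of which are tested.
No error propagation is attempted: published circumferences of damaged
femora carry unquantified uncertainty and the source convention reports
point estimates.

**REQ.** REQ = M_Br/(0.0155·M_Bd^0.553), masses in grams. Brain mass is
fill·EV·ρ with ρ = 1 g/cm³ (brain tissue density near unity) and fill
fractions defaulting to 0.37 and 0.50 — the conventional bracketing
assumptions for how much of a non-maniraptoriform endocast was brain
rather than dural envelope and venous sinus. The fractions are
configuration, not constants, and REQ is linear in the fill at fixed EV
and body mass.

## Hearing

x = log₁₀(ECD/BCL); best hearing range = 6104.3x + 6975 Hz; mean best
frequency = 3311.3x + 4000.8 Hz. Base-10 logarithms are used: the
comparative-table frequencies re-derive exactly (integer rounding) under
base 10 and under no other base. Frequencies are kept at full precision
internally and rounded to integer Hz only for reporting. BCL is accepted
as a measured input (anteroposterior distance from the anterior
basisphenoid limit, excluding the cultriform process, to the posterior
occipital-condyle margin); it is not computed from meshes. Rows of the
packaged hearing table lacking BCL are carried as stored literature values
and flagged non-recomputable; nothing is imputed.

The two lines cross at x ≈ −1.065; every tabulated taxon lies above the
crossover, so best range exceeds mean frequency throughout the observed
span. Three literature rows (Irritator mean, Alioramus best, one
Velociraptor best) differ by 1 Hz from re-derivation with the printed
1-decimal inputs — their sources evidently used unrounded measurements —
and are flagged non-recomputable rather than pinned; the audit pins only
rows that reproduce exactly.

## Olfaction

Olfactory ratio = 100·(longest bulb diameter)/(longest cerebral-hemisphere
diameter), measured regardless of orientation. Body-size context uses
log₁₀(ratio in %) against log₁₀(body mass in g); reference regression
lines are user-supplied (slope, intercept) because no coefficients are
packaged — the plot draws data and reference only. A specimen without a
usable femur may borrow another specimen's mass estimate; the report
records the provenance string alongside the borrowed value.

## Rounding profile

All reported roundings live in one profile (integer Hz, REQ 1 dp,
midbrain ratios 2 dp, percentages 1 dp, whole kg) so CLI output, reports
and tests cannot drift apart. Rounding is half-up (ties away from zero),
matching the printed comparative tables; stored values keep full
precision. The fixture audit compares each recomputed value at the
precision its printed cell actually shows (e.g. a ratio printed "0.8" is
compared at 1 decimal, "1.31" at 2).

## Reference tables

The five packaged CSVs are verbatim row-for-row transcriptions of the
comparative tables this pipeline reproduces, with thousands separators
stripped and en-dash ranges normalised to min/max pairs at load. Each row
carries a `source` citation and recomputability flags set only where every
input needed for re-derivation is printed *and* re-derivation reproduces
the printed value at its printed precision. Known quirks are stored as
notes rather than silently corrected: one REQ-table row's 37%/50% volumes
were misreported in its original source (and its printed REQ at 50% does
not re-derive); flexure angles are stored-only because no reproducible
protocol exists for measuring them from a mesh.

## Synthetic data

The generator is the pipeline's stand-in for raw CT data; it emulates the
*measurement* structure of the study, not the anatomy.

- **Ellipsoid endocasts** are scaled icospheres; `subdivisions` counts
  subdivision passes (0 = icosahedron). Every level is inscribed, so mesh
  volume strictly underestimates 4/3·π·abc, by ~0.2% at the default 4
  passes — an analytic error bound the volume tests lean on.
- **Tubes** (cochlear-duct stand-ins) sweep a regular n-gon along a
  polyline with parallel-transport frames and flat end caps. A straight
  tube is an exact n-gonal prism of volume ½n·r²·sin(2π/n)·L, 0.64% below
  the smooth cylinder at the default n = 32. A radius exceeding half the
  shortest segment warns of possible self-intersection.
- **Cohorts** draw measurements log-uniformly (body-size-like quantities
  span orders of magnitude) from one seeded `numpy` Generator stream.
  Cochlear duct length is drawn *jointly* with basicranial length: BCL
  log-uniform over 15–110 mm, then ECD log-uniform within the intersection
  of 6–20 mm and an ECD/BCL band of 0.155–0.43 — the span observed across
  the comparative hearing table. Independent draws over the two rectangles
  would produce duct/basicranium quotients (up to 1.33) never seen in
  archosaurs and hearing estimates far outside the empirical 2000–4800 Hz
  band the tests check. Olfactory bulb length is likewise drawn as a
  quotient (0.27–0.71) of cerebrum diameter. Ground truths are computed by
  a straight-line re-implementation of each closed form inside the
  generator, deliberately independent of the pipeline modules, so
  generator/pipeline agreement (tested at 1e-9 relative on 100+ specimen
  cohorts) is a genuine dual-route check.

What passing synthetic tests show: the closed forms, their composition,
the mesh integrator and the I/O round-trip are implemented correctly. What
they do not show: anything about segmentation quality, CT artefacts,
taphonomic deformation, or whether a real endocast's neurovascular
features were excluded consistently — those live upstream of this package.

## Problem sizes

Everything here is desk-scale: the acceptance computations are closed-form
evaluations on single specimens; property tests use cohorts of 100–200
synthetic specimens and meshes of ≤ ~5000 faces, chosen because the
quantities under test (agreement to 1e-9; discretisation error bounds)
are already fully resolved at those sizes.

## Known limitations

- Volume of nested shells treats each shell as solid (no cavity
  subtraction).
- The body-mass equation covers bipeds only; the quadrupedal
  (humeral+femoral) variant is out of scope.
- Hearing inference implements a single estimator family; critiques of it
  exist and no alternative estimator is provided.
- Flexure angles are carried as data, never measured.
- The olfactory "expected ratio for body size" cannot be computed without
  a user-supplied reference regression.
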