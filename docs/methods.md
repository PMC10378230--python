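# Methods

## Geometric model

All constructions live in a right-handed RAS-like frame: x = subject's
right, y = anterior, z = superior, millimetres.  File readers convert
external conventions (e.g. Slicer's LPS) at the boundary; nothing downstream
depends on the global axes — every reported angle is invariant under rigid
motion, uniform scaling and mirror reflection of the input landmarks (the
test suite asserts this to 1e-6°).

Planes are stored as anchor + unit normal.  Normals follow the right-hand
rule on construction-argument order, but no public result depends on a
normal's sign: dihedral angles are symmetric, and trace angles take explicit
anatomical orientation hints.

### Individual track

| Plane | Through |
|---|---|
| MCF | rMCF, lMCF, Ba |
| PM  | rMCF, lMCF, PNS |
| MR  | mCo, rGo, lGo |
| FOP | rPoc, lPoc, mAoc |

mCo and mAoc are exact midpoints of their bilateral pairs.

Two angle conventions are offered for MCF^PM and MCF^MR:

* **trace** (default): the angle between the planes' intersection lines with
  the estimated mid-sagittal plane, each trace oriented by an anatomical
  hint.  MCF^PM orients the cranial-base trace toward Ba and the PM trace
  toward PNS, matching the 2-D vertex angle at SE; MCF^MR orients the
  cranial-base trace *away* from Ba (as the 2-D ray Ar→SE does) and the
  ramus trace from condylar toward gonial level, yielding the obtuse
  posterior angle of typical anatomy.  This is the convention under which
  3-D values are directly comparable with lateral-cephalogram measurements.
* **dihedral**: the angle between oriented plane normals, for users who want
  the pure 3-D quantity.

The mid-sagittal plane is estimated as the plane through Ba whose normal is
the normalized sum of the unit left-to-right vectors of the MCF, condylion
and gonion pairs.  For an exactly mirror-symmetric set this is the true
symmetry plane; swapping a pair's labels only flips the normal's sign, which
is immaterial downstream.

### Neutral track (3-D)

1. MCFx = intersection of the rMCF–lMCF chord with the mid-sagittal plane.
2. Sphere centered at Ba, radius |Ba–MCFx|; its mid-sagittal cut is the
   construction circle (center Ba, same radius).
3. CPBa = plane through Ba parallel to PM.  SEn is the circle point whose
   ray from Ba makes the neutral angle (default 40.3°, configurable) with
   CPBa — measured **in the section**, i.e. against CPBa's trace on the
   mid-sagittal plane.  For symmetric subjects this equals the ray-to-plane
   angle; for asymmetric ones only the in-section reading keeps the
   construction's defining identity exact, and it is also what a sagittal
   working view measures.  Among the up-to-four candidates the
   anterior-superior branch is chosen deterministically: the candidate whose
   ray has the largest dot product with Ba→MCFx.
4. PMn = plane through SEn parallel to PM.
5. rSEn/lSEn flank SEn laterally (offset δ, default 5 mm, minimum 0.1 mm);
   MCFn = plane through Ba, rSEn, lSEn.  Two placements:
   * `tangent` (default): SEn ± δ·(sagittal normal).  MCFn then contains
     the Ba–SEn ray exactly, so the plane — and the 40.3° identity — is
     exact and independent of δ.
   * `on_sphere`: the flanks stay on the sphere, on the constant-elevation
     circle through SEn (sphere ∩ plane through SEn parallel to CPBa),
     displaced so their lateral coordinate is ±δ.  The chord midpoint of two
     circle points is shorter than the radius, so the sagittal trace of MCFn
     steepens slightly: on the template the MCFn^PMn trace angle is 40.56°
     at δ = 5 mm (+0.26°), 40.34° at δ = 2 mm, converging to 40.3° as
     δ → 0.  The mode exists because "arbitrary points on the circumference"
     admits this stricter on-sphere reading; the deviation is the price of
     keeping the flanks on the sphere.
6. CPCo = plane through mCo parallel to PMn; GoP = plane through rGo and
   lGo perpendicular to PMn.  Each neutral gonion is its gonion displaced
   purely along the PMn normal until its distance to PMn equals half the
   CPCo–PMn distance — the unique reading under which Gon is simultaneously
   "at the gonion's level" (it stays inside GoP, since GoP contains the PMn
   normal direction) and "halfway between PMn and CPCo".  MRn = plane
   through mCo, rGon, lGon.
7. FOPn = plane through rPoc and lPoc perpendicular to PMn.

Self-check identities, measured (not assumed) on every result: MCFn^PMn =
neutral angle (trace, tangent mode), FOPn^PMn = 90°, PMn^PM = 0°, |Ba–SEn| =
sphere radius, Gon equidistance — all to 1e-9 in the tests.

### Neutral track (2-D)

The classical drawing: circle centered at **Ar** with radius |Ar–SE| (the
2-D construction pivots on articulare, the 3-D one on basion — both are
implemented as their respective traditions define them, and the discrepancy
is part of what the cohort comparison measures).  SEn is the anterior
circle point whose ray from Ar makes the neutral angle with the PM
direction; by alternate interior angles the vertex angle at SEn between
MCFn (Ar–SEn) and PMn (∥ PM through SEn) is then the same value.  Gon keeps
Go's coordinate along PMn and sits halfway between PMn and its parallel
through Ar; MRn = Ar–Gon; FOPn ⊥ PMn through Poc.

## Numerical choices

* Degeneracy tolerance 1e-9 (mm or mm²): triangle areas, cross-product
  norms, segment-in-plane tests.
* All angles are computed as `atan2(|u×v|, u·v)`, not `arccos(u·v)`: near 0°
  and 180° the arccos form turns one-ulp dot-product noise into ~1e-6°
  errors, which would swamp the construction's exact identities.
* Branch selectors are direction hints (maximize the dot product); a tie
  between geometrically distinct candidates raises a branch-ambiguity error
  rather than guessing.
* Angle-returning APIs are degrees; radians are internal only.

## Synthetic data generator

The generator emulates a bilaterally quasi-symmetric skeletal-Class-I-like
anatomy from a fixed mirror-symmetric template (Ba at the origin, cranial
floor mid-chord at (0, 45, 18) mm, so the construction sphere radius is
48.47 mm).  Knobs, in application order:

1. global `scale` (cohort default U(0.9, 1.1));
2. `ramus_angle_offset` — rotates the gonions about the lateral axis through
   mCo; by construction it shifts the trace-convention MCF^MR by exactly the
   offset, which the recovery tests exploit as ground truth;
3. `cranial_base_offset` — rotates Ba about the lateral axis through the MCF
   mid-chord, shifting MCF^PM by exactly the offset (cohort default for both
   offsets: N(0, 3°));
4. `asymmetry` — each bilateral pair is shifted laterally by a uniform draw
   in ±amplitude (cohort default amplitude U(0, 2) mm);
5. `noise_sd` — isotropic Gaussian noise on every landmark (cohort default
   0.5 mm, chosen so cohort angle SDs land in the few-degree range typical
   of cephalometric samples; the angle-SD-vs-noise relation is asserted
   monotone in the tests rather than calibrated to any external dataset).

The paired 2-D set is the exact mid-sagittal projection (the generator works
in the canonical frame, so projection drops x): SE, Ptm, Go, Poc, Aoc are
projections of the corresponding mid-chords/midpoints.  **Ar** has no 3-D
counterpart; it is emulated as the foot of the perpendicular from the
projected mCo onto the projected cranial-base line (Ba–SE).  Articulare
lies on the cranial-base shadow near the condyle, and this rule makes the
2-D MCF line collinear with the 3-D MCF plane's sagittal trace, so
noise-free symmetric subjects reproduce MCF^PM identically in 2-D and 3-D
(asserted to 1e-6°).  MCF^MR retains a small systematic 2-D/3-D gap (~0.1°
on the template, up to ~1° at large rotational offsets) because the 2-D
ramus ray is anchored at Ar rather than at the projected mCo — a real
feature of the 2-D method, not a bug, and precisely what the paired
comparison is for.

What the generator does **not** emulate: true cortical-surface landmark
ambiguity, scanner distortion, occlusal artifacts, or any correlation
structure between landmarks beyond the rigid group rotations.  Passing tests
therefore demonstrate the geometry and the statistical procedure, not
clinical accuracy on real CBCT data.

Cohort generation derives subject *i*'s RNG stream from
`SeedSequence(master_seed, spawn_key=(i,))`, so cohorts are bit-reproducible
and subjects independent of cohort size.

## Statistics

Implemented from their formulas (scipy supplies only distribution
functions; library implementations appear as cross-checks in tests):

* descriptives: mean and sample SD (n−1);
* normality: KS sup-distance against N(sample mean, sample SD).  Because the
  parameters are estimated, the p-value uses the **Lilliefors** correction —
  Monte-Carlo null distribution of D (10⁴ replicates, fixed seed, cached per
  sample size).  A `naive` option computes the classical KS p for
  comparison; it is anticonservative here (the tests assert the ordering);
* paired t: t = mean(d)/(sd(d)/√n) on d = 2D−3D, df = n−1, two-sided p.
  Type-I error is calibrated to 0.05 ± 0.015 over 2000 seeded null
  replicates at n = 18, SD 4°.
* significance threshold α = 0.05 throughout; per-variable failures in a
  cohort run are collected into the report, not raised.

## Problem sizes

Defaults keep everything desk-scale: cohort runs use n = 18 subjects;
the brute-force SEn cross-check samples 10⁶ circle points; the invariance
suite applies 100 random similarity transforms; statistical calibration uses
2000 replicates.  The full test suite runs in a few seconds.

## Known limitations

* The mid-sagittal estimator assumes roughly bilateral anatomy; grossly
  asymmetric inputs degrade MCFx and everything downstream (the parser's
  validation warns on inverted laterality but cannot judge clinical
  plausibility).
* The 2-D/3-D comparability of MCF^MR depends on how articulare is related
  to the condylar axis; the generator's Ar rule is one deterministic choice,
  and real cephalograms will differ.
* `on_sphere` mode's flank placement uses the constant-elevation circle; an
  axial-slice placement tied to scanner orientation is deliberately not
  offered, as it would break rigid-motion invariance.
* No normative database of individual-vs-neutral deltas is included; the
  track-delta output is descriptive, not a severity classification.
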