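# Methods

This note documents the models, conventions and numerical choices behind
`planscope`, in the spirit of a methods appendix: what each quantity means,
which decisions were genuinely open, and what the synthetic fixtures do and
do not demonstrate.

## Plan model and the segment-time problem

A VMAT arc is modeled as its DICOM control-point sequence: per control
point, the gantry angle, the cumulative meterset weight (normalized to
[0, 1]), both MLC bank tip positions on the IEC-X axis, and the X/Y jaws.
Leaf-pair boundaries live on IEC-Y; the pair gap is `bank_b − bank_a` and
must be ≥ −0.01 mm (float tolerance for the interdigitation check).
Only MLCX-type machines and single fraction groups are supported; setup
fields without an MLC sequence are skipped with a warning on read.

DICOM plans carry no timestamps, so leaf speeds and accelerations need a
delivery-time model.  Each segment's duration is the longest of its three
mechanical bottlenecks — gantry rotation, dose-rate-limited MU delivery,
and the fastest-moving leaf:

    t_i = max( |Δgantry_i| / v_gantry,  ΔMU_i / (Ṁ_max/60),  max_leaf |Δx| / v_leaf )

with configurable machine limits defaulting to a TrueBeam-class linac:
4.8 °/s, 600 MU/min, 25 mm/s.  Gantry deltas are shortest-arc absolute
values, so the model is invariant to arc direction.  This is the standard
reconstruction used for complexity analysis; absolute speed/acceleration
values (and hence the LS/LA fractions) scale with the assumed limits,
which is why the limits are part of the configuration rather than
constants.

## Complexity scores

Leaf speed for segment *i* is `|Δx|/t_i` per leaf and bank; acceleration
at interior control point *j* is `|v_j − v_{j−1}| / (½(t_{j−1}+t_j))`.
LS/LA report the fraction of samples in half-open bins (default 4 mm/s
bins to 20 plus overflow; 40 mm/s² bins to 200 plus overflow; the
headline bins are [16, 20) mm/s and [160, 200) mm/s²).  The denominator
pools moving **and** static leaf samples of a bank — whether static leaves
belong in the denominator is a genuine convention choice; pooling them is
the one adopted here and the generator's expected values follow it.

Aperture scores are evaluated per control point and combined into a
per-arc value as a delivered-MU-weighted mean over segments (the segment
value being the midpoint of its two bounding control points).  For
uniformly spaced meterset weights this reduces to a plain mean; a switch
disables the weighting.  Conventions:

- **CAS** counts leaves, not pairs: a bank-A tip strictly past x = 0, or a
  bank-B tip strictly before it, each add one crossing; the denominator is
  2 × (pairs inside the Y jaws).  Note that because `bank_b ≥ bank_a`, the
  two leaves of one pair can never both cross, so a single control point's
  crossing fraction cannot exceed 0.5 under this definition.
- **CLS** calls a pair closed when its gap ≤ 0.5 mm (`closed_tolerance`);
  exact zero gaps are rare in clinical DICOM because of dosimetric leaf
  gaps.
- **SAS_x** divides pairs with `closed_tolerance < gap < x` by the open
  pairs only (gap > tolerance); control points with no open pair
  contribute zero.  SAS is monotone non-decreasing in x by construction.
- **MFA** sums, over pairs inside the Y jaws, the gap clipped laterally to
  the X jaws times the leaf width.
- Pairs whose boundary strip lies fully outside the Y jaws are excluded
  from all denominators.

At plan level, CAS/CLS/SAS are **summed over arcs** by default.  Summing
is how multi-arc head-and-neck tabulations that report CAS > 1 or
SAS > 100% come about, and it keeps per-arc and per-plan values in a
fixed relationship; a `mu_weighted_mean` switch yields normalized
plan values instead.  MFA aggregates as a MU-weighted mean over arcs,
LS/LA fractions pool all arcs' samples, and MU/CP is total MU over total
control points (pooled, not a mean of ratios).

## DVH and plan quality

Structures are rasterized by voxel-center inclusion: a voxel belongs to a
structure when its center lies inside the polygons of the nearest contour
slice (|Δz| ≤ dz/2), with the even-odd rule so nested contours form holes.
On a 1-mm grid this carries a 1–2% volume error; an n×n in-plane
supersampling option (majority vote) is available for cochlea-scale
structures.  Cumulative DVHs use 0.01-Gy bins; D_x% readouts interpolate
linearly within bins and return the highest dose covering at least the
requested volume; D_1cc converts 1 cm³ through the structure volume.
D_max is the maximum voxel dose (not D0.035cc).

`CN = (PTV_PD/PTV)·(PTV_PD/PIV)` with PIV taken over the body mask when
one is provided, else the whole grid.  `HI = (D2 − D98)/D50`.  Protocol
constraints are strict inequalities; a rule may carry an "or" alternate
(e.g. D_max < 54 Gy *or* D1% < 60 Gy) and paired organs support a
one-side alternate (mean < 26 Gy, or one parotid < 30 Gy).  The bundled
lens limit uses the permissive end (15 Gy) of the protocol's 6–15 Gy
range.  The hot-spot check flags a body maximum strictly above 110% of
prescription; the normalization scale is `prescription / D95(PTV)` where
D95 is the **exact voxel quantile** rather than the interpolated DVH
readout, so that applying the scale guarantees V100 ≥ 95% afterwards.

## Gamma analysis

2D global gamma, mirroring EPID portal-dosimetry practice: the dose
difference is normalized to the maximum of the reference image, the 10%
threshold excludes low-dose reference pixels from numerator and
denominator, and the evaluated image is sampled by bilinear interpolation
over a search disc of radius 3×DTA at a step of DTA/10 (both
configurable; the search visits offsets by increasing radius and stops
once the spatial term alone exceeds every pixel's running minimum, which
makes the identity case cheap).  Local-normalization gamma and 3D gamma
are out of scope.  Tests cross-check the rates against an independent
per-pixel exhaustive search at half the step size; agreement is within
0.5 percentage points on 64×64 fields.

## Paired cohort statistics

The Wilcoxon signed-rank test is implemented directly: zero differences
are dropped before ranking (Wilcoxon's convention; Pratt's available),
tied magnitudes receive mid-ranks, and for n ≤ 25 the two-sided p-value
comes from the exact null distribution, computed by dynamic programming
over doubled (hence integer) rank sums — identical to enumerating all 2ⁿ
sign assignments.  Beyond n = 25 a normal approximation with tie
correction and a 0.5 continuity correction is used; at n = 20 the two
paths agree within 0.01.  Comparisons are two-sided at α = 0.05 with
pairwise deletion of incomplete patients and **no multiplicity
correction** — deliberately matching common practice in paired planning
studies; with a dozen metrics the family-wise error is accordingly
higher than 5% unless differences are strongly correlated (see the
cohort generator below).

## Synthetic fixtures: what they emulate, and what they do not

**Plans.**  Arcs default to 178 control points (a full 358° arc at ~2°
spacing) driving 60 pairs of 5-mm leaves, 3 or 4 arcs, ~550 MU total.
Each pair is assigned a persistent state — closed at the midline,
small-aperture (gap drawn in 0.6–0.9 of the stated threshold), or wide
open (gap ~ N(30, 5) mm clipped) — with crossing pairs held on one side
of the axis; rounded state counts make the per-control-point CAS/CLS/SAS
exact by construction.  Pairs then oscillate rigidly as triangle waves on
a 0.01-mm lattice at speeds drawn from a piecewise-constant profile
(clamped to each pair's feasible excursion), so segment times stay
gantry-limited and realized speeds match the programmed ones to ~0.2%.
Positions, weights and dose values are pre-quantized to what the DICOM
writers store, making write→read round trips bit-lossless.  These plans
exercise every metric path and the I/O, but they are *not* dosimetrically
realistic: apertures do not conform to an anatomy, speed profiles are
stationary, and accelerations are near zero (the LA fractions of real
plans are nonzero).  Passing recovery tests therefore demonstrates metric
correctness, not clinical realism.

**Dose cases.**  A simultaneous-integrated-boost-like geometry: nested
PTV spheres (20/30/40 mm), OAR spheres, a body sphere, and a spherically
symmetric sigmoid dose `D(r) = D_max σ((r_iso − r)/w)` placed so the
prescription isodose sits exactly at a chosen radius.  Concentric mode
sets that radius from the requested coverage; offset mode shifts the dose
sphere so the conformity number follows the analytic sphere-overlap
volume.  Expected CN/HI are computed analytically, making the phantom an
oracle for the DVH pipeline at rasterization accuracy (±0.03 on CN on a
1-mm grid).  Real dose distributions are neither spherical nor monotone;
the phantom validates arithmetic, not dose-calculation fidelity.

**Gamma pairs.**  A smooth three-lobe Gaussian field; the evaluated image
is an analytic resample (exact sub-pixel shift), a global scale, plus
spatially correlated Gaussian noise (σ = 2 px smoothing) mimicking EPID
noise.  Pure-scale and pure-shift cases have closed-form pass/fail
expectations.

**Cohorts.**  Paired metric tables for n patients (default 20, arcs drawn
3-or-4 at the 9:11 split).  Cohort B = cohort A + per-metric shifts + a
paired perturbation.  The perturbation is a single per-patient latent
"re-optimization shift", scaled to each metric's characteristic
magnitude and **fully correlated across metrics** by default: one
re-optimization moves all modulation metrics of that plan together, and
this choice also keeps the family-wise false-positive rate of the
uncorrected 12-metric comparison at the single-test level, so a null
cohort shows no significant metric in ~95% of runs.  An independent
per-metric noise component can be added; doing so raises the family-wise
rate accordingly.  Values are not clipped to physical ranges, preserving
the exact symmetry of null differences.

## Numerical details and limitations

- Half-open bins everywhere a range is binned; values exactly at an upper
  edge fall in the next bin.
- DVH readouts are exact to one 0.01-Gy bin; CN is exact given the masks.
- The gamma search is a discrete minimum: rates are accurate to the
  offset step (≤ 0.5 pp at DTA/10 on the fixture fields); pixels outside
  the evaluated image are sampled edge-extended.
- Degenerate inputs raise typed errors: empty masks, all-zero paired
  differences, zero-MU beams, empty value arrays.
- Problem sizes used by the shipped acceptance script: 20 five-control-
  point oracle plans, one full 3-arc 178×60 plan, 100 random plans for
  the SAS ordering, a 128³ 1-mm phantom, 64×64 gamma fields, 10⁴
  signed-rank null replicates at n = 20, and 120 cohort simulations —
  together they complete in well under a minute on one core, and the
  choices balance statistical resolution against runtime.
- Not covered: step-and-shoot IMRT, dynamic jaws, couch motion,
  dual-layer MLCs, biological indices, local gamma, 3D gamma, dose
  calculation, and multiple-testing correction (reported p-values are
  per-metric).
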