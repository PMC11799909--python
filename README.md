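# planscope

Analysis toolkit for volumetric-modulated arc therapy (VMAT) treatment
plans: MLC beam-complexity scores from DICOM-RT plans, DVH-based
plan-quality metrics against a head-and-neck constraint protocol,
2D gamma-index patient-specific QA, and paired nonparametric cohort
comparison — plus a synthetic-data generator that produces DICOM-valid
multi-arc head-and-neck fixtures with analytic ground truth.

It is written for medical physicists and researchers who evaluate
automated or knowledge-based planning pipelines: given two paired sets of
plans (for example, re-optimized vs. original), `planscope` extracts every
number such an evaluation reports and tests the differences.

## What it computes

**Beam complexity** (per arc, and aggregated per plan) from the DICOM
control-point sequence:

- LS / LA — fractions of leaf-speed and leaf-acceleration samples in
  configurable ranges (reported bins: 16–20 mm/s and 160–200 mm/s²,
  per bank A/B). Segment durations follow the standard delivery-time
  model, `t = max(Δgantry/v_g, ΔMU/Ṁ, max|Δleaf|/v_leaf)`, with
  TrueBeam-like defaults (4.8°/s, 600 MU/min, 25 mm/s).
- MFA — monitor-unit-weighted mean field area (mm²).
- CAS — cross-axis score, the proportion of leaf tips extended past the
  IEC-X midline.
- CLS — closed leaf score, the proportion of closed leaf pairs.
- SAS₁/₂/₅/₁₀ — small aperture scores, the percentage of open pairs with
  a gap below 1/2/5/10 mm.
- MU/CP — monitor units per control point.

**Plan quality** from RT Dose + RT Structure Set:

- Conformity number `CN = (PTV_PD/PTV) · (PTV_PD/PIV)`, where PTV_PD is
  the target volume receiving the prescription dose and PIV the total
  volume receiving it.
- Heterogeneity index `HI = (D2 − D98)/D50` of the target DVH.
- D_max / D_mean / D_1cc / D_1% per organ at risk, evaluated against a
  bundled RTOG-0225/0615-style constraint protocol (YAML, editable),
  plus the 110% hot-spot and 95%-coverage normalization checks.

**Patient-specific QA**: global-normalization 2D gamma index at
3%/2 mm, 2%/2 mm and 1%/1 mm (10% low-dose threshold), with Max/Min/
Mean/SD passing-rate tables over a cohort.

**Cohort statistics**: per-metric paired Wilcoxon signed-rank tests
(exact null distribution for n ≤ 25, tie-corrected normal approximation
beyond) at α = 0.05, with mean ± SD (min–max) summaries.

## Worked example

Generate a synthetic 3-arc head-and-neck plan (178 control points per arc,
60 leaf pairs) and score it:

```bash
planscope synth plan --seed 11 -o demo
planscope complexity demo/rtplan.dcm -o demo/complexity.json
cat demo/complexity.json
```

```json
{
  "per_plan": {
    "CAS": 0.8999999999999999,
    "CLS": 0.6000000000000001,
    "LA_A160-200": 0.0,
    "LA_B160-200": 0.0,
    "LS_A16-20": 0.15,
    "LS_B16-20": 0.15,
    "MFA": 4118.9,
    "MU_per_CP": 1.0299623595505618,
    "SAS_10mm": 150.0,
    "SAS_1mm": 0.0,
    "SAS_2mm": 0.0,
    "SAS_5mm": 150.0
  },
  "plan_id": "synthetic"
}
```

The generator was asked (defaults) for per-arc crossing fraction 0.3,
closed fraction 0.2, and 40% of pairs open below 5 mm.  Reading the
output: per-plan CAS/CLS/SAS are *sums over the three arcs* (the
aggregation convention for multi-arc plans, switchable to a MU-weighted
mean), so CAS = 3 × 0.3 and CLS = 3 × 0.2; SAS₅ = 3 × 50%, because 40%
small-aperture pairs among the 80% open pairs is 50% of the open ones;
MFA is the MU-weighted mean aperture area in mm²; MU/CP ≈ 1.0 is typical
for a ~550 MU head-and-neck arc set.  The file `demo/ground_truth.json`
carries the generator's expected values for comparison.

The same CLI exposes `quality`, `gamma`, `compare` (long-format cohort
CSV → Wilcoxon table), `synth case|pair|cohort`, and `run` (batch
pipeline over a patient manifest).  Everything is equally usable as a
library: see `planscope.plan_complexity_report`, `planscope.quality_report`,
`planscope.gamma_map`, `planscope.compare_cohorts`.

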