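"""Synthetic VMAT fixtures with analytic ground truth.

Every generator here emulates the structure of a multi-arc head-and-neck
VMAT cohort — 3 or 4 full arcs of ~178 control points driving 60 MLC leaf
pairs, simultaneous-integrated-boost dose geometry with nested spherical
targets and organ-at-risk spheres, EPID-like 2D dose images, and paired
20-patient metric tables — while keeping every quantity of interest known
by construction.  Generators are pure functions of their seed and
parameters, and ship an expected-value map alongside each fixture so the
measuring modules can be tested for parameter recovery.

Leaf trajectories are triangle waves on an exact 0.01-mm position lattice:
each open pair oscillates rigidly (constant gap) inside a feasibility
interval at a programmed speed, so aperture-state counts — and hence the
cross-axis, closed-leaf and small-aperture scores — are constant across
control points and recovered exactly, while leaf speeds follow the
programmed profile under the default machine limits.  All coordinates are
pre-quantized to the precision the DICOM writers store (0.01 mm positions,
1e-6 meterset weights, 1e-5 Gy dose), so a write/read round trip is
bit-lossless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .plan_model import (
    Beam,
    Contour,
    ControlPoint,
    DoseGrid,
    MachineLimits,
    ParameterError,
    Plan,
    StructureSet,
)
from .gamma_analysis import DoseImage

FULL_ARC_DEG = 358.0
DOSE_QUANTUM = 1e-5       # Gy, matches the RT Dose writer scaling

#: Characteristic scales of the complexity metrics used by the cohort
#: generator (typical multi-arc head-and-neck VMAT magnitudes).
COHORT_BASELINES: dict[str, float] = {
    "LS_A16-20": 0.20, "LS_B16-20": 0.21,
    "LA_A160-200": 0.23, "LA_B160-200": 0.23,
    "MFA": 6300.0, "CAS": 0.85, "CLS": 0.07,
    "SAS_1mm": 64.0, "SAS_2mm": 66.0, "SAS_5mm": 73.0, "SAS_10mm": 87.0,
    "MU_per_CP": 1.0,
}

DEFAULT_SPEED_PROFILE = [(0.0, 0.15), (5.0, 0.20), (10.0, 0.20),
                         (14.0, 0.15), (18.0, 0.20), (23.0, 0.10)]


def _q(x, decimals: int):
    return np.round(np.asarray(x, dtype=float), decimals)


# ---------------------------------------------------------------------------
# Plans
# ---------------------------------------------------------------------------


@dataclass
class SynthPlanParams:
    """Targets and sizes for a synthetic multi-arc VMAT plan.

    ``target_crossing_fraction`` (f), ``target_closed_fraction`` (c) and
    ``small_aperture_fraction`` (s) are fractions of all leaf pairs that are,
    respectively, crossing the midline, closed, and open-but-narrower than
    ``small_gap_mm``.  Because a pair's two leaves can never both cross the
    midline, feasibility requires 2f + c <= 1.
    """

    seed: int = 0
    n_arcs: int = 3
    n_cp_per_arc: int = 178
    n_leaf_pairs: int = 60
    leaf_width: float = 5.0                    # mm
    target_crossing_fraction: float = 0.3      # f
    target_closed_fraction: float = 0.2        # c
    small_aperture_fraction: float = 0.4       # s
    small_gap_mm: float = 5.0                  # gap threshold the s fraction refers to
    aperture_mean: float = 30.0                # mm, gap of wide-open pairs
    aperture_sd: float = 5.0                   # mm
    leaf_speed_profile: list[tuple[float, float]] = field(
        default_factory=lambda: list(DEFAULT_SPEED_PROFILE))
    total_mu: float = 550.0
    jaw_x: tuple[float, float] = (-100.0, 100.0)
    jaw_y: tuple[float, float] = (-150.0, 150.0)
    machine_limits: MachineLimits = field(default_factory=MachineLimits)
    plan_id: str = "synthetic"

    def __post_init__(self) -> None:
        f, c, s = (self.target_crossing_fraction, self.target_closed_fraction,
                   self.small_aperture_fraction)
        if not (0 <= f <= 1 and 0 <= c <= 1 and 0 <= s <= 1):
            raise ParameterError("f, c, s must lie in [0, 1]")
        if 2 * f + c > 1 + 1e-9:
            raise ParameterError(
                "infeasible targets: crossing pairs must be open and one-sided, "
                "so 2f + c <= 1 is required")
        if s + c > 1 + 1e-9:
            raise ParameterError("infeasible targets: s + c <= 1 is required")
        if self.n_arcs < 1 or self.n_cp_per_arc < 2 or self.n_leaf_pairs < 1:
            raise ParameterError("plan sizes must be positive")
        speeds = [v for v, _ in self.leaf_speed_profile]
        if any(v < 0 for v in speeds):
            raise ParameterError("programmed speeds must be non-negative")
        if max(speeds) > self.machine_limits.max_leaf_speed:
            raise ParameterError("programmed speed exceeds the machine leaf-speed limit")


def _triangle_positions(lo: float, step: float, m: int, phase: int,
                        n_cp: int) -> np.ndarray:
    """Triangle-wave lattice positions lo + j*step with j bouncing in [0, m]."""
    k = np.arange(n_cp) + phase
    j = m - np.abs(m - (k % (2 * m)))
    return _q(lo + j * step, 2)


def _synth_beam(params: SynthPlanParams, rng: np.random.Generator,
                arc_index: int, beam_mu: float) -> tuple[Beam, dict]:
    n = params.n_leaf_pairs
    n_cp = params.n_cp_per_arc
    limits = params.machine_limits
    step_g = FULL_ARC_DEG / (n_cp - 1)
    t_nom = step_g / limits.max_gantry_speed
    x1, x2 = params.jaw_x

    n_closed = round(params.target_closed_fraction * n)
    n_small = round(params.small_aperture_fraction * n)
    n_open = n - n_closed
    n_cross = round(2 * params.target_crossing_fraction * n)
    if n_cross > n_open or n_small > n_open:
        raise ParameterError("rounded state counts are infeasible at this n_leaf_pairs")

    order = rng.permutation(n)
    closed_idx = order[:n_closed]
    small_idx = order[n_closed:n_closed + n_small]
    open_idx = order[n_closed:]
    cross_idx = open_idx[rng.permutation(n_open)[:n_cross]]

    gaps = np.zeros(n)
    gaps[small_idx] = _q(rng.uniform(0.6, 0.9, n_small) * params.small_gap_mm, 2)
    wide_idx = np.setdiff1d(open_idx, small_idx, assume_unique=False)
    lo_gap = max(12.0, 1.2 * params.small_gap_mm)
    wide = np.clip(rng.normal(params.aperture_mean, params.aperture_sd, wide_idx.size),
                   lo_gap, 60.0)
    gaps[wide_idx] = _q(wide, 2)

    cross_side = np.zeros(n, dtype=int)          # +1: bank A crosses, -1: bank B
    cross_side[cross_idx] = rng.choice([1, -1], n_cross)

    speeds_profile = np.array([v for v, _ in params.leaf_speed_profile])
    weights = np.array([w for _, w in params.leaf_speed_profile], dtype=float)
    weights /= weights.sum()
    programmed = rng.choice(speeds_profile, size=n, p=weights)
    programmed[closed_idx] = 0.0

    bank_a = np.zeros((n_cp, n))
    realized_speed = np.zeros(n)
    for p in range(n):
        g = gaps[p]
        if p in closed_idx:
            bank_a[:, p] = 0.0
            continue
        if cross_side[p] == 1:        # bank A tip stays > 0
            lo, hi = 0.5, min(x2 - g, 40.0)
        elif cross_side[p] == -1:     # bank B tip stays < 0: a in [x1, -0.5-g]
            lo, hi = max(x1, -40.0 - g), -0.5 - g
        else:                         # straddle: a < 0 < a+g
            delta = min(0.25, g / 4.0)
            lo, hi = delta - g, -delta
        width = hi - lo
        if width <= 0.02:
            bank_a[:, p] = _q(0.5 * (lo + hi), 2)
            continue
        step = round(programmed[p] * t_nom, 2)
        if step < 0.01:
            bank_a[:, p] = _q(lo + rng.uniform(0, width), 2)
            continue
        if step > width:
            step = math.floor(width * 100) / 100.0
        m = max(1, int(math.floor(width / step)))
        phase = int(rng.integers(0, 2 * m))
        bank_a[:, p] = _triangle_positions(round(lo, 2), step, m, phase, n_cp)
        realized_speed[p] = step / t_nom
    bank_b = _q(bank_a + gaps, 2)

    direction = "CW" if arc_index % 2 == 0 else "CCW"
    start = float(rng.uniform(0, 360))
    sign = -1.0 if direction == "CW" else 1.0
    angles = _q((start + sign * step_g * np.arange(n_cp)) % 360.0, 2)
    mw = _q(np.arange(n_cp) / (n_cp - 1), 6)
    mw[-1] = 1.0

    half = params.leaf_width * n / 2.0
    boundaries = _q(-half + params.leaf_width * np.arange(n + 1), 2)
    cps = [
        ControlPoint(
            index=i,
            cumulative_meterset_weight=float(mw[i]),
            gantry_angle=float(angles[i]),
            bank_a_positions=bank_a[i].copy(),
            bank_b_positions=bank_b[i].copy(),
            jaw_x=params.jaw_x,
            jaw_y=params.jaw_y,
        )
        for i in range(n_cp)
    ]
    beam = Beam(beam_mu=beam_mu, control_points=cps, leaf_boundaries=boundaries,
                arc_direction=direction, machine_limits=limits,
                name=f"Arc{arc_index + 1}")

    open_gaps = gaps[open_idx]
    expected = {
        "CAS": n_cross / (2 * n),
        "CLS": n_closed / n,
        "MFA": float(np.sum(gaps) * params.leaf_width),
        "MU_per_CP": beam_mu / n_cp,
    }
    for thr in (1.0, 2.0, 5.0, 10.0):
        expected[f"SAS_{thr:g}mm"] = 100.0 * float(
            np.count_nonzero(open_gaps < thr) / max(1, open_gaps.size))
    expected[f"SAS_{params.small_gap_mm:g}mm_target"] = (
        100.0 * params.small_aperture_fraction
        / max(1e-12, 1.0 - params.target_closed_fraction))
    # Both leaves of a pair share its speed, so bank A and B see the same samples.
    ls = float(np.count_nonzero((realized_speed >= 16) & (realized_speed < 20)) / n)
    expected["LS_A16-20"] = ls
    expected["LS_B16-20"] = ls
    expected["LA_A160-200"] = 0.0
    expected["LA_B160-200"] = 0.0
    return beam, expected


def synth_plan(params: SynthPlanParams) -> tuple[Plan, dict]:
    """Generate a synthetic VMAT plan and its expected per-beam metric map."""
    rng = np.random.default_rng(params.seed)
    mu_per_arc = round(params.total_mu / params.n_arcs, 4)
    beams, per_beam = [], []
    for k in range(params.n_arcs):
        beam, exp = _synth_beam(params, rng, k, mu_per_arc)
        beams.append(beam)
        per_beam.append(exp)
    plan = Plan(plan_id=params.plan_id, beams=beams,
                prescription_dose=70.0, n_fractions=33)
    per_plan: dict[str, float] = {}
    for key in ("CAS", "CLS", "SAS_1mm", "SAS_2mm", "SAS_5mm", "SAS_10mm"):
        per_plan[key] = float(sum(e[key] for e in per_beam))
    mu_total = mu_per_arc * params.n_arcs
    per_plan["MFA"] = float(np.mean([e["MFA"] for e in per_beam]))
    per_plan["MU_per_CP"] = mu_total / (params.n_cp_per_arc * params.n_arcs)
    return plan, {"per_beam": per_beam, "per_plan": per_plan}


# ---------------------------------------------------------------------------
# Dose grid + structures
# ---------------------------------------------------------------------------


def sphere_overlap_volume(r1: float, r2: float, d: float) -> float:
    """Intersection volume (mm^3) of two spheres with radii r1, r2 at distance d."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        r = min(r1, r2)
        return 4.0 / 3.0 * math.pi * r**3
    return (math.pi * (r1 + r2 - d) ** 2
            * (d**2 + 2 * d * (r1 + r2) - 3 * (r1 - r2) ** 2)
            / (12 * d))


@dataclass
class SynthCaseParams:
    """Geometry and dose model of a synthetic SIB-like head-and-neck case.

    The dose is a spherically symmetric sigmoid around the boost target::

        D(r) = Dmax * sigmoid((r_iso - r) / w),   Dmax = Rx * (1 + hotspot/100)

    with ``r_iso`` placed so the prescription isodose surface sits exactly at
    the requested radius.  The prescription isodose sphere either sits
    concentric with the target (radius set by ``coverage`` or explicitly) or
    is shifted by ``isodose_offset`` mm, in which case the expected
    conformity number follows from the analytic sphere-overlap volume.
    """

    seed: int = 0
    grid_shape: tuple[int, int, int] = (128, 128, 128)    # (nz, ny, nx)
    spacing: float = 1.0                                  # mm, isotropic
    ptv_radii: dict[str, float] = field(
        default_factory=lambda: {"PTV_high": 20.0, "PTV_intermediate": 30.0,
                                 "PTV_low": 40.0})
    oar_spheres: dict[str, tuple[tuple[float, float, float], float]] = field(
        default_factory=lambda: {
            "Spinal cord": ((0.0, 45.0, 0.0), 6.0),
            "Left parotid": ((-45.0, 0.0, 0.0), 10.0),
            "Right parotid": ((45.0, 0.0, 0.0), 10.0),
        })
    body_radius: float = 60.0
    prescription: float = 70.0                            # Gy
    coverage: float = 0.98                                # fraction of PTV_high at Rx
    isodose_radius: float | None = None                   # mm, overrides coverage
    isodose_offset: float = 0.0                           # mm along +x
    falloff_width: float = 3.0                            # mm, sigmoid scale
    hotspot_percent: float = 7.0                          # Dmax above Rx, %

    def __post_init__(self) -> None:
        radii = sorted(self.ptv_radii.values())
        if any(r <= 0 for r in radii):
            raise ParameterError("PTV radii must be positive")
        if not 0 < self.coverage <= 1:
            raise ParameterError("coverage must lie in (0, 1]")
        extent = min(self.grid_shape) * self.spacing / 2.0
        if max(radii) + abs(self.isodose_offset) >= extent:
            raise ParameterError("PTV is not contained in the dose grid")


def _sphere_contours(center: tuple[float, float, float], radius: float,
                     zs: np.ndarray, n_vertices: int = 72) -> list[Contour]:
    cx, cy, cz = center
    contours = []
    theta = 2 * math.pi * np.arange(n_vertices) / n_vertices
    for z in zs:
        h = z - cz
        if abs(h) >= radius:
            continue
        r_sl = math.sqrt(radius**2 - h**2)
        if r_sl < 0.5:
            continue
        verts = np.column_stack([cx + r_sl * np.cos(theta), cy + r_sl * np.sin(theta)])
        contours.append(Contour(z=float(z), vertices=_q(verts, 2)))
    return contours


def offset_for_coverage(radius: float, coverage: float) -> float:
    """Center offset making two equal spheres of ``radius`` overlap by ``coverage``."""
    if not 0 < coverage < 1:
        raise ParameterError("coverage must lie in (0, 1) for an offset construction")
    v_full = 4.0 / 3.0 * math.pi * radius**3
    return float(brentq(
        lambda d: sphere_overlap_volume(radius, radius, d) - coverage * v_full,
        1e-9, 2 * radius - 1e-9))


def _case_dose_profile(params: SynthCaseParams) -> tuple[float, float, float]:
    """(r_p, r_iso, dmax): prescription radius, sigmoid midpoint shift, peak dose."""
    r_high = min(params.ptv_radii.values())
    if params.isodose_radius is not None:
        r_p = params.isodose_radius
    elif params.isodose_offset > 0:
        # Offset mode keeps the target's radius for the prescription isodose;
        # the achieved coverage is reported in the expected map.
        r_p = r_high
    else:
        r_p = r_high * params.coverage ** (1.0 / 3.0)
    dmax = params.prescription * (1.0 + params.hotspot_percent / 100.0)
    frac = params.prescription / dmax
    r_iso = r_p + params.falloff_width * math.log(frac / (1.0 - frac))
    return r_p, r_iso, dmax


def _dose_at_radius(r: np.ndarray, params: SynthCaseParams) -> np.ndarray:
    _, r_iso, dmax = _case_dose_profile(params)
    return dmax / (1.0 + np.exp(np.clip((r - r_iso) / params.falloff_width, -60, 60)))


def synth_case(params: SynthCaseParams) -> tuple[DoseGrid, StructureSet, dict]:
    """Generate a dose grid, structure set and expected CN/HI map."""
    nz, ny, nx = params.grid_shape
    sp = params.spacing
    origin = (-(nx - 1) / 2.0 * sp, -(ny - 1) / 2.0 * sp, -(nz - 1) / 2.0 * sp)
    xs = origin[0] + sp * np.arange(nx)
    ys = origin[1] + sp * np.arange(ny)
    zs = origin[2] + sp * np.arange(nz)

    r_p, r_iso, dmax = _case_dose_profile(params)
    off = params.isodose_offset
    zz, yy, xx = np.meshgrid(zs, ys, xs, indexing="ij")
    r = np.sqrt((xx - off) ** 2 + yy**2 + zz**2)
    dose = _dose_at_radius(r, params)
    dose = np.round(dose / DOSE_QUANTUM) * DOSE_QUANTUM
    grid = DoseGrid(values=dose, origin=origin, spacing=(sp, sp, sp))

    structures: dict[str, list[Contour]] = {}
    for name, radius in params.ptv_radii.items():
        structures[name] = _sphere_contours((0.0, 0.0, 0.0), radius, zs)
    for name, (center, radius) in params.oar_spheres.items():
        structures[name] = _sphere_contours(center, radius, zs)
    structures["BODY"] = _sphere_contours((0.0, 0.0, 0.0), params.body_radius, zs)
    ss = StructureSet(structures=structures)

    r_high = min(params.ptv_radii.values())
    v_ptv = 4.0 / 3.0 * math.pi * r_high**3
    v_iso = 4.0 / 3.0 * math.pi * r_p**3
    v_overlap = sphere_overlap_volume(r_high, r_p, off)
    cn = (v_overlap / v_ptv) * (v_overlap / v_iso) if v_iso > 0 else 0.0

    expected: dict = {"CN": cn, "prescription_radius_mm": r_p,
                      "coverage": v_overlap / v_ptv,
                      "max_dose": float(dose.max())}
    if off == 0:
        # Dose is monotone in r, so D_q sits at the radius enclosing q% volume.
        def d_at(q: float) -> float:
            return float(_dose_at_radius(np.array([r_high * (q / 100.0) ** (1 / 3)]),
                                         params)[0])
        d2, d50, d98 = d_at(2), d_at(50), d_at(98)
        expected["HI"] = (d2 - d98) / d50
        expected["D2"], expected["D50"], expected["D98"] = d2, d50, d98
    return grid, ss, expected


# ---------------------------------------------------------------------------
# Gamma image pairs
# ---------------------------------------------------------------------------


def synth_dose_pair(
    seed: int = 0,
    shift_mm: tuple[float, float] = (0.0, 0.0),
    scale_percent: float = 0.0,
    noise_percent: float = 0.0,
    shape: tuple[int, int] = (64, 64),
    spacing: tuple[float, float] = (2.0, 2.0),
) -> tuple[DoseImage, DoseImage]:
    """A smooth multi-lobe reference field and a transformed copy.

    The evaluated image is the analytic reference resampled at coordinates
    shifted by ``shift_mm`` (y, x), scaled by ``1 + scale_percent/100``, with
    spatially correlated Gaussian noise of ``noise_percent`` of the maximum
    added (mimicking EPID noise).  Pure-scale and pure-shift cases therefore
    have exact gamma expectations.
    """
    rng = np.random.default_rng(seed)
    ny, nx = shape
    ys = np.arange(ny) * spacing[0]
    xs = np.arange(nx) * spacing[1]
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    cy, cx = ys[-1] / 2.0, xs[-1] / 2.0
    lobes = [
        (1.0, cy - 15.0, cx - 20.0, 18.0),
        (0.8, cy + 18.0, cx + 12.0, 15.0),
        (0.6, cy - 5.0, cx + 30.0, 12.0),
    ]

    def field_at(y, x):
        out = np.zeros_like(y, dtype=float)
        for amp, ly, lx, sigma in lobes:
            out += amp * np.exp(-((y - ly) ** 2 + (x - lx) ** 2) / (2 * sigma**2))
        return 100.0 * out

    ref = field_at(yy, xx)
    ev = (1.0 + scale_percent / 100.0) * field_at(yy - shift_mm[0], xx - shift_mm[1])
    if noise_percent > 0:
        from scipy.ndimage import gaussian_filter

        raw = gaussian_filter(rng.standard_normal(shape), sigma=2.0)
        raw /= raw.std()
        ev = ev + noise_percent / 100.0 * ref.max() * raw
    ev = np.maximum(ev, 0.0)
    return DoseImage(values=ref, spacing=spacing), DoseImage(values=ev, spacing=spacing)


# ---------------------------------------------------------------------------
# Paired cohorts
# ---------------------------------------------------------------------------


def synth_cohort(
    seed: int = 0,
    n_patients: int = 20,
    effects: dict[str, float] | None = None,
    metrics: list[str] | None = None,
    between_patient_sd: float = 0.15,
    paired_noise_sd: float = 0.05,
    independent_noise_sd: float = 0.0,
    cohort_labels: tuple[str, str] = ("original", "reoptimized"),
) -> tuple[pd.DataFrame, dict]:
    """Paired per-patient metric values for two cohorts with known effects.

    Cohort B equals cohort A plus the specified per-metric shifts plus a
    paired perturbation.  The perturbation is a single per-patient latent
    "re-optimization shift" scaled to each metric's characteristic magnitude:
    re-optimizing one plan moves all its modulation metrics jointly, so the
    paired noise is fully correlated across metrics by default
    (``independent_noise_sd`` adds an uncorrelated component).  SDs are
    fractions of each metric's characteristic scale.

    Returns a long-format table (patient_id, cohort, metric, value, n_arcs)
    and an expected map naming the metrics that truly differ.
    """
    if n_patients < 2:
        raise ParameterError("a cohort needs at least 2 patients")
    rng = np.random.default_rng(seed)
    effects = effects or {}
    metrics = metrics or list(COHORT_BASELINES)
    unknown = set(effects) - set(metrics)
    if unknown:
        raise ParameterError(f"effects given for unknown metrics: {sorted(unknown)}")

    # 3 vs 4 full arcs drawn at the 9:11 split typical of 20-patient cohorts.
    n_arcs = rng.choice([3, 4], size=n_patients, p=[0.45, 0.55])
    latent = rng.standard_normal(n_patients)

    rows = []
    a_label, b_label = cohort_labels
    for m in metrics:
        mu = COHORT_BASELINES.get(m, 1.0)
        scale = abs(mu) if mu != 0 else 1.0
        base = mu + between_patient_sd * scale * rng.standard_normal(n_patients)
        shift = effects.get(m, 0.0)
        noise = paired_noise_sd * scale * latent
        if independent_noise_sd > 0:
            noise = noise + independent_noise_sd * scale * rng.standard_normal(n_patients)
        for i in range(n_patients):
            pid = f"P{i + 1:03d}"
            rows.append((pid, a_label, m, base[i], int(n_arcs[i])))
            rows.append((pid, b_label, m, base[i] + shift + noise[i], int(n_arcs[i])))
    table = pd.DataFrame(rows, columns=["patient_id", "cohort", "metric",
                                        "value", "n_arcs"])
    expected = {"shifted_metrics": sorted(k for k, v in effects.items() if v != 0),
                "cohorts": list(cohort_labels), "n_patients": n_patients}
    return table, expected
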