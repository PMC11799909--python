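"""MLC beam-complexity scores for VMAT arcs.

Implements the standard aperture-based complexity family: fractions of leaf
speed (LS) and leaf acceleration (LA) falling in configurable ranges, the
MU-weighted mean field area (MFA), the cross-axis score (CAS, proportion of
leaf tips crossing the beam central axis), the closed leaf score (CLS), the
small aperture scores (SAS) at 1/2/5/10 mm gap thresholds, and monitor units
per control point (MU/CP).

Per-beam aperture scores are delivered-MU-weighted means over segments (the
segment value being the mean of its two bounding control points), which
reduces to a plain control-point mean for uniform meterset spacing.  At plan
level, CAS/CLS/SAS are summed over arcs by default, MFA is MU-weighted over
arcs, LS/LA fractions pool the samples of all arcs, and MU/CP is total MU
over total control points.  The sum aggregation (which lets multi-arc plans
exceed 1, resp. 100%) matches how multi-arc head-and-neck plans are commonly
tabulated; a MU-weighted-mean switch is provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .plan_model import Beam, ControlPoint, ParameterError, Plan, segment_times

DEFAULT_SPEED_BINS = [(0.0, 4.0), (4.0, 8.0), (8.0, 12.0), (12.0, 16.0),
                      (16.0, 20.0), (20.0, math.inf)]
DEFAULT_ACCEL_BINS = [(0.0, 40.0), (40.0, 80.0), (80.0, 120.0), (120.0, 160.0),
                      (160.0, 200.0), (200.0, math.inf)]

#: JSON report keys, in output order.
REPORT_KEYS = [
    "LS_A16-20", "LS_B16-20", "LA_A160-200", "LA_B160-200",
    "MFA", "CAS", "CLS", "SAS_1mm", "SAS_2mm", "SAS_5mm", "SAS_10mm",
    "MU_per_CP",
]


@dataclass
class ComplexityConfig:
    """Tunable conventions behind the complexity scores.

    speed_bins / accel_bins are half-open [lo, hi) ranges in mm/s and mm/s^2;
    the reported LS/LA keys pick the 16-20 mm/s and 160-200 mm/s^2 bins.
    ``closed_tolerance`` is the gap (mm) at or below which a leaf pair counts
    as closed.  ``plan_aggregation`` chooses how per-arc CAS/CLS/SAS combine
    into a plan value.
    """

    speed_bins: list[tuple[float, float]] = field(
        default_factory=lambda: list(DEFAULT_SPEED_BINS))
    accel_bins: list[tuple[float, float]] = field(
        default_factory=lambda: list(DEFAULT_ACCEL_BINS))
    sas_thresholds: list[float] = field(default_factory=lambda: [1.0, 2.0, 5.0, 10.0])
    closed_tolerance: float = 0.5          # mm
    plan_aggregation: str = "sum"          # "sum" | "mu_weighted_mean"
    mu_weighted: bool = True               # ΔMU-weight per-beam aperture scores
    ls_report_bin: tuple[float, float] = (16.0, 20.0)
    la_report_bin: tuple[float, float] = (160.0, 200.0)

    def __post_init__(self) -> None:
        for bins in (self.speed_bins, self.accel_bins):
            for (lo1, hi1), (lo2, _) in zip(bins, bins[1:]):
                if not (lo1 < hi1 <= lo2):
                    raise ParameterError("bins must be ordered and non-overlapping")
        if sorted(self.sas_thresholds) != list(self.sas_thresholds):
            raise ParameterError("sas_thresholds must be ascending")
        if self.closed_tolerance >= min(self.sas_thresholds):
            raise ParameterError("closed_tolerance must be below the smallest SAS threshold")
        if self.plan_aggregation not in ("sum", "mu_weighted_mean"):
            raise ParameterError("plan_aggregation must be 'sum' or 'mu_weighted_mean'")


# ---------------------------------------------------------------------------
# Kinematics
# ---------------------------------------------------------------------------


def leaf_kinematics(
    beam: Beam, times: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-leaf speeds and accelerations for both banks.

    Returns ``(speed_a, speed_b, accel_a, accel_b)`` with speeds shaped
    (n_leaves, n_segments) in mm/s and accelerations (n_leaves, n_segments-1)
    in mm/s^2.  The acceleration at interior control point j is
    ``|v_j - v_{j-1}| / (0.5 (t_{j-1} + t_j))``.  Static zero-time segments
    yield zero speed.
    """
    times = np.asarray(times, dtype=float)
    a = np.stack([cp.bank_a_positions for cp in beam.control_points])
    b = np.stack([cp.bank_b_positions for cp in beam.control_points])

    def speeds(bank: np.ndarray) -> np.ndarray:
        travel = np.abs(np.diff(bank, axis=0)).T       # (n_leaves, n_seg)
        with np.errstate(divide="ignore", invalid="ignore"):
            v = np.where(times > 0, travel / times, 0.0)
        return v

    def accels(v: np.ndarray) -> np.ndarray:
        if v.shape[1] < 2:
            return np.empty((v.shape[0], 0))
        dt = 0.5 * (times[:-1] + times[1:])
        dv = np.abs(np.diff(v, axis=1))
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(dt > 0, dv / dt, 0.0)

    va, vb = speeds(a), speeds(b)
    return va, vb, accels(va), accels(vb)


def fraction_in_range(values: np.ndarray, lo: float, hi: float) -> float:
    """Fraction of samples with ``lo <= v < hi`` (half-open bin).

    The denominator is every sample passed in — moving and static leaves alike.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ParameterError("fraction_in_range is undefined for empty input")
    if not lo < hi:
        raise ParameterError("range must satisfy lo < hi")
    return float(np.count_nonzero((values >= lo) & (values < hi)) / values.size)


# ---------------------------------------------------------------------------
# Aperture geometry
# ---------------------------------------------------------------------------


def pairs_in_y_jaw(leaf_boundaries: np.ndarray, jaw_y: tuple[float, float]) -> np.ndarray:
    """Boolean mask of leaf pairs whose boundary strip overlaps the Y jaw opening."""
    lo = np.asarray(leaf_boundaries[:-1], dtype=float)
    hi = np.asarray(leaf_boundaries[1:], dtype=float)
    y1, y2 = jaw_y
    return (hi > y1) & (lo < y2)


def aperture_area(
    control_point: ControlPoint, leaf_boundaries: np.ndarray,
    jaws: tuple[tuple[float, float], tuple[float, float]] | None = None,
) -> float:
    """Open aperture area of one control point, mm^2.

    Each pair contributes its open gap clipped laterally to the X jaws, times
    its leaf width; pairs whose strip lies entirely outside the Y jaws are
    excluded.
    """
    jaw_x, jaw_y = jaws if jaws is not None else (control_point.jaw_x, control_point.jaw_y)
    inside = pairs_in_y_jaw(leaf_boundaries, jaw_y)
    a = control_point.bank_a_positions
    b = control_point.bank_b_positions
    open_len = np.maximum(0.0, np.minimum(b, jaw_x[1]) - np.maximum(a, jaw_x[0]))
    widths = np.diff(np.asarray(leaf_boundaries, dtype=float))
    return float(np.sum(open_len * widths * inside))


# ---------------------------------------------------------------------------
# ΔMU-weighted control-point scores
# ---------------------------------------------------------------------------


def _segment_weighted_mean(cp_values: np.ndarray, beam: Beam, config: ComplexityConfig) -> float:
    """ΔMU-weighted mean over segments of the midpoint of bounding CP values."""
    cp_values = np.asarray(cp_values, dtype=float)
    seg_values = 0.5 * (cp_values[:-1] + cp_values[1:])
    if config.mu_weighted:
        w = beam.delta_mu()
        total = w.sum()
        if total <= 0:
            raise ParameterError("all segment MU are zero")
        return float(np.sum(seg_values * w) / total)
    return float(seg_values.mean())


def _cp_cross_fraction(cp: ControlPoint, inside: np.ndarray) -> float:
    n = int(inside.sum())
    if n == 0:
        return 0.0
    cross_a = np.count_nonzero((cp.bank_a_positions > 0) & inside)
    cross_b = np.count_nonzero((cp.bank_b_positions < 0) & inside)
    return (cross_a + cross_b) / (2 * n)


def _cp_closed_fraction(cp: ControlPoint, inside: np.ndarray, tol: float) -> float:
    n = int(inside.sum())
    if n == 0:
        return 0.0
    return np.count_nonzero((cp.gaps <= tol) & inside) / n


def _cp_small_fraction(cp: ControlPoint, inside: np.ndarray, tol: float, thr: float) -> float:
    gaps = cp.gaps
    open_mask = (gaps > tol) & inside
    n_open = int(open_mask.sum())
    if n_open == 0:
        return 0.0
    return np.count_nonzero(open_mask & (gaps < thr)) / n_open


def cas(beam: Beam, config: ComplexityConfig | None = None) -> float:
    """Cross-axis score: proportion of in-field leaf tips past the IEC-X midline."""
    config = config or ComplexityConfig()
    vals = [
        _cp_cross_fraction(cp, pairs_in_y_jaw(beam.leaf_boundaries, cp.jaw_y))
        for cp in beam.control_points
    ]
    return _segment_weighted_mean(np.array(vals), beam, config)


def cls(beam: Beam, config: ComplexityConfig | None = None) -> float:
    """Closed leaf score: proportion of in-field pairs with gap <= closed_tolerance."""
    config = config or ComplexityConfig()
    vals = [
        _cp_closed_fraction(cp, pairs_in_y_jaw(beam.leaf_boundaries, cp.jaw_y),
                            config.closed_tolerance)
        for cp in beam.control_points
    ]
    return _segment_weighted_mean(np.array(vals), beam, config)


def sas(beam: Beam, threshold_mm: float, config: ComplexityConfig | None = None) -> float:
    """Small aperture score at one gap threshold, percent of open pairs."""
    config = config or ComplexityConfig()
    if threshold_mm <= config.closed_tolerance:
        raise ParameterError("SAS threshold must exceed closed_tolerance")
    vals = [
        _cp_small_fraction(cp, pairs_in_y_jaw(beam.leaf_boundaries, cp.jaw_y),
                           config.closed_tolerance, threshold_mm)
        for cp in beam.control_points
    ]
    return 100.0 * _segment_weighted_mean(np.array(vals), beam, config)


def mfa(beam: Beam, config: ComplexityConfig | None = None) -> float:
    """Mean field area: ΔMU-weighted mean aperture area over segments, mm^2."""
    config = config or ComplexityConfig()
    areas = np.array([
        aperture_area(cp, beam.leaf_boundaries, (cp.jaw_x, cp.jaw_y))
        for cp in beam.control_points
    ])
    seg_areas = 0.5 * (areas[:-1] + areas[1:])
    w = beam.delta_mu()
    total = w.sum()
    if total <= 0:
        raise ParameterError("all segment MU are zero")
    return float(np.sum(seg_areas * w) / total)


def mu_per_cp(obj: Plan | Beam) -> float:
    """Monitor units per control point; pooled (ΣMU / ΣCP) for a plan."""
    if isinstance(obj, Beam):
        return obj.beam_mu / obj.n_control_points
    total_mu = sum(b.beam_mu for b in obj.beams)
    total_cp = sum(b.n_control_points for b in obj.beams)
    return total_mu / total_cp


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------


@dataclass
class ComplexityReport:
    """Per-beam and plan-aggregated complexity scores, keyed by REPORT_KEYS."""

    per_beam: list[dict[str, float]]
    per_plan: dict[str, float]
    plan_id: str = ""


def beam_complexity(beam: Beam, config: ComplexityConfig | None = None) -> dict[str, float]:
    """All complexity scores of one arc as a flat dict (REPORT_KEYS)."""
    config = config or ComplexityConfig()
    times = segment_times(beam)
    va, vb, aa, ab = leaf_kinematics(beam, times)
    ls_lo, ls_hi = config.ls_report_bin
    la_lo, la_hi = config.la_report_bin
    out = {
        "LS_A16-20": fraction_in_range(va, ls_lo, ls_hi),
        "LS_B16-20": fraction_in_range(vb, ls_lo, ls_hi),
        "LA_A160-200": fraction_in_range(aa, la_lo, la_hi) if aa.size else 0.0,
        "LA_B160-200": fraction_in_range(ab, la_lo, la_hi) if ab.size else 0.0,
        "MFA": mfa(beam, config),
        "CAS": cas(beam, config),
        "CLS": cls(beam, config),
    }
    for thr in config.sas_thresholds:
        out[f"SAS_{thr:g}mm"] = sas(beam, thr, config)
    out["MU_per_CP"] = mu_per_cp(beam)
    return out


def plan_complexity_report(plan: Plan, config: ComplexityConfig | None = None) -> ComplexityReport:
    """Assemble the per-beam and plan-level complexity report for a plan."""
    config = config or ComplexityConfig()
    per_beam = [beam_complexity(b, config) for b in plan.beams]
    mu = np.array([b.beam_mu for b in plan.beams])
    mu_w = mu / mu.sum()

    per_plan: dict[str, float] = {}
    # LS/LA pooled over all leaf-segment samples of all arcs.
    pooled: dict[str, list[np.ndarray]] = {k: [] for k in
                                           ("LS_A", "LS_B", "LA_A", "LA_B")}
    for b in plan.beams:
        times = segment_times(b)
        va, vb, aa, ab = leaf_kinematics(b, times)
        pooled["LS_A"].append(va.ravel())
        pooled["LS_B"].append(vb.ravel())
        pooled["LA_A"].append(aa.ravel())
        pooled["LA_B"].append(ab.ravel())
    ls_lo, ls_hi = config.ls_report_bin
    la_lo, la_hi = config.la_report_bin
    per_plan["LS_A16-20"] = fraction_in_range(np.concatenate(pooled["LS_A"]), ls_lo, ls_hi)
    per_plan["LS_B16-20"] = fraction_in_range(np.concatenate(pooled["LS_B"]), ls_lo, ls_hi)
    la_a = np.concatenate(pooled["LA_A"])
    la_b = np.concatenate(pooled["LA_B"])
    per_plan["LA_A160-200"] = fraction_in_range(la_a, la_lo, la_hi) if la_a.size else 0.0
    per_plan["LA_B160-200"] = fraction_in_range(la_b, la_lo, la_hi) if la_b.size else 0.0

    per_plan["MFA"] = float(np.sum(mu_w * [r["MFA"] for r in per_beam]))
    agg_keys = ["CAS", "CLS"] + [f"SAS_{t:g}mm" for t in config.sas_thresholds]
    for key in agg_keys:
        vals = np.array([r[key] for r in per_beam])
        if config.plan_aggregation == "sum":
            per_plan[key] = float(vals.sum())
        else:
            per_plan[key] = float(np.sum(mu_w * vals))
    per_plan["MU_per_CP"] = mu_per_cp(plan)
    return ComplexityReport(per_beam=per_beam, per_plan=per_plan, plan_id=plan.plan_id)
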