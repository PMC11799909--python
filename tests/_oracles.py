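"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plain Python loops over control points and
leaf pairs, deliberately avoiding the vectorized code paths of the package,
so agreement is evidence of correctness rather than of shared bugs.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np


# ---------------------------------------------------------------------------
# Complexity metrics by explicit loops
# ---------------------------------------------------------------------------


def oracle_segment_times(beam):
    limits = beam.machine_limits
    cps = beam.control_points
    times = []
    for i in range(len(cps) - 1):
        dg = abs(cps[i + 1].gantry_angle - cps[i].gantry_angle)
        dg = min(dg, 360.0 - dg)
        dmu = (cps[i + 1].cumulative_meterset_weight
               - cps[i].cumulative_meterset_weight) * beam.beam_mu
        travel = 0.0
        for p in range(cps[i].n_leaf_pairs):
            travel = max(travel,
                         abs(cps[i + 1].bank_a_positions[p] - cps[i].bank_a_positions[p]),
                         abs(cps[i + 1].bank_b_positions[p] - cps[i].bank_b_positions[p]))
        times.append(max(dg / limits.max_gantry_speed,
                         dmu / (limits.max_dose_rate / 60.0),
                         travel / limits.max_leaf_speed))
    return times


def _pair_in_y(beam, p):
    lo, hi = beam.leaf_boundaries[p], beam.leaf_boundaries[p + 1]
    y1, y2 = beam.control_points[0].jaw_y
    return hi > y1 and lo < y2


def _cp_values(beam, fn):
    """Per-control-point values of fn(cp, in_field_pair_indices)."""
    out = []
    for cp in beam.control_points:
        pairs = [p for p in range(cp.n_leaf_pairs) if _pair_in_y(beam, p)]
        out.append(fn(cp, pairs))
    return out


def _weighted(beam, cp_values):
    num = den = 0.0
    for i in range(len(cp_values) - 1):
        dmu = (beam.control_points[i + 1].cumulative_meterset_weight
               - beam.control_points[i].cumulative_meterset_weight) * beam.beam_mu
        num += 0.5 * (cp_values[i] + cp_values[i + 1]) * dmu
        den += dmu
    return num / den


def oracle_cas(beam):
    def fn(cp, pairs):
        cross = 0
        for p in pairs:
            if cp.bank_a_positions[p] > 0:
                cross += 1
            if cp.bank_b_positions[p] < 0:
                cross += 1
        return cross / (2 * len(pairs)) if pairs else 0.0
    return _weighted(beam, _cp_values(beam, fn))


def oracle_cls(beam, closed_tol=0.5):
    def fn(cp, pairs):
        closed = sum(
            1 for p in pairs
            if cp.bank_b_positions[p] - cp.bank_a_positions[p] <= closed_tol)
        return closed / len(pairs) if pairs else 0.0
    return _weighted(beam, _cp_values(beam, fn))


def oracle_sas(beam, threshold, closed_tol=0.5):
    def fn(cp, pairs):
        n_open = n_small = 0
        for p in pairs:
            gap = cp.bank_b_positions[p] - cp.bank_a_positions[p]
            if gap > closed_tol:
                n_open += 1
                if gap < threshold:
                    n_small += 1
        return n_small / n_open if n_open else 0.0
    return 100.0 * _weighted(beam, _cp_values(beam, fn))


def oracle_mfa(beam):
    def fn(cp, pairs):
        area = 0.0
        x1, x2 = cp.jaw_x
        for p in pairs:
            a, b = cp.bank_a_positions[p], cp.bank_b_positions[p]
            seg = min(b, x2) - max(a, x1)
            if seg > 0:
                area += seg * (beam.leaf_boundaries[p + 1] - beam.leaf_boundaries[p])
        return area
    return _weighted(beam, _cp_values(beam, fn))


def oracle_speed_fraction(beam, lo, hi, bank="a"):
    times = oracle_segment_times(beam)
    cps = beam.control_points
    n_in = n_all = 0
    for i, t in enumerate(times):
        for p in range(cps[0].n_leaf_pairs):
            pos0 = (cps[i].bank_a_positions[p] if bank == "a"
                    else cps[i].bank_b_positions[p])
            pos1 = (cps[i + 1].bank_a_positions[p] if bank == "a"
                    else cps[i + 1].bank_b_positions[p])
            v = abs(pos1 - pos0) / t if t > 0 else 0.0
            n_all += 1
            if lo <= v < hi:
                n_in += 1
    return n_in / n_all


# ---------------------------------------------------------------------------
# Gamma by exhaustive fine-grid search
# ---------------------------------------------------------------------------


def oracle_gamma_rate(reference, evaluated, dose_diff, dta, threshold=10.0,
                      step_fraction=0.05, radius_factor=3.0):
    """Passing rate by per-pixel exhaustive search on a fine offset grid."""
    ref = reference.values
    max_ref = ref.max()
    dd = dose_diff / 100.0 * max_ref
    cutoff = threshold / 100.0 * max_ref
    ey, ex = evaluated.spacing
    ny, nx = evaluated.values.shape

    step = dta * step_fraction
    radius = dta * radius_factor
    n_off = int(math.floor(radius / step))
    offsets = []
    for iy in range(-n_off, n_off + 1):
        for ix in range(-n_off, n_off + 1):
            oy, ox = iy * step, ix * step
            if oy * oy + ox * ox <= radius * radius + 1e-12:
                offsets.append((oy, ox))

    def bilinear(y_mm, x_mm):
        fy, fx = y_mm / ey, x_mm / ex
        fy = min(max(fy, 0.0), ny - 1.0)
        fx = min(max(fx, 0.0), nx - 1.0)
        i0, j0 = int(math.floor(fy)), int(math.floor(fx))
        i1, j1 = min(i0 + 1, ny - 1), min(j0 + 1, nx - 1)
        wy, wx = fy - i0, fx - j0
        v = evaluated.values
        return ((1 - wy) * (1 - wx) * v[i0, j0] + (1 - wy) * wx * v[i0, j1]
                + wy * (1 - wx) * v[i1, j0] + wy * wx * v[i1, j1])

    n_eval = n_pass = 0
    for i in range(ref.shape[0]):
        for j in range(ref.shape[1]):
            if ref[i, j] < cutoff:
                continue
            n_eval += 1
            y_mm = i * reference.spacing[0]
            x_mm = j * reference.spacing[1]
            best = math.inf
            for oy, ox in offsets:
                spatial = (oy * oy + ox * ox) / (dta * dta)
                if spatial >= best:
                    continue
                d = bilinear(y_mm + oy, x_mm + ox) - ref[i, j]
                g2 = (d / dd) ** 2 + spatial
                if g2 < best:
                    best = g2
            if best <= 1.0:
                n_pass += 1
    return 100.0 * n_pass / n_eval


# ---------------------------------------------------------------------------
# Wilcoxon by full sign enumeration
# ---------------------------------------------------------------------------


def oracle_wilcoxon_p(differences):
    """Two-sided exact p by enumerating all 2^n sign assignments (n <= ~14)."""
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = d.size
    absd = np.abs(d)
    # Mid-ranks by explicit counting.
    ranks = np.empty(n)
    for i in range(n):
        less = int(np.sum(absd < absd[i]))
        equal = int(np.sum(absd == absd[i]))
        ranks[i] = less + (equal + 1) / 2.0
    w_obs = float(ranks[d > 0].sum())
    n_low = n_high = 0
    for signs in product((1, -1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s > 0)
        if w <= w_obs + 1e-9:
            n_low += 1
        if w >= w_obs - 1e-9:
            n_high += 1
    total = 2**n
    return min(1.0, 2.0 * min(n_low / total, n_high / total))
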