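"""Paired two-cohort comparison: Wilcoxon signed-rank tests and summary tables.

The comparison machinery mirrors how paired planning studies are reported:
per metric, mean +/- sample SD with the min-max range for each cohort, and a
two-sided Wilcoxon signed-rank p-value at alpha = 0.05.  No multiplicity
correction is applied (a deliberate, documented choice for comparability
with common practice in planning studies).

The signed-rank test is implemented here rather than delegated: zeros are
dropped (Wilcoxon's convention; Pratt's is available), ties receive
mid-ranks, and the null distribution is evaluated exactly for n <= 25 via
dynamic programming over the (doubled, hence integer) rank sums — identical
to full 2^n sign enumeration — with a tie-corrected, continuity-corrected
normal approximation beyond.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .plan_model import ParameterError

logger = logging.getLogger(__name__)

EXACT_N_MAX = 25


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------


@lru_cache(maxsize=256)
def _exact_distribution(doubled_ranks: tuple[int, ...]) -> np.ndarray:
    """PMF of the doubled positive-rank sum over all 2^n sign assignments.

    Entry k is the number of assignments with doubled rank sum k, divided by
    2^n.  Doubling makes mid-ranks integral, so the support is exact.
    """
    total = sum(doubled_ranks)
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    return counts / 2 ** len(doubled_ranks)


def wilcoxon_signed_rank(
    differences,
    zero_method: str = "wilcox",
    mode: str = "auto",
) -> dict:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Returns ``{"p_value", "statistic", "n", "method"}`` where the statistic
    is W+, the sum of ranks of positive differences.  ``zero_method`` is
    "wilcox" (drop zeros before ranking) or "pratt" (rank with zeros, then
    drop them from the statistic).  ``mode`` selects "exact" (n <= 25),
    "approx", or "auto".
    """
    d = np.asarray(differences, dtype=float)
    if d.size == 0 or np.all(d == 0):
        raise ParameterError("the signed-rank test is undefined when all differences are zero")
    if zero_method not in ("wilcox", "pratt"):
        raise ParameterError("zero_method must be 'wilcox' or 'pratt'")

    if zero_method == "wilcox":
        d = d[d != 0]
        ranks = rankdata(np.abs(d))
    else:
        ranks_all = rankdata(np.abs(d))
        keep = d != 0
        ranks = ranks_all[keep]
        d = d[keep]
    n = d.size
    w_plus = float(ranks[d > 0].sum())

    if mode == "auto":
        mode = "exact" if n <= EXACT_N_MAX else "approx"

    if mode == "exact":
        doubled = tuple(sorted(int(round(2 * r)) for r in ranks))
        pmf = _exact_distribution(doubled)
        k = int(round(2 * w_plus))
        p_low = pmf[: k + 1].sum()
        p_high = pmf[k:].sum()
        p = min(1.0, 2.0 * min(p_low, p_high))
    elif mode == "approx":
        mean = n * (n + 1) / 4.0
        # Tie correction over groups of equal |d| (zeros removed).
        _, counts = np.unique(np.abs(d), return_counts=True)
        tie_term = float(np.sum(counts**3 - counts)) / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        if var <= 0:
            raise ParameterError("degenerate variance in the normal approximation")
        diff = w_plus - mean
        # Continuity correction of 0.5 toward the mean.
        z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var)
        p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    else:
        raise ParameterError("mode must be 'exact', 'approx' or 'auto'")
    return {"p_value": float(p), "statistic": w_plus, "n": int(n), "method": mode}


# ---------------------------------------------------------------------------
# Summaries and cohort comparison
# ---------------------------------------------------------------------------


def summarize(values) -> dict:
    """Mean, sample SD (ddof=1), min and max; SD flagged 0 for n = 1."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ParameterError("cannot summarize an empty sample")
    return {
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
        "min": float(v.min()),
        "max": float(v.max()),
        "n": int(v.size),
    }


@dataclass
class PairedComparison:
    metric: str
    n: int
    summary_a: dict
    summary_b: dict
    p_value: float | None
    significant: bool
    tested: bool = True
    note: str = ""

    def as_row(self) -> dict:
        row = {"metric": self.metric, "n": self.n, "p_value": self.p_value,
               "significant": self.significant}
        for label, s in (("a", self.summary_a), ("b", self.summary_b)):
            if s:
                for k in ("mean", "sd", "min", "max"):
                    row[f"{k}_{label}"] = s[k]
        return row


def compare_cohorts(
    table: pd.DataFrame,
    alpha: float = 0.05,
    cohorts: tuple[str, str] | None = None,
    **wilcoxon_kwargs,
) -> list[PairedComparison]:
    """Paired comparison of every metric between two cohorts.

    ``table`` is long-format with columns patient_id, cohort, metric, value.
    Patients missing a value in either cohort are excluded pairwise (logged).
    Metrics with no nonzero paired difference are reported untested.
    """
    required = {"patient_id", "cohort", "metric", "value"}
    if not required.issubset(table.columns):
        raise ParameterError(f"cohort table needs columns {sorted(required)}")
    labels = sorted(table["cohort"].unique()) if cohorts is None else list(cohorts)
    if len(labels) != 2:
        raise ParameterError(f"exactly two cohorts required, found {labels}")
    a_label, b_label = labels

    results: list[PairedComparison] = []
    for metric, group in table.groupby("metric", sort=True):
        wide = group.pivot_table(index="patient_id", columns="cohort",
                                 values="value", aggfunc="first")
        if a_label not in wide.columns or b_label not in wide.columns:
            results.append(PairedComparison(metric, 0, {}, {}, None, False,
                                            tested=False, note="cohort missing"))
            continue
        complete = wide.dropna(subset=[a_label, b_label])
        n_dropped = len(wide) - len(complete)
        if n_dropped:
            logger.info("metric %s: %d incomplete pair(s) excluded", metric, n_dropped)
        if complete.empty:
            results.append(PairedComparison(metric, 0, {}, {}, None, False,
                                            tested=False, note="no complete pairs"))
            continue
        a = complete[a_label].to_numpy()
        b = complete[b_label].to_numpy()
        diffs = b - a
        if np.all(diffs == 0):
            results.append(PairedComparison(
                metric, len(complete), summarize(a), summarize(b), None, False,
                tested=False, note="all paired differences zero"))
            continue
        test = wilcoxon_signed_rank(diffs, **wilcoxon_kwargs)
        results.append(PairedComparison(
            metric=metric, n=len(complete),
            summary_a=summarize(a), summary_b=summarize(b),
            p_value=test["p_value"],
            significant=test["p_value"] < alpha,
        ))
    return results


def comparison_table(results: list[PairedComparison]) -> pd.DataFrame:
    """Flat DataFrame of paired comparisons (one row per metric)."""
    return pd.DataFrame([r.as_row() for r in results])
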