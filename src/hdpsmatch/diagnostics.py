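"""Balance diagnostics and unadjusted effect estimates.

The absolute standardized difference (ASDD) of a covariate between two
groups is the absolute between-group difference over the pooled SD of the
two groups: |p1 - p2| / sqrt((p1(1-p1) + p2(1-p2)) / 2) for a binary
covariate and |m1 - m2| / sqrt((s1^2 + s2^2) / 2) for a continuous one.
Values above 0.1 conventionally flag imbalance. Treatment effects are
unadjusted odds ratios from the 2x2 exposure-by-outcome table with Wald
95% confidence intervals; in matched sub-cohorts no adjustment beyond the
matching is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .covariates import COVARIATE_LABELS, TABLE1_CHARACTERISTICS

__all__ = [
    "asdd_binary",
    "asdd_continuous",
    "round3",
    "balance_table",
    "balance_table_from_counts",
    "EffectEstimate",
    "estimate_or",
]


def round3(x: float) -> float:
    """Round to 3 decimals, half away from zero (report convention)."""
    if not math.isfinite(x):
        return x
    return math.copysign(math.floor(abs(x) * 1000.0 + 0.5) / 1000.0, x)


def asdd_binary(n1: int, x1: int, n2: int, x2: int) -> float:
    """ASDD of a binary covariate from group sizes and positive counts.

    Returns 0 when both proportions are equal (including the degenerate
    0/0-variance case) and +inf when both variances vanish but the
    proportions differ (one group all-positive, the other all-negative).
    """
    for n, x in ((n1, x1), (n2, x2)):
        if n < 1:
            raise ValueError("group size must be >= 1")
        if not 0 <= x <= n:
            raise ValueError(f"count {x} outside 0..{n}")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (p1 * (1.0 - p1) + p2 * (1.0 - p2)) / 2.0
    if pooled == 0.0:
        return 0.0 if p1 == p2 else math.inf
    return abs(p1 - p2) / math.sqrt(pooled)


def asdd_continuous(mean1: float, sd1: float, mean2: float, sd2: float) -> float:
    """ASDD of a continuous covariate from group means and SDs."""
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    pooled = (sd1 * sd1 + sd2 * sd2) / 2.0
    if pooled == 0.0:
        return 0.0 if mean1 == mean2 else math.inf
    return abs(mean1 - mean2) / math.sqrt(pooled)


def _summarize(rows: pd.DataFrame) -> dict:
    a = rows["asdd"].to_numpy(dtype=float)
    return {
        "n_unbalanced": int(rows["flag_unbalanced"].sum()),
        "mean_asdd": float(a.mean()),
        "min_asdd": float(a.min()),
        "max_asdd": float(a.max()),
    }


def balance_table(cohort: pd.DataFrame,
                  covariates: list[str] | None = None,
                  threshold: float = 0.1,
                  group_col: str = "exposure") -> tuple[pd.DataFrame, dict]:
    """Per-covariate balance rows for a cohort, in fixed report order.

    ``age`` is summarized as mean (SD), all other covariates as count (%).
    A row is flagged unbalanced when its ASDD exceeds ``threshold``
    (strictly). Returns the rows and a summary (number unbalanced,
    mean/min/max ASDD over all rows).
    """
    covariates = covariates or TABLE1_CHARACTERISTICS
    high = cohort[cohort[group_col] == "high"]
    low = cohort[cohort[group_col] == "lower"]
    rows = []
    for cov in covariates:
        if cov == "age":
            m1, s1 = float(low[cov].mean()), float(low[cov].std(ddof=1))
            m2, s2 = float(high[cov].mean()), float(high[cov].std(ddof=1))
            a = asdd_continuous(m1, s1, m2, s2)
            rows.append({
                "covariate": cov, "label": COVARIATE_LABELS.get(cov, cov),
                "low_summary": f"{m1:.1f} ({s1:.1f})",
                "high_summary": f"{m2:.1f} ({s2:.1f})",
                "asdd": a, "flag_unbalanced": a > threshold,
            })
        else:
            x1, x2 = int(low[cov].sum()), int(high[cov].sum())
            a = asdd_binary(len(low), x1, len(high), x2)
            rows.append({
                "covariate": cov, "label": COVARIATE_LABELS.get(cov, cov),
                "low_summary": f"{x1} ({100.0 * x1 / len(low):.1f})",
                "high_summary": f"{x2} ({100.0 * x2 / len(high):.1f})",
                "asdd": a, "flag_unbalanced": a > threshold,
            })
    frame = pd.DataFrame(rows)
    return frame, _summarize(frame)


def balance_table_from_counts(table: pd.DataFrame, n_low: int, n_high: int,
                              threshold: float = 0.1) -> tuple[pd.DataFrame, dict]:
    """Balance rows from printed summary counts rather than patient rows.

    ``table`` needs columns ``covariate``, ``type`` ("binary"/"continuous"),
    ``low_count``/``high_count`` for binary rows and ``low_mean``/``low_sd``/
    ``high_mean``/``high_sd`` for continuous rows.
    """
    rows = []
    for r in table.itertuples(index=False):
        if r.type == "continuous":
            a = asdd_continuous(r.low_mean, r.low_sd, r.high_mean, r.high_sd)
        else:
            a = asdd_binary(n_low, int(r.low_count), n_high, int(r.high_count))
        rows.append({"covariate": r.covariate, "asdd": a,
                     "flag_unbalanced": a > threshold})
    frame = pd.DataFrame(rows)
    return frame, _summarize(frame)


@dataclass
class EffectEstimate:
    """Unadjusted odds ratio with Wald 95% CI from a 2x2 table."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    cells: tuple[int, int, int, int]  # cases_high, noncases_high, cases_lower, noncases_lower
    method_label: str = "full"
    continuity_corrected: bool = False

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.odds_ratio <= self.ci_high):
            raise ValueError("CI must bracket the odds ratio")


def estimate_or(cells: tuple[int, int, int, int],
                method_label: str = "full") -> EffectEstimate:
    """Odds ratio (a*d)/(b*c) with Wald 95% CI from exposure-outcome cells.

    ``cells`` = (cases_high, noncases_high, cases_lower, noncases_lower).
    Any zero cell triggers the Haldane-Anscombe correction (+0.5 to every
    cell), flagged on the estimate.
    """
    if any(c < 0 for c in cells):
        raise ValueError("cell counts must be non-negative")
    a, b, c, d = (float(v) for v in cells)
    corrected = min(a, b, c, d) == 0.0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    lo = math.exp(math.log(or_) - 1.96 * se)
    hi = math.exp(math.log(or_) + 1.96 * se)
    return EffectEstimate(odds_ratio=or_, ci_low=lo, ci_high=hi,
                          cells=tuple(int(v) for v in cells),
                          method_label=method_label,
                          continuity_corrected=corrected)


def outcome_cells(cohort: pd.DataFrame) -> tuple[int, int, int, int]:
    """2x2 exposure-by-outcome cells of a cohort frame."""
    high = cohort["exposure"] == "high"
    y = cohort["outcome"].astype(bool)
    return (int((high & y).sum()), int((high & ~y).sum()),
            int((~high & y).sum()), int((~high & ~y).sum()))
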