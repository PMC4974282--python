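"""Diagnostic-accuracy statistics: 2x2 tables, exact intervals, reports.

Sensitivity, specificity, predictive values and overall accuracy are
binomial proportions; each is reported with an exact (Clopper-Pearson)
confidence interval obtained by inverting the binomial tails, computed
here through the standard beta-quantile identity. Reports render every
cell as an integer percentage with its interval, rounding the point
estimate half away from zero (so 92.5% prints as 93).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from scipy.stats import beta as _beta

from .cohort import Call
from .adjudicate import ReferenceClass, adjudicate

__all__ = [
    "ContingencyTable",
    "ProportionEstimate",
    "build_table",
    "clopper_pearson",
    "accuracy_profile",
    "render_table",
    "METRICS",
    "round_half_away",
]

METRICS = ("sensitivity", "specificity", "ppv", "npv", "accuracy")


@dataclass(frozen=True)
class ContingencyTable:
    """TP/FP/FN/TN counts for one test against the reference standard."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def build_table(calls: Sequence[Call], truths: Sequence[Call]) -> ContingencyTable:
    """Aggregate aligned per-patient calls and truths into a 2x2 table."""
    if len(calls) != len(truths):
        raise ValueError(
            f"calls ({len(calls)}) and truths ({len(truths)}) must be aligned"
        )
    counts = {cls: 0 for cls in ReferenceClass}
    for call, truth in zip(calls, truths):
        counts[adjudicate(call, truth)] += 1
    return ContingencyTable(
        tp=counts[ReferenceClass.TP],
        fp=counts[ReferenceClass.FP],
        fn=counts[ReferenceClass.FN],
        tn=counts[ReferenceClass.TN],
    )


def clopper_pearson(k: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Exact equal-tailed binomial interval for k successes in n trials.

    The lower bound solves ``P(X >= k | p) = alpha/2`` (0 when k = 0) and
    the upper bound solves ``P(X <= k | p) = alpha/2`` (1 when k = n),
    i.e. the equal-tailed inversion of the binomial distribution, computed
    via beta quantiles.
    """
    if not 0 <= k <= n or n < 1:
        raise ValueError(f"need 0 <= k <= n and n >= 1, got k={k}, n={n}")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    alpha = 1.0 - confidence
    low = 0.0 if k == 0 else float(_beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(_beta.ppf(1 - alpha / 2, k + 1, n - k))
    return low, high


@dataclass(frozen=True)
class ProportionEstimate:
    numerator: int
    denominator: int
    point: float
    ci_low: float
    ci_high: float
    confidence: float = 0.95

    @classmethod
    def from_counts(
        cls, numerator: int, denominator: int, confidence: float = 0.95
    ) -> "ProportionEstimate":
        low, high = clopper_pearson(numerator, denominator, confidence)
        return cls(
            numerator=numerator,
            denominator=denominator,
            point=numerator / denominator,
            ci_low=low,
            ci_high=high,
            confidence=confidence,
        )


def accuracy_profile(
    table: ContingencyTable, confidence: float = 0.95
) -> dict[str, Optional[ProportionEstimate]]:
    """Sensitivity, specificity, PPV, NPV and accuracy for one 2x2 table.

    A metric whose denominator is zero (e.g. sensitivity in a cohort with
    no truth-positive patients) is returned as None; the others are still
    estimated.
    """
    if table.total == 0:
        raise ValueError("empty contingency table")
    pairs = {
        "sensitivity": (table.tp, table.tp + table.fn),
        "specificity": (table.tn, table.fp + table.tn),
        "ppv": (table.tp, table.tp + table.fp),
        "npv": (table.tn, table.fn + table.tn),
        "accuracy": (table.tp + table.tn, table.total),
    }
    return {
        name: (
            ProportionEstimate.from_counts(num, den, confidence) if den > 0 else None
        )
        for name, (num, den) in pairs.items()
    }


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (92.5 -> 93)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def render_cell(est: Optional[ProportionEstimate]) -> str:
    if est is None:
        return "-"
    return (
        f"{round_half_away(100 * est.point)} "
        f"({round_half_away(100 * est.ci_low)}-{round_half_away(100 * est.ci_high)})"
    )


def render_table(
    profiles: dict[str, dict[str, Optional[ProportionEstimate]]], n_label: str
) -> str:
    """Plain-text accuracy table: one row per test, one column per metric."""
    if not profiles:
        raise ValueError("no profiles to render")
    header = ["Method", "Sensitivity", "Specificity", "PPV", "NPV", "Accuracy"]
    rows = [[name] + [render_cell(profile[m]) for m in METRICS] for name, profile in profiles.items()]
    widths = [max(len(r[i]) for r in [header] + rows) for i in range(len(header))]
    lines = [
        f"Accuracy for the detection of distant metastases ({n_label})",
        "  ".join(h.ljust(w) for h, w in zip(header, widths)).rstrip(),
    ]
    for r in rows:
        lines.append("  ".join(c.ljust(w) for c, w in zip(r, widths)).rstrip())
    return "\n".join(lines) + "\n"
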