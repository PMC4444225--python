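"""Cohort-level summaries and exact statistics.

Confidence intervals on proportions are exact (Clopper–Pearson, obtained
by inverting binomial tail probabilities); two-by-two comparisons use
Fisher's exact test with the probability-mass definition of the two-sided
p-value.  Percentages destined for reports are rounded half-up to one
decimal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import CohortManifest, VariantCall
from .ppv_classification import DetectionOutcome, DetectionStatus, PpvSelection

__all__ = [
    "ppv_burden",
    "BurdenSummary",
    "detection_rate",
    "DetectionReport",
    "binomial_ci",
    "fisher_exact",
    "summarize_scores_by_class",
    "round_percent",
]


def round_percent(fraction: float, ndigits: int = 1) -> float:
    """Round a fraction to a percentage, half-up (report convention)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(fraction * 100).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# burden


@dataclass
class BurdenSummary:
    """Per-cohort PPV burden: mean per individual and count histogram."""

    per_cohort_mean: dict[str, float] = field(default_factory=dict)
    per_cohort_histogram: dict[str, dict[int, int]] = field(default_factory=dict)
    per_sample_counts: dict[str, int] = field(default_factory=dict)

    def mean(self, cohort: str) -> float:
        return self.per_cohort_mean[cohort]


def ppv_burden(selection: PpvSelection, manifest: CohortManifest) -> BurdenSummary:
    """Mean PPVs per individual and histogram, per cohort label.

    Every manifest sample contributes (zero when it has no PPVs).
    """
    summary = BurdenSummary()
    for label in manifest.cohort_labels:
        ids = manifest.sample_ids(cohort_label=label)
        counts = [selection.count_for(s) for s in ids]
        hist: dict[int, int] = {}
        for k in counts:
            hist[k] = hist.get(k, 0) + 1
        summary.per_cohort_mean[label] = float(np.mean(counts)) if counts else 0.0
        summary.per_cohort_histogram[label] = dict(sorted(hist.items()))
        for s, k in zip(ids, counts):
            summary.per_sample_counts[s] = k
    return summary


# ---------------------------------------------------------------------------
# detection rate


@dataclass
class DetectionReport:
    n_total: int
    n_expected: int
    n_high_quality: int
    n_low_quality: int
    n_not_detected: int
    low_quality_categories: dict[str, int]

    @property
    def rate(self) -> float:
        """High-quality detections over expected-detectable samples."""
        return self.n_high_quality / self.n_expected

    @property
    def low_quality_indel_fraction(self) -> Optional[float]:
        n_low = sum(self.low_quality_categories.values())
        if n_low == 0:
            return None
        return self.low_quality_categories.get("indel", 0) / n_low


def detection_rate(statuses: Sequence[DetectionStatus]) -> DetectionReport:
    """Confirmation rate of clinically diagnosed mutations.

    The denominator is the expected-detectable samples (CNV/IVS diagnoses
    excluded); low-quality recoveries count against the rate but are
    broken down by mutation category for reporting.
    """
    by = {o: [s for s in statuses if s.status is o] for o in DetectionOutcome}
    n_expected = len(statuses) - len(by[DetectionOutcome.NOT_EXPECTED])
    if n_expected == 0:
        raise ValueError("no expected-detectable samples")
    low_cats: dict[str, int] = {}
    for s in by[DetectionOutcome.DETECTED_LOW_QUALITY]:
        if s.category:
            low_cats[s.category] = low_cats.get(s.category, 0) + 1
    return DetectionReport(
        n_total=len(statuses),
        n_expected=n_expected,
        n_high_quality=len(by[DetectionOutcome.DETECTED_HIGH_QUALITY]),
        n_low_quality=len(by[DetectionOutcome.DETECTED_LOW_QUALITY]),
        n_not_detected=len(by[DetectionOutcome.NOT_DETECTED]),
        low_quality_categories=dict(sorted(low_cats.items())),
    )


# ---------------------------------------------------------------------------
# exact statistics


def binomial_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper–Pearson) two-sided confidence interval for k/n.

    The lower bound is 0 when k = 0 and the upper bound 1 when k = n.
    """
    if not (0 <= k <= n) or n < 1:
        raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    if not (0.0 < level < 1.0):
        raise ValueError(f"confidence level must be in (0,1), got {level}")
    ci = stats.binomtest(k, n).proportion_ci(confidence_level=level, method="exact")
    return (float(ci.low), float(ci.high))


def fisher_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Probability-mass convention: the sum of hypergeometric probabilities
    of all tables with the observed margins whose probability does not
    exceed the observed table's.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    if a + b + c + d == 0:
        raise ValueError("table is all zeros")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


# ---------------------------------------------------------------------------
# deleteriousness-score summaries


def summarize_scores_by_class(calls: Iterable[VariantCall]) -> pd.DataFrame:
    """Per-consequence-class distribution of deleteriousness scores.

    Calls without a score are excluded from the quantiles but counted in
    ``n_absent``.  Classes with no scored calls do not appear as rows;
    an all-absent input yields an empty frame whose ``n_absent`` total is
    still available via the ``attrs``.
    """
    calls = list(calls)
    n_absent_total = sum(1 for c in calls if c.score is None)
    rows = []
    scored: dict[str, list[float]] = {}
    absent: dict[str, int] = {}
    for c in calls:
        key = c.consequence.value
        if c.score is None:
            absent[key] = absent.get(key, 0) + 1
        else:
            scored.setdefault(key, []).append(c.score)
    for key in sorted(scored):
        v = np.array(scored[key])
        rows.append(
            {
                "consequence": key,
                "n": len(v),
                "n_absent": absent.get(key, 0),
                "median": float(np.median(v)),
                "q1": float(np.quantile(v, 0.25)),
                "q3": float(np.quantile(v, 0.75)),
            }
        )
    df = pd.DataFrame(
        rows, columns=["consequence", "n", "n_absent", "median", "q1", "q3"]
    )
    df.attrs["n_absent_total"] = n_absent_total
    return df
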