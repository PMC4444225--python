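"""Variant quality-threshold calibration by replicate genotype concordance.

Whole-genome platforms attach a variant quality score to each called
allele.  To pick a usable threshold, the same individual is sequenced
twice (e.g. lymphoblast and fibroblast DNA) and genotype concordance
between the two replicate genomes is measured across a sweep of quality
thresholds: raising the threshold trades called sites for concordance.
The working defaults — SNVs kept only when both allele qualities reach
100, indels only above 150 — reflect that indels are called with
systematically lower quality than SNVs and need a stricter cut.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .models import Genotype, VariantCall, VarType

__all__ = [
    "ConcordancePoint",
    "QcConfig",
    "passes_quality",
    "genotype_concordance",
    "sweep_thresholds",
    "apply_quality_filter",
    "FilterSummary",
    "write_sweep_table",
]


@dataclass(frozen=True)
class ConcordancePoint:
    """One point of a concordance-vs-threshold sweep.

    ``concordance`` is ``None`` when no site passes the threshold in both
    replicates (an empty universe is reported as absent, never as 0).
    """

    threshold: int
    var_class: str  # "snv" or "indel"
    concordance: Optional[float]
    fraction_excluded: float


@dataclass(frozen=True)
class QcConfig:
    """Quality-filter thresholds.

    ``snv_min_quality`` is an inclusive lower bound applied to both allele
    qualities; ``indel_min_quality`` is an exclusive bound (an indel at
    exactly the bound is excluded).  ``strict_both_alleles=True`` retains a
    call only when every relevant allele quality passes; the lenient
    alternative excludes only when all of them fail.
    """

    snv_min_quality: int = 100
    indel_min_quality: int = 150
    strict_both_alleles: bool = True
    sweep_grid: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.snv_min_quality < 0 or self.indel_min_quality < 0:
            raise ValueError("quality thresholds must be non-negative")


def _relevant_qualities(call: VariantCall) -> tuple[int, ...]:
    # hemizygous calls have a single haplotype; the second entry is ignored
    if call.genotype is Genotype.HEMI:
        return (call.allele_quality[0],)
    return call.allele_quality


def passes_quality(call: VariantCall, qc: QcConfig) -> bool:
    quals = _relevant_qualities(call)
    if call.var_type is VarType.SNV:
        ok = [q >= qc.snv_min_quality for q in quals]
    else:
        ok = [q > qc.indel_min_quality for q in quals]
    return all(ok) if qc.strict_both_alleles else any(ok)


@dataclass
class FilterSummary:
    """Per-class retained/excluded accounting for one filter pass."""

    n_input: dict[str, int] = field(default_factory=dict)
    n_retained: dict[str, int] = field(default_factory=dict)

    def n_excluded(self, var_class: str) -> int:
        return self.n_input.get(var_class, 0) - self.n_retained.get(var_class, 0)

    def fraction_excluded(self, var_class: str) -> Optional[float]:
        n = self.n_input.get(var_class, 0)
        if n == 0:
            return None
        return self.n_excluded(var_class) / n


def apply_quality_filter(
    calls: Iterable[VariantCall], qc: QcConfig
) -> tuple[list[VariantCall], FilterSummary]:
    """Retain calls passing the class-specific quality thresholds."""
    summary = FilterSummary()
    retained: list[VariantCall] = []
    for c in calls:
        cls = "snv" if c.var_type is VarType.SNV else "indel"
        summary.n_input[cls] = summary.n_input.get(cls, 0) + 1
        if passes_quality(c, qc):
            retained.append(c)
            summary.n_retained[cls] = summary.n_retained.get(cls, 0) + 1
    for cls in summary.n_input:
        summary.n_retained.setdefault(cls, 0)
    return retained, summary


# ---------------------------------------------------------------------------
# replicate concordance


def _class_of(call: VariantCall) -> str:
    return "snv" if call.var_type is VarType.SNV else "indel"


def _min_quality(call: VariantCall) -> int:
    return min(_relevant_qualities(call))


def genotype_concordance(
    rep_a: Sequence[VariantCall],
    rep_b: Sequence[VariantCall],
    threshold: int,
    var_class: str = "snv",
) -> ConcordancePoint:
    """Genotype concordance between two replicate genomes at one threshold.

    A site (chrom, pos, ref, alt) of the requested class enters the
    passing universe when every replicate that calls it does so with all
    relevant allele qualities >= ``threshold``.  Concordance is the
    fraction of the universe called with an identical genotype in both
    replicates; a site passing in only one replicate is discordant.
    ``fraction_excluded`` is measured against all sites of the class seen
    in either replicate.
    """
    a = {c.key: c for c in rep_a if _class_of(c) == var_class}
    b = {c.key: c for c in rep_b if _class_of(c) == var_class}
    all_sites = set(a) | set(b)
    universe = {
        k
        for k in all_sites
        if all(_min_quality(d[k]) >= threshold for d in (a, b) if k in d)
    }
    if not all_sites:
        return ConcordancePoint(threshold, var_class, None, 0.0)
    if not universe:
        return ConcordancePoint(threshold, var_class, None, 1.0)
    n_match = sum(
        1 for k in universe if k in a and k in b and a[k].genotype == b[k].genotype
    )
    return ConcordancePoint(
        threshold=threshold,
        var_class=var_class,
        concordance=n_match / len(universe),
        fraction_excluded=1.0 - len(universe) / len(all_sites),
    )


def sweep_thresholds(
    rep_pairs: Sequence[tuple[Sequence[VariantCall], Sequence[VariantCall]]],
    grid: Sequence[int],
    var_class: str = "snv",
) -> list[ConcordancePoint]:
    """Average concordance over replicate pairs along a threshold grid.

    Each grid value yields one point whose concordance and excluded
    fraction are means over the pairs (pairs with an empty passing
    universe are skipped in the concordance mean).
    """
    if not rep_pairs:
        raise ValueError("at least one replicate pair is required")
    if len(grid) == 0:
        raise ValueError("threshold grid must be non-empty")
    points = []
    for t in sorted(grid):
        per_pair = [genotype_concordance(a, b, t, var_class) for a, b in rep_pairs]
        concs = [p.concordance for p in per_pair if p.concordance is not None]
        points.append(
            ConcordancePoint(
                threshold=t,
                var_class=var_class,
                concordance=sum(concs) / len(concs) if concs else None,
                fraction_excluded=sum(p.fraction_excluded for p in per_pair)
                / len(per_pair),
            )
        )
    return points


def write_sweep_table(points: Sequence[ConcordancePoint], path: Union[str, Path]) -> None:
    pd.DataFrame(
        [
            {
                "threshold": p.threshold,
                "var_class": p.var_class,
                "concordance": "" if p.concordance is None else p.concordance,
                "fraction_excluded": p.fraction_excluded,
            }
            for p in points
        ]
    ).to_csv(path, sep="\t", index=False)
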