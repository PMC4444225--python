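"""Potentially-pathogenic-variant (PPV) and loss-of-function classification.

A PPV is a quality-passing nonsynonymous variant with allele frequency
below a threshold (default 1%) in *both* reference panels, in a gene of
the analysis panel.  A variant absent from a panel counts as passing that
panel's check — that is what makes it novel.  LoF classes: nonsense,
canonical-splice-disrupting, misstart and nonstop SNVs, plus frameshift
indels; in-frame indels are never LoF.  In-silico deleteriousness scores
play no part in the classification.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .models import (
    Consequence,
    GenePanel,
    SampleRecord,
    VariantCall,
    VarType,
)
from .qc_calibration import QcConfig, passes_quality

__all__ = [
    "PpvMode",
    "PpvConfig",
    "LofClass",
    "DetectionStatus",
    "DetectionOutcome",
    "is_nonsynonymous",
    "is_rare",
    "classify_lof",
    "is_ppv",
    "select_ppvs",
    "PpvSelection",
    "confirm_clinical_mutation",
    "write_ppv_table",
]

_NONSYNONYMOUS = frozenset(
    {
        Consequence.MISSENSE,
        Consequence.NONSENSE,
        Consequence.SPLICE_DISRUPT,
        Consequence.MISSTART,
        Consequence.NONSTOP,
        Consequence.FRAMESHIFT,
        Consequence.INFRAME_INDEL,
    }
)

_LOF_SNV_CONSEQ = frozenset(
    {
        Consequence.NONSENSE,
        Consequence.SPLICE_DISRUPT,
        Consequence.MISSTART,
        Consequence.NONSTOP,
    }
)


class PpvMode(str, enum.Enum):
    """Progressively stricter PPV definitions: all nonsynonymous PPVs, LoF
    PPVs only, or LoF single-nucleotide variants only."""

    ALL = "all"
    LOF = "lof"
    LOF_SNV = "lof_snv"


@dataclass(frozen=True)
class PpvConfig:
    frequency_threshold: float = 0.01
    mode: PpvMode = PpvMode.ALL

    def __post_init__(self) -> None:
        if not (0.0 < self.frequency_threshold <= 1.0):
            raise ValueError(
                f"frequency_threshold must be in (0, 1], got {self.frequency_threshold}"
            )


class LofClass(str, enum.Enum):
    LOF_SNV = "lof_snv"
    LOF_INDEL = "lof_indel"
    NOT_LOF = "not_lof"


class DetectionOutcome(str, enum.Enum):
    DETECTED_HIGH_QUALITY = "detected_high_quality"
    DETECTED_LOW_QUALITY = "detected_low_quality"
    NOT_DETECTED = "not_detected"
    NOT_EXPECTED = "not_expected"


@dataclass(frozen=True)
class DetectionStatus:
    sample_id: str
    status: DetectionOutcome
    category: Optional[str] = None  # diagnosed-mutation category (snv/indel/cnv/ivs)


def is_nonsynonymous(call: VariantCall) -> bool:
    """True for every protein-altering consequence class; synonymous and
    unclassifiable ('other') consequences are not nonsynonymous."""
    return call.consequence in _NONSYNONYMOUS


def is_rare(call: VariantCall, cfg: PpvConfig = PpvConfig()) -> bool:
    """True when every *present* panel frequency is below the threshold.

    Absent frequencies pass: a variant seen in neither panel is novel and
    therefore rare by definition.
    """
    for f in (call.freq_panel_a, call.freq_panel_b):
        if f is not None and f >= cfg.frequency_threshold:
            return False
    return True


def classify_lof(call: VariantCall) -> LofClass:
    if call.var_type is VarType.SNV and call.consequence in _LOF_SNV_CONSEQ:
        return LofClass.LOF_SNV
    if call.consequence is Consequence.FRAMESHIFT:
        return LofClass.LOF_INDEL
    return LofClass.NOT_LOF


def _mode_keeps(call: VariantCall, mode: PpvMode) -> bool:
    if mode is PpvMode.ALL:
        return True
    lof = classify_lof(call)
    if mode is PpvMode.LOF:
        return lof in (LofClass.LOF_SNV, LofClass.LOF_INDEL)
    return lof is LofClass.LOF_SNV


def is_ppv(
    call: VariantCall,
    panel_genes: set[str],
    cfg: PpvConfig,
    qc: Optional[QcConfig] = None,
) -> bool:
    if call.gene is None or call.gene not in panel_genes:
        return False
    if qc is not None and not passes_quality(call, qc):
        return False
    return is_nonsynonymous(call) and is_rare(call, cfg) and _mode_keeps(call, cfg.mode)


@dataclass
class PpvSelection:
    """Per-sample PPV sets selected under one mode.

    ``per_sample`` maps sample_id -> deduplicated, deterministically
    ordered calls; samples with zero PPVs may be absent from the mapping.
    """

    per_sample: dict[str, list[VariantCall]]
    mode: PpvMode
    frequency_threshold: float

    @property
    def n_ppvs(self) -> int:
        """Total PPV count across samples (one per sample per variant)."""
        return sum(len(v) for v in self.per_sample.values())

    @property
    def unique_variant_count(self) -> int:
        """Distinct (gene, chrom, pos, ref, alt) across all samples."""
        return len(
            {(c.gene,) + c.key for calls in self.per_sample.values() for c in calls}
        )

    def count_for(self, sample_id: str) -> int:
        return len(self.per_sample.get(sample_id, []))

    def novel_fraction(self) -> Optional[float]:
        """Fraction of PPVs absent from reference panel A (novel)."""
        total = self.n_ppvs
        if total == 0:
            return None
        novel = sum(
            1
            for calls in self.per_sample.values()
            for c in calls
            if c.freq_panel_a is None
        )
        return novel / total

    def genes_per_sample(self) -> dict[str, set[str]]:
        return {
            s: {c.gene for c in calls} for s, calls in self.per_sample.items() if calls
        }


def select_ppvs(
    calls: Iterable[VariantCall],
    panel: GenePanel,
    cfg: PpvConfig = PpvConfig(),
    qc: Optional[QcConfig] = None,
) -> PpvSelection:
    """Select each sample's PPV set on a gene panel.

    The panel's excluded genes are removed before matching.  Pass ``qc``
    when the calls have not already been quality-filtered.  Within a
    sample, duplicate reports of the same (gene, site, alleles) collapse
    to one PPV.  The result is independent of input order.
    """
    genes = panel.genes
    if not genes:
        raise ValueError(f"gene panel {panel.name!r} has no usable genes")
    picked: dict[str, dict[tuple, VariantCall]] = {}
    for c in calls:
        if is_ppv(c, genes, cfg, qc):
            picked.setdefault(c.sample_id, {}).setdefault((c.gene,) + c.key, c)
    per_sample = {
        s: [d[k] for k in sorted(d)] for s, d in sorted(picked.items())
    }
    return PpvSelection(
        per_sample=per_sample, mode=cfg.mode, frequency_threshold=cfg.frequency_threshold
    )


def confirm_clinical_mutation(
    sample_calls: Sequence[VariantCall],
    sample: SampleRecord,
    qc: QcConfig = QcConfig(),
) -> DetectionStatus:
    """Check whether WGS recovered a sample's clinically diagnosed mutation.

    Identity is an exact (gene, chrom, pos, ref, alt) match.  CNV and IVS
    diagnoses are outside the pipeline's detection scope and come back
    ``not_expected``; a matching call failing the quality filter is
    ``detected_low_quality``.
    """
    mut = sample.clinical_mutation
    if mut is None:
        raise ValueError(f"sample {sample.sample_id} has no clinical mutation on record")
    if not mut.expected_detectable:
        return DetectionStatus(sample.sample_id, DetectionOutcome.NOT_EXPECTED,
                               mut.category.value)
    matches = [
        c
        for c in sample_calls
        if c.sample_id == sample.sample_id
        and c.gene == mut.gene
        and c.chrom == mut.chrom
        and c.pos == mut.pos
        and c.ref_allele == mut.ref
        and c.alt_allele == mut.alt
    ]
    if not matches:
        return DetectionStatus(sample.sample_id, DetectionOutcome.NOT_DETECTED,
                               mut.category.value)
    if any(passes_quality(c, qc) for c in matches):
        return DetectionStatus(sample.sample_id, DetectionOutcome.DETECTED_HIGH_QUALITY,
                               mut.category.value)
    return DetectionStatus(sample.sample_id, DetectionOutcome.DETECTED_LOW_QUALITY,
                           mut.category.value)


def write_ppv_table(selection: PpvSelection, path: Union[str, Path]) -> None:
    rows = []
    for sample_id, calls in selection.per_sample.items():
        for c in calls:
            rows.append(
                {
                    "sample_id": sample_id,
                    "gene": c.gene,
                    "chrom": c.chrom,
                    "pos": c.pos,
                    "ref": c.ref_allele,
                    "alt": c.alt_allele,
                    "var_type": c.var_type.value,
                    "consequence": c.consequence.value,
                    "lof_class": classify_lof(c).value,
                    "mode": selection.mode.value,
                    "qual_allele1": c.allele_quality[0],
                    "qual_allele2": c.allele_quality[1],
                    "freq_panel_a": "" if c.freq_panel_a is None else c.freq_panel_a,
                    "freq_panel_b": "" if c.freq_panel_b is None else c.freq_panel_b,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
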