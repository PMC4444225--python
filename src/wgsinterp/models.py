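"""Domain types for clinical WGS variant interpretation.

The central record is :class:`VariantCall`: one non-reference call in one
sample, carrying the per-allele variant quality scores used for QC, the
coding-consequence class used for loss-of-function (LoF) classification,
and allele frequencies from two reference panels (an ESP6500-like exome
panel and a HapMap-like panel sequenced on the same platform) used for
rare-variant filtering.  Frequencies are kept *absent* (``None``) rather
than zero when a variant is missing from a panel, so that "novel" remains
distinguishable downstream.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "VarType",
    "Genotype",
    "Consequence",
    "Inheritance",
    "MutationCategory",
    "VariantCall",
    "PanelEntry",
    "GenePanel",
    "ClinicalMutation",
    "SampleRecord",
    "CohortManifest",
    "ValidationError",
]


class ValidationError(ValueError):
    """A record violates a domain-type invariant."""


class VarType(str, enum.Enum):
    SNV = "snv"
    INS = "ins"
    DEL = "del"
    SUB = "sub"


class Genotype(str, enum.Enum):
    HET = "het"
    HOM = "hom"
    HEMI = "hemi"


class Consequence(str, enum.Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    SPLICE_DISRUPT = "splice_disrupt"
    MISSTART = "misstart"
    NONSTOP = "nonstop"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


class Inheritance(str, enum.Enum):
    DOMINANT = "dominant"
    RECESSIVE = "recessive"
    X_LINKED = "x_linked"


class MutationCategory(str, enum.Enum):
    """Category of a clinically diagnosed mutation.

    ``cnv`` and ``ivs`` (copy-number and intronic intervening-sequence
    variants) are outside what this pipeline can detect and mark a sample
    as not-expected-detectable.
    """

    SNV = "snv"
    INDEL = "indel"
    CNV = "cnv"
    IVS = "ivs"


_BASES = set("ACGT")
_INDEL_TYPES = frozenset({VarType.INS, VarType.DEL, VarType.SUB})
_INDEL_CONSEQ = frozenset({Consequence.FRAMESHIFT, Consequence.INFRAME_INDEL})


def _valid_allele(a: str) -> bool:
    return a == "-" or (len(a) >= 1 and set(a) <= _BASES)


@dataclass(frozen=True)
class VariantCall:
    """One non-reference variant call in one sample.

    ``allele_quality`` always holds two entries, one per haplotype call;
    the second entry is ignored for hemizygous calls.  ``freq_panel_a`` /
    ``freq_panel_b`` are population allele frequencies; ``None`` means the
    variant is absent from that panel (novel).
    """

    sample_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    var_type: VarType
    genotype: Genotype
    allele_quality: tuple[int, int]
    consequence: Consequence
    gene: Optional[str] = None
    freq_panel_a: Optional[float] = None
    freq_panel_b: Optional[float] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if not _valid_allele(self.ref_allele) or not _valid_allele(self.alt_allele):
            raise ValidationError(
                f"alleles must be over ACGT or '-': {self.ref_allele!r}>{self.alt_allele!r}"
            )
        if self.var_type is VarType.SNV and not (
            len(self.ref_allele) == 1 == len(self.alt_allele)
            and self.ref_allele != "-"
            and self.alt_allele != "-"
        ):
            raise ValidationError(
                f"snv requires single-base ref and alt: {self.ref_allele!r}>{self.alt_allele!r}"
            )
        if self.consequence in _INDEL_CONSEQ and self.var_type not in _INDEL_TYPES:
            raise ValidationError(
                f"{self.consequence.value} consequence requires an indel var_type, "
                f"got {self.var_type.value}"
            )
        if len(self.allele_quality) != 2:
            raise ValidationError("allele_quality must have exactly two entries")
        if any(q < 0 for q in self.allele_quality):
            raise ValidationError("allele qualities must be non-negative")
        for f in (self.freq_panel_a, self.freq_panel_b):
            if f is not None and not (0.0 <= f <= 1.0):
                raise ValidationError(f"frequency out of [0,1]: {f}")

    @property
    def is_indel(self) -> bool:
        """True for insertions, deletions and block substitutions."""
        return self.var_type in _INDEL_TYPES

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Site/allele identity (chrom, pos, ref, alt)."""
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)

    def with_sample(self, sample_id: str) -> "VariantCall":
        return replace(self, sample_id=sample_id)


@dataclass(frozen=True)
class PanelEntry:
    gene: str
    inheritance: Inheritance
    cancer_associated: bool
    coding_length: int

    def __post_init__(self) -> None:
        if self.coding_length <= 0:
            raise ValidationError(f"coding_length must be > 0 for {self.gene}")


@dataclass
class GenePanel:
    """A named disease-gene panel with per-gene metadata.

    ``excluded_genes`` lists genes dropped from analysis (e.g. platform
    artifact genes); they remain listed in ``entries`` so panel composition
    counts stay faithful to the source panel.
    """

    name: str
    entries: dict[str, PanelEntry] = field(default_factory=dict)
    excluded_genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for g, e in self.entries.items():
            if g != e.gene:
                raise ValidationError(f"entry key {g!r} != entry gene {e.gene!r}")

    @property
    def genes(self) -> set[str]:
        """Panel genes used for analysis (excluded genes removed)."""
        return set(self.entries) - self.excluded_genes

    def counts_by_inheritance(self) -> dict[Inheritance, int]:
        out = {m: 0 for m in Inheritance}
        for e in self.entries.values():
            out[e.inheritance] += 1
        return out

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, gene: str) -> bool:
        return gene in self.entries


@dataclass(frozen=True)
class ClinicalMutation:
    """A sample's clinically diagnosed mutation (from prior targeted testing)."""

    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    category: MutationCategory

    @property
    def expected_detectable(self) -> bool:
        """WGS is expected to detect SNVs and small indels, not CNV/IVS."""
        return self.category not in (MutationCategory.CNV, MutationCategory.IVS)


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    cohort_class: str  # "control" or "test"
    cohort_label: str  # free label, e.g. BRCA1 / BRCA2 / nonBRCA
    clinical_mutation: Optional[ClinicalMutation] = None

    def __post_init__(self) -> None:
        if self.cohort_class not in ("control", "test"):
            raise ValidationError(
                f"cohort_class must be 'control' or 'test', got {self.cohort_class!r}"
            )


@dataclass
class CohortManifest:
    """Samples with cohort membership and optional diagnosed mutations."""

    samples: list[SampleRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            dups = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicated sample_id(s): {dups}")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def sample_ids(self, cohort_label: Optional[str] = None,
                   cohort_class: Optional[str] = None) -> list[str]:
        out = []
        for s in self.samples:
            if cohort_label is not None and s.cohort_label != cohort_label:
                continue
            if cohort_class is not None and s.cohort_class != cohort_class:
                continue
            out.append(s.sample_id)
        return out

    @property
    def cohort_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.cohort_label)
        return list(seen)

    def by_id(self, sample_id: str) -> SampleRecord:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)
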