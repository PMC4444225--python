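"""Read and write variant tables, gene panels and cohort manifests.

Two variant-table dialects are supported:

``tsv``
    A flat per-call table (one row = one call in one sample) with a fixed,
    documented column set (:data:`TSV_COLUMNS`).  This mirrors the
    masterVar-style per-genome tables produced by whole-genome pipelines
    that report two per-allele variant quality scores.  ``"-"`` alleles
    (pure insertion/deletion notation without an anchor base) are permitted.

``vcf``
    VCF 4.x, multi-sample.  The two per-allele qualities travel in a
    two-entry integer FORMAT field and the gene / consequence / frequency /
    score annotations in INFO keys; all key names are configurable through
    :class:`VcfFieldMap`.  Alleles are anchor-based and left-normalized;
    ``"-"`` notation is rejected.

Parsers never silently drop rows: every input row becomes either a
:class:`~wgsinterp.models.VariantCall` (one per sample with a non-reference
genotype) or an entry in the line-numbered rejection report.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import pysam

from .models import (
    ClinicalMutation,
    CohortManifest,
    Consequence,
    GenePanel,
    Genotype,
    Inheritance,
    MutationCategory,
    PanelEntry,
    SampleRecord,
    ValidationError,
    VariantCall,
    VarType,
)

__all__ = [
    "TSV_COLUMNS",
    "VcfFieldMap",
    "ReadResult",
    "read_variant_table",
    "write_variant_table",
    "read_gene_panel",
    "write_gene_panel",
    "read_cohort_manifest",
    "write_cohort_manifest",
    "infer_var_type",
]

TSV_COLUMNS = [
    "sample_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "var_type",
    "genotype",
    "qual_allele1",
    "qual_allele2",
    "consequence",
    "gene",
    "freq_panel_a",
    "freq_panel_b",
    "score",
]


@dataclass(frozen=True)
class VcfFieldMap:
    """Names of the VCF FORMAT/INFO keys carrying the annotations."""

    allele_quality: str = "AQ"  # FORMAT, Number=2, Integer
    gene: str = "GENE"  # INFO, String
    consequence: str = "CSQCLS"  # INFO, String
    freq_panel_a: str = "FPA"  # INFO, Float
    freq_panel_b: str = "FPB"  # INFO, Float
    score: str = "SCORE"  # INFO, Float

    @classmethod
    def from_mapping(cls, mapping: dict) -> "VcfFieldMap":
        return cls(**{k: v for k, v in mapping.items() if k in cls.__dataclass_fields__})


@dataclass
class ReadResult:
    """Parsed calls plus a line-numbered report of rejected rows."""

    calls: list[VariantCall]
    rejected: list[tuple[int, str]] = field(default_factory=list)
    n_input_rows: int = 0

    def __iter__(self):
        return iter(self.calls)

    def __len__(self) -> int:
        return len(self.calls)


def infer_var_type(ref: str, alt: str) -> VarType:
    """Classify by allele lengths ("-" counts as length zero)."""
    lr = 0 if ref == "-" else len(ref)
    la = 0 if alt == "-" else len(alt)
    if lr == 1 and la == 1:
        return VarType.SNV
    if lr < la:
        return VarType.INS
    if lr > la:
        return VarType.DEL
    return VarType.SUB


# ---------------------------------------------------------------------------
# TSV dialect


def _opt_float(v) -> Optional[float]:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return float(v)


def _read_tsv(path: Path) -> ReadResult:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"variant TSV {path} missing column(s): {missing}")
    calls: list[VariantCall] = []
    rejected: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # header is line 1
        try:
            calls.append(
                VariantCall(
                    sample_id=row.sample_id,
                    chrom=row.chrom,
                    pos=int(row.pos),
                    ref_allele=row.ref,
                    alt_allele=row.alt,
                    var_type=VarType(row.var_type),
                    genotype=Genotype(row.genotype),
                    allele_quality=(int(row.qual_allele1), int(row.qual_allele2)),
                    consequence=Consequence(row.consequence),
                    gene=row.gene or None,
                    freq_panel_a=_opt_float(row.freq_panel_a),
                    freq_panel_b=_opt_float(row.freq_panel_b),
                    score=_opt_float(row.score),
                )
            )
        except (ValidationError, ValueError) as exc:
            rejected.append((line_no, str(exc)))
    return ReadResult(calls=calls, rejected=rejected, n_input_rows=len(df))


def _write_tsv(calls: Sequence[VariantCall], path: Path) -> None:
    rows = []
    for c in calls:
        rows.append(
            {
                "sample_id": c.sample_id,
                "chrom": c.chrom,
                "pos": c.pos,
                "ref": c.ref_allele,
                "alt": c.alt_allele,
                "var_type": c.var_type.value,
                "genotype": c.genotype.value,
                "qual_allele1": c.allele_quality[0],
                "qual_allele2": c.allele_quality[1],
                "consequence": c.consequence.value,
                "gene": c.gene or "",
                "freq_panel_a": "" if c.freq_panel_a is None else repr(c.freq_panel_a),
                "freq_panel_b": "" if c.freq_panel_b is None else repr(c.freq_panel_b),
                "score": "" if c.score is None else repr(c.score),
            }
        )
    pd.DataFrame(rows, columns=TSV_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF dialect

_FLOAT_SIG = 6  # VCF Float is single precision; round on read to its precision


def _round_sig(x: Optional[float]) -> Optional[float]:
    if x is None or x == 0:
        return x
    return float(f"{x:.{_FLOAT_SIG}g}")


def _read_vcf(path: Path, field_map: VcfFieldMap) -> ReadResult:
    fm = field_map
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise ValidationError(f"malformed VCF header in {path}: {exc}") from exc
    with vf:
        for key, kind in [
            (fm.gene, "INFO"),
            (fm.consequence, "INFO"),
            (fm.allele_quality, "FORMAT"),
        ]:
            pool = vf.header.info if kind == "INFO" else vf.header.formats
            if key not in pool:
                raise ValidationError(
                    f"VCF {path} lacks required {kind} field {key!r}; "
                    "check the field-map configuration"
                )
        calls: list[VariantCall] = []
        rejected: list[tuple[int, str]] = []
        n_rows = 0
        for rec_idx, rec in enumerate(vf):
            n_rows += 1
            try:
                calls.extend(_calls_from_vcf_record(rec, fm))
            except (ValidationError, ValueError, KeyError) as exc:
                rejected.append((rec_idx + 1, f"{rec.chrom}:{rec.pos}: {exc}"))
    return ReadResult(calls=calls, rejected=rejected, n_input_rows=n_rows)


def _calls_from_vcf_record(rec, fm: VcfFieldMap) -> list[VariantCall]:
    if rec.alts is None or len(rec.alts) != 1:
        raise ValidationError("exactly one ALT allele per record is required")
    alt = rec.alts[0]
    gene = rec.info.get(fm.gene)
    if isinstance(gene, tuple):
        gene = gene[0]
    csq_raw = rec.info.get(fm.consequence)
    if isinstance(csq_raw, tuple):
        csq_raw = csq_raw[0]
    consequence = Consequence(csq_raw)
    fpa = rec.info.get(fm.freq_panel_a)
    fpb = rec.info.get(fm.freq_panel_b)
    score = rec.info.get(fm.score)
    out = []
    for sample_name, sdata in rec.samples.items():
        gt = sdata.get("GT")
        if gt is None or all(a in (None, 0) for a in gt):
            continue  # reference or missing genotype yields no call
        alleles = [a for a in gt if a is not None]
        if len(alleles) == 1:
            genotype = Genotype.HEMI
        elif all(a == 1 for a in alleles):
            genotype = Genotype.HOM
        else:
            genotype = Genotype.HET
        aq = sdata.get(fm.allele_quality)
        if aq is None:
            raise ValidationError(f"sample {sample_name} lacks {fm.allele_quality}")
        aq = tuple(int(q) for q in aq)
        if len(aq) == 1:
            aq = (aq[0], aq[0])
        out.append(
            VariantCall(
                sample_id=sample_name,
                chrom=rec.chrom,
                pos=rec.pos,
                ref_allele=rec.ref,
                alt_allele=alt,
                var_type=infer_var_type(rec.ref, alt),
                genotype=genotype,
                allele_quality=aq,
                consequence=consequence,
                gene=gene,
                freq_panel_a=_round_sig(fpa),
                freq_panel_b=_round_sig(fpb),
                score=_round_sig(score),
            )
        )
    return out


def _write_vcf(calls: Sequence[VariantCall], path: Path, field_map: VcfFieldMap) -> None:
    fm = field_map
    for c in calls:
        if c.ref_allele == "-" or c.alt_allele == "-":
            raise ValidationError(
                f"'-' alleles are not representable in the vcf dialect "
                f"({c.chrom}:{c.pos}); left-normalize with an anchor base"
            )
    header = pysam.VariantHeader()
    header.add_meta("source", "wgsinterp")
    for chrom in sorted({c.chrom for c in calls}):
        header.contigs.add(chrom)
    header.info.add(fm.gene, 1, "String", "Gene symbol")
    header.info.add(fm.consequence, 1, "String", "Coding consequence class")
    header.info.add(fm.freq_panel_a, 1, "Float", "Reference panel A allele frequency")
    header.info.add(fm.freq_panel_b, 1, "Float", "Reference panel B allele frequency")
    header.info.add(fm.score, 1, "Float", "Deleteriousness score")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add(fm.allele_quality, 2, "Integer", "Per-allele variant quality")
    samples = sorted({c.sample_id for c in calls})
    for s in samples:
        header.add_sample(s)

    by_site: dict[tuple, dict[str, VariantCall]] = {}
    for c in calls:
        site = by_site.setdefault(c.key + (c.gene, c.consequence), {})
        if c.sample_id in site:
            raise ValidationError(
                f"duplicate call for sample {c.sample_id} at {c.chrom}:{c.pos}"
            )
        site[c.sample_id] = c

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for key in sorted(by_site, key=lambda k: (k[0], k[1], k[2], k[3])):
            site = by_site[key]
            any_call = next(iter(site.values()))
            rec = out.new_record(
                contig=any_call.chrom,
                start=any_call.pos - 1,
                alleles=(any_call.ref_allele, any_call.alt_allele),
            )
            if any_call.gene is not None:
                rec.info[fm.gene] = any_call.gene
            rec.info[fm.consequence] = any_call.consequence.value
            if any_call.freq_panel_a is not None:
                rec.info[fm.freq_panel_a] = any_call.freq_panel_a
            if any_call.freq_panel_b is not None:
                rec.info[fm.freq_panel_b] = any_call.freq_panel_b
            if any_call.score is not None:
                rec.info[fm.score] = any_call.score
            for s in samples:
                if s in site:
                    c = site[s]
                    if c.genotype is Genotype.HOM:
                        gt = (1, 1)
                    elif c.genotype is Genotype.HEMI:
                        gt = (1,)
                    else:
                        gt = (0, 1)
                    rec.samples[s]["GT"] = gt
                    rec.samples[s][fm.allele_quality] = list(c.allele_quality)
                else:
                    rec.samples[s]["GT"] = (0, 0)
                    rec.samples[s][fm.allele_quality] = (0, 0)
            out.write(rec)


# ---------------------------------------------------------------------------
# public variant-table API


def read_variant_table(
    path: Union[str, Path],
    dialect: str = "tsv",
    field_map: VcfFieldMap = VcfFieldMap(),
) -> ReadResult:
    """Parse a variant table into :class:`VariantCall` records.

    Returns a :class:`ReadResult`; rows violating type invariants land in
    ``result.rejected`` as ``(line_number, reason)`` pairs rather than
    raising, so ``len(result.calls)`` plus sample-expanded rejections always
    accounts for the full input.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        return _read_tsv(path)
    if dialect == "vcf":
        return _read_vcf(path, field_map)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_variant_table(
    calls: Sequence[VariantCall],
    path: Union[str, Path],
    dialect: str = "tsv",
    field_map: VcfFieldMap = VcfFieldMap(),
) -> None:
    path = Path(path)
    if dialect == "tsv":
        _write_tsv(calls, path)
    elif dialect == "vcf":
        _write_vcf(calls, path, field_map)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# gene panel


def read_gene_panel(path: Union[str, Path], name: Optional[str] = None) -> GenePanel:
    """Load a gene panel from TSV (gene / inheritance / cancer_associated /
    coding_length [/ excluded]) or JSON with the same keys."""
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        rows = payload["entries"]
        panel_name = name or payload.get("name", path.stem)
        excluded = set(payload.get("excluded_genes", []))
    else:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
        required = {"gene", "inheritance", "cancer_associated", "coding_length"}
        if missing := required - set(df.columns):
            raise ValidationError(f"gene panel {path} missing column(s): {sorted(missing)}")
        rows = df.to_dict("records")
        panel_name = name or path.stem
        excluded = {
            r["gene"] for r in rows if str(r.get("excluded", "")).lower() in ("1", "true")
        }
    if not rows:
        raise ValidationError(f"gene panel {path} is empty")
    entries: dict[str, PanelEntry] = {}
    for r in rows:
        g = r["gene"]
        if g in entries:
            raise ValidationError(f"duplicate gene symbol in panel: {g}")
        entries[g] = PanelEntry(
            gene=g,
            inheritance=Inheritance(r["inheritance"]),
            cancer_associated=str(r["cancer_associated"]).lower() in ("1", "true"),
            coding_length=int(r["coding_length"]),
        )
    return GenePanel(name=panel_name, entries=entries, excluded_genes=excluded)


def write_gene_panel(panel: GenePanel, path: Union[str, Path]) -> None:
    rows = [
        {
            "gene": e.gene,
            "inheritance": e.inheritance.value,
            "cancer_associated": int(e.cancer_associated),
            "coding_length": e.coding_length,
            "excluded": int(e.gene in panel.excluded_genes),
        }
        for e in panel.entries.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# cohort manifest

MANIFEST_COLUMNS = [
    "sample_id",
    "cohort_class",
    "cohort_label",
    "mut_gene",
    "mut_chrom",
    "mut_pos",
    "mut_ref",
    "mut_alt",
    "mut_category",
]


def read_cohort_manifest(path: Union[str, Path]) -> CohortManifest:
    df = pd.read_csv(Path(path), sep="\t", dtype=str, keep_default_na=False)
    if missing := {"sample_id", "cohort_class", "cohort_label"} - set(df.columns):
        raise ValidationError(f"manifest {path} missing column(s): {sorted(missing)}")
    samples = []
    for row in df.to_dict("records"):
        mut = None
        if row.get("mut_gene"):
            mut = ClinicalMutation(
                gene=row["mut_gene"],
                chrom=row.get("mut_chrom", ""),
                pos=int(row["mut_pos"]) if row.get("mut_pos") else 0,
                ref=row.get("mut_ref", ""),
                alt=row.get("mut_alt", ""),
                category=MutationCategory(row["mut_category"]),
            )
        samples.append(
            SampleRecord(
                sample_id=row["sample_id"],
                cohort_class=row["cohort_class"],
                cohort_label=row["cohort_label"],
                clinical_mutation=mut,
            )
        )
    return CohortManifest(samples=samples)


def write_cohort_manifest(manifest: CohortManifest, path: Union[str, Path]) -> None:
    rows = []
    for s in manifest.samples:
        m = s.clinical_mutation
        rows.append(
            {
                "sample_id": s.sample_id,
                "cohort_class": s.cohort_class,
                "cohort_label": s.cohort_label,
                "mut_gene": m.gene if m else "",
                "mut_chrom": m.chrom if m else "",
                "mut_pos": m.pos if m else "",
                "mut_ref": m.ref if m else "",
                "mut_alt": m.alt if m else "",
                "mut_category": m.category.value if m else "",
            }
        )
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, sep="\t", index=False)
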