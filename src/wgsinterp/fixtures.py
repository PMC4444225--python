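"""Packaged worked-example fixtures: the 163-gene clinical panel, the
published loss-of-function findings in both cohorts, and the
clinical-mutation confirmation scenario.

Gene symbols, inheritance modes, cancer-association flags, patient labels,
variant labels and all counts are the published ones.  Genomic coordinates
and coding lengths are NOT published at this granularity, so the builders
assign deterministic synthetic coordinates (one megabase block per gene)
and synthetic log-normal coding lengths; every quantity the pipeline
computes from these fixtures depends only on the published fields.

Cohort sizes: 176 carriers of a known BRCA1/2 mutation (88 + 88, the
"control" population for gene-variance analysis) and 82 non-BRCA cancer
genetics patients (the "test" population).
"""

from __future__ import annotations

import numpy as np

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
    VariantCall,
    VarType,
)

__all__ = [
    "PANEL_DOMINANT",
    "PANEL_RECESSIVE",
    "PANEL_X_LINKED",
    "CANCER_ASSOCIATED",
    "TABLE2_ROWS",
    "TABLE3_ROWS",
    "clinical_panel",
    "clinvar_style_panel",
    "table2_calls",
    "table3_calls",
    "cohort_manifest",
    "detection_scenario",
]

# 135 dominant disease genes of the clinical panel (FAM175A listed under its
# primary symbol; the source also gives the alias Abraxas).
PANEL_DOMINANT = [
    "ACTA2", "ACTC1", "ACVRL1", "APC", "APOB", "ATM", "ATR", "BAP1", "BARD1",
    "BMPR1A", "BRCA1", "BRCA2", "BRIP1", "CACNA1C", "CACNA1S", "CACNB2",
    "CDC73", "CDH1", "CDK4", "CDKN1A", "CDKN2A", "CDKN2B", "CHEK1", "CHEK2",
    "CNBP", "COL3A1", "CREBBP", "DMPK", "DSC2", "DSG2", "DSP", "EGFR",
    "ELAC2", "ENG", "EPCAM", "FAM175A", "FBN1", "FH", "FLCN", "GALNT12",
    "GCH1", "GEN1", "GPD1L", "GREM1", "HCN4", "HIP1", "HIP1R", "HMBS",
    "HOXB1", "HOXB13", "HTT", "JAK2", "KCNE1", "KCNE2", "KCNE3", "KCNH1",
    "KCNH2", "KCNJ2", "KCNQ1", "KDR", "KIT", "LDLR", "LMNA", "MEN1", "MET",
    "MITF", "MLH1", "MLH3", "MRE11A", "MSH2", "MSH6", "MUTYH", "MYBPC3",
    "MYH11", "MYH7", "MYL2", "MYL3", "MYLK", "NBN", "NF1", "NF2", "NTRK1",
    "PALB2", "PCSK9", "PDGFRA", "PKP2", "PLN", "PMS2", "PRKAG2", "PRKAR1A",
    "PROC", "PROS1", "PRSS1", "PTCH1", "PTEN", "RAD50", "RAD51", "RAD51C",
    "RAD51D", "RAS", "RB1", "RBBP8", "RBM20", "RET", "RYR1", "RYR2",
    "SCN1B", "SCN3B", "SCN5A", "SDHAF2", "SDHB", "SDHC", "SDHD", "SERPINC1",
    "SGCD", "SMAD3", "SMAD4", "SMARCB1", "SMO", "STK11", "TGFB3", "TGFBR1",
    "TGFBR2", "TMEM43", "TNNI3", "TNNT2", "TP53", "TP53BP1", "TPM1", "TSC1",
    "TSC2", "VHL", "WT1", "XRCC2", "XRCC3",
]

# 24 recessive disease genes.
PANEL_RECESSIVE = [
    "ATP7B", "BCHE", "BLM", "CASQ2", "CFTR", "COQ2", "COQ9", "CPT2", "F5",
    "GAA", "HAMP", "HFE", "HFE2", "IDUA", "INPP5B", "LDLRAP1", "PAH",
    "PCBD1", "PTS", "QDPR", "SERPINA1", "SLC25A13", "SLC37A4", "SLC7A9",
]

# 4 X-linked disease genes.
PANEL_X_LINKED = ["DMD", "EMD", "GLA", "OTC"]

# Cancer-associated subset of the panel (set in bold in the source panel).
CANCER_ASSOCIATED = frozenset(
    {
        "APC", "ATM", "ATR", "BAP1", "BARD1", "BMPR1A", "BRCA1", "BRCA2",
        "BRIP1", "CDC73", "CDH1", "CDK4", "CDKN1A", "CDKN2A", "CDKN2B",
        "CHEK1", "CHEK2", "CREBBP", "EGFR", "ELAC2", "EPCAM", "FAM175A",
        "FH", "FLCN", "GALNT12", "GEN1", "GREM1", "HOXB13", "JAK2", "KDR",
        "KIT", "MEN1", "MET", "MITF", "MLH1", "MLH3", "MRE11A", "MSH2",
        "MSH6", "MUTYH", "NBN", "NF1", "NF2", "NTRK1", "PALB2", "PDGFRA",
        "PMS2", "PTCH1", "PTEN", "RAD50", "RAD51", "RAD51C", "RAD51D",
        "RAS", "RB1", "RET", "SDHAF2", "SDHB", "SDHC", "SDHD", "SMAD4",
        "SMARCB1", "SMO", "STK11", "TP53", "TP53BP1", "TSC1", "TSC2", "VHL",
        "WT1", "XRCC2", "XRCC3", "BLM",
    }
)

# Published LoF PPVs in cancer-associated genes, BRCA1/2-carrier cohort.
# (patient, gene, variant label, consequence class, section); sections:
# "panel" = discovered on the 163-gene panel, "clinvar" = discovered after
# expanding to the ClinVar gene set.
TABLE2_ROWS = [
    ("BRCA1.60", "CHEK2", "c.573+1G>A", "splice_disrupt", "panel"),
    ("BRCA1.61", "ATM", "p.Glu2290*", "frameshift", "panel"),  # the one indel
    ("BRCA2.7", "RAD50", "c.3G>A", "misstart", "panel"),
    ("BRCA2.13", "ATM", "p.Glu1978*", "nonsense", "panel"),
    ("BRCA2.65", "CDKN2B", "p.Glu35*", "nonsense", "panel"),
    ("BRCA2.93", "CHEK2", "p.Gln20*", "nonsense", "panel"),
    ("BRCA1.48", "ERCC3", "p.Arg109*", "nonsense", "clinvar"),
    ("BRCA1.73", "DLEC1", "c.2436-2A>G", "splice_disrupt", "clinvar"),
    ("BRCA1.74", "FANCC", "p.Arg548*", "nonsense", "clinvar"),
]

# Published LoF PPVs in cancer-associated genes, non-BRCA cohort; sections:
# "confirmed" = mutation already diagnosed by standard clinical testing,
# "discovered_panel" / "discovered_clinvar" = newly identified.
TABLE3_ROWS = [
    ("UTSW3", "TP53", "p.Arg196*", "nonsense", "confirmed"),
    ("UTSW12", "APC", "p.Asp170Valfs*4", "frameshift", "confirmed"),
    ("UTSW13", "FH", "p.Gln185Leufs*18", "frameshift", "confirmed"),
    ("UTSW16", "APC", "p.Arg1920Glufs*50", "frameshift", "confirmed"),
    ("UTSW31", "MSH6", "p.Phe569Hisfs*7", "frameshift", "confirmed"),
    ("UTSW32", "MSH6", "p.Arg911*", "nonsense", "confirmed"),
    ("UTSW38", "FH", "p.Gln185Leufs*18", "frameshift", "confirmed"),
    ("UTSW44", "MSH2", "p.Arg389*", "nonsense", "confirmed"),
    ("UTSW53", "MSH6", "p.Lys1013Ilefs*3", "frameshift", "confirmed"),
    ("UTSW55", "APC", "p.Glu1309Aspfs*4", "frameshift", "confirmed"),
    ("UTSW78", "ATM", "p.Val835Serfs*7", "frameshift", "confirmed"),
    ("UTSW78", "RAD50", "p.Thr109Asnfs*20", "frameshift", "confirmed"),
    ("UTSW9", "PALB2", "p.Tyr1183*", "nonsense", "discovered_panel"),
    ("UTSW13", "RAD51C", "p.Arg193*", "nonsense", "discovered_panel"),
    ("UTSW36", "PALB2", "p.Glu27*", "nonsense", "discovered_panel"),
    ("UTSW22", "FANCM", "p.Gln1701*", "nonsense", "discovered_clinvar"),
    ("UTSW51", "FANCM", "p.Gln1701*", "nonsense", "discovered_clinvar"),
    ("UTSW76", "ERCC3", "p.Arg109*", "nonsense", "discovered_clinvar"),
    ("UTSW82", "FANCA", "p.Glu288*", "nonsense", "discovered_clinvar"),
]

# Genes appearing only in the ClinVar-scale findings, not on the 163 panel.
CLINVAR_EXTRA_GENES = ["DLEC1", "ERCC3", "FANCA", "FANCC", "FANCM"]


def _all_fixture_genes() -> list[str]:
    return sorted(
        set(PANEL_DOMINANT) | set(PANEL_RECESSIVE) | set(PANEL_X_LINKED)
        | set(CLINVAR_EXTRA_GENES)
    )


_GENE_INDEX = {g: i for i, g in enumerate(_all_fixture_genes())}


def _gene_chrom(gene: str) -> str:
    return str(_GENE_INDEX[gene] % 22 + 1)


def _gene_start(gene: str) -> int:
    return (_GENE_INDEX[gene] + 1) * 1_000_000


def _synthetic_coding_lengths() -> dict[str, int]:
    # synthetic: log-normal lengths, deterministic per gene list order
    genes = _all_fixture_genes()
    rng = np.random.default_rng(np.random.SeedSequence([163]))
    lengths = np.maximum(
        300, np.round(rng.lognormal(7.6, 0.7, size=len(genes))).astype(int)
    )
    return {g: int(lengths[i]) for i, g in enumerate(genes)}


_CODING_LENGTHS = _synthetic_coding_lengths()


def clinical_panel() -> GenePanel:
    """The 163-gene clinical panel (135 dominant, 24 recessive, 4 X-linked).

    Coding lengths are synthetic placeholders; inheritance and
    cancer-association flags are published.
    """
    entries: dict[str, PanelEntry] = {}
    for genes, mode in [
        (PANEL_DOMINANT, Inheritance.DOMINANT),
        (PANEL_RECESSIVE, Inheritance.RECESSIVE),
        (PANEL_X_LINKED, Inheritance.X_LINKED),
    ]:
        for g in genes:
            entries[g] = PanelEntry(
                gene=g,
                inheritance=mode,
                cancer_associated=g in CANCER_ASSOCIATED,
                coding_length=_CODING_LENGTHS[g],
            )
    return GenePanel(name="clinical-163", entries=entries)


def clinvar_style_panel() -> GenePanel:
    """The clinical panel extended with the extra disease genes that only
    enter at ClinVar scale (ERCC3, FANCA, FANCC, FANCM, DLEC1), all
    cancer-associated dominant entries with synthetic coding lengths."""
    base = clinical_panel()
    entries = dict(base.entries)
    for g in CLINVAR_EXTRA_GENES:
        entries[g] = PanelEntry(
            gene=g,
            inheritance=Inheritance.DOMINANT,
            cancer_associated=True,
            coding_length=_CODING_LENGTHS[g],
        )
    return GenePanel(name="clinvar-style", entries=entries)


# stable per-(gene, label) variant coordinates, in first-appearance order
_VARIANT_OFFSETS: dict[tuple[str, str], int] = {}
for _p, _g, _label, _csq, _sec in TABLE2_ROWS + TABLE3_ROWS:
    _VARIANT_OFFSETS.setdefault((_g, _label), 11 + 10 * len(_VARIANT_OFFSETS))


def _fixture_call(
    patient: str, gene: str, label: str, csq: str, quality: tuple[int, int] = (250, 250)
) -> VariantCall:
    pos = _gene_start(gene) + _VARIANT_OFFSETS[(gene, label)]
    consequence = Consequence(csq)
    if consequence is Consequence.FRAMESHIFT:
        ref, alt, vt = "AC", "A", VarType.DEL
    else:
        ref, alt, vt = "C", "A", VarType.SNV
    return VariantCall(
        sample_id=patient,
        chrom=_gene_chrom(gene),
        pos=pos,
        ref_allele=ref,
        alt_allele=alt,
        var_type=vt,
        genotype=Genotype.HET,
        allele_quality=quality,
        consequence=consequence,
        gene=gene,
        freq_panel_a=None,
        freq_panel_b=None,
    )


def table2_calls() -> list[VariantCall]:
    """The nine published LoF PPVs found in BRCA1/2-carrier genomes."""
    return [_fixture_call(p, g, lab, csq) for p, g, lab, csq, _ in TABLE2_ROWS]


def table3_calls() -> list[VariantCall]:
    """The published LoF PPVs found in the 82 non-BRCA genomes
    (19 findings in 17 distinct patients)."""
    return [_fixture_call(p, g, lab, csq) for p, g, lab, csq, _ in TABLE3_ROWS]


def cohort_manifest() -> CohortManifest:
    """Manifest for the two clinic cohorts: 88 + 88 BRCA1/2-carriers
    (control) and 82 non-BRCA patients (test)."""
    samples = []
    for label, n in [("BRCA1", 88), ("BRCA2", 88)]:
        samples += [
            SampleRecord(f"{label}.{i + 1}", "control", label) for i in range(n)
        ]
    samples += [SampleRecord(f"UTSW{i + 1}", "test", "nonBRCA") for i in range(82)]
    return CohortManifest(samples=samples)


def detection_scenario() -> tuple[CohortManifest, list[VariantCall]]:
    """The clinical-mutation confirmation scenario for the 176 carriers.

    Published accounting, encoded per sample: of 88 BRCA1-mutation
    carriers, 13 diagnoses were CNV/IVS (not WGS-detectable), leaving 75
    expected; 67 were recovered at high quality and 8 only at low quality.
    All 88 BRCA2 diagnoses were expected; 78 high quality, 10 low.  16 of
    the 18 low-quality recoveries were indel diagnoses.  Which individual
    samples fall in each bucket is synthetic; the bucket sizes are the
    published ones.
    """
    spec = {
        # label: (n, n_not_expected, n_low_quality, n_low_indel)
        "BRCA1": (88, 13, 8, 7),
        "BRCA2": (88, 0, 10, 9),
    }
    samples: list[SampleRecord] = []
    calls: list[VariantCall] = []
    for label, (n, n_skip, n_low, n_low_indel) in spec.items():
        gene = label
        chrom, start = _gene_chrom(gene), _gene_start(gene)
        for i in range(n):
            sid = f"{label}.{i + 1}"
            pos = start + 100 + i
            if i < n_skip:
                category = MutationCategory.CNV if i % 2 == 0 else MutationCategory.IVS
                mut = ClinicalMutation(gene, chrom, pos, "C", "A", category)
                samples.append(SampleRecord(sid, "control", label, mut))
                continue  # CNV/IVS events have no small-variant call
            j = i - n_skip
            low = j < n_low
            indel = low and j < n_low_indel
            if indel:
                ref, alt, vt, csq = "AC", "A", VarType.DEL, Consequence.FRAMESHIFT
                category = MutationCategory.INDEL
                quality = (140, 140)  # below the exclusive indel bound of 150
            else:
                ref, alt, vt, csq = "C", "A", VarType.SNV, Consequence.NONSENSE
                category = MutationCategory.SNV
                quality = (60, 60) if low else (250, 250)
            mut = ClinicalMutation(gene, chrom, pos, ref, alt, category)
            samples.append(SampleRecord(sid, "control", label, mut))
            calls.append(
                VariantCall(
                    sample_id=sid,
                    chrom=chrom,
                    pos=pos,
                    ref_allele=ref,
                    alt_allele=alt,
                    var_type=vt,
                    genotype=Genotype.HET,
                    allele_quality=quality,
                    consequence=csq,
                    gene=gene,
                    freq_panel_a=None,
                    freq_panel_b=None,
                )
            )
    return CohortManifest(samples=samples), calls
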