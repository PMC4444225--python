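import pytest

from wgsinterp import fixtures as fx
from wgsinterp.models import (
    Consequence,
    Genotype,
    VariantCall,
    VarType,
)


def make_call(
    sample_id="S1",
    chrom="1",
    pos=1000,
    ref="C",
    alt="A",
    var_type=VarType.SNV,
    genotype=Genotype.HET,
    quality=(200, 200),
    consequence=Consequence.MISSENSE,
    gene="GENE1",
    freq_a=None,
    freq_b=None,
    score=None,
):
    return VariantCall(
        sample_id=sample_id,
        chrom=chrom,
        pos=pos,
        ref_allele=ref,
        alt_allele=alt,
        var_type=var_type,
        genotype=genotype,
        allele_quality=quality,
        consequence=consequence,
        gene=gene,
        freq_panel_a=freq_a,
        freq_panel_b=freq_b,
        score=score,
    )


@pytest.fixture(scope="session")
def clinical_panel():
    return fx.clinical_panel()


@pytest.fixture(scope="session")
def clinvar_panel():
    return fx.clinvar_style_panel()


@pytest.fixture(scope="session")
def cohorts_manifest():
    return fx.cohort_manifest()
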