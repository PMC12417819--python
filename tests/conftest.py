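import pytest

from germdmg import (
    AnnotatedVariant,
    ClinVar,
    Consequence,
    Genotype,
    PredictorPanel,
    Verdict,
    build_curation_queue,
    classify,
    default_panel,
    helium_score,
)
from germdmg.scoring import PREDICTORS
from germdmg.synthetic_data import GENE_LOCI


@pytest.fixture(scope="session")
def panel():
    return default_panel()


def make_variant(
    gene="BRCA2",
    chrom=None,
    pos=None,
    ref="G",
    alt="A",
    consequence=Consequence.MISSENSE,
    af=0.0,
    clinvar=ClinVar.ABSENT,
    vaf=0.5,
    genotype=Genotype.HET,
    n_damaging=0,
):
    """Annotated variant with domain-plausible defaults, placed at its gene locus."""
    loc = GENE_LOCI.get(gene, ("1", 1_000_000))
    verdicts = {p: Verdict.DAMAGING for p in PREDICTORS[:n_damaging]}
    return AnnotatedVariant(
        chrom=chrom or loc[0],
        pos=pos or loc[1],
        ref=ref,
        alt=alt,
        gene_symbol=gene,
        consequence=consequence,
        population_af=af,
        clinvar=clinvar,
        vaf=vaf,
        genotype=genotype,
        predictor_panel=PredictorPanel(verdicts),
    )


def make_classified(panel, gene, phenotype_match=False, **variant_kwargs):
    """Run one variant through scoring -> filtration -> classification."""
    v = make_variant(gene=gene, **variant_kwargs)
    sv = helium_score(v, panel.entry(gene))
    queue = build_curation_queue([sv], panel)
    assert queue, f"variant in {gene} was not admitted to the curation queue"
    return classify(queue[0], phenotype_match=phenotype_match)
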