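import numpy as np
import pytest

from germdmg import (
    AdmitReason,
    ClinVar,
    Consequence,
    GenePanel,
    GenePanelEntry,
    Genotype,
    Inheritance,
    Pathway,
    SpliceMode,
    TrafficLight,
    ZygosityClass,
    build_curation_queue,
    find_compound_hets,
    helium_score,
    is_rare,
    zygosity_class,
)
from germdmg.filtration import COMPOUND_HET_MIN_SCORE, SCORE_THRESHOLD
from germdmg.panel import PanelLookupError

from conftest import make_variant


@pytest.mark.parametrize(
    "vaf,genotype,expected",
    [
        (0.65, Genotype.HET, ZygosityClass.LIKELY_BIALLELIC),
        (0.60, Genotype.HET, ZygosityClass.HETEROZYGOUS),  # strict "above 0.6"
        (0.48, Genotype.HOM_ALT, ZygosityClass.LIKELY_BIALLELIC),
        (0.30, Genotype.HET, ZygosityClass.HETEROZYGOUS),
    ],
)
def test_zygosity_class(vaf, genotype, expected):
    assert zygosity_class(make_variant(vaf=vaf, genotype=genotype)) is expected


def _scored(panel, gene, **kw):
    return helium_score(make_variant(gene=gene, **kw), panel.entry(gene))


def test_compound_het_pair_detection(panel):
    a = _scored(panel, "MUTYH", pos=45_794_915, clinvar=ClinVar.PATHOGENIC)
    b = _scored(panel, "MUTYH", pos=45_795_100, clinvar=ClinVar.PATHOGENIC)
    pairs = find_compound_hets([a, b], "MUTYH")
    assert pairs == [(a, b)]
    assert find_compound_hets([a], "MUTYH") == []


def test_compound_het_requires_eligible_score_and_het(panel):
    plp = _scored(panel, "MUTYH", pos=45_794_915, clinvar=ClinVar.PATHOGENIC)
    low = _scored(panel, "MUTYH", pos=45_795_200, af=0.2)  # common, score 0
    hom = _scored(panel, "MUTYH", pos=45_795_300, clinvar=ClinVar.PATHOGENIC,
                  genotype=Genotype.HOM_ALT)
    assert find_compound_hets([plp, low, hom], "MUTYH") == []


def test_three_eligible_hets_give_all_pairs(panel):
    """C(3,2) pairs, matching brute-force enumeration, in position order."""
    import itertools

    svs = [
        _scored(panel, "MUTYH", pos=45_794_915 + 100 * k, clinvar=ClinVar.PATHOGENIC)
        for k in range(3)
    ]
    pairs = find_compound_hets(list(reversed(svs)), "MUTYH")
    assert pairs == list(itertools.combinations(svs, 2))
    assert len(pairs) == 3


def test_green_dominant_high_score_admitted(panel):
    sv = _scored(panel, "BRCA2", clinvar=ClinVar.PATHOGENIC)
    queue = build_curation_queue([sv], panel)
    assert len(queue) == 1
    assert queue[0].admit_reason is AdmitReason.GREEN_HIGH_SCORE
    assert queue[0].partner_variant is None


def _custom_panel():
    """Panel with a non-excepted recessive gene and an amber gene."""
    return GenePanel(
        [
            GenePanelEntry("RECG", TrafficLight.GREEN, Inheritance.RECESSIVE, True, Pathway.FA),
            GenePanelEntry("AMBG", TrafficLight.AMBER, Inheritance.DOMINANT, True, Pathway.HR),
            GenePanelEntry("REDG", TrafficLight.RED, Inheritance.DOMINANT, True, Pathway.HR),
        ]
    )


def test_recessive_single_het_not_admitted():
    panel = _custom_panel()
    sv = _scored(panel, "RECG", chrom="9", pos=1000, clinvar=ClinVar.PATHOGENIC, vaf=0.5)
    assert build_curation_queue([sv], panel) == []


def test_recessive_biallelic_and_compound_het_admitted():
    panel = _custom_panel()
    biallelic = _scored(panel, "RECG", chrom="9", pos=1000, clinvar=ClinVar.PATHOGENIC, vaf=0.9)
    queue = build_curation_queue([biallelic], panel)
    assert [q.admit_reason for q in queue] == [AdmitReason.RECESSIVE_BIALLELIC]

    a = _scored(panel, "RECG", chrom="9", pos=1000, clinvar=ClinVar.PATHOGENIC)
    b = _scored(panel, "RECG", chrom="9", pos=2000, clinvar=ClinVar.PATHOGENIC)
    queue = build_curation_queue([a, b], panel)
    assert [q.admit_reason for q in queue] == [AdmitReason.RECESSIVE_COMPOUND_HET] * 2
    assert queue[0].partner_variant == b.variant
    assert queue[1].partner_variant == a.variant


def test_mutyh_single_het_admitted_by_exception(panel):
    sv = _scored(panel, "MUTYH", clinvar=ClinVar.PATHOGENIC, vaf=0.5)
    queue = build_curation_queue([sv], panel)
    assert [q.admit_reason for q in queue] == [AdmitReason.SINGLE_HIT_EXCEPTION]


def test_amber_and_red_genes_never_admitted():
    panel = _custom_panel()
    for gene in ("AMBG", "REDG"):
        sv = _scored(panel, gene, chrom="9", pos=1000, clinvar=ClinVar.PATHOGENIC)
        assert sv.helium_score == 100
        assert build_curation_queue([sv], panel) == []


def test_splice_carveout_modes(panel):
    sv = _scored(panel, "BRCA2", consequence=Consequence.SPLICE_REGION, af=0.001)
    assert sv.helium_score == 50  # below the score gate on its own
    queue = build_curation_queue([sv], panel, splice_mode=SpliceMode.CARVEOUT)
    assert [q.admit_reason for q in queue] == [AdmitReason.SPLICE_CARVEOUT]
    assert build_curation_queue([sv], panel, splice_mode=SpliceMode.EXCLUDE) == []
    # common splice-region variants fail the rarity gate even under carve-out
    common = _scored(panel, "BRCA2", consequence=Consequence.SPLICE_REGION, af=0.05)
    assert build_curation_queue([common], panel) == []


def test_unknown_gene_raises_lookup_error(panel):
    sv = _scored(panel, "BRCA2", clinvar=ClinVar.PATHOGENIC)
    object.__setattr__(sv.variant, "gene_symbol", "NOTINPANEL")
    with pytest.raises(PanelLookupError):
        build_curation_queue([sv], panel)


def test_admission_monotone_in_score(panel):
    """Raising a variant's score never removes it from the queue."""
    low = _scored(panel, "BRCA2", consequence=Consequence.MISSENSE, af=0.001, n_damaging=4)
    high = _scored(panel, "BRCA2", consequence=Consequence.MISSENSE, af=0.001,
                   n_damaging=4, clinvar=ClinVar.PATHOGENIC)
    assert low.helium_score < high.helium_score
    admitted_low = {id(q.scored) for q in build_curation_queue([low], panel)}
    assert not admitted_low  # score 60 < threshold
    assert len(build_curation_queue([high], panel)) == 1


def _brute_force_admitted(scored_variants, panel):
    """Independent per-variant re-evaluation of all filtration predicates."""
    admitted = []
    for sv in scored_variants:
        e = panel.entry(sv.variant.gene_symbol)
        if e.traffic_light is not TrafficLight.GREEN:
            continue
        if sv.variant.consequence is Consequence.SPLICE_REGION:
            eligible = is_rare(sv.variant.population_af)
        else:
            eligible = sv.helium_score >= SCORE_THRESHOLD
        if not eligible:
            continue
        if e.inheritance is Inheritance.RECESSIVE:
            biallelic = sv.variant.vaf > 0.6 or sv.variant.genotype is Genotype.HOM_ALT
            has_partner = any(
                o is not sv
                and o.variant.gene_symbol == sv.variant.gene_symbol
                and o.variant.genotype is Genotype.HET
                and o.helium_score >= COMPOUND_HET_MIN_SCORE
                and sv.variant.genotype is Genotype.HET
                and sv.helium_score >= COMPOUND_HET_MIN_SCORE
                for o in scored_variants
            )
            if not (biallelic or has_partner or e.dosage_sensitive_exception):
                continue
        admitted.append(sv)
    return {id(sv) for sv in admitted}


def test_queue_matches_brute_force_on_random_patients(panel):
    """Full agreement with an independent rule-by-rule filter on random inputs."""
    rng = np.random.default_rng(42)
    genes = [e.gene_symbol for e in panel.green_entries()]
    for _ in range(50):
        scored = []
        for k in range(int(rng.integers(1, 12))):
            gene = genes[int(rng.integers(len(genes)))]
            v = make_variant(
                gene=gene,
                pos=int(rng.integers(1_000, 5_000_000)),
                consequence=list(Consequence)[int(rng.integers(len(Consequence)))],
                af=float(rng.choice([0.0, 0.001, 0.02, 0.3])),
                clinvar=list(ClinVar)[int(rng.integers(len(ClinVar)))],
                vaf=float(rng.uniform(0.2, 0.95)),
                genotype=Genotype.HET if rng.random() < 0.8 else Genotype.HOM_ALT,
                n_damaging=int(rng.integers(0, 7)),
            )
            scored.append(helium_score(v, panel.entry(gene)))
        queue = build_curation_queue(scored, panel)
        assert {id(q.scored) for q in queue} == _brute_force_admitted(scored, panel)


def test_no_common_variant_admitted_without_clinvar(panel):
    """Queue never contains a common variant unless ClinVar P/LP admitted it."""
    rng = np.random.default_rng(7)
    genes = [e.gene_symbol for e in panel.green_entries()]
    for _ in range(30):
        gene = genes[int(rng.integers(len(genes)))]
        v = make_variant(gene=gene, af=float(rng.uniform(0.01, 0.5)),
                         clinvar=ClinVar.ABSENT, n_damaging=6,
                         consequence=Consequence.FRAMESHIFT)
        sv = helium_score(v, panel.entry(gene))
        assert build_curation_queue([sv], panel) == []
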