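"""Variant-filtration rules producing the manual-curation queue.

A variant enters the curation queue iff its gene carries a green traffic
light AND its prioritization score exceeds 99, with splice-region variants
carved out (queued on rarity alone, since they cannot be confidently
scored). For autosomal recessive genes a single heterozygous hit is not
enough: the variant must look biallelic (VAF > 0.6 or called homozygous),
or be a member of a candidate compound-heterozygote pair, unless the gene
carries the dosage-sensitivity exception (MUTYH, CHEK2, Fanconi anemia
genes), in which case a single hit is queued.

Compound-het phase is unknowable from single-sample VCFs; any two
heterozygous score-eligible variants in one gene are treated as a candidate
pair (trans phase assumed).
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

from .panel import GenePanel, Inheritance, TrafficLight
from .scoring import AnnotatedVariant, Consequence, Genotype, ScoredVariant, is_rare

#: VAF strictly above this is taken as evidence of a biallelic state
BIALLELIC_VAF = 0.6

#: queue-entry score threshold ("over 99" on the 0-100 integer scale)
SCORE_THRESHOLD = 100

#: minimum surrogate score for a variant to count as compound-het eligible
COMPOUND_HET_MIN_SCORE = 50


class ZygosityClass(str, enum.Enum):
    LIKELY_BIALLELIC = "likely_biallelic"
    HETEROZYGOUS = "heterozygous"


class AdmitReason(str, enum.Enum):
    GREEN_HIGH_SCORE = "green_high_score"
    SPLICE_CARVEOUT = "splice_carveout"
    RECESSIVE_BIALLELIC = "recessive_biallelic"
    RECESSIVE_COMPOUND_HET = "recessive_compound_het"
    SINGLE_HIT_EXCEPTION = "single_hit_exception"


class SpliceMode(str, enum.Enum):
    """How '(excluding splice variants)' is read.

    CARVEOUT: splice-region variants are exempt from the score threshold and
    enter the queue on rarity alone (default). EXCLUDE: splice-region
    variants are excluded from curation entirely.
    """

    CARVEOUT = "carveout"
    EXCLUDE = "exclude"


@dataclass(frozen=True)
class CurationQueueItem:
    scored: ScoredVariant
    admit_reason: AdmitReason
    partner_variant: Optional[AnnotatedVariant] = None

    def __post_init__(self) -> None:
        has_partner = self.partner_variant is not None
        if has_partner != (self.admit_reason is AdmitReason.RECESSIVE_COMPOUND_HET):
            raise ValueError(
                "partner_variant must be set iff admit_reason is recessive_compound_het"
            )


def zygosity_class(variant: AnnotatedVariant) -> ZygosityClass:
    """Biallelic if VAF > 0.6 (strict) or the called genotype is hom-alt."""
    if variant.vaf > BIALLELIC_VAF or variant.genotype is Genotype.HOM_ALT:
        return ZygosityClass.LIKELY_BIALLELIC
    return ZygosityClass.HETEROZYGOUS


def find_compound_hets(
    variants: Sequence[ScoredVariant], gene: str
) -> list[tuple[ScoredVariant, ScoredVariant]]:
    """All unordered pairs of distinct heterozygous eligible variants in ``gene``.

    Eligibility means a surrogate score >= 50. Pairs are returned in
    deterministic position-sorted order.
    """
    eligible = sorted(
        (
            sv
            for sv in variants
            if sv.variant.gene_symbol == gene
            and sv.variant.genotype is Genotype.HET
            and sv.helium_score >= COMPOUND_HET_MIN_SCORE
        ),
        key=lambda sv: (sv.variant.chrom, sv.variant.pos, sv.variant.ref, sv.variant.alt),
    )
    return list(itertools.combinations(eligible, 2))


def _score_eligible(sv: ScoredVariant, splice_mode: SpliceMode) -> Optional[AdmitReason]:
    """Base admission reason from traffic light + score, before zygosity logic."""
    v = sv.variant
    if v.consequence is Consequence.SPLICE_REGION:
        if splice_mode is SpliceMode.EXCLUDE:
            return None
        return AdmitReason.SPLICE_CARVEOUT if is_rare(v.population_af) else None
    if sv.helium_score >= SCORE_THRESHOLD:
        return AdmitReason.GREEN_HIGH_SCORE
    return None


def build_curation_queue(
    patient_variants: Sequence[ScoredVariant],
    panel: GenePanel,
    splice_mode: SpliceMode = SpliceMode.CARVEOUT,
) -> list[CurationQueueItem]:
    """Apply the full filtration rule set to one patient's scored variants.

    Every variant's gene must be present in the panel (lookup error
    otherwise). Output order is deterministic (chrom, pos, ref, alt).
    """
    # candidate compound-het partners per recessive gene
    partners: dict[int, AnnotatedVariant] = {}
    recessive_genes = {
        sv.variant.gene_symbol
        for sv in patient_variants
        if panel.entry(sv.variant.gene_symbol).inheritance is Inheritance.RECESSIVE
    }
    for gene in recessive_genes:
        for a, b in find_compound_hets(patient_variants, gene):
            partners.setdefault(id(a), b.variant)
            partners.setdefault(id(b), a.variant)

    items: list[CurationQueueItem] = []
    for sv in sorted(
        patient_variants,
        key=lambda s: (s.variant.chrom, s.variant.pos, s.variant.ref, s.variant.alt),
    ):
        entry = panel.entry(sv.variant.gene_symbol)
        if entry.traffic_light is not TrafficLight.GREEN:
            continue
        base = _score_eligible(sv, splice_mode)
        if base is None:
            continue
        if entry.inheritance is Inheritance.RECESSIVE:
            if zygosity_class(sv.variant) is ZygosityClass.LIKELY_BIALLELIC:
                items.append(CurationQueueItem(sv, AdmitReason.RECESSIVE_BIALLELIC))
            elif id(sv) in partners:
                items.append(
                    CurationQueueItem(
                        sv, AdmitReason.RECESSIVE_COMPOUND_HET, partner_variant=partners[id(sv)]
                    )
                )
            elif entry.dosage_sensitive_exception:
                items.append(CurationQueueItem(sv, AdmitReason.SINGLE_HIT_EXCEPTION))
            # single het in a non-excepted recessive gene: not curated
        else:
            # dominant, X-linked and unknown inheritance follow dominant logic
            items.append(CurationQueueItem(sv, base))
    return items
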