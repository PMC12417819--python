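"""Five-tier classification scaffold and the reporting decision.

Manual ACMG/AMP curation cannot be automated; this module implements the
deterministic scaffold that the stated evidence forces:

* ClinVar pathogenic (non-conflicting)            -> pathogenic
* ClinVar likely-pathogenic, or a novel rare LOF
  variant in a tumor-suppressor gene (PVS1+PM2)   -> likely_pathogenic
* rare missense with in-silico consensus, or a
  rare splice-region variant                      -> vus
* anything else                                   -> likely_benign

Cases needing human judgment therefore surface as VUS. A variant is
*reportable* iff it is P/LP, or a VUS with functional score >= 3 and
clinical score >= 1. The functional score (0-5 surrogate) adds +2 for
in-silico consensus, +2 for a loss-of-function consequence and +1 for
rarity; the clinical score is 1 when a phenotype-match flag is supplied in
patient metadata, else 0.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

from .filtration import CurationQueueItem
from .scoring import ClinVar, Consequence, is_rare


class Tier(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    VUS = "vus"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"


#: minimum functional / clinical grading for a reportable VUS
VUS_FUNCTIONAL_MIN = 3.0
VUS_CLINICAL_MIN = 1.0


def is_reportable(tier: Tier, functional_score: float, clinical_score: float) -> bool:
    return tier in (Tier.PATHOGENIC, Tier.LIKELY_PATHOGENIC) or (
        tier is Tier.VUS
        and functional_score >= VUS_FUNCTIONAL_MIN
        and clinical_score >= VUS_CLINICAL_MIN
    )


@dataclass(frozen=True)
class ClassifiedVariant:
    item: CurationQueueItem
    tier: Tier
    functional_score: float
    clinical_score: float
    reportable: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.functional_score <= 5.0:
            raise ValueError(f"functional_score out of [0,5]: {self.functional_score}")
        if self.clinical_score < 0:
            raise ValueError(f"clinical_score must be >= 0: {self.clinical_score}")
        if self.reportable != is_reportable(
            self.tier, self.functional_score, self.clinical_score
        ):
            raise ValueError("reportable flag violates the reporting invariant")

    @property
    def gene_symbol(self) -> str:
        return self.item.scored.variant.gene_symbol


def classify(item: CurationQueueItem, phenotype_match: bool = False) -> ClassifiedVariant:
    """Assign the tier, grading scores and reporting decision for one queued variant."""
    sv = item.scored
    v = sv.variant
    rare = is_rare(v.population_af)

    if v.clinvar is ClinVar.PATHOGENIC:
        tier = Tier.PATHOGENIC
    elif v.clinvar is ClinVar.LIKELY_PATHOGENIC or (
        rare and v.is_lof and v.clinvar is ClinVar.ABSENT and "rare_novel_lof_tsg" in sv.score_rationale
    ):
        tier = Tier.LIKELY_PATHOGENIC
    elif rare and (
        (v.consequence is Consequence.MISSENSE and sv.consensus_deleterious)
        or v.consequence is Consequence.SPLICE_REGION
    ):
        tier = Tier.VUS
    else:
        tier = Tier.LIKELY_BENIGN

    functional = min(
        5.0,
        (2.0 if sv.consensus_deleterious else 0.0)
        + (2.0 if v.is_lof else 0.0)
        + (1.0 if rare else 0.0),
    )
    clinical = 1.0 if phenotype_match else 0.0
    return ClassifiedVariant(
        item=item,
        tier=tier,
        functional_score=functional,
        clinical_score=clinical,
        reportable=is_reportable(tier, functional, clinical),
    )


def reportable_set(patient: Sequence[ClassifiedVariant]) -> list[ClassifiedVariant]:
    """Reportable subset in deterministic (chrom, pos, ref, alt) order."""
    return sorted(
        (cv for cv in patient if cv.reportable),
        key=lambda cv: (
            cv.item.scored.variant.chrom,
            cv.item.scored.variant.pos,
            cv.item.scored.variant.ref,
            cv.item.scored.variant.alt,
        ),
    )
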