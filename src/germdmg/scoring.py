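"""Deterministic germline variant prioritization score and predictor consensus.

The prioritization score is an integer on a 0-100 scale whose top tier
(score 100, i.e. "over 99") encodes the curation-triggering criteria: the
variant is rare in population controls (<1% max allele frequency) AND is
either annotated pathogenic/likely-pathogenic in ClinVar or is a novel
loss-of-function variant in a tumor-suppressor gene. Intermediate tiers (60
for rare missense with in-silico consensus support, 50 for rare
non-canonical splice-region variants) exist so that compound-heterozygote
candidates and splice variants can be queued; they are surrogate values, not
calibrated probabilities.

Missense support uses a consensus of six categorical in-silico predictors
(PolyPhen, SIFT, PROVEAN, FATHMM, MetaSVM, MetaLR): at least 4 of 6 must
call the variant damaging, with a missing verdict counting as not damaging.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping

from .panel import GenePanelEntry

PREDICTORS = ("polyphen", "sift", "provean", "fathmm", "metasvm", "metalr")

#: minimum number of damaging verdicts for missense consensus
CONSENSUS_MIN_DAMAGING = 4

#: population-control allele-frequency threshold for "rare" (strict <)
RARITY_THRESHOLD = 0.01


class DomainError(ValueError):
    """Raised when a value is outside its documented domain."""


class ContractError(ValueError):
    """Raised when an operation's precondition is violated."""


class Verdict(str, enum.Enum):
    DAMAGING = "damaging"
    TOLERATED = "tolerated"
    MISSING = "missing"


class Consequence(str, enum.Enum):
    STOP_GAINED = "stop_gained"
    FRAMESHIFT = "frameshift"
    CANONICAL_SPLICE = "canonical_splice"
    SPLICE_REGION = "splice_region"
    START_LOST = "start_lost"
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


#: loss-of-function consequences (canonical_splice = the ±1/2 dinucleotides)
LOF_CONSEQUENCES = frozenset(
    {
        Consequence.STOP_GAINED,
        Consequence.FRAMESHIFT,
        Consequence.CANONICAL_SPLICE,
        Consequence.START_LOST,
    }
)


class ClinVar(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    VUS = "vus"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"
    CONFLICTING = "conflicting"  # treated as not-P/LP
    ABSENT = "absent"


class Genotype(str, enum.Enum):
    HET = "het"
    HOM_ALT = "hom_alt"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class PredictorPanel:
    """Verdicts from the six in-silico predictors; absent slots are missing."""

    verdicts: Mapping[str, Verdict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        full = {name: Verdict.MISSING for name in PREDICTORS}
        for name, v in dict(self.verdicts).items():
            if name not in full:
                raise DomainError(f"unknown predictor: {name}")
            full[name] = Verdict(v)
        object.__setattr__(self, "verdicts", full)

    def n_damaging(self) -> int:
        return sum(1 for v in self.verdicts.values() if v is Verdict.DAMAGING)

    @classmethod
    def all_damaging(cls) -> "PredictorPanel":
        return cls({name: Verdict.DAMAGING for name in PREDICTORS})

    @classmethod
    def all_missing(cls) -> "PredictorPanel":
        return cls()


def insilico_consensus(panel: PredictorPanel) -> bool:
    """True iff at least 4 of the 6 predictors call the variant damaging."""
    return panel.n_damaging() >= CONSENSUS_MIN_DAMAGING


def is_rare(af: float, threshold: float = RARITY_THRESHOLD) -> bool:
    """True iff the population allele frequency is strictly below ``threshold``."""
    if not 0.0 <= af <= 1.0:
        raise DomainError(f"allele frequency out of [0,1]: {af}")
    return af < threshold


@dataclass(frozen=True)
class AnnotatedVariant:
    """One annotated germline variant call (VCF 1-based coordinates).

    ``population_af`` is the maximum allele frequency over annotated control
    populations; variants absent from controls carry 0.0.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene_symbol: str
    consequence: Consequence
    population_af: float
    clinvar: ClinVar
    vaf: float
    genotype: Genotype
    predictor_panel: PredictorPanel = field(default_factory=PredictorPanel)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise DomainError(f"pos must be >= 1, got {self.pos}")
        if not 0.0 <= self.population_af <= 1.0:
            raise DomainError(f"population_af out of [0,1]: {self.population_af}")
        if not 0.0 <= self.vaf <= 1.0:
            raise DomainError(f"vaf out of [0,1]: {self.vaf}")
        if self.ref == self.alt:
            raise DomainError("ref and alt alleles must differ")

    @property
    def is_lof(self) -> bool:
        return self.consequence in LOF_CONSEQUENCES


@dataclass(frozen=True)
class ScoredVariant:
    """A variant with its prioritization score and the rules that fired."""

    variant: AnnotatedVariant
    helium_score: int
    consensus_deleterious: bool
    score_rationale: tuple[str, ...]

    def __post_init__(self) -> None:
        if not 0 <= self.helium_score <= 100:
            raise DomainError(f"score out of [0,100]: {self.helium_score}")
        if self.helium_score > 0 and not self.score_rationale:
            raise DomainError("positive score requires a non-empty rationale")


# Scoring rubric, evaluated in fixed order; the score is the max tier among
# fired rules and the rationale lists every fired rule in this order.
_RULE_CLINVAR_PLP = "rare_clinvar_plp"
_RULE_NOVEL_LOF_TSG = "rare_novel_lof_tsg"
_RULE_MISSENSE_CONSENSUS = "rare_missense_consensus"
_RULE_SPLICE_REGION = "rare_splice_region"

RUBRIC_TIERS: dict[str, int] = {
    _RULE_CLINVAR_PLP: 100,
    _RULE_NOVEL_LOF_TSG: 100,
    _RULE_MISSENSE_CONSENSUS: 60,
    _RULE_SPLICE_REGION: 50,
}


def helium_score(variant: AnnotatedVariant, panel_entry: GenePanelEntry) -> ScoredVariant:
    """Score one variant against its panel entry.

    Deterministic: identical inputs give an identical :class:`ScoredVariant`
    including rationale order. The gene of the variant must match the panel
    entry.
    """
    if variant.gene_symbol != panel_entry.gene_symbol:
        raise ContractError(
            f"gene mismatch: variant {variant.gene_symbol!r} vs panel entry "
            f"{panel_entry.gene_symbol!r}"
        )

    rare = is_rare(variant.population_af)
    consensus = insilico_consensus(variant.predictor_panel)
    clinvar_plp = variant.clinvar in (ClinVar.PATHOGENIC, ClinVar.LIKELY_PATHOGENIC)

    fired: list[str] = []
    if rare and clinvar_plp:
        fired.append(_RULE_CLINVAR_PLP)
    if (
        rare
        and variant.is_lof
        and panel_entry.is_tumor_suppressor
        and variant.clinvar is ClinVar.ABSENT
    ):
        fired.append(_RULE_NOVEL_LOF_TSG)
    if rare and variant.consequence is Consequence.MISSENSE and consensus:
        fired.append(_RULE_MISSENSE_CONSENSUS)
    if rare and variant.consequence is Consequence.SPLICE_REGION:
        fired.append(_RULE_SPLICE_REGION)

    score = max((RUBRIC_TIERS[r] for r in fired), default=0)
    return ScoredVariant(
        variant=variant,
        helium_score=score,
        consensus_deleterious=consensus,
        score_rationale=tuple(fired),
    )
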