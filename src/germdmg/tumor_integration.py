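"""Tumor-germline integration: second hits and somatic driver pathways.

A germline variant "definitively contributes" to tumorigenesis when the
tumor shows a second hit at the same locus/gene: copy-neutral LOH (minor
allele copy number < 0.5 with total copy number retained), one-copy loss,
a somatic P/LP variant in the same gene, or loss of RNA expression (tumor
TPM below 0.3x the cohort median, anchored to a worked case with ratio
1.76/6.3 ~ 0.279).

Somatic drivers are grouped into pathways with a bundled gene->pathway map
covering the recurrently altered drivers of diffuse midline glioma (ATRX,
PPM1D, BRAF, NF1, PTPN11, ACVR1, TP53, PI3K-AKT-mTOR members, ...).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from statistics import median
from typing import Iterable, Optional, Sequence

from .classification import ClassifiedVariant
from .scoring import DomainError


class DataError(ValueError):
    """Raised for inconsistent input data (e.g. overlapping CN segments)."""


#: minor allele copy number below this counts as LOH
LOH_MINOR_CN = 0.5

#: total copy number at/above this distinguishes copy-neutral LOH from loss
CN_NEUTRAL_TOTAL = 1.5

#: tumor TPM below this fraction of the cohort median counts as expression loss
EXPRESSION_LOSS_RATIO = 0.3


def _norm_chrom(chrom: str) -> str:
    c = chrom.lower()
    return c[3:] if c.startswith("chr") else c


@dataclass(frozen=True)
class CNSegment:
    """Allele-specific copy-number segment, 1-based inclusive coordinates."""

    chrom: str
    start: int
    end: int
    total_cn: float
    minor_cn: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise DataError(f"segment start > end: {self.chrom}:{self.start}-{self.end}")
        if self.total_cn < 0 or self.minor_cn < 0:
            raise DataError("copy numbers must be non-negative")
        if self.minor_cn > self.total_cn / 2 + 1e-6:
            raise DataError(
                f"minor_cn {self.minor_cn} exceeds total_cn/2 for {self.chrom}:{self.start}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def covers(self, chrom: str, pos: int) -> bool:
        return _norm_chrom(self.chrom) == _norm_chrom(chrom) and self.start <= pos <= self.end


class Mechanism(str, enum.Enum):
    CN_LOH = "cn_loh"
    COPY_LOSS = "copy_loss"
    SOMATIC_SNV_SAME_GENE = "somatic_snv_same_gene"
    EXPRESSION_LOSS = "expression_loss"
    NONE = "none"


@dataclass(frozen=True)
class SecondHitEvidence:
    patient_id: str
    gene: str
    mechanism: Mechanism
    supporting_value: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mechanism is Mechanism.NONE and self.supporting_value is not None:
            raise DataError("mechanism=none must not carry a supporting value")


class SomaticPathway(str, enum.Enum):
    """Pathway grouping for somatic drivers (distinct from the germline panel)."""

    DNA_DAMAGE = "DNA_damage"
    MAPK_ERK = "MAPK_ERK"
    RTK = "RTK"
    PI3K_AKT_MTOR = "PI3K_AKT_mTOR"
    BMP = "BMP"
    TP53 = "TP53"
    EPIGENETICS = "epigenetics"
    OTHER = "other"


DEFAULT_SOMATIC_PATHWAY_MAP: dict[str, SomaticPathway] = {
    "ATRX": SomaticPathway.DNA_DAMAGE,
    "PPM1D": SomaticPathway.DNA_DAMAGE,
    "ATM": SomaticPathway.DNA_DAMAGE,
    "POLE": SomaticPathway.DNA_DAMAGE,
    "BRAF": SomaticPathway.MAPK_ERK,
    "NF1": SomaticPathway.MAPK_ERK,
    "PTPN11": SomaticPathway.MAPK_ERK,
    "MAPK12": SomaticPathway.MAPK_ERK,
    "ACVR1": SomaticPathway.BMP,
    "PIK3CA": SomaticPathway.PI3K_AKT_MTOR,
    "PIK3R1": SomaticPathway.PI3K_AKT_MTOR,
    "AKT1": SomaticPathway.PI3K_AKT_MTOR,
    "AKT2": SomaticPathway.PI3K_AKT_MTOR,
    "AKT3": SomaticPathway.PI3K_AKT_MTOR,
    "MTOR": SomaticPathway.PI3K_AKT_MTOR,
    "PTEN": SomaticPathway.PI3K_AKT_MTOR,
    "TSC1": SomaticPathway.PI3K_AKT_MTOR,
    "TSC2": SomaticPathway.PI3K_AKT_MTOR,
    "TP53": SomaticPathway.TP53,
    "FGFR1": SomaticPathway.RTK,
    "PDGFRA": SomaticPathway.RTK,
    "EGFR": SomaticPathway.RTK,
}


@dataclass
class SomaticDriverProfile:
    patient_id: str
    pathway_hits: dict[SomaticPathway, int]

    def count(self, pathway: SomaticPathway) -> int:
        return self.pathway_hits.get(pathway, 0)

    @property
    def total(self) -> int:
        return sum(self.pathway_hits.values())


def detect_cn_loh(
    chrom: str,
    pos: int,
    segments: Sequence[CNSegment],
    patient_id: str = "",
    gene: str = "",
) -> SecondHitEvidence:
    """Classify the allele-specific copy-number state over one locus.

    cn_loh when the covering segment has minor CN < 0.5 with total CN >= 1.5;
    copy_loss when minor CN < 0.5 with total CN < 1.5; none when no segment
    covers the locus or the minor allele is retained.
    """
    covering = [s for s in segments if s.covers(chrom, pos)]
    if len(covering) > 1:
        raise DataError(f"{len(covering)} segments overlap locus {chrom}:{pos}")
    if not covering:
        return SecondHitEvidence(patient_id, gene, Mechanism.NONE)
    seg = covering[0]
    if seg.minor_cn >= LOH_MINOR_CN:
        return SecondHitEvidence(patient_id, gene, Mechanism.NONE)
    mech = Mechanism.CN_LOH if seg.total_cn >= CN_NEUTRAL_TOTAL else Mechanism.COPY_LOSS
    return SecondHitEvidence(patient_id, gene, mech, supporting_value=seg.minor_cn)


def expression_loss(
    gene: str,
    patient_tpm: float,
    cohort_tpms: Sequence[float],
    cutoff: float = EXPRESSION_LOSS_RATIO,
    patient_id: str = "",
) -> SecondHitEvidence:
    """Flag loss of expression when tumor TPM < ``cutoff`` x cohort median."""
    if patient_tpm < 0 or any(t < 0 for t in cohort_tpms):
        raise DomainError("TPM values must be non-negative")
    if not cohort_tpms:
        raise DomainError("cohort TPM collection must be non-empty")
    med = median(cohort_tpms)
    ratio = patient_tpm / med if med > 0 else float("inf")
    if med > 0 and ratio < cutoff:
        return SecondHitEvidence(patient_id, gene, Mechanism.EXPRESSION_LOSS, supporting_value=ratio)
    return SecondHitEvidence(patient_id, gene, Mechanism.NONE)


def assign_somatic_pathways(
    patient_id: str,
    somatic_genes: Iterable[str],
    pathway_map: Optional[dict[str, SomaticPathway]] = None,
) -> SomaticDriverProfile:
    """Count somatic P/LP drivers per pathway; unknown genes go to 'other'."""
    pmap = DEFAULT_SOMATIC_PATHWAY_MAP if pathway_map is None else pathway_map
    hits: dict[SomaticPathway, int] = {p: 0 for p in SomaticPathway}
    for gene in somatic_genes:
        pw = pmap.get(gene)
        if pw is None:
            warnings.warn(f"somatic gene {gene} not in pathway map; counted as 'other'")
            pw = SomaticPathway.OTHER
        hits[pw] += 1
    return SomaticDriverProfile(patient_id, {p: c for p, c in hits.items() if c > 0})


def definitive_contribution(
    reportable_germline: Sequence[ClassifiedVariant],
    second_hits: Sequence[SecondHitEvidence],
) -> bool:
    """True iff any reportable germline gene carries second-hit evidence."""
    genes = {cv.gene_symbol for cv in reportable_germline}
    return any(
        ev.gene in genes and ev.mechanism is not Mechanism.NONE for ev in second_hits
    )
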