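"""Cohort-level aggregation: prevalence, pathway counts, 2x2 associations.

Carrier prevalence is the percentage of patients with at least one
reportable germline variant, printed to one decimal (half-away-from-zero,
matching clinical reporting style: 19/252 -> 7.5%). Reportable variants are
tallied per panel pathway. Binary genotype-phenotype associations use
Fisher's exact test (two-sided, summing hypergeometric probabilities no
larger than the observed table's) or the 1-df Pearson chi-squared test; the
default 'auto' rule picks Fisher whenever any expected cell is below 5.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import TYPE_CHECKING, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .classification import ClassifiedVariant
from .genome_loh import LOHProfile
from .panel import GenePanel, Pathway
from .tumor_integration import SecondHitEvidence, SomaticDriverProfile

if TYPE_CHECKING:  # avoid a circular import; signatures uses fisher_exact_2x2
    from .signatures import SignatureExposure

#: relative tolerance for hypergeometric probability ties (R/scipy convention)
FISHER_TIE_RTOL = 1e-7

#: expected-cell threshold below which 'auto' picks Fisher over chi-squared
CHISQ_MIN_EXPECTED = 5.0


class DiagnosisGroup(str, enum.Enum):
    DIPG = "DIPG"
    DMG_OTHER = "DMG_other"


class H3Status(str, enum.Enum):
    H3_3 = "H3_3"
    H3_1 = "H3_1"
    ALTERED_OTHER = "altered_other"
    WILDTYPE = "wildtype"
    UNKNOWN = "unknown"


class Location(str, enum.Enum):
    PONS = "pons"
    THALAMUS = "thalamus"
    SPINE = "spine"
    OTHER = "other"
    UNKNOWN = "unknown"


@dataclass
class PatientRecord:
    """Per-patient bundle of germline, somatic, segment and signature results."""

    patient_id: str
    diagnosis_group: DiagnosisGroup = DiagnosisGroup.DIPG
    h3_status: H3Status = H3Status.UNKNOWN
    location: Location = Location.UNKNOWN
    reportable_germline: list[ClassifiedVariant] = field(default_factory=list)
    somatic_profile: Optional[SomaticDriverProfile] = None
    loh: Optional[LOHProfile] = None
    exposure: Optional["SignatureExposure"] = None
    second_hits: list[SecondHitEvidence] = field(default_factory=list)

    @property
    def is_carrier(self) -> bool:
        return len(self.reportable_germline) > 0


@dataclass
class AssociationResult:
    name: str
    table: np.ndarray
    method: str
    p_value: float
    adjusted_p: Optional[float] = None


@dataclass
class CohortSummary:
    n_patients: int
    n_carriers: int
    prevalence_pct: float
    pathway_variant_counts: dict[Pathway, int] = field(default_factory=dict)
    association_results: list[AssociationResult] = field(default_factory=list)


def format_pct(numerator: int, denominator: int) -> float:
    """Percentage to one decimal, rounding half away from zero (19/252 -> 7.5)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def prevalence(cohort: Sequence[PatientRecord]) -> CohortSummary:
    """Carrier count and prevalence percentage for a cohort."""
    if len(cohort) == 0:
        raise ValueError("cohort must contain at least one patient")
    ids = [p.patient_id for p in cohort]
    if len(set(ids)) != len(ids):
        raise ValueError("patient_id must be unique within the cohort")
    n_carriers = sum(1 for p in cohort if p.is_carrier)
    return CohortSummary(
        n_patients=len(cohort),
        n_carriers=n_carriers,
        prevalence_pct=format_pct(n_carriers, len(cohort)),
    )


def pathway_variant_counts(
    variants: Sequence[ClassifiedVariant], panel: GenePanel
) -> dict[Pathway, int]:
    """Count each reportable variant once under its gene's panel pathway."""
    counts: dict[Pathway, int] = {p: 0 for p in Pathway}
    for cv in variants:
        counts[panel.entry(cv.gene_symbol).pathway] += 1
    return counts


def _as_table(table) -> np.ndarray:
    arr = np.asarray(table, dtype=np.int64)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    if np.any(arr < 0):
        raise ValueError("table cells must be non-negative")
    return arr


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value by hypergeometric enumeration.

    Sums, over all tables with the observed margins, the probabilities that
    do not exceed the observed table's probability (relative tie tolerance
    1e-7, the convention R and scipy use). A zero margin returns p = 1 with
    a warning.
    """
    arr = _as_table(table)
    a, b = int(arr[0, 0]), int(arr[0, 1])
    c, d = int(arr[1, 0]), int(arr[1, 1])
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if n == 0 or r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        warnings.warn("degenerate 2x2 margin; Fisher p set to 1")
        return 1.0
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[support == a][0]
    p = float(pmf[pmf <= p_obs * (1.0 + FISHER_TIE_RTOL)].sum())
    return min(p, 1.0)


def chisq_2x2(table) -> float:
    """1-df Pearson chi-squared p-value (no continuity correction)."""
    arr = _as_table(table)
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        warnings.warn("degenerate 2x2 margin; chi-squared p set to 1")
        return 1.0
    _, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return float(p)


def association_2x2(table, method: str = "auto") -> float:
    """Two-sided association p-value for a 2x2 table.

    method='fisher' or 'chisq' force the test; 'auto' picks Fisher whenever
    any expected cell is below 5, matching standard practice.
    """
    arr = _as_table(table)
    if method == "fisher":
        return fisher_exact_2x2(arr)
    if method == "chisq":
        return chisq_2x2(arr)
    if method != "auto":
        raise ValueError(f"unknown method: {method}")
    n = arr.sum()
    if n == 0:
        warnings.warn("empty 2x2 table; p set to 1")
        return 1.0
    expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / n
    if np.any(expected < CHISQ_MIN_EXPECTED):
        return fisher_exact_2x2(arr)
    return chisq_2x2(arr)


def carrier_association(
    cohort: Sequence[PatientRecord],
    feature: Mapping[str, bool],
    name: str = "carrier_vs_feature",
    method: str = "auto",
) -> AssociationResult:
    """2x2 association between carrier status and a binary patient feature.

    Only patients present in ``feature`` enter the table, so comparisons with
    partial data availability use their own explicit denominators.
    """
    table = np.zeros((2, 2), dtype=int)
    for p in cohort:
        if p.patient_id not in feature:
            continue
        i = 0 if p.is_carrier else 1
        j = 0 if feature[p.patient_id] else 1
        table[i, j] += 1
    used = method
    if method == "auto":
        n = table.sum()
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n if n else np.zeros((2, 2))
        used = "fisher" if n == 0 or np.any(expected < CHISQ_MIN_EXPECTED) else "chisq"
    return AssociationResult(
        name=name, table=table, method=used, p_value=association_2x2(table, method)
    )
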