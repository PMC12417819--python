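"""Genome-wide loss-of-heterozygosity fraction and rank-sum associations.

Genome-wide LOH is the proportion of the autosomal genome (fixed denominator
2 881 033 286 bp, the GRCh37 autosome total) covered by allele-specific
copy-number segments whose minor allele copy number falls below 0.5.
Group comparisons (e.g. somatic TP53-mutant vs wild type, germline HR-mutant
vs intact) use a one-tailed Wilcoxon rank-sum test — exact for combined
n <= 20 without ties, normal approximation with tie correction otherwise —
with Holm correction across the declared family of tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tumor_integration import CNSegment, DataError, _norm_chrom

#: fixed autosomal genome size used as the LOH denominator (bp)
GENOME_SIZE = 2_881_033_286

#: GRCh37 autosome lengths; they sum exactly to GENOME_SIZE
AUTOSOME_LENGTHS: dict[str, int] = {
    "1": 249_250_621,
    "2": 243_199_373,
    "3": 198_022_430,
    "4": 191_154_276,
    "5": 180_915_260,
    "6": 171_115_067,
    "7": 159_138_663,
    "8": 146_364_022,
    "9": 141_213_431,
    "10": 135_534_747,
    "11": 135_006_516,
    "12": 133_851_895,
    "13": 115_169_878,
    "14": 107_349_540,
    "15": 102_531_392,
    "16": 90_354_753,
    "17": 81_195_210,
    "18": 78_077_248,
    "19": 59_128_983,
    "20": 63_025_520,
    "21": 48_129_895,
    "22": 51_304_566,
}
assert sum(AUTOSOME_LENGTHS.values()) == GENOME_SIZE

X_LENGTH = 155_270_560

#: LOH calling threshold on the minor allele copy number
LOH_MINOR_CN = 0.5

AUTOSOMES = frozenset(str(i) for i in range(1, 23))
_KNOWN_NON_AUTOSOMES = frozenset({"x", "y", "mt", "m"})

#: largest combined sample size for which the exact rank-sum null is used
EXACT_RANKSUM_MAX_N = 20


@dataclass(frozen=True)
class LOHProfile:
    patient_id: str
    loh_bases: int
    genome_size: int = GENOME_SIZE

    def __post_init__(self) -> None:
        if not 0 <= self.loh_bases <= self.genome_size:
            raise DataError(f"loh_bases out of range: {self.loh_bases}")

    @property
    def loh_fraction(self) -> float:
        return self.loh_bases / self.genome_size


def _check_overlaps(segments: Sequence[CNSegment]) -> None:
    by_chrom: dict[str, list[CNSegment]] = {}
    for s in segments:
        by_chrom.setdefault(_norm_chrom(s.chrom), []).append(s)
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end:
                raise DataError(
                    f"overlapping segments on {chrom}: "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )


def genome_loh_fraction(
    segments: Sequence[CNSegment], patient_id: str = ""
) -> LOHProfile:
    """Sum autosomal LOH segment lengths against the fixed genome size.

    Segment coordinates are 1-based inclusive (length = end - start + 1).
    Non-autosomal segments are ignored; unrecognized chromosome labels are
    ignored with a warning; overlapping segments raise :class:`DataError`.
    """
    autosomal: list[CNSegment] = []
    for s in segments:
        c = _norm_chrom(s.chrom)
        if c in AUTOSOMES:
            autosomal.append(s)
        elif c not in _KNOWN_NON_AUTOSOMES:
            warnings.warn(f"unknown chromosome label {s.chrom!r}; segment ignored")
    _check_overlaps(autosomal)
    loh_bases = sum(s.length for s in autosomal if s.minor_cn < LOH_MINOR_CN)
    return LOHProfile(patient_id=patient_id, loh_bases=loh_bases)


def rank_sum_one_tailed(
    group: Sequence[float], other: Sequence[float], alternative: str = "greater"
) -> float:
    """One-tailed Wilcoxon rank-sum p-value of ``group`` against ``other``.

    Exact null distribution for combined n <= 20 without ties; normal
    approximation with mid-ranks and tie-corrected variance otherwise. All
    observations identical returns p = 1 with a warning.
    """
    if alternative not in ("greater", "less"):
        raise ValueError(f"alternative must be 'greater' or 'less', got {alternative}")
    x = np.asarray(group, dtype=float)
    y = np.asarray(other, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all observations identical; rank-sum p set to 1")
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(pooled) <= EXACT_RANKSUM_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.pvalue)


def holm_adjust(pvalues: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values for one declared family of tests."""
    if len(pvalues) == 0:
        return []
    _, adjusted, _, _ = multipletests(pvalues, method="holm")
    return [float(p) for p in adjusted]


def loh_association(
    fractions: Sequence[float],
    labels: Sequence[bool],
    alternative: str = "greater",
) -> float:
    """Rank-sum p-value comparing LOH fractions of label-true vs label-false patients.

    ``alternative='greater'`` tests whether the label-true group tends to
    have higher genome-wide LOH. Holm adjustment across a family of such
    tests is applied separately via :func:`holm_adjust`.
    """
    if len(fractions) != len(labels):
        raise ValueError("fractions and labels must align")
    lab = np.asarray(labels, dtype=bool)
    vals = np.asarray(fractions, dtype=float)
    return rank_sum_one_tailed(vals[lab], vals[~lab], alternative=alternative)
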