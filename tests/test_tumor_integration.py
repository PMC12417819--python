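import numpy as np
import pytest

from germdmg import (
    ClinVar,
    CNSegment,
    DataError,
    Mechanism,
    SomaticPathway,
    assign_somatic_pathways,
    definitive_contribution,
    detect_cn_loh,
    expression_loss,
)
from germdmg.scoring import DomainError

from conftest import make_classified


def test_cn_loh_vs_copy_loss_vs_none():
    seg_cnloh = CNSegment("3", 1_000, 2_000, total_cn=2.0, minor_cn=0.0)
    seg_loss = CNSegment("3", 5_000, 6_000, total_cn=1.0, minor_cn=0.0)
    seg_het = CNSegment("3", 9_000, 10_000, total_cn=2.0, minor_cn=1.0)
    segs = [seg_cnloh, seg_loss, seg_het]
    assert detect_cn_loh("3", 1_500, segs).mechanism is Mechanism.CN_LOH
    assert detect_cn_loh("3", 5_500, segs).mechanism is Mechanism.COPY_LOSS
    assert detect_cn_loh("3", 9_500, segs).mechanism is Mechanism.NONE
    assert detect_cn_loh("3", 100_000, segs).mechanism is Mechanism.NONE  # uncovered
    assert detect_cn_loh("chr3", 1_500, segs).mechanism is Mechanism.CN_LOH  # prefix-insensitive


def test_overlapping_segments_at_locus_raise():
    segs = [
        CNSegment("1", 100, 200, 2.0, 0.0),
        CNSegment("1", 150, 250, 2.0, 1.0),
    ]
    with pytest.raises(DataError):
        detect_cn_loh("1", 160, segs)


def test_cn_loh_matches_per_base_scan_on_random_genomes():
    """Oracle equivalence: classify loci by brute-force per-base segment scan."""
    rng = np.random.default_rng(5)
    for _ in range(20):
        # random non-overlapping segments on a 10 kb toy chromosome
        cuts = np.sort(rng.choice(np.arange(2, 10_000), size=8, replace=False))
        bounds = [1, *cuts.tolist(), 10_000]
        segs = []
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            if rng.random() < 0.3:
                continue  # leave a gap
            minor = float(rng.choice([0.0, 0.3, 1.0]))
            total = float(rng.choice([1.0, 2.0, 3.0]))
            segs.append(CNSegment("7", lo, hi - 1, max(total, 2 * minor), minor))
        base_map = {}
        for s in segs:
            for b in range(s.start, s.end + 1):
                base_map[b] = s
        for pos in rng.integers(1, 10_000, size=40):
            got = detect_cn_loh("7", int(pos), segs).mechanism
            s = base_map.get(int(pos))
            if s is None or s.minor_cn >= 0.5:
                expected = Mechanism.NONE
            elif s.total_cn >= 1.5:
                expected = Mechanism.CN_LOH
            else:
                expected = Mechanism.COPY_LOSS
            assert got is expected


def test_expression_loss_worked_example():
    """Tumor TPM 1.76 against a cohort with median 6.3 flags loss (ratio ~0.279)."""
    cohort = [1.13, 2.0, 6.3, 10.0, 16.94]
    ev = expression_loss("BRCA1", 1.76, cohort)
    assert ev.mechanism is Mechanism.EXPRESSION_LOSS
    assert ev.supporting_value == pytest.approx(1.76 / 6.3, abs=1e-12)
    assert ev.supporting_value == pytest.approx(0.279, abs=1e-3)


def test_expression_at_median_and_zero():
    cohort = [4.0, 6.3, 9.0]
    assert expression_loss("BRCA2", 6.3, cohort).mechanism is Mechanism.NONE
    ev = expression_loss("BRCA2", 0.0, cohort)
    assert ev.mechanism is Mechanism.EXPRESSION_LOSS
    assert ev.supporting_value == 0.0


def test_expression_domain_errors():
    with pytest.raises(DomainError):
        expression_loss("BRCA2", -1.0, [5.0])
    with pytest.raises(DomainError):
        expression_loss("BRCA2", 1.0, [])


def test_somatic_pathway_assignment():
    prof = assign_somatic_pathways("P1", ["ATRX", "PPM1D"])
    assert prof.count(SomaticPathway.DNA_DAMAGE) == 2
    assert prof.total == 2

    empty = assign_somatic_pathways("P2", [])
    assert empty.total == 0

    mapk = assign_somatic_pathways("P3", ["BRAF", "NF1", "PTPN11"])
    assert mapk.count(SomaticPathway.MAPK_ERK) == 3

    with pytest.warns(UserWarning, match="NOVELGENE"):
        other = assign_somatic_pathways("P4", ["NOVELGENE"])
    assert other.count(SomaticPathway.OTHER) == 1


def test_definitive_contribution(panel):
    fancd2 = make_classified(panel, "FANCD2", clinvar=ClinVar.PATHOGENIC, vaf=0.7)
    segs = [CNSegment("3", 9_000_000, 11_000_000, 2.0, 0.0)]
    hit = detect_cn_loh("3", 10_068_098, segs, patient_id="P1", gene="FANCD2")
    assert hit.mechanism is Mechanism.CN_LOH
    assert definitive_contribution([fancd2], [hit])

    # expression loss in both genes of a double carrier also counts
    brca2 = make_classified(panel, "BRCA2", clinvar=ClinVar.PATHOGENIC)
    fance = make_classified(panel, "FANCE", clinvar=ClinVar.PATHOGENIC, vaf=0.7)
    ev = [
        expression_loss("BRCA2", 0.5, [5.0, 6.0, 7.0], patient_id="P2"),
        expression_loss("FANCE", 0.4, [5.0, 6.0, 7.0], patient_id="P2"),
    ]
    assert definitive_contribution([brca2, fance], ev)

    # heterozygous carrier with expressed mutant allele and no LOH: no second hit
    palb2 = make_classified(panel, "PALB2", clinvar=ClinVar.PATHOGENIC)
    none_ev = expression_loss("PALB2", 6.0, [5.0, 6.0, 7.0], patient_id="P3")
    assert none_ev.mechanism is Mechanism.NONE
    assert not definitive_contribution([palb2], [none_ev])
    # evidence for a gene the patient does not carry does not count
    assert not definitive_contribution([palb2], ev)


def test_definitive_contribution_monotone(panel):
    """Adding further evidence never flips a true call to false."""
    brca2 = make_classified(panel, "BRCA2", clinvar=ClinVar.PATHOGENIC)
    base = [expression_loss("BRCA2", 0.1, [5.0, 6.0, 7.0])]
    assert definitive_contribution([brca2], base)
    more = base + [expression_loss("BRCA2", 6.0, [5.0, 6.0, 7.0])]
    assert definitive_contribution([brca2], more)


def test_segment_invariants():
    with pytest.raises(DataError):
        CNSegment("1", 10, 5, 2.0, 1.0)
    with pytest.raises(DataError):
        CNSegment("1", 1, 10, 2.0, 1.5)  # minor > total/2
    with pytest.raises(DataError):
        CNSegment("1", 1, 10, -1.0, 0.0)
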