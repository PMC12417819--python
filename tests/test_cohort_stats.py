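import math

import numpy as np
import pytest
import scipy.stats as st
from hypothesis import given, settings
from hypothesis import strategies as st_h

from germdmg import (
    ClinVar,
    Consequence,
    PatientRecord,
    Pathway,
    association_2x2,
    chisq_2x2,
    fisher_exact_2x2,
    format_pct,
    pathway_variant_counts,
    prevalence,
)

from conftest import make_classified, make_variant


@pytest.mark.parametrize(
    "num,den,expected",
    [(19, 252, 7.5), (10, 150, 6.7), (118, 188, 62.8), (50, 186, 26.9),
     (0, 100, 0.0), (1, 3, 33.3), (1, 8, 12.5), (1, 16, 6.3)],  # 6.25 rounds half away
)
def test_format_pct(num, den, expected):
    assert format_pct(num, den) == expected


def test_format_pct_requires_positive_denominator():
    with pytest.raises(ValueError):
        format_pct(1, 0)


def _record(pid, carrier, panel):
    rec = PatientRecord(patient_id=pid)
    if carrier:
        rec.reportable_germline = [
            make_classified(panel, "BRCA2", clinvar=ClinVar.PATHOGENIC)
        ]
    return rec


def test_prevalence(panel):
    cohort = [_record(f"P{i}", i < 19, panel) for i in range(252)]
    s = prevalence(cohort)
    assert (s.n_patients, s.n_carriers, s.prevalence_pct) == (252, 19, 7.5)

    none = prevalence([_record(f"P{i}", False, panel) for i in range(100)])
    assert (none.n_carriers, none.prevalence_pct) == (0, 0.0)

    third = prevalence([_record(f"P{i}", i == 0, panel) for i in range(3)])
    assert third.prevalence_pct == 33.3


def test_prevalence_errors_and_permutation_invariance(panel):
    with pytest.raises(ValueError):
        prevalence([])
    with pytest.raises(ValueError, match="unique"):
        prevalence([_record("P1", False, panel), _record("P1", False, panel)])
    cohort = [_record(f"P{i}", i % 7 == 0, panel) for i in range(40)]
    rng = np.random.default_rng(0)
    shuffled = list(cohort)
    rng.shuffle(shuffled)
    assert prevalence(cohort).prevalence_pct == prevalence(shuffled).prevalence_pct


def test_pathway_counts_for_printed_reportable_list(panel):
    """The cohort's 21 reportable variants tally HR=9, FA=4, MMR=2."""
    gene_counts = {
        "PALB2": 3, "BRCA2": 2, "CHEK2": 2, "BRCA1": 1, "BRIP1": 1,
        "FANCE": 1, "FANCD2": 1, "FANCM": 1, "SLX4": 1,
        "PMS2": 1, "MSH2": 1,
        "LZTR1": 2, "FGFR2": 1, "SDHA": 1, "MAX": 1, "HOXB13": 1,
    }
    from germdmg import classify, helium_score
    from germdmg.filtration import AdmitReason, CurationQueueItem

    variants = []
    for gene, n in gene_counts.items():
        for k in range(n):
            if gene == "BRIP1":
                # the BRIP1 finding is a curated VUS (functional 3, clinical 1)
                sv = helium_score(
                    make_variant(gene=gene, consequence=Consequence.MISSENSE,
                                 af=0.0001, n_damaging=4),
                    panel.entry(gene),
                )
                cv = classify(
                    CurationQueueItem(sv, AdmitReason.GREEN_HIGH_SCORE),
                    phenotype_match=True,
                )
                assert cv.reportable and cv.tier.value == "vus"
            else:
                cv = make_classified(
                    panel, gene, pos=1_000_000 + k, clinvar=ClinVar.PATHOGENIC, vaf=0.7
                )
            variants.append(cv)
    assert len(variants) == 21
    counts = pathway_variant_counts(variants, panel)
    assert counts[Pathway.HR] == 9
    assert counts[Pathway.FA] == 4
    assert counts[Pathway.MMR] == 2
    assert counts[Pathway.MAPK_ERK] == 2
    assert sum(counts.values()) == 21


def test_pathway_counts_edge_cases(panel):
    assert sum(pathway_variant_counts([], panel).values()) == 0
    lztr1 = make_classified(panel, "LZTR1", clinvar=ClinVar.PATHOGENIC)
    assert pathway_variant_counts([lztr1], panel)[Pathway.MAPK_ERK] == 1


def _fisher_oracle(a, b, c, d):
    """Integer-arithmetic hypergeometric enumeration, independent of scipy."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    denom = math.comb(n, c1)
    support = range(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = {k: math.comb(r1, k) * math.comb(n - r1, c1 - k) / denom for k in support}
    cutoff = pmf[a] * (1 + 1e-7)
    return min(1.0, sum(p for p in pmf.values() if p <= cutoff))


def test_fisher_worked_examples():
    assert fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)
    assert fisher_exact_2x2([[0, 10], [10, 0]]) == pytest.approx(2 / math.comb(20, 10), rel=1e-9)
    # carriers-without-PI3K-drivers style table against the enumeration oracle
    assert fisher_exact_2x2([[0, 19], [50, 136]]) == pytest.approx(
        _fisher_oracle(0, 19, 50, 136), abs=1e-12
    )


def test_fisher_matches_scipy_cross_check():
    rng = np.random.default_rng(8)
    for _ in range(50):
        a, b, c, d = (int(x) for x in rng.integers(0, 15, size=4))
        if (a + b) * (a + c) * (b + d) * (c + d) == 0:
            continue
        ours = fisher_exact_2x2([[a, b], [c, d]])
        theirs = st.fisher_exact([[a, b], [c, d]])[1]
        assert ours == pytest.approx(theirs, rel=1e-9)


@given(
    st_h.tuples(
        st_h.integers(0, 12), st_h.integers(0, 12), st_h.integers(0, 12), st_h.integers(0, 12)
    )
)
@settings(derandomize=True, max_examples=120)
def test_fisher_symmetries(cells):
    a, b, c, d = cells
    p = fisher_exact_2x2([[a, b], [c, d]])
    assert p == pytest.approx(fisher_exact_2x2([[a, c], [b, d]]), abs=1e-12)  # transpose
    assert p == pytest.approx(fisher_exact_2x2([[c, d], [a, b]]), abs=1e-12)  # row swap
    assert p == pytest.approx(fisher_exact_2x2([[b, a], [d, c]]), abs=1e-12)  # col swap
    assert 0.0 <= p <= 1.0


def test_chisq_and_auto_method():
    table = [[30, 70], [50, 50]]
    expected_p = st.chi2_contingency(np.array(table), correction=False)[1]
    assert chisq_2x2(table) == pytest.approx(expected_p)
    # large balanced table: auto == chisq
    assert association_2x2(table, "auto") == pytest.approx(expected_p)
    # sparse table: auto falls back to Fisher
    sparse = [[0, 19], [50, 136]]
    assert association_2x2(sparse, "auto") == pytest.approx(fisher_exact_2x2(sparse))


def test_degenerate_margins_warn_and_return_one():
    with pytest.warns(UserWarning):
        assert fisher_exact_2x2([[0, 0], [3, 4]]) == 1.0
    with pytest.warns(UserWarning):
        assert association_2x2([[0, 0], [0, 0]], "auto") == 1.0
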