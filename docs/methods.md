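# Methods

This note documents the models, rules and numerical choices implemented in
`germdmg`, the defaults and why they were chosen, and what the synthetic
cohorts do and do not establish about real data.

## Variant prioritization and filtration

**Score.** The prioritization score is a deterministic integer on a 0–100
scale. The original in-house scoring software behind this style of analysis
is unpublished, so the scale here is a documented surrogate whose *top tier*
is exact by construction: score 100 (the only value "over 99") iff the
variant is rare (max control-population allele frequency strictly below 1%)
AND either carries a ClinVar pathogenic/likely-pathogenic assertion or is a
novel (ClinVar-absent) loss-of-function variant in a tumor-suppressor gene.
Intermediate tiers — 60 for rare missense with 4-of-6 in-silico consensus,
50 for rare non-canonical splice-region variants — exist only so that
compound-het candidates and splice variants can be queued; they are not
calibrated probabilities and no claim is made that they match any external
scale. Loss-of-function consequences are {stop_gained, frameshift,
canonical_splice, start_lost}, with canonical_splice meaning the ±1/2
donor/acceptor dinucleotides. ClinVar "conflicting" counts as not-P/LP
(conservative). A variant absent from control populations carries AF 0.0 so
that novel variants pass the rarity gate.

**Filtration.** A variant enters the manual-curation queue iff its gene is
green in the panel and the score exceeds 99. Two deliberate readings were
fixed here:

* *Splice carve-out.* "Excluding splice variants" from the score gate is
  ambiguous; the default reading exempts rare splice-region variants from
  the score requirement (they cannot be confidently scored). The opposite
  reading — excluding them from curation entirely — is available as
  `SpliceMode.EXCLUDE`.
* *Recessive zygosity.* For autosomal recessive genes a variant must look
  biallelic (VAF strictly above 0.6, or a hom-alt genotype call) or be one of
  a candidate compound-heterozygote pair; genes flagged dosage-sensitive
  (MUTYH, CHEK2, Fanconi anemia genes) are queued on a single hit. Phase is
  unknowable from single-sample VCFs, so any two heterozygous score-eligible
  (≥ 50) variants in one recessive gene form a candidate pair (trans
  assumed) — the standard conservative practice absent parental data.
  X-linked genes follow dominant-style logic (paper-silent case; simplest
  defensible default).

**Classification.** Manual ACMG/AMP curation is not automatable; the
deterministic scaffold implemented here reproduces every call the recorded
evidence forces: ClinVar pathogenic → P; ClinVar LP or novel rare LOF in a
tumor suppressor (PVS1+PM2-style) → LP; rare missense with consensus
support, or rare splice-region → VUS; everything else → likely benign.
Cases needing human judgment therefore surface as VUS. The reporting rule is
exact: report P, LP, or VUS with functional score ≥ 3 and clinical score
≥ 1. The functional score (0–5) is a surrogate for the published grading
framework it imitates (+2 in-silico consensus, +2 LOF consequence, +1
rarity) and the clinical score is 1 iff patient metadata carries a
phenotype-match flag; both are config-level choices, not claims of
equivalence with the external framework.

## Panel

The bundled default panel is a documented reconstruction, not the original
curated 191-gene list (which is not public): it contains the genes named in
the cohort's reportable findings (PALB2, BRCA2, CHEK2, BRCA1, BRIP1, FANCE,
FANCD2, FANCM, SLX4, PMS2, MSH2, LZTR1, FGFR2, SDHA, MAX, HOXB13) plus MUTYH
and TP53, with pathways exactly as the cohort analysis grouped them —
including CHEK2 under homologous recombination with the dosage-sensitivity
exception. Users supply fuller panels as TSV; red-light genes are retained
in the panel object but excluded from analysis.

## Second hits

A germline finding "definitively contributes" when the tumor shows a second
hit in the same gene. Thresholds:

* **CN-LOH** — covering segment with minor allele CN < 0.5 (mirroring the
  genome-wide LOH definition) and total CN ≥ 1.5; below 1.5 the call is
  copy loss. 1.5 is the midpoint convention separating copy-neutral from
  one-copy states; the source analysis used "CN-LOH" without numeric bounds.
* **Expression loss** — tumor TPM below 0.3× the cohort median for that
  gene. The cutoff is anchored to the only quantified case available
  (1.76 TPM vs cohort median 6.3, ratio ≈ 0.279) and is config-overridable;
  no claim is made that 0.3 matches the original (unstated) criterion.
* **Somatic same-gene variant** — membership of the gene in the patient's
  somatic P/LP driver table.

## Genome-wide LOH and rank-sum tests

LOH fraction = (sum of autosomal segment lengths with minor CN < 0.5) /
2 881 033 286 bp. The denominator is fixed — it equals the GRCh37 autosome
total, and the synthetic genome uses the GRCh37 per-chromosome lengths so
that planted fractions are exact. Segments are 1-based inclusive (length =
end − start + 1), matching ASCAT-style files; overlapping segments are a
data error, unknown contig labels are warned and ignored, sex chromosomes
are silently excluded.

Group comparisons use the one-tailed Wilcoxon rank-sum test: the exact null
distribution for combined n ≤ 20 without ties, otherwise the normal
approximation with mid-ranks and tie-corrected variance
(`scipy.stats.mannwhitneyu`). All-identical inputs return p = 1 with a
warning. Holm's step-down correction (via statsmodels) is applied across
whatever family of tests one pipeline invocation declares; the family is a
user choice because no canonical family exists.

## 2×2 association tests

Fisher's exact test is computed in-package as the two-sided sum of
hypergeometric probabilities not exceeding the observed table's probability,
with the relative tie tolerance 1e-7 that R and scipy use — implemented
directly so the tie rule is explicit and testable against integer-arithmetic
enumeration (scipy's `fisher_exact` serves as an independent cross-check in
the tests). The chi-squared test is the 1-df Pearson statistic without
continuity correction. The `auto` method picks Fisher whenever any expected
cell is below 5. Degenerate margins return p = 1 with a warning.
Percentages are printed to one decimal, rounding half away from zero
(e.g. 19/252 → 7.5, 1/16 → 6.3).

## Mutational signatures

Refitting solves a non-negative least-squares problem per catalog
(`scipy.optimize.nnls`): exposures = argmin over e ≥ 0 of
‖counts − profiles·e‖₂. Fractions are exposures normalized to sum 1;
reconstruction quality is cosine similarity, clipped to [0, 1]. The 96
channels are pyrimidine-centered and alphabetically ordered (A[C>A]A …
T[T>G]T); reference matrices are user-supplied TSVs in that order. The
high-signature-3 flag defaults to a fraction threshold of 0.30, anchored to
the 33.8–38.8% range of the flagged cases in the motivating cohort (the
original cutoff is unstated) and overridable. Indel and copy-number
signature classes are out of scope for fitting, but the exposure model
carries arbitrary signature names so user-supplied matrices of any class
work through the same operation. De-novo extraction (NMF) and doublet
signatures are not implemented.

The bundled test matrix is synthetic: five profiles concentrating ~95% of
their mass on disjoint 16-channel blocks (near-orthogonal, so recovery is
well-conditioned) plus a flat 1/96 profile named SBS3, mimicking the
featurelessness of the HR-deficiency signature. It is a fixture for testing
recovery bounds, not a stand-in for COSMIC profiles.

## Synthetic cohorts

The generator defines the study conditions used by the tests and the
acceptance script:

* Carrier patients receive exactly one planted variant — ClinVar pathogenic,
  AF 0, heterozygous (VAF ~N(0.5, 0.03) clipped to [0.40, 0.58]) — or a
  compound-het pair when the drawn gene is recessive and non-excepted.
  Default gene weights follow the motivating cohort's printed P/LP counts.
* Background variants are common (AF uniform on [0.02, 0.5]) or
  ClinVar-benign, hence rule-separable from planted truth; `hard_mode` adds
  borderline rare-missense VUS (4/6 damaging, no phenotype match) that enter
  the curation queue without becoming reportable.
* Segment profiles plant an exact genome-wide LOH fraction (drawn around
  0.25 for somatic-TP53-mutant patients, 0.05 otherwise) as random disjoint
  intervals; planted CN-LOH second hits overwrite a ±500 kb window around
  the germline locus with (total 2, minor 0). Carriers *without* a planted
  second hit have any accidental LOH over their germline locus restored to
  heterozygosity, and their germline gene's TPM clamped to ≥ 0.6× the
  cohort median, so that flagged patients are exactly the planted ones.
* Catalogs are multinomial draws (default n = 5000) from signature mixtures;
  HR/FA carriers with a second hit receive a 0.35 signature-3 weight,
  everyone else 0.05.
* Determinism: one master seed; each patient's stream is
  `default_rng([seed, patient_index])`, so runs are byte-identical given a
  config and partial regeneration is stable.

What passing these tests shows: the rule engine, thresholds, statistics and
file plumbing are correct on inputs where the truth is known and separable.
What it does not show: performance on real cohorts — real annotation is
noisy (conflicting ClinVar records, missing predictor verdicts, imperfect
AF panels), real segment profiles are far more fragmented, catalogs carry
signatures outside the reference matrix, and manual curation judgment is
not modelled. The clean separability of the default generator is a design
choice; `hard_mode` probes the queue under borderline inputs but still does
not emulate annotation noise.

## Problem sizes

The bundled tests and the acceptance script run cohorts of 200–252 patients
(the motivating study's scale), 30-segment LOH profiles, and
5000-mutation catalogs; the statistical oracle sweeps enumerate all 2×2
tables with N ≤ 40 and rank-sum permutations up to combined n = 10. These
sizes keep a full run to well under a minute on one CPU while exercising
every code path at the study's own scale.

## Known limitations

* The score's intermediate tiers and the VUS functional/clinical grading are
  surrogates; only the top-tier and reporting-rule semantics are exact.
* Compound-het detection assumes trans phase; trio phasing is out of scope.
* Germline CNV/SV calling, survival analysis (Kaplan–Meier, log-rank,
  logistic regression), methylation analysis and upstream read
  alignment/variant calling are out of scope.
* The expression-loss rule uses a single cohort-median cutoff; it does not
  model allele-specific expression or methylation-driven silencing.
* `detect_cn_loh` requires non-overlapping segments and flags violations
  rather than resolving them.
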