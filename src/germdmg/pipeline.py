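"""End-to-end orchestration over a run directory.

Reads the per-patient inputs a cohort study provides (annotated germline
VCFs, somatic driver TSV, allele-specific CN segment TSV, expression TSV,
SBS-96 catalog TSV, clinical cohort TSV), runs screening -> classification
-> tumor integration -> cohort statistics, and returns per-patient records
plus the cohort summary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from .classification import ClassifiedVariant, classify, reportable_set
from .cohort_stats import (
    CohortSummary,
    DiagnosisGroup,
    H3Status,
    Location,
    PatientRecord,
    pathway_variant_counts,
    prevalence,
)
from .filtration import SpliceMode, build_curation_queue
from .genome_loh import genome_loh_fraction
from .panel import GenePanel, default_panel
from .scoring import helium_score
from .signatures import (
    CHANNELS_96,
    MutationCatalog,
    SignatureMatrix,
    fit_exposures,
    synthetic_signature_matrix,
)
from .tumor_integration import (
    CNSegment,
    Mechanism,
    SecondHitEvidence,
    assign_somatic_pathways,
    detect_cn_loh,
    expression_loss,
)
from .vcfio import VcfFieldConfig, read_patient_vcf


@dataclass
class PipelineResult:
    summary: CohortSummary
    records: list[PatientRecord]

    @property
    def n_definitive(self) -> int:
        from .tumor_integration import definitive_contribution

        return sum(
            1
            for r in self.records
            if r.is_carrier and definitive_contribution(r.reportable_germline, r.second_hits)
        )


def screen_patient(
    vcf_path: str | Path,
    panel: GenePanel,
    vcf_config: VcfFieldConfig = VcfFieldConfig(),
    splice_mode: SpliceMode = SpliceMode.CARVEOUT,
    phenotype_match: bool = False,
) -> list[ClassifiedVariant]:
    """Score, filter and classify one patient's germline VCF; returns reportables."""
    variants = read_patient_vcf(vcf_path, vcf_config)
    scored = []
    for v in variants:
        if v.gene_symbol not in panel:
            warnings.warn(f"gene {v.gene_symbol} not in panel; variant skipped")
            continue
        scored.append(helium_score(v, panel.entry(v.gene_symbol)))
    queue = build_curation_queue(scored, panel, splice_mode)
    classified = [classify(item, phenotype_match=phenotype_match) for item in queue]
    return reportable_set(classified)


def _segments_by_patient(path: Path) -> dict[str, list[CNSegment]]:
    if not path.exists():
        return {}
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out: dict[str, list[CNSegment]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.sample), []).append(
            CNSegment(
                chrom=str(row.chrom),
                start=int(row.startpos),
                end=int(row.endpos),
                total_cn=float(row.nTotal),
                minor_cn=float(row.nMinor),
            )
        )
    return out


def run_pipeline(
    run_dir: str | Path,
    panel: Optional[GenePanel] = None,
    vcf_config: VcfFieldConfig = VcfFieldConfig(),
    splice_mode: SpliceMode = SpliceMode.CARVEOUT,
    sigs: Optional[SignatureMatrix] = None,
) -> PipelineResult:
    """Run the complete analysis over a run directory (see synthetic_data)."""
    run = Path(run_dir)
    panel = panel or default_panel()
    sigs = sigs or synthetic_signature_matrix()

    cohort_df = pd.read_csv(run / "cohort.tsv", sep="\t", dtype=str)
    segments = _segments_by_patient(run / "segments.tsv")

    somatic_path = run / "somatic.tsv"
    somatic_by_patient: dict[str, list[str]] = {}
    if somatic_path.exists():
        sdf = pd.read_csv(somatic_path, sep="\t", dtype=str)
        for row in sdf.itertuples(index=False):
            somatic_by_patient.setdefault(str(row.patient_id), []).append(str(row.gene))

    expr_path = run / "expression.tsv"
    expr = pd.read_csv(expr_path, sep="\t", index_col=0) if expr_path.exists() else None

    cat_path = run / "catalogs.tsv"
    catalogs = None
    if cat_path.exists():
        catalogs = pd.read_csv(cat_path, sep="\t", index_col=0)
        if list(catalogs.index) != list(CHANNELS_96):
            raise ValueError("catalog TSV channels are not in canonical SBS-96 order")

    records: list[PatientRecord] = []
    for row in cohort_df.itertuples(index=False):
        pid = str(row.patient_id)
        phenotype_match = str(getattr(row, "phenotype_match", "no")).lower() in (
            "yes",
            "true",
            "1",
        )
        vcf_path = run / "germline" / f"{pid}.vcf"
        reportables = (
            screen_patient(vcf_path, panel, vcf_config, splice_mode, phenotype_match)
            if vcf_path.exists()
            else []
        )

        rec = PatientRecord(
            patient_id=pid,
            diagnosis_group=DiagnosisGroup(str(row.diagnosis_group)),
            h3_status=H3Status(str(row.h3_status)),
            location=Location(str(row.location)),
            reportable_germline=reportables,
        )

        patient_segments = segments.get(pid, [])
        if patient_segments:
            rec.loh = genome_loh_fraction(patient_segments, patient_id=pid)

        somatic_genes = somatic_by_patient.get(pid, [])
        if somatic_genes:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rec.somatic_profile = assign_somatic_pathways(pid, somatic_genes)

        if catalogs is not None and pid in catalogs.columns:
            counts = catalogs[pid].to_numpy()
            if counts.sum() > 0:
                rec.exposure = fit_exposures(MutationCatalog(pid, counts), sigs)

        # second-hit evidence for every reportable germline gene
        hits: list[SecondHitEvidence] = []
        for cv in reportables:
            v = cv.item.scored.variant
            gene = cv.gene_symbol
            if patient_segments:
                ev = detect_cn_loh(v.chrom, v.pos, patient_segments, patient_id=pid, gene=gene)
                if ev.mechanism is not Mechanism.NONE:
                    hits.append(ev)
            if expr is not None and gene in expr.index:
                cohort_tpms = expr.loc[gene].astype(float).tolist()
                ev = expression_loss(
                    gene, float(expr.loc[gene, pid]), cohort_tpms, patient_id=pid
                )
                if ev.mechanism is not Mechanism.NONE:
                    hits.append(ev)
            if gene in somatic_genes:
                hits.append(
                    SecondHitEvidence(pid, gene, Mechanism.SOMATIC_SNV_SAME_GENE, 1.0)
                )
        rec.second_hits = hits
        records.append(rec)

    summary = prevalence(records)
    all_reportable = [cv for r in records for cv in r.reportable_germline]
    summary.pathway_variant_counts = pathway_variant_counts(all_reportable, panel)
    return PipelineResult(summary=summary, records=records)
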