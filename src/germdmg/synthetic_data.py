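"""Synthetic cohort generator with planted, rule-separable ground truth.

Emulates the per-patient inputs of a germline predisposition study of
diffuse midline glioma — annotated single-sample germline VCFs, somatic
driver tables, ASCAT-like allele-specific copy-number segments, gene x
patient TPM expression tables and SBS-96 mutation catalogs — on a synthetic
GRCh37-sized genome whose autosomes sum exactly to 2 881 033 286 bp.

Planted truth: selected carrier patients receive exactly one pathogenic
germline variant (or a compound-het pair when the chosen gene is recessive
and not dosage-excepted); selected carriers additionally receive a tumor
second hit realized either as a copy-neutral LOH segment over the germline
locus or as depressed tumor expression of the germline gene. Background
variants in all patients are common (population AF 0.02-0.5) or
ClinVar-benign, hence rule-separable from planted hits; "hard mode" adds
borderline rare-missense VUS to stress the curation queue. Everything is
deterministic given the master seed (per-patient streams are derived by
seeding a generator with the entropy pair ``[seed, patient_index]``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genome_loh import AUTOSOME_LENGTHS, GENOME_SIZE
from .panel import GenePanel, Inheritance, TrafficLight, default_panel
from .scoring import (
    PREDICTORS,
    AnnotatedVariant,
    ClinVar,
    Consequence,
    Genotype,
    PredictorPanel,
    Verdict,
)
from .signatures import CHANNELS_96, MutationCatalog, SignatureMatrix, synthetic_signature_matrix
from .tumor_integration import CNSegment, Mechanism, _norm_chrom
from .vcfio import VcfFieldConfig, write_patient_vcf


class ConfigError(ValueError):
    """Raised for infeasible simulation configurations."""


#: approximate GRCh37 loci of the bundled panel genes (chrom, position)
GENE_LOCI: dict[str, tuple[str, int]] = {
    "MUTYH": ("1", 45_794_915),
    "MSH2": ("2", 47_630_206),
    "FANCD2": ("3", 10_068_098),
    "SDHA": ("5", 218_356),
    "FANCE": ("6", 35_420_157),
    "PMS2": ("7", 6_012_870),
    "FGFR2": ("10", 123_237_844),
    "BRCA2": ("13", 32_889_611),
    "FANCM": ("14", 45_605_136),
    "MAX": ("14", 65_472_818),
    "PALB2": ("16", 23_614_483),
    "SLX4": ("16", 3_631_182),
    "BRCA1": ("17", 41_197_695),
    "BRIP1": ("17", 59_760_656),
    "HOXB13": ("17", 46_802_126),
    "CHEK2": ("22", 29_083_731),
    "LZTR1": ("22", 21_336_558),
    "TP53": ("17", 7_571_720),
}

#: default carrier gene frequencies, mirroring the cohort's printed P/LP counts
DEFAULT_CARRIER_GENE_WEIGHTS: dict[str, float] = {
    "PALB2": 3,
    "BRCA2": 2,
    "CHEK2": 2,
    "LZTR1": 2,
    "BRCA1": 1,
    "FANCE": 1,
    "FANCD2": 1,
    "FANCM": 1,
    "SLX4": 1,
    "PMS2": 1,
    "MSH2": 1,
    "FGFR2": 1,
    "SDHA": 1,
    "MAX": 1,
    "HOXB13": 1,
}

_SECOND_HIT_HALF_WIDTH = 500_000


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort."""

    n_patients: int
    n_carriers: int
    seed: int = 0
    carrier_gene_weights: Optional[Mapping[str, float]] = None
    planted_second_hits: Sequence[tuple[int, str]] = ()
    background_variant_rate: float = 3.0
    loh_fraction_means: Mapping[str, float] = field(
        default_factory=lambda: {"tp53_mutant": 0.25, "tp53_wildtype": 0.05}
    )
    n_loh_segments: int = 30
    n_mutations: int = 5000
    sig3_carrier_weight: float = 0.35
    sig3_background_weight: float = 0.05
    hard_mode: bool = False

    def __post_init__(self) -> None:
        if self.n_carriers > self.n_patients:
            raise ConfigError("n_carriers cannot exceed n_patients")
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        seen = set()
        for idx, mech in self.planted_second_hits:
            if not 0 <= idx < self.n_patients:
                raise ConfigError(f"second-hit patient index out of range: {idx}")
            if idx in seen:
                raise ConfigError(f"duplicate second-hit patient index: {idx}")
            seen.add(idx)
            try:
                mechanism = Mechanism(mech)
            except ValueError:
                raise ConfigError(f"unsupported planted mechanism: {mech}") from None
            if mechanism not in (Mechanism.CN_LOH, Mechanism.EXPRESSION_LOSS):
                raise ConfigError(f"unsupported planted mechanism: {mech}")
        if len(seen) > self.n_carriers:
            raise ConfigError("more planted second hits than carriers")


@dataclass
class TruthRecord:
    patient_id: str
    carrier: bool
    genes: list[str] = field(default_factory=list)
    variant_loci: list[tuple[str, int]] = field(default_factory=list)
    second_hit: Optional[str] = None
    loh_target: float = 0.0
    tp53_somatic: bool = False
    sig3_weight: float = 0.0


@dataclass
class TruthTable:
    records: list[TruthRecord]

    def carriers(self) -> list[str]:
        return [r.patient_id for r in self.records if r.carrier]

    def to_json(self, path: str | Path) -> None:
        payload = {
            r.patient_id: {
                "carrier": r.carrier,
                "genes": r.genes,
                "variant_loci": [[c, p] for c, p in r.variant_loci],
                "second_hit": r.second_hit,
                "loh_target": r.loh_target,
                "tp53_somatic": r.tp53_somatic,
                "sig3_weight": r.sig3_weight,
            }
            for r in self.records
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def _patient_rng(seed: int, index: int) -> np.random.Generator:
    # stable per-patient substream: entropy pair [master seed, patient index]
    return np.random.default_rng([seed, index])


def _split_integer(rng: np.random.Generator, total: int, parts: int, minimum: int) -> np.ndarray:
    """Random composition of ``total`` into ``parts`` parts each >= minimum."""
    if parts <= 0:
        raise ConfigError("parts must be positive")
    spare = total - minimum * parts
    if spare < 0:
        raise ConfigError(f"cannot split {total} into {parts} parts of >= {minimum}")
    return rng.multinomial(spare, np.full(parts, 1.0 / parts)) + minimum


def simulate_segments(
    target_fraction: float,
    n_segments: int,
    seed: int | np.random.Generator = 0,
) -> list[CNSegment]:
    """Whole-genome segment profile with an exact planted autosomal LOH fraction.

    LOH bases total ``round(target_fraction * GENOME_SIZE)`` exactly, spread
    over ``n_segments`` random disjoint intervals (split at chromosome
    boundaries when needed); the rest of the autosomes is covered by
    copy-neutral heterozygous segments (total CN 2, minor CN 1).
    """
    if not 0.0 <= target_fraction <= 1.0:
        raise ConfigError(f"target_fraction out of [0,1]: {target_fraction}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    loh_total = round(target_fraction * GENOME_SIZE)
    chroms = list(AUTOSOME_LENGTHS.items())
    offsets = np.cumsum([0] + [ln for _, ln in chroms])

    intervals: list[tuple[int, int]] = []  # concatenated 0-based half-open
    if loh_total > 0:
        if n_segments < 1:
            raise ConfigError("n_segments must be >= 1 when target_fraction > 0")
        n_eff = min(n_segments, loh_total)
        if n_segments > loh_total:
            raise ConfigError(
                f"cannot place {n_segments} non-empty segments over {loh_total} LOH bases"
            )
        seg_sizes = _split_integer(rng, loh_total, n_eff, minimum=1)
        gap_sizes = _split_integer(rng, GENOME_SIZE - loh_total, n_eff + 1, minimum=0)
        cursor = 0
        for size, gap in zip(seg_sizes, gap_sizes[:-1]):
            cursor += int(gap)
            intervals.append((cursor, cursor + int(size)))
            cursor += int(size)

    segments: list[CNSegment] = []
    for ci, (chrom, length) in enumerate(chroms):
        lo, hi = offsets[ci], offsets[ci + 1]
        local: list[tuple[int, int]] = []
        for s, e in intervals:
            cs, ce = max(s, lo), min(e, hi)
            if cs < ce:
                local.append((cs - lo, ce - lo))
        local.sort()
        cursor = 0
        for s, e in local:
            if s > cursor:
                segments.append(CNSegment(chrom, cursor + 1, s, 2.0, 1.0))
            segments.append(CNSegment(chrom, s + 1, e, 2.0, 0.0))
            cursor = e
        if cursor < length:
            segments.append(CNSegment(chrom, cursor + 1, length, 2.0, 1.0))
    return segments


def simulate_catalog(
    mixture: Mapping[str, float] | Sequence[float],
    n_mutations: int,
    seed: int | np.random.Generator = 0,
    sigs: Optional[SignatureMatrix] = None,
    patient_id: str = "sim",
) -> MutationCatalog:
    """Multinomial SBS-96 catalog drawn from a mixture of signature profiles."""
    if n_mutations <= 0:
        raise ConfigError("n_mutations must be positive")
    sigs = sigs or synthetic_signature_matrix()
    if isinstance(mixture, Mapping):
        weights = np.zeros(len(sigs.names))
        for name, w in mixture.items():
            weights[sigs.index_of(name)] = w
    else:
        weights = np.asarray(mixture, dtype=float)
        if weights.shape != (len(sigs.names),):
            raise ConfigError("mixture length must match the signature matrix")
    if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-6:
        raise ConfigError("mixture weights must be non-negative and sum to 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    channel_probs = sigs.profiles @ weights
    counts = rng.multinomial(n_mutations, channel_probs / channel_probs.sum())
    return MutationCatalog(patient_id=patient_id, counts=counts)


def _force_loh_at(
    segments: list[CNSegment], chrom: str, pos: int
) -> list[CNSegment]:
    """Replace the region around a locus with a copy-neutral LOH segment."""
    length = AUTOSOME_LENGTHS[_norm_chrom(chrom)]
    lo = max(1, pos - _SECOND_HIT_HALF_WIDTH)
    hi = min(length, pos + _SECOND_HIT_HALF_WIDTH)
    out: list[CNSegment] = []
    for s in segments:
        if _norm_chrom(s.chrom) != _norm_chrom(chrom) or s.end < lo or s.start > hi:
            out.append(s)
            continue
        if s.start < lo:
            out.append(CNSegment(s.chrom, s.start, lo - 1, s.total_cn, s.minor_cn))
        if s.end > hi:
            out.append(CNSegment(s.chrom, hi + 1, s.end, s.total_cn, s.minor_cn))
    out.append(CNSegment(chrom, lo, hi, 2.0, 0.0))
    return out


def _clear_loh_at(segments: list[CNSegment], chrom: str, pos: int) -> list[CNSegment]:
    """Restore heterozygosity of any LOH segment covering a locus."""
    out: list[CNSegment] = []
    for s in segments:
        if s.covers(chrom, pos) and s.minor_cn < 0.5:
            out.append(CNSegment(s.chrom, s.start, s.end, max(s.total_cn, 2.0), 1.0))
        else:
            out.append(s)
    return out


def _planted_variants(
    gene: str, panel: GenePanel, rng: np.random.Generator
) -> list[AnnotatedVariant]:
    """One pathogenic variant, or a compound-het pair for non-excepted recessive genes."""
    entry = panel.entry(gene)
    chrom, pos = GENE_LOCI[gene]
    damaging = PredictorPanel({p: Verdict.DAMAGING for p in PREDICTORS})
    compound = (
        entry.inheritance is Inheritance.RECESSIVE
        and not entry.dosage_sensitive_exception
    )
    n_alleles = 2 if compound else 1
    out = []
    for k in range(n_alleles):
        lof = bool(entry.is_tumor_suppressor and rng.random() < 0.6)
        out.append(
            AnnotatedVariant(
                chrom=chrom,
                pos=pos + 50 * k,
                ref="G",
                alt="T" if lof else "A",
                gene_symbol=gene,
                consequence=Consequence.FRAMESHIFT if lof else Consequence.MISSENSE,
                population_af=0.0,
                clinvar=ClinVar.PATHOGENIC,
                vaf=float(np.clip(rng.normal(0.5, 0.03), 0.40, 0.58)),
                genotype=Genotype.HET,
                predictor_panel=damaging,
            )
        )
    return out


def _background_variants(
    panel: GenePanel, rng: np.random.Generator, rate: float, hard_mode: bool,
    reserved: set[tuple[str, int]],
) -> list[AnnotatedVariant]:
    genes = [e.gene_symbol for e in panel if e.gene_symbol in GENE_LOCI]
    tolerated = PredictorPanel({p: Verdict.TOLERATED for p in PREDICTORS})
    out: list[AnnotatedVariant] = []
    n = int(rng.poisson(rate))
    for _ in range(n):
        gene = genes[int(rng.integers(len(genes)))]
        chrom, locus = GENE_LOCI[gene]
        pos = locus + int(rng.integers(1_000, 200_000))
        if (chrom, pos) in reserved:
            continue
        reserved.add((chrom, pos))
        benign_clinvar = rng.random() < 0.3
        out.append(
            AnnotatedVariant(
                chrom=chrom,
                pos=pos,
                ref="C",
                alt="T",
                gene_symbol=gene,
                consequence=Consequence.MISSENSE if rng.random() < 0.5 else Consequence.SYNONYMOUS,
                population_af=0.001 if benign_clinvar else float(rng.uniform(0.02, 0.5)),
                clinvar=ClinVar.BENIGN if benign_clinvar else ClinVar.ABSENT,
                vaf=float(np.clip(rng.normal(0.5, 0.04), 0.3, 0.7)),
                genotype=Genotype.HET,
                predictor_panel=tolerated,
            )
        )
    if hard_mode and rng.random() < 0.3:
        # borderline VUS: rare missense with consensus support, no phenotype match
        gene = genes[int(rng.integers(len(genes)))]
        chrom, locus = GENE_LOCI[gene]
        pos = locus + int(rng.integers(200_000, 300_000))
        if (chrom, pos) not in reserved:
            reserved.add((chrom, pos))
            out.append(
                AnnotatedVariant(
                    chrom=chrom,
                    pos=pos,
                    ref="A",
                    alt="G",
                    gene_symbol=gene,
                    consequence=Consequence.MISSENSE,
                    population_af=0.001,
                    clinvar=ClinVar.ABSENT,
                    vaf=0.5,
                    genotype=Genotype.HET,
                    predictor_panel=PredictorPanel(
                        {p: Verdict.DAMAGING for p in PREDICTORS[:4]}
                    ),
                )
            )
    return out


_SOMATIC_GENES = ("ATRX", "PPM1D", "ATM", "POLE", "BRAF", "NF1", "PTPN11",
                  "MAPK12", "ACVR1", "PIK3CA", "PTEN", "MTOR")


def simulate_cohort(
    config: SimulationConfig,
    out_dir: str | Path,
    panel: Optional[GenePanel] = None,
    vcf_config: VcfFieldConfig = VcfFieldConfig(),
) -> TruthTable:
    """Generate a full synthetic run directory plus its truth table.

    Emits ``germline/<patient>.vcf``, ``somatic.tsv``, ``segments.tsv``,
    ``expression.tsv``, ``catalogs.tsv``, ``cohort.tsv`` and ``truth.json``
    under ``out_dir``. Deterministic given the config (including seed).
    """
    panel = panel or default_panel()
    sigs = synthetic_signature_matrix()

    weights_map = dict(
        config.carrier_gene_weights
        if config.carrier_gene_weights is not None
        else DEFAULT_CARRIER_GENE_WEIGHTS
    )
    for gene in weights_map:
        if gene not in panel:
            raise ConfigError(f"carrier gene not in panel: {gene}")
        if panel.entry(gene).traffic_light is not TrafficLight.GREEN:
            raise ConfigError(f"carrier gene is not green in panel: {gene}")
        if gene not in GENE_LOCI:
            raise ConfigError(f"carrier gene has no locus defined: {gene}")
    genes_arr = sorted(weights_map)
    w = np.array([weights_map[g] for g in genes_arr], dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ConfigError("carrier gene weights must be non-negative with positive sum")
    w = w / w.sum()

    out = Path(out_dir)
    (out / "germline").mkdir(parents=True, exist_ok=True)

    rng_master = np.random.default_rng([config.seed, 2**20])
    hit_by_patient = {idx: Mechanism(m) for idx, m in config.planted_second_hits}
    carrier_idx = sorted(hit_by_patient)
    remaining = [i for i in range(config.n_patients) if i not in hit_by_patient]
    extra = config.n_carriers - len(carrier_idx)
    if extra > 0:
        carrier_idx += sorted(
            int(i) for i in rng_master.choice(remaining, size=extra, replace=False)
        )
    carrier_set = set(carrier_idx)

    records: list[TruthRecord] = []
    somatic_rows: list[dict] = []
    segment_rows: list[dict] = []
    catalogs: dict[str, np.ndarray] = {}
    cohort_rows: list[dict] = []
    planted_loci: dict[str, list[tuple[str, int, str]]] = {}

    for i in range(config.n_patients):
        rng = _patient_rng(config.seed, i)
        pid = f"P{i:04d}"
        rec = TruthRecord(patient_id=pid, carrier=i in carrier_set)

        variants: list[AnnotatedVariant] = []
        reserved: set[tuple[str, int]] = set()
        if rec.carrier:
            gene = genes_arr[int(rng.choice(len(genes_arr), p=w))]
            planted = _planted_variants(gene, panel, rng)
            variants.extend(planted)
            rec.genes = [gene]
            rec.variant_loci = [(v.chrom, v.pos) for v in planted]
            reserved.update((v.chrom, v.pos) for v in planted)
            planted_loci[pid] = [(v.chrom, v.pos, gene) for v in planted]
        variants.extend(
            _background_variants(
                panel, rng, config.background_variant_rate, config.hard_mode, reserved
            )
        )
        write_patient_vcf(variants, out / "germline" / f"{pid}.vcf", pid, vcf_config)

        # clinical covariates, loosely matching the cohort's distributions
        diagnosis = "DIPG" if rng.random() < 0.61 else "DMG_other"
        h3 = rng.choice(
            ["H3_3", "H3_1", "altered_other", "wildtype", "unknown"],
            p=[0.60, 0.13, 0.05, 0.05, 0.17],
        )
        location = rng.choice(
            ["pons", "thalamus", "spine", "other", "unknown"],
            p=[0.62, 0.20, 0.03, 0.05, 0.10],
        )
        cohort_rows.append(
            {
                "patient_id": pid,
                "diagnosis_group": diagnosis,
                "h3_status": h3,
                "location": location,
                "phenotype_match": "no",
            }
        )

        # somatic drivers (never overlapping the germline panel genes used here)
        tp53 = bool(rng.random() < 0.6)
        rec.tp53_somatic = tp53
        if tp53:
            somatic_rows.append({"patient_id": pid, "gene": "TP53", "variant_class": "missense"})
        for _ in range(int(rng.poisson(0.8))):
            g = _SOMATIC_GENES[int(rng.integers(len(_SOMATIC_GENES)))]
            somatic_rows.append({"patient_id": pid, "gene": g, "variant_class": "missense"})

        # allele-specific CN segments with a planted genome-wide LOH fraction
        mean = (
            config.loh_fraction_means["tp53_mutant"]
            if tp53
            else config.loh_fraction_means["tp53_wildtype"]
        )
        target = float(np.clip(rng.normal(mean, mean * 0.25 + 0.005), 0.0, 0.8))
        rec.loh_target = target
        segments = simulate_segments(target, config.n_loh_segments, rng)

        hit = hit_by_patient.get(i)
        if hit is Mechanism.CN_LOH:
            chrom, pos = GENE_LOCI[rec.genes[0]]
            segments = _force_loh_at(segments, chrom, pos)
            rec.second_hit = Mechanism.CN_LOH.value
        elif rec.carrier:
            for chrom, pos in rec.variant_loci:
                segments = _clear_loh_at(segments, chrom, pos)
            if hit is Mechanism.EXPRESSION_LOSS:
                rec.second_hit = Mechanism.EXPRESSION_LOSS.value
        for s in segments:
            segment_rows.append(
                {
                    "sample": pid,
                    "chrom": s.chrom,
                    "startpos": s.start,
                    "endpos": s.end,
                    "nTotal": s.total_cn,
                    "nMinor": s.minor_cn,
                }
            )

        # SBS catalog: HR/FA carriers with a confirmed second hit mimic HRD
        hrd_like = rec.carrier and rec.second_hit is not None and panel.entry(
            rec.genes[0]
        ).pathway.value in ("HR", "FA")
        sig3_w = config.sig3_carrier_weight if hrd_like else config.sig3_background_weight
        rec.sig3_weight = sig3_w
        rest = np.array([0.50, 0.20, 0.15, 0.10, 0.05]) * (1.0 - sig3_w)
        mixture = dict(zip(("SBS1", "SBS2", "SBS5", "SBS8", "SBS13"), rest))
        mixture["SBS3"] = sig3_w
        catalog = simulate_catalog(mixture, config.n_mutations, rng, sigs, patient_id=pid)
        catalogs[pid] = catalog.counts

        records.append(rec)

    # expression table: lognormal TPM per gene; planted losses and carrier clamps
    rng_expr = np.random.default_rng([config.seed, 2**21])
    gene_rows = sorted(GENE_LOCI)
    pids = [r.patient_id for r in records]
    expr = pd.DataFrame(
        {
            pid: np.round(rng_expr.lognormal(mean=np.log(6.0), sigma=0.4, size=len(gene_rows)), 3)
            for pid in pids
        },
        index=pd.Index(gene_rows, name="gene"),
    )
    for rec in records:
        if not rec.carrier:
            continue
        gene = rec.genes[0]
        med = float(expr.loc[gene].median())
        if rec.second_hit == Mechanism.EXPRESSION_LOSS.value:
            expr.loc[gene, rec.patient_id] = round(0.05 * med, 3)
        else:
            # keep unaffected carriers clear of the expression-loss cutoff
            expr.loc[gene, rec.patient_id] = max(
                float(expr.loc[gene, rec.patient_id]), round(0.6 * med, 3)
            )

    pd.DataFrame(somatic_rows, columns=["patient_id", "gene", "variant_class"]).to_csv(
        out / "somatic.tsv", sep="\t", index=False
    )
    pd.DataFrame(segment_rows).to_csv(out / "segments.tsv", sep="\t", index=False)
    expr.to_csv(out / "expression.tsv", sep="\t")
    cat_df = pd.DataFrame(catalogs, index=pd.Index(CHANNELS_96, name="channel"))
    cat_df.to_csv(out / "catalogs.tsv", sep="\t")
    pd.DataFrame(cohort_rows).to_csv(out / "cohort.tsv", sep="\t", index=False)

    truth = TruthTable(records)
    truth.to_json(out / "truth.json")
    return truth
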