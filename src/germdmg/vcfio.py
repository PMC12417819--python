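"""Annotated single-sample VCF ingestion (cyvcf2) and emission.

Annotation is read from INFO keys whose names are configurable (YAML):
maximum control-population allele frequency, ClinVar assertion, predicted
consequence, gene symbol, and the six categorical in-silico predictor
verdicts. Genotype comes from GT; the variant allele fraction from a VF
format field when present, else from allelic depths (AD).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml
from cyvcf2 import VCF

from .genome_loh import AUTOSOME_LENGTHS, X_LENGTH
from .scoring import (
    PREDICTORS,
    AnnotatedVariant,
    ClinVar,
    Consequence,
    Genotype,
    PredictorPanel,
    Verdict,
)


@dataclass(frozen=True)
class VcfFieldConfig:
    """INFO/FORMAT key names used to ingest annotated VCFs."""

    af_key: str = "AF_POPMAX"
    clinvar_key: str = "CLNSIG"
    consequence_key: str = "CSQ"
    gene_key: str = "GENE"
    predictor_keys: dict[str, str] = field(
        default_factory=lambda: {p: p.upper() for p in PREDICTORS}
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "VcfFieldConfig":
        with Path(path).open("r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("af_key", "clinvar_key", "consequence_key", "gene_key"):
            if key in data:
                kwargs[key] = str(data[key])
        if "predictor_keys" in data:
            kwargs["predictor_keys"] = {
                str(k): str(v) for k, v in data["predictor_keys"].items()
            }
        return cls(**kwargs)


_CLINVAR_TOKENS = {
    "pathogenic": ClinVar.PATHOGENIC,
    "likely_pathogenic": ClinVar.LIKELY_PATHOGENIC,
    "likely pathogenic": ClinVar.LIKELY_PATHOGENIC,
    "uncertain_significance": ClinVar.VUS,
    "vus": ClinVar.VUS,
    "likely_benign": ClinVar.LIKELY_BENIGN,
    "likely benign": ClinVar.LIKELY_BENIGN,
    "benign": ClinVar.BENIGN,
    "absent": ClinVar.ABSENT,
}


def _parse_clinvar(token: Optional[str]) -> ClinVar:
    if token is None or token == "":
        return ClinVar.ABSENT
    t = str(token).strip().lower()
    if t.startswith("conflicting"):
        return ClinVar.CONFLICTING
    return _CLINVAR_TOKENS.get(t, ClinVar.ABSENT)


def _parse_consequence(token: Optional[str]) -> Consequence:
    if token is None:
        return Consequence.OTHER
    t = str(token).strip().lower()
    for member in Consequence:
        if member.value == t:
            return member
    # common VEP aliases
    aliases = {
        "stop_gained": Consequence.STOP_GAINED,
        "frameshift_variant": Consequence.FRAMESHIFT,
        "splice_donor_variant": Consequence.CANONICAL_SPLICE,
        "splice_acceptor_variant": Consequence.CANONICAL_SPLICE,
        "splice_region_variant": Consequence.SPLICE_REGION,
        "start_lost": Consequence.START_LOST,
        "missense_variant": Consequence.MISSENSE,
        "synonymous_variant": Consequence.SYNONYMOUS,
    }
    return aliases.get(t, Consequence.OTHER)


def read_patient_vcf(
    path: str | Path, config: VcfFieldConfig = VcfFieldConfig()
) -> list[AnnotatedVariant]:
    """Read one annotated single-sample VCF into AnnotatedVariant records."""
    out: list[AnnotatedVariant] = []
    vcf = VCF(str(path))
    try:
        for rec in vcf:
            info = rec.INFO
            verdicts = {}
            for pred, key in config.predictor_keys.items():
                tok = info.get(key)
                if tok is not None:
                    verdicts[pred] = Verdict(str(tok).strip().lower())
            gt_type = rec.gt_types[0] if len(rec.gt_types) else 2
            genotype = {0: Genotype.UNKNOWN, 1: Genotype.HET, 3: Genotype.HOM_ALT}.get(
                int(gt_type), Genotype.UNKNOWN
            )
            vaf = 0.0
            vf = rec.format("VF")
            if vf is not None:
                vaf = float(vf[0][0])
            else:
                ad = rec.format("AD")
                if ad is not None:
                    ref_d, alt_d = float(ad[0][0]), float(ad[0][1])
                    depth = ref_d + alt_d
                    vaf = alt_d / depth if depth > 0 else 0.0
            af = info.get(config.af_key)
            out.append(
                AnnotatedVariant(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=rec.ALT[0] if rec.ALT else "N",
                    gene_symbol=str(info.get(config.gene_key) or ""),
                    consequence=_parse_consequence(info.get(config.consequence_key)),
                    population_af=float(af) if af is not None else 0.0,
                    clinvar=_parse_clinvar(info.get(config.clinvar_key)),
                    vaf=min(max(vaf, 0.0), 1.0),
                    genotype=genotype,
                    predictor_panel=PredictorPanel(verdicts),
                )
            )
    finally:
        vcf.close()
    return out


def write_patient_vcf(
    variants: Sequence[AnnotatedVariant],
    path: str | Path,
    sample_id: str,
    config: VcfFieldConfig = VcfFieldConfig(),
) -> None:
    """Emit a VCF 4.2 single-sample file readable by :func:`read_patient_vcf`."""
    lines = ["##fileformat=VCFv4.2", f"##source=germdmg-synthetic sample={sample_id}"]
    for chrom, length in AUTOSOME_LENGTHS.items():
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append(f"##contig=<ID=X,length={X_LENGTH}>")
    lines.append(
        f'##INFO=<ID={config.gene_key},Number=1,Type=String,Description="Gene symbol">'
    )
    lines.append(
        f'##INFO=<ID={config.af_key},Number=1,Type=Float,Description="Max control population AF">'
    )
    lines.append(
        f'##INFO=<ID={config.clinvar_key},Number=1,Type=String,Description="ClinVar assertion">'
    )
    lines.append(
        f'##INFO=<ID={config.consequence_key},Number=1,Type=String,Description="Predicted consequence">'
    )
    for pred, key in config.predictor_keys.items():
        lines.append(
            f'##INFO=<ID={key},Number=1,Type=String,Description="{pred} verdict">'
        )
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    lines.append(
        '##FORMAT=<ID=VF,Number=1,Type=Float,Description="Variant allele fraction">'
    )
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_id
    )
    for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
        info_parts = [
            f"{config.gene_key}={v.gene_symbol}",
            f"{config.af_key}={v.population_af:.6g}",
            f"{config.consequence_key}={v.consequence.value}",
        ]
        if v.clinvar is not ClinVar.ABSENT:
            info_parts.append(f"{config.clinvar_key}={v.clinvar.value}")
        for pred, key in config.predictor_keys.items():
            verdict = v.predictor_panel.verdicts[pred]
            if verdict is not Verdict.MISSING:
                info_parts.append(f"{key}={verdict.value}")
        gt = {"het": "0/1", "hom_alt": "1/1", "unknown": "./."}[v.genotype.value]
        depth = 100
        alt_d = round(v.vaf * depth)
        sample = f"{gt}:{depth - alt_d},{alt_d}:{v.vaf:.6f}"
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t"
            + ";".join(info_parts)
            + "\tGT:AD:VF\t"
            + sample
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
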