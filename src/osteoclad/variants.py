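"""Somatic variant records and their readers/writers.

Two on-disk dialects carry the same information:

* ``annotated_tsv`` — a ``#``-headed TSV with fixed annotation columns plus one
  ``presence:<sample>`` column per sample; ``.`` marks missing scores.
* ``vcf_subset`` — VCF v4.2 with per-sample ``GT`` and the GATK INFO keys
  (QD, MQ, FS, SOR, MQRankSum, ReadPosRankSum) plus annotation INFO keys.
  Reading goes through :mod:`cyvcf2`; writing emits plain VCF text.

Positions are 1-based (VCF convention). Absent scores stay absent — readers
never impute.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._tsv import read_hashed_tsv, write_hashed_tsv
from .errors import ParseError

EFFECTS = ("synonymous", "missense", "truncating", "splice", "noncoding")

SCORE_KEYS = ("sift", "polyphen2", "mutation_taster", "gerp", "cadd", "phylop")
QUALITY_KEYS = ("qd", "mq", "fs", "sor", "mq_rank_sum", "read_pos_rank_sum")

_VCF_INFO_OF_QUALITY = {
    "qd": "QD",
    "mq": "MQ",
    "fs": "FS",
    "sor": "SOR",
    "mq_rank_sum": "MQRankSum",
    "read_pos_rank_sum": "ReadPosRankSum",
}
_VCF_INFO_OF_SCORE = {
    "sift": "SIFT",
    "polyphen2": "POLYPHEN2",
    "mutation_taster": "MUTATION_TASTER",
    "gerp": "GERP",
    "cadd": "CADD",
    "phylop": "PHYLOP",
}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))


@dataclass
class VariantRecord:
    """One somatic SNV or indel with annotations and per-sample presence."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str = "."
    effect: str = "noncoding"
    context: str | None = None  # reference-strand trinucleotide, SNVs only
    scores: dict[str, float] = field(default_factory=dict)
    quality: dict[str, float] = field(default_factory=dict)
    presence: dict[str, int] = field(default_factory=dict)
    clonality: str | None = None  # {"clonal", "subclonal"} or unset

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ParseError(f"variant {self.chrom}:{self.pos}: position must be >= 1")
        if self.ref == self.alt:
            raise ParseError(f"variant {self.chrom}:{self.pos}: ref == alt ({self.ref})")
        if self.effect not in EFFECTS:
            raise ParseError(f"variant {self.chrom}:{self.pos}: unknown effect {self.effect!r}")
        if self.presence and not any(self.presence.values()):
            raise ParseError(f"variant {self.chrom}:{self.pos}: present in no sample")
        if self.is_snv and self.context is not None:
            if len(self.context) != 3 or self.context[1].upper() != self.ref.upper():
                raise ParseError(
                    f"variant {self.chrom}:{self.pos}: context {self.context!r} middle base != ref {self.ref!r}"
                )

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    def samples_present(self) -> list[str]:
        return [s for s, v in self.presence.items() if v]


def _fmt(v: float | None) -> str:
    if v is None:
        return "."
    return f"{v:g}"


def _parse_float(v) -> float | None:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v in (".", ""):
        return None
    return float(v)


# ---------------------------------------------------------------------------
# annotated TSV dialect
# ---------------------------------------------------------------------------

_FIXED_COLS = ["chrom", "pos", "ref", "alt", "gene", "effect", "context", "clonality"]


def _read_tsv(path: str | Path) -> list[VariantRecord]:
    df = read_hashed_tsv(path, required=tuple(_FIXED_COLS[:6]))
    sample_cols = [c for c in df.columns if c.startswith("presence:")]
    if not sample_cols:
        raise ParseError(f"{path}: no 'presence:<sample>' columns")
    records = []
    for i, row in df.iterrows():
        try:
            scores = {k: _parse_float(row.get(k)) for k in SCORE_KEYS}
            quality = {k: _parse_float(row.get(k)) for k in QUALITY_KEYS}
            rec = VariantRecord(
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                ref=str(row["ref"]),
                alt=str(row["alt"]),
                gene=str(row["gene"]),
                effect=str(row["effect"]),
                context=None if pd.isna(row.get("context")) else str(row["context"]),
                scores={k: v for k, v in scores.items() if v is not None},
                quality={k: v for k, v in quality.items() if v is not None},
                presence={c.split(":", 1)[1]: int(row[c]) for c in sample_cols},
                clonality=None if pd.isna(row.get("clonality")) else str(row["clonality"]),
            )
        except (ValueError, TypeError, ParseError) as exc:
            raise ParseError(f"{path}: row {i + 1}: {exc}") from exc
        records.append(rec)
    return records


def _write_tsv(records: list[VariantRecord], path: str | Path) -> None:
    samples = sorted({s for r in records for s in r.presence})
    rows = []
    for r in records:
        row = {
            "chrom": r.chrom,
            "pos": r.pos,
            "ref": r.ref,
            "alt": r.alt,
            "gene": r.gene,
            "effect": r.effect,
            "context": r.context if r.context else None,
            "clonality": r.clonality,
        }
        for k in SCORE_KEYS:
            row[k] = _fmt(r.scores.get(k))
        for k in QUALITY_KEYS:
            row[k] = _fmt(r.quality.get(k))
        for s in samples:
            row[f"presence:{s}"] = r.presence.get(s, 0)
        rows.append(row)
    cols = _FIXED_COLS + list(SCORE_KEYS) + list(QUALITY_KEYS) + [f"presence:{s}" for s in samples]
    write_hashed_tsv(
        pd.DataFrame(rows, columns=cols),
        path,
        preamble=["annotated somatic variant table; pos is 1-based; '.' = missing"],
    )


# ---------------------------------------------------------------------------
# VCF v4.2 subset dialect
# ---------------------------------------------------------------------------

def _read_vcf(path: str | Path) -> list[VariantRecord]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ParseError(f"{path}: VCF has no sample columns")
    records = []
    for v in vcf:
        # htslib hands INFO floats back as float32; normalise to the writer's
        # 6-significant-digit precision so round-trips are exact
        scores = {}
        for key, info_key in _VCF_INFO_OF_SCORE.items():
            val = v.INFO.get(info_key)
            if val is not None:
                scores[key] = float(f"{float(val):.6g}")
        quality = {}
        for key, info_key in _VCF_INFO_OF_QUALITY.items():
            val = v.INFO.get(info_key)
            if val is not None:
                quality[key] = float(f"{float(val):.6g}")
        gene = v.INFO.get("GENE") or "."
        effect = v.INFO.get("EFFECT") or "noncoding"
        context = v.INFO.get("CONTEXT") or None
        clonality = v.INFO.get("CLONALITY") or None
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        presence = {s: int(g in (1, 3)) for s, g in zip(samples, v.gt_types)}
        try:
            records.append(
                VariantRecord(
                    chrom=v.CHROM,
                    pos=v.POS,
                    ref=v.REF,
                    alt=v.ALT[0],
                    gene=gene,
                    effect=effect,
                    context=context,
                    scores=scores,
                    quality=quality,
                    presence=presence,
                    clonality=clonality,
                )
            )
        except ParseError as exc:
            raise ParseError(f"{path}: {v.CHROM}:{v.POS}: {exc}") from exc
    return records


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">
##INFO=<ID=FS,Number=1,Type=Float,Description="FisherStrand phred p">
##INFO=<ID=SOR,Number=1,Type=Float,Description="Symmetric odds ratio">
##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Mapping quality rank sum">
##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read position rank sum">
##INFO=<ID=SIFT,Number=1,Type=Float,Description="SIFT score">
##INFO=<ID=POLYPHEN2,Number=1,Type=Float,Description="PolyPhen2 score">
##INFO=<ID=MUTATION_TASTER,Number=1,Type=Float,Description="MutationTaster score">
##INFO=<ID=GERP,Number=1,Type=Float,Description="GERP++ score">
##INFO=<ID=CADD,Number=1,Type=Float,Description="CADD phred score">
##INFO=<ID=PHYLOP,Number=1,Type=Float,Description="PhyloP score">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=EFFECT,Number=1,Type=String,Description="Coding effect category">
##INFO=<ID=CONTEXT,Number=1,Type=String,Description="Reference-strand trinucleotide context">
##INFO=<ID=CLONALITY,Number=1,Type=String,Description="clonal or subclonal">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def _write_vcf(records: list[VariantRecord], path: str | Path) -> None:
    samples = sorted({s for r in records for s in r.presence})
    chroms = sorted({r.chrom for r in records})
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_VCF_HEADER)
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for r in records:
            info = []
            for key, info_key in _VCF_INFO_OF_QUALITY.items():
                if key in r.quality:
                    info.append(f"{info_key}={r.quality[key]:g}")
            for key, info_key in _VCF_INFO_OF_SCORE.items():
                if key in r.scores:
                    info.append(f"{info_key}={r.scores[key]:g}")
            if r.gene and r.gene != ".":
                info.append(f"GENE={r.gene}")
            info.append(f"EFFECT={r.effect}")
            if r.context:
                info.append(f"CONTEXT={r.context}")
            if r.clonality:
                info.append(f"CLONALITY={r.clonality}")
            gts = "\t".join("0/1" if r.presence.get(s, 0) else "0/0" for s in samples)
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\t.\t{';'.join(info) or '.'}\tGT\t{gts}\n"
            )


def read_variant_table(path: str | Path, dialect: str = "annotated_tsv") -> list[VariantRecord]:
    """Read variants from ``annotated_tsv`` or ``vcf_subset`` (see module docs)."""
    if dialect == "annotated_tsv":
        return _read_tsv(path)
    if dialect == "vcf_subset":
        return _read_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_variant_table(records: list[VariantRecord], path: str | Path,
                        dialect: str = "annotated_tsv") -> None:
    if dialect == "annotated_tsv":
        _write_tsv(records, path)
    elif dialect == "vcf_subset":
        _write_vcf(records, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
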