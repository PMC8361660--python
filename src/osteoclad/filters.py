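"""Hard quality filtering and in-silico pathogenicity prioritization.

The hard filters mirror the GATK-style site annotations, retained only when
every PRESENT metric satisfies its strict inequality (absent rank-sum
annotations are undefined for some genotype configurations and never fail a
record):

    QD > 10.0, MQ > 40.0, FS < 30.0, SOR < 3.0,
    MQRankSum > -12.5, ReadPosRankSum > -8.0

Prioritization keeps protein-truncating and splice-site variants outright,
keeps curated known-pathogenic (gene, change) entries, and otherwise requires
ALL six in-silico scores to be present and passing:

    SIFT < 0.05, PolyPhen2 > 0.7, MutationTaster > 0.7,
    GERP++ > 0, CADD > 10, PhyloP > 0

All inequalities are strict; boundary values fail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .variants import VariantRecord, revcomp

# (threshold, direction): value passes iff value OP threshold, strictly.
_HARD_DEFAULTS = {
    "qd": (10.0, ">"),
    "mq": (40.0, ">"),
    "fs": (30.0, "<"),
    "sor": (3.0, "<"),
    "mq_rank_sum": (-12.5, ">"),
    "read_pos_rank_sum": (-8.0, ">"),
}

_PATHO_DEFAULTS = {
    "sift": (0.05, "<"),
    "polyphen2": (0.7, ">"),
    "mutation_taster": (0.7, ">"),
    "gerp": (0.0, ">"),
    "cadd": (10.0, ">"),
    "phylop": (0.0, ">"),
}

PYRIMIDINE_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


@dataclass
class FilterPolicy:
    """Threshold bundle for hard filtering and prioritization.

    ``curated_pathogenic`` is a set of ``(gene, "ref>alt@pos")`` or plain
    ``(gene, change)`` labels supplied as an input file — membership rescues a
    variant regardless of scores (no database lookup is performed).
    """

    hard: dict[str, tuple[float, str]] = field(default_factory=lambda: dict(_HARD_DEFAULTS))
    pathogenicity: dict[str, tuple[float, str]] = field(default_factory=lambda: dict(_PATHO_DEFAULTS))
    keep_truncating_splice: bool = True
    curated_pathogenic: set[tuple[str, str]] = field(default_factory=set)


def _passes(value: float, threshold: float, direction: str) -> bool:
    return value > threshold if direction == ">" else value < threshold


def apply_hard_filters(
    variants: list[VariantRecord], policy: FilterPolicy | None = None
) -> tuple[list[VariantRecord], dict[str, list[str]]]:
    """Apply the strict hard-quality filters.

    Returns ``(retained, reasons)`` where ``reasons`` maps the key of every
    REMOVED variant to the list of violated metric names. A record is retained
    iff every present metric passes; absent metrics never fail a record.
    Idempotent: re-filtering the retained set removes nothing.
    """
    policy = policy or FilterPolicy()
    retained: list[VariantRecord] = []
    reasons: dict[str, list[str]] = {}
    for rec in variants:
        failed = [
            name
            for name, (thr, op) in policy.hard.items()
            if name in rec.quality and not _passes(rec.quality[name], thr, op)
        ]
        if failed:
            reasons[rec.key] = failed
        else:
            retained.append(rec)
    return retained, reasons


def prioritize_pathogenic(
    variants: list[VariantRecord], policy: FilterPolicy | None = None
) -> list[VariantRecord]:
    """Keep putatively pathogenic variants.

    Keep iff effect is truncating/splice (override, regardless of scores), OR
    the (gene, change) pair is curated-pathogenic, OR ALL six in-silico scores
    are present and strictly passing. A record missing any score cannot pass
    the in-silico route.
    """
    policy = policy or FilterPolicy()
    kept = []
    for rec in variants:
        if policy.keep_truncating_splice and rec.effect in ("truncating", "splice"):
            kept.append(rec)
            continue
        change = f"{rec.ref}>{rec.alt}@{rec.pos}"
        if (rec.gene, change) in policy.curated_pathogenic or (rec.gene, f"{rec.ref}>{rec.alt}") in policy.curated_pathogenic:
            kept.append(rec)
            continue
        ok = all(
            name in rec.scores and _passes(rec.scores[name], thr, op)
            for name, (thr, op) in policy.pathogenicity.items()
        )
        if ok:
            kept.append(rec)
    return kept


def spectrum_6(variants: list[VariantRecord]) -> dict[str, int]:
    """Six-class substitution spectrum in the pyrimidine convention.

    Purine-reference SNVs are complemented into the corresponding pyrimidine
    class (e.g. G>A counts as C>T). Non-SNV records are skipped with a notice.
    Returns counts over ``C>A, C>G, C>T, T>A, T>C, T>G`` summing to the SNV
    count.
    """
    counts = {cls: 0 for cls in PYRIMIDINE_CLASSES}
    skipped = 0
    for rec in variants:
        if not rec.is_snv:
            skipped += 1
            continue
        ref, alt = rec.ref.upper(), rec.alt.upper()
        if ref in "AG":
            ref, alt = revcomp(ref), revcomp(alt)
        counts[f"{ref}>{alt}"] += 1
    if skipped:
        import warnings

        warnings.warn(f"spectrum_6: skipped {skipped} non-SNV record(s)", stacklevel=2)
    return counts


def spectrum_6_vector(variants: list[VariantRecord]) -> np.ndarray:
    c = spectrum_6(variants)
    return np.array([c[k] for k in PYRIMIDINE_CLASSES], dtype=int)
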