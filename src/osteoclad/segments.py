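"""Allele-specific copy-number segment profiles (SEG-like TSV).

Segment coordinates are 0-based half-open. ``total_cn = major_cn + minor_cn``
with ``minor_cn <= major_cn``. Within a sample and chromosome, segments must
be sorted and non-overlapping; readers reject violations rather than repairing
them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._tsv import read_hashed_tsv, write_hashed_tsv
from .errors import ParseError
from .genome import GenomeBuild

_SEX_NAMES = {"X", "Y", "chrX", "chrY"}


@dataclass(frozen=True)
class Segment:
    chrom: str
    start: int
    end: int
    total_cn: int
    major_cn: int
    minor_cn: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ParseError(f"segment {self.chrom}:{self.start}-{self.end}: start >= end")
        if self.total_cn < 0 or self.minor_cn < 0:
            raise ParseError(f"segment {self.chrom}:{self.start}-{self.end}: negative copy number")
        if self.minor_cn > self.major_cn:
            raise ParseError(
                f"segment {self.chrom}:{self.start}-{self.end}: minor_cn {self.minor_cn} > major_cn {self.major_cn}"
            )
        if self.total_cn != self.major_cn + self.minor_cn:
            raise ParseError(
                f"segment {self.chrom}:{self.start}-{self.end}: total_cn != major_cn + minor_cn"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def state(self) -> tuple[int, int]:
        return (self.major_cn, self.minor_cn)


@dataclass
class SegmentProfile:
    """Per-sample allele-specific copy-number profile."""

    sample_id: str
    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.segments = sorted(self.segments, key=lambda s: (s.chrom, s.start))
        by_chrom: dict[str, Segment] = {}
        for seg in self.segments:
            prev = by_chrom.get(seg.chrom)
            if prev is not None and seg.start < prev.end:
                raise ParseError(
                    f"sample {self.sample_id}: overlapping segments on {seg.chrom}: "
                    f"{prev.start}-{prev.end} and {seg.start}-{seg.end}"
                )
            by_chrom[seg.chrom] = seg

    def chrom_segments(self, chrom: str) -> list[Segment]:
        return [s for s in self.segments if s.chrom == chrom]

    def autosomal_segments(self, genome: GenomeBuild | None = None) -> list[Segment]:
        if genome is not None:
            auto = {c.name for c in genome.autosomes}
            return [s for s in self.segments if s.chrom in auto]
        return [s for s in self.segments if s.chrom not in _SEX_NAMES]

    def ploidy(self, genome: GenomeBuild | None = None) -> float:
        """Length-weighted mean total copy number over autosomal segments."""
        segs = self.autosomal_segments(genome)
        total = sum(s.length for s in segs)
        if total == 0:
            raise ParseError(f"sample {self.sample_id}: no autosomal segments")
        return sum(s.length * s.total_cn for s in segs) / total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.sample_id,
                "chrom": [s.chrom for s in self.segments],
                "start": [s.start for s in self.segments],
                "end": [s.end for s in self.segments],
                "total_cn": [s.total_cn for s in self.segments],
                "major_cn": [s.major_cn for s in self.segments],
                "minor_cn": [s.minor_cn for s in self.segments],
            }
        )


def read_segment_file(path: str | Path) -> dict[str, SegmentProfile]:
    """Read a SEG-like TSV into one :class:`SegmentProfile` per sample."""
    df = read_hashed_tsv(path, required=("sample", "chrom", "start", "end", "total_cn", "major_cn", "minor_cn"))
    profiles: dict[str, list[Segment]] = {}
    for i, row in df.iterrows():
        try:
            seg = Segment(
                chrom=str(row["chrom"]),
                start=int(row["start"]),
                end=int(row["end"]),
                total_cn=int(row["total_cn"]),
                major_cn=int(row["major_cn"]),
                minor_cn=int(row["minor_cn"]),
            )
        except (ValueError, TypeError, ParseError) as exc:
            raise ParseError(f"{path}: row {i + 1}: {exc}") from exc
        profiles.setdefault(str(row["sample"]), []).append(seg)
    return {sid: SegmentProfile(sid, segs) for sid, segs in profiles.items()}


def write_segment_file(profiles: dict[str, SegmentProfile] | list[SegmentProfile], path: str | Path) -> None:
    if isinstance(profiles, dict):
        profiles = list(profiles.values())
    frames = [p.to_frame() for p in profiles]
    write_hashed_tsv(
        pd.concat(frames, ignore_index=True),
        path,
        preamble=["allele-specific copy-number segments; coordinates 0-based half-open"],
    )
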