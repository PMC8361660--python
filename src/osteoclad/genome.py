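"""Genome-build model: chromosome lengths, centromere intervals, arm geometry.

Coordinates are 0-based half-open throughout this module (BED/SEG convention);
variant positions elsewhere are 1-based (VCF convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from ._tsv import read_hashed_tsv, write_hashed_tsv
from .errors import ParseError

MB = 1_000_000


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    centromere_start: int
    centromere_end: int
    is_sex: bool = False

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ParseError(f"chromosome {self.name}: non-positive length {self.length}")
        if not (0 <= self.centromere_start < self.centromere_end <= self.length):
            raise ParseError(
                f"chromosome {self.name}: centromere [{self.centromere_start}, "
                f"{self.centromere_end}) out of range for length {self.length}"
            )


@dataclass(frozen=True)
class Arm:
    """One chromosome arm, 0-based half-open, excluding the centromere."""

    chrom: str
    start: int
    end: int
    arm: str  # "p" (telomere at start) or "q" (telomere at end)

    @property
    def length(self) -> int:
        return self.end - self.start


class GenomeBuild:
    """Ordered set of chromosomes with centromere anchors.

    Sex chromosomes are carried through I/O but excluded by the scar/burden
    computations downstream (exclusion happens at computation, not parsing).
    """

    def __init__(self, chromosomes: list[Chromosome]):
        names = [c.name for c in chromosomes]
        if len(set(names)) != len(names):
            raise ParseError("duplicate chromosome names in genome build")
        self.chromosomes: list[Chromosome] = list(chromosomes)
        self._by_name = {c.name: c for c in self.chromosomes}

    def __getitem__(self, name: str) -> Chromosome:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"chromosome {name!r} not in build") from None

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __len__(self) -> int:
        return len(self.chromosomes)

    @property
    def autosomes(self) -> list[Chromosome]:
        return [c for c in self.chromosomes if not c.is_sex]

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes)

    def arms(self, autosomes_only: bool = True) -> list[Arm]:
        out: list[Arm] = []
        for c in self.autosomes if autosomes_only else self.chromosomes:
            out.append(Arm(c.name, 0, c.centromere_start, "p"))
            out.append(Arm(c.name, c.centromere_end, c.length, "q"))
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [c.name for c in self.chromosomes],
                "length": [c.length for c in self.chromosomes],
                "centromere_start": [c.centromere_start for c in self.chromosomes],
                "centromere_end": [c.centromere_end for c in self.chromosomes],
                "is_sex": [int(c.is_sex) for c in self.chromosomes],
            }
        )


def load_genome_build(path: str | Path) -> GenomeBuild:
    """Read a genome-build table (columns: name, length, centromere_start,
    centromere_end, is_sex)."""
    df = read_hashed_tsv(path, required=("name", "length", "centromere_start", "centromere_end", "is_sex"))
    chroms = []
    for i, row in df.iterrows():
        try:
            chroms.append(
                Chromosome(
                    name=str(row["name"]),
                    length=int(row["length"]),
                    centromere_start=int(row["centromere_start"]),
                    centromere_end=int(row["centromere_end"]),
                    is_sex=bool(int(row["is_sex"])),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}: malformed row {i + 1}: {exc}") from exc
    return GenomeBuild(chroms)


def write_genome_build(build: GenomeBuild, path: str | Path) -> None:
    write_hashed_tsv(
        build.to_frame(),
        path,
        preamble=["genome build table; coordinates 0-based half-open"],
    )


def toy_build(n_chromosomes: int = 10, chrom_length: int = 100 * MB,
              centromere: tuple[int, int] = (45 * MB, 55 * MB)) -> GenomeBuild:
    """Small uniform build used throughout the test-suite and the simulator:
    ``n_chromosomes`` autosomes of ``chrom_length`` bp each with a centromere
    at ``centromere`` (defaults: 10 x 100 Mb, centromere [45, 55) Mb)."""
    return GenomeBuild(
        [
            Chromosome(f"c{i + 1}", chrom_length, centromere[0], centromere[1], is_sex=False)
            for i in range(n_chromosomes)
        ]
    )


def human_grch37() -> GenomeBuild:
    """GRCh37 chromosome lengths and centromere intervals, shipped as a static
    data file (provenance in the file header)."""
    with resources.as_file(resources.files("osteoclad.data") / "grch37_build.tsv") as p:
        return load_genome_build(p)
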