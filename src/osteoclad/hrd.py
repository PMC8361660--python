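"""Homologous-recombination-deficiency genomic-scar scores.

Three allele-specific copy-number scar counts are computed per sample on the
autosomes only (sex chromosomes are excluded at computation time):

* **LOH** — number of loss-of-heterozygosity regions (minor copy number 0,
  at least one copy retained) longer than 15 Mb that do not span an entire
  chromosome.
* **TAI** — number of allele-imbalanced regions (major != minor) longer than
  11 Mb that extend to a sub-telomere without crossing the centromere.
* **LST** — number of large-scale state transitions: after removing segments
  shorter than 3 Mb and merging identical flanking states, junctions between
  two segments each longer than 10 Mb whose allele-specific states differ,
  counted within chromosome arms.

Size cutoffs are strict ("longer than"); boundary-length regions do not
count. The composite is the plain sum, with positivity at a threshold of 42
or a pathogenic BRCA1/BRCA2 status (mutation route).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ParseError
from .genome import MB, GenomeBuild
from .segments import Segment, SegmentProfile

LOH_MIN_LENGTH = 15 * MB
TAI_MIN_LENGTH = 11 * MB
LST_MIN_SEGMENT = 10 * MB
LST_SMOOTH_BELOW = 3 * MB
HRD_POSITIVE_THRESHOLD = 42


@dataclass
class HRDResult:
    loh: int
    tai: int
    lst: int
    positive: bool | None = None
    brca_status: str = "wildtype"  # {"wildtype", "pathogenic"}
    lst_ploidy_adjusted: float | None = None

    @property
    def total(self) -> int:
        return self.loh + self.tai + self.lst

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.loh, self.tai, self.lst)


def _merge_identical(segments: list[Segment]) -> list[Segment]:
    """Merge contiguous segments with identical (total, major, minor) states."""
    merged: list[Segment] = []
    for seg in segments:
        if (
            merged
            and merged[-1].chrom == seg.chrom
            and merged[-1].end == seg.start
            and merged[-1].state == seg.state
            and merged[-1].total_cn == seg.total_cn
        ):
            prev = merged.pop()
            seg = Segment(seg.chrom, prev.start, seg.end, seg.total_cn, seg.major_cn, seg.minor_cn)
        merged.append(seg)
    return merged


def _runs(segments: list[Segment], predicate) -> list[tuple[int, int]]:
    """Maximal contiguous runs of segments satisfying ``predicate`` -> (start, end)."""
    runs: list[tuple[int, int]] = []
    cur: tuple[int, int] | None = None
    prev_end = None
    for seg in segments:
        if predicate(seg):
            if cur is not None and prev_end == seg.start:
                cur = (cur[0], seg.end)
            else:
                if cur is not None:
                    runs.append(cur)
                cur = (seg.start, seg.end)
            prev_end = seg.end
        else:
            if cur is not None:
                runs.append(cur)
                cur = None
            prev_end = None
    if cur is not None:
        runs.append(cur)
    return runs


def loh_score(profile: SegmentProfile, genome: GenomeBuild,
              exclude_whole_chromosome: bool = True) -> int:
    count = 0
    for chrom in genome.autosomes:
        segs = _merge_identical(profile.chrom_segments(chrom.name))
        for start, end in _runs(segs, lambda s: s.minor_cn == 0 and s.total_cn >= 1):
            if end - start <= LOH_MIN_LENGTH:
                continue
            if exclude_whole_chromosome and start == 0 and end == chrom.length:
                continue
            count += 1
    return count


def tai_score(profile: SegmentProfile, genome: GenomeBuild,
              telomere_window: int = 0) -> int:
    """Telomeric allelic imbalance count.

    ``telomere_window`` relaxes the requirement that the imbalanced region
    reach the exact chromosome-end coordinate (for noisy segmentations);
    the default demands an exact touch.
    """
    count = 0
    for chrom in genome.autosomes:
        segs = _merge_identical(profile.chrom_segments(chrom.name))
        for start, end in _runs(segs, lambda s: s.major_cn != s.minor_cn):
            if end - start <= TAI_MIN_LENGTH:
                continue
            touches_p = start <= telomere_window
            touches_q = end >= chrom.length - telomere_window
            within_p = end <= chrom.centromere_start
            within_q = start >= chrom.centromere_end
            if (touches_p and within_p) or (touches_q and within_q):
                count += 1
    return count


def _clip_to_arm(segments: list[Segment], arm_start: int, arm_end: int) -> list[Segment]:
    out = []
    for s in segments:
        lo, hi = max(s.start, arm_start), min(s.end, arm_end)
        if lo < hi:
            out.append(Segment(s.chrom, lo, hi, s.total_cn, s.major_cn, s.minor_cn))
    return out


def lst_score(profile: SegmentProfile, genome: GenomeBuild) -> int:
    """Raw large-scale-transition count (no ploidy correction)."""
    count = 0
    for chrom in genome.autosomes:
        segs = profile.chrom_segments(chrom.name)
        for arm_start, arm_end in ((0, chrom.centromere_start), (chrom.centromere_end, chrom.length)):
            arm = _clip_to_arm(segs, arm_start, arm_end)
            # merge identical contiguous states BEFORE the small-segment
            # filter: scores must be invariant under segment splitting
            arm = _merge_identical(arm)
            arm = [s for s in arm if s.length >= LST_SMOOTH_BELOW]
            # after the deletion, list-neighbours separated only by removed
            # short segments are treated as flanking; identical states merge
            merged: list[Segment] = []
            for s in arm:
                if merged and merged[-1].state == s.state and merged[-1].total_cn == s.total_cn \
                        and s.start - merged[-1].end < LST_SMOOTH_BELOW:
                    prev = merged.pop()
                    s = Segment(s.chrom, prev.start, s.end, s.total_cn, s.major_cn, s.minor_cn)
                merged.append(s)
            for left, right in zip(merged, merged[1:]):
                if right.start - left.end >= LST_SMOOTH_BELOW:
                    continue  # genuine coverage gap, not a breakpoint
                if left.length > LST_MIN_SEGMENT and right.length > LST_MIN_SEGMENT \
                        and (left.state != right.state or left.total_cn != right.total_cn):
                    count += 1
    return count


def hrd_scores(profile: SegmentProfile, genome: GenomeBuild,
               exclude_whole_chromosome_loh: bool = True,
               telomere_window: int = 0,
               ploidy_adjust_lst: bool = False) -> HRDResult:
    """Compute the three scar components for one sample.

    ``ploidy_adjust_lst`` additionally reports a linear ploidy correction of
    the LST count (2.5 transitions per ploidy unit above diploid, interpolating
    the published diploid/tetraploid cutoff shift); the composite always uses
    the raw count.
    """
    if not profile.segments:
        raise ParseError(f"sample {profile.sample_id}: empty profile")
    loh = loh_score(profile, genome, exclude_whole_chromosome=exclude_whole_chromosome_loh)
    tai = tai_score(profile, genome, telomere_window=telomere_window)
    lst = lst_score(profile, genome)
    adjusted = None
    if ploidy_adjust_lst:
        adjusted = max(0.0, lst - 2.5 * (profile.ploidy(genome) - 2.0))
    result = HRDResult(loh=loh, tai=tai, lst=lst, lst_ploidy_adjusted=adjusted)
    result.positive = result.total >= HRD_POSITIVE_THRESHOLD
    return result


def hrd_classify(components: tuple[int, int, int] | HRDResult,
                 threshold: int = HRD_POSITIVE_THRESHOLD,
                 brca_status: str = "wildtype",
                 strictly_greater: bool = False) -> HRDResult:
    """Composite positivity call: total >= threshold (default 42) OR pathogenic
    BRCA1/BRCA2 status. ``strictly_greater`` switches the score route to
    ``total > threshold``."""
    if isinstance(components, HRDResult):
        loh, tai, lst = components.as_tuple()
    else:
        loh, tai, lst = components
    if min(loh, tai, lst) < 0:
        raise ValueError("scar components must be non-negative")
    if brca_status not in ("wildtype", "pathogenic"):
        raise ValueError(f"unknown brca_status {brca_status!r}")
    total = loh + tai + lst
    score_positive = total > threshold if strictly_greater else total >= threshold
    return HRDResult(
        loh=loh,
        tai=tai,
        lst=lst,
        positive=bool(score_positive or brca_status == "pathogenic"),
        brca_status=brca_status,
    )
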