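"""Copy-number alteration analytics: burden, similarity, event classification,
and complex-rearrangement (chromothripsis / staircase) detection.

All computations run on autosomes only and classify relative to a diploid
baseline (total copy number 2). The focal/broad boundary follows the common
cytogenetic threshold of 10 Mb (strictly less than = focal); amplification
means total copy number of 5 or more, biallelic deletion total copy number 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParseError
from .genome import MB, GenomeBuild
from .segments import Segment, SegmentProfile

FOCAL_THRESHOLD = 10 * MB
AMP_THRESHOLD = 5


@dataclass
class CNAEvent:
    chrom: str
    start: int
    end: int
    kind: str  # {gain, loss, amplification, biallelic_deletion}
    scope: str | None = None  # {focal, broad}
    complex_kind: str | None = None  # {chromothripsis, staircase_centromeric, staircase_telomeric}
    max_total_cn: int | None = None
    n_switches: int | None = None

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_gain(self) -> bool:
        return self.kind in ("gain", "amplification")

    @property
    def is_loss(self) -> bool:
        return self.kind in ("loss", "biallelic_deletion")


def altered_fraction(profile: SegmentProfile, genome: GenomeBuild) -> float:
    """Fraction of the autosomal genome with total copy number != 2.

    Uncovered autosomal bases are treated as copy-neutral; the denominator is
    the total autosomal length of the build.
    """
    segs = profile.autosomal_segments(genome)
    if not segs:
        raise ParseError(f"sample {profile.sample_id}: no autosomal segments")
    altered = sum(s.length for s in segs if s.total_cn != 2)
    denom = sum(c.length for c in genome.autosomes)
    return altered / denom


def _direction_track(profile: SegmentProfile, chrom: str, breaks: np.ndarray) -> np.ndarray:
    """Per-interval direction (-1 loss, 0 neutral, +1 gain) over ``breaks`` intervals."""
    out = np.zeros(len(breaks) - 1, dtype=int)
    for s in profile.chrom_segments(chrom):
        if s.total_cn == 2:
            continue
        i = np.searchsorted(breaks, s.start, side="left")
        j = np.searchsorted(breaks, s.end, side="left")
        out[i:j] = 1 if s.total_cn > 2 else -1
    return out


def jaccard_cna(profile_a: SegmentProfile, profile_b: SegmentProfile,
                genome: GenomeBuild) -> float:
    """Jaccard similarity of copy-number alteration footprints.

    Each autosomal base is classified as loss/neutral/gain against a diploid
    baseline; the similarity is (bases altered in BOTH samples with the same
    direction) / (bases altered in either). Two fully neutral profiles are
    defined as similarity 1.0 (with a notice).
    """
    inter = 0
    union = 0
    for chrom in genome.autosomes:
        pts = {0, chrom.length}
        for p in (profile_a, profile_b):
            for s in p.chrom_segments(chrom.name):
                pts.add(s.start)
                pts.add(s.end)
        breaks = np.array(sorted(pts))
        lengths = np.diff(breaks)
        da = _direction_track(profile_a, chrom.name, breaks)
        db = _direction_track(profile_b, chrom.name, breaks)
        altered_either = (da != 0) | (db != 0)
        same_dir = (da == db) & (da != 0)
        union += int(lengths[altered_either].sum())
        inter += int(lengths[same_dir].sum())
    if union == 0:
        import warnings

        warnings.warn("jaccard_cna: both profiles fully copy-neutral; similarity defined as 1.0",
                      stacklevel=2)
        return 1.0
    return inter / union


def classify_cna_events(profile: SegmentProfile, genome: GenomeBuild,
                        amp_threshold: int = AMP_THRESHOLD,
                        focal_threshold: int = FOCAL_THRESHOLD) -> list[CNAEvent]:
    """Classify altered regions into gain / loss / amplification /
    biallelic_deletion events with a focal/broad scope.

    Adjacent segments of the same kind are merged before the length-based
    scope call; a region is focal iff strictly shorter than
    ``focal_threshold``.
    """

    def kind_of(seg: Segment) -> str | None:
        if seg.total_cn == 0:
            return "biallelic_deletion"
        if seg.total_cn >= amp_threshold:
            return "amplification"
        if seg.total_cn > 2:
            return "gain"
        if seg.total_cn < 2:
            return "loss"
        return None

    events: list[CNAEvent] = []
    for chrom in genome.autosomes:
        cur: CNAEvent | None = None
        prev_end = None
        for seg in profile.chrom_segments(chrom.name):
            k = kind_of(seg)
            if k is None:
                cur = None
                prev_end = seg.end
                continue
            if cur is not None and cur.kind == k and prev_end == seg.start:
                cur.end = seg.end
                cur.max_total_cn = max(cur.max_total_cn, seg.total_cn)
            else:
                cur = CNAEvent(chrom.name, seg.start, seg.end, k, max_total_cn=seg.total_cn)
                events.append(cur)
            prev_end = seg.end
    for ev in events:
        ev.scope = "focal" if ev.length < focal_threshold else "broad"
    return events


@dataclass
class ComplexEventParams:
    min_oscillations: int = 10  # copy-state switches within a chromothripsis region
    max_states: int = 3  # distinct total-CN states allowed in the oscillation
    min_steps: int = 3  # strictly monotonic segments in a staircase
    anchor_window: int = 1 * MB  # distance from centromere edge / chromosome end


def _merged_totals(profile: SegmentProfile, chrom: str) -> list[Segment]:
    """Contiguous segments merged on equal total copy number."""
    merged: list[Segment] = []
    for s in profile.chrom_segments(chrom):
        if merged and merged[-1].end == s.start and merged[-1].total_cn == s.total_cn:
            prev = merged.pop()
            s = Segment(s.chrom, prev.start, s.end, s.total_cn, max(prev.major_cn, s.major_cn),
                        s.total_cn - max(prev.major_cn, s.major_cn))
        merged.append(s)
    return merged


def detect_complex_events(profile: SegmentProfile, genome: GenomeBuild,
                          params: ComplexEventParams | None = None) -> list[CNAEvent]:
    """Detect chromothripsis-like oscillations and centromere/telomere-anchored
    staircase amplifications.

    Chromothripsis: a maximal contiguous region whose total-CN sequence
    switches at least ``min_oscillations`` times among at most ``max_states``
    distinct states. Staircase: a run of at least ``min_steps`` strictly
    monotonically increasing total-CN segments whose highest-CN boundary lies
    within ``anchor_window`` of a centromere edge (centromeric) or chromosome
    end (telomeric).
    """
    params = params or ComplexEventParams()
    events: list[CNAEvent] = []
    for chrom in genome.autosomes:
        segs = _merged_totals(profile, chrom.name)
        # split at contiguity gaps
        blocks: list[list[Segment]] = []
        for s in segs:
            if blocks and blocks[-1][-1].end == s.start:
                blocks[-1].append(s)
            else:
                blocks.append([s])
        for block in blocks:
            events.extend(_chromothripsis_in_block(block, params))
            events.extend(_staircases_in_block(block, chrom, params))
    return events


def _chromothripsis_in_block(block: list[Segment], params: ComplexEventParams) -> list[CNAEvent]:
    n = len(block)
    totals = [s.total_cn for s in block]
    windows: list[tuple[int, int]] = []  # inclusive segment-index ranges
    j_max = 0
    for i in range(n):
        # extend the furthest window starting at i with <= max_states states
        states: dict[int, int] = {}
        j = i
        while j < n:
            states[totals[j]] = states.get(totals[j], 0) + 1
            if len(states) > params.max_states:
                break
            j += 1
        last = j - 1
        if last - i >= params.min_oscillations and last > j_max:
            windows.append((i, last))
            j_max = last
    out = []
    for i, j in windows:
        seg_lo, seg_hi = block[i], block[j]
        out.append(
            CNAEvent(
                chrom=seg_lo.chrom,
                start=seg_lo.start,
                end=seg_hi.end,
                kind="gain" if max(totals[i : j + 1]) > 2 else "loss",
                complex_kind="chromothripsis",
                max_total_cn=max(totals[i : j + 1]),
                n_switches=j - i,
            )
        )
    return out


def _staircases_in_block(block: list[Segment], chrom, params: ComplexEventParams) -> list[CNAEvent]:
    # the copy-neutral baseline is not a staircase step
    block = [s for s in block if s.total_cn != 2]
    out: list[CNAEvent] = []
    n = len(block)
    for direction in (+1, -1):  # +1: CN increases left->right, -1: decreases
        i = 0
        while i < n:
            j = i
            while j + 1 < n and block[j + 1].start == block[j].end and \
                    direction * (block[j + 1].total_cn - block[j].total_cn) > 0:
                j += 1
            if j - i + 1 >= params.min_steps:
                # boundary at the high-CN extreme of the run
                extreme = block[j].end if direction == +1 else block[i].start
                anchor = _anchor_kind(extreme, chrom, params.anchor_window)
                if anchor is not None:
                    out.append(
                        CNAEvent(
                            chrom=block[i].chrom,
                            start=block[i].start,
                            end=block[j].end,
                            kind="amplification" if max(s.total_cn for s in block[i : j + 1]) >= AMP_THRESHOLD else "gain",
                            complex_kind=f"staircase_{anchor}",
                            max_total_cn=max(s.total_cn for s in block[i : j + 1]),
                            n_switches=j - i,
                        )
                    )
                i = j + 1
            else:
                i += 1
    return out


def _anchor_kind(pos: int, chrom, window: int) -> str | None:
    if pos <= window or pos >= chrom.length - window:
        return "telomeric"
    if abs(pos - chrom.centromere_start) <= window or abs(pos - chrom.centromere_end) <= window:
        return "centromeric"
    return None
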