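"""HRD scar scores: strict boundaries, closed loop with the planting
constructor, equivalence with a bin-level brute-force reference, and
segmentation-split invariance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import osteoclad as oc
from osteoclad.errors import InfeasibleConfigError, ParseError
from osteoclad.segments import Segment, SegmentProfile

from conftest import MB, diploid_profile, profile_from_states, random_profile


# --- brute-force reference: direct definition scan at 1 Mb bins ------------


def _bin_tracks(profile, chrom_len_mb, chrom):
    total = np.full(chrom_len_mb, -1, dtype=int)
    major = np.full(chrom_len_mb, -1, dtype=int)
    minor = np.full(chrom_len_mb, -1, dtype=int)
    for s in profile.chrom_segments(chrom):
        total[s.start // MB: s.end // MB] = s.total_cn
        major[s.start // MB: s.end // MB] = s.major_cn
        minor[s.start // MB: s.end // MB] = s.minor_cn
    return total, major, minor


def _mask_runs(mask):
    runs, start = [], None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(mask)))
    return runs


def brute_force_hrd(profile, genome):
    loh = tai = lst = 0
    for chrom in genome.autosomes:
        L = chrom.length // MB
        cen_lo, cen_hi = chrom.centromere_start // MB, chrom.centromere_end // MB
        total, major, minor = _bin_tracks(profile, L, chrom.name)
        covered = total >= 0
        for a, b in _mask_runs(covered & (minor == 0) & (total >= 1)):
            if b - a > 15 and not (a == 0 and b == L):
                loh += 1
        for a, b in _mask_runs(covered & (major != minor)):
            if b - a <= 11:
                continue
            if (a == 0 and b <= cen_lo) or (b == L and a >= cen_hi):
                tai += 1
        for lo, hi in ((0, cen_lo), (cen_hi, L)):
            state = [(i, tuple(x)) for i, x in enumerate(zip(total[lo:hi], major[lo:hi], minor[lo:hi]))
                     if total[lo:hi][i] >= 0]
            # compress into runs of constant state
            runs = []
            for i, s in state:
                if runs and runs[-1][2] == s and runs[-1][1] == i:
                    runs[-1] = (runs[-1][0], i + 1, s)
                else:
                    runs.append((i, i + 1, s))
            runs = [r for r in runs if r[1] - r[0] >= 3]  # small-segment smoothing
            merged = []
            for r in runs:
                if merged and merged[-1][2] == r[2] and r[0] - merged[-1][1] < 3:
                    merged[-1] = (merged[-1][0], r[1], r[2])
                else:
                    merged.append(list(r) if False else (r[0], r[1], r[2]))
            for left, right in zip(merged, merged[1:]):
                if right[0] - left[1] >= 3:
                    continue
                if left[1] - left[0] > 10 and right[1] - right[0] > 10 and left[2] != right[2]:
                    lst += 1
    return loh, tai, lst


# --- explicit cases --------------------------------------------------------


def test_diploid_genome_scores_zero(toy_genome):
    res = oc.hrd_scores(diploid_profile(toy_genome), toy_genome)
    assert res.as_tuple() == (0, 0, 0)
    assert not res.positive


def test_interstitial_loh_counted_and_boundary_excluded(toy_genome):
    # 20 Mb copy-neutral LOH (major 2, minor 0), interstitial
    p = profile_from_states({"c1": [(5, 25, 2, 2, 0)]})
    assert oc.hrd_scores(p, toy_genome).loh == 1
    # exactly 15.0 Mb -> not "longer than 15 Mb"
    p = profile_from_states({"c1": [(5, 20, 2, 2, 0)]})
    assert oc.hrd_scores(p, toy_genome).loh == 0


def test_whole_chromosome_loh_excluded_by_default(toy_genome):
    p = profile_from_states({"c1": [(0, 100, 2, 2, 0)]})
    assert oc.hrd_scores(p, toy_genome).loh == 0
    assert oc.hrd_scores(p, toy_genome, exclude_whole_chromosome_loh=False).loh == 1


def test_tai_requires_telomere_touch_and_arm_containment(toy_genome):
    # 12 Mb imbalance at the p telomere, inside the arm
    p = profile_from_states({"c1": [(0, 12, 3, 2, 1)]})
    assert oc.hrd_scores(p, toy_genome).tai == 1
    # same segment interstitial -> no TAI
    p = profile_from_states({"c1": [(2, 14, 3, 2, 1)]})
    assert oc.hrd_scores(p, toy_genome).tai == 0
    # spans the centromere -> excluded
    p = profile_from_states({"c1": [(0, 60, 3, 2, 1)]})
    assert oc.hrd_scores(p, toy_genome).tai == 0
    # exactly 11 Mb -> excluded (strictly "more than")
    p = profile_from_states({"c1": [(0, 11, 3, 2, 1)]})
    assert oc.hrd_scores(p, toy_genome).tai == 0


def test_lst_junction_rules(toy_genome):
    # two long blocks with a state change inside the p arm -> 1 junction
    p = profile_from_states({"c1": [(12, 24, 3, 2, 1)]})  # flanked by long diploid
    assert oc.hrd_scores(p, toy_genome).lst == 2  # both junctions have >10 Mb flanks
    # short (<3 Mb) interruptions are smoothed away
    p = profile_from_states({"c1": [(12, 24, 3, 2, 1), (24, 26, 6, 3, 3), (26, 33, 3, 2, 1)]})
    assert oc.hrd_scores(p, toy_genome).lst == 2  # merged 12-33 block, same two junctions
    # both flanks must be strictly longer than 10 Mb: a 10 Mb block fails
    p = profile_from_states({"c1": [(35, 45, 3, 2, 1)]})
    assert oc.hrd_scores(p, toy_genome).lst == 0


def test_sex_chromosomes_ignored():
    g = oc.GenomeBuild([
        oc.genome.Chromosome("a1", 100 * MB, 45 * MB, 55 * MB),
        oc.genome.Chromosome("X", 100 * MB, 45 * MB, 55 * MB, is_sex=True),
    ])
    p = profile_from_states({"a1": [], "X": [(5, 30, 2, 2, 0), (60, 95, 5, 4, 1)]})
    assert oc.hrd_scores(p, g).as_tuple() == (0, 0, 0)


def test_empty_profile_rejected(toy_genome):
    with pytest.raises(ParseError, match="empty"):
        oc.hrd_scores(SegmentProfile("s", []), toy_genome)


def test_missing_allele_decomposition_rejected(tmp_path):
    # the Segment type itself enforces total = major + minor
    with pytest.raises(ParseError):
        Segment("c1", 0, MB, 3, 1, 1)


# --- composite classification ----------------------------------------------


@pytest.mark.parametrize("components,positive", [
    ((14, 14, 14), True),   # total 42 -> positive at the >=42 rule
    ((14, 14, 13), False),  # total 41
    ((42, 0, 0), True),
    ((0, 0, 0), False),
])
def test_composite_threshold(components, positive):
    assert oc.hrd_classify(components).positive is positive


def test_brca_route_overrides_score():
    res = oc.hrd_classify((0, 0, 0), brca_status="pathogenic")
    assert res.positive and res.total == 0


def test_strictly_greater_flag():
    assert not oc.hrd_classify((14, 14, 14), strictly_greater=True).positive
    assert oc.hrd_classify((15, 14, 14), strictly_greater=True).positive


# --- constructive closed loop ----------------------------------------------


@pytest.mark.parametrize("targets", [(0, 0, 0), (2, 1, 3), (1, 0, 0), (0, 1, 0),
                                     (0, 0, 1), (5, 3, 6), (14, 14, 14)])
def test_planted_targets_recovered_exactly(targets, toy_genome):
    p = oc.plant_scar_profile(targets, toy_genome, seed=3)
    assert oc.hrd_scores(p, toy_genome).as_tuple() == targets


def test_unachievable_targets_rejected(toy_genome):
    with pytest.raises(InfeasibleConfigError):
        oc.plant_scar_profile((0, 25, 0), toy_genome)  # more TAI than arms


# --- brute-force equivalence + split invariance ----------------------------


def test_scores_match_brute_force_on_random_profiles(toy_genome):
    rng = np.random.default_rng(2024)
    for _ in range(120):
        p = random_profile(rng, toy_genome)
        got = oc.hrd_scores(p, toy_genome).as_tuple()
        assert got == brute_force_hrd(p, toy_genome), p.to_frame().to_string()


def _split_randomly(profile, rng, n_splits=20):
    segs = list(profile.segments)
    for _ in range(n_splits):
        i = int(rng.integers(len(segs)))
        s = segs[i]
        if s.length < 2:
            continue
        cut = int(rng.integers(s.start + 1, s.end))
        segs[i: i + 1] = [
            Segment(s.chrom, s.start, cut, s.total_cn, s.major_cn, s.minor_cn),
            Segment(s.chrom, cut, s.end, s.total_cn, s.major_cn, s.minor_cn),
        ]
    return SegmentProfile(profile.sample_id, segs)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_scores_invariant_under_segment_splitting(seed):
    genome = oc.toy_build()
    rng = np.random.default_rng(seed)
    base = oc.plant_scar_profile((3, 2, 4), genome, seed=seed % 17)
    split = _split_randomly(base, rng)
    assert oc.hrd_scores(split, genome).as_tuple() == oc.hrd_scores(base, genome).as_tuple()
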