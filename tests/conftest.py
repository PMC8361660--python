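import numpy as np
import pytest

import osteoclad as oc
from osteoclad.segments import Segment, SegmentProfile

MB = 1_000_000


@pytest.fixture(scope="session")
def toy_genome():
    return oc.toy_build()


@pytest.fixture(scope="session")
def small_cohort():
    """One deterministic default cohort shared across tests."""
    return oc.simulate_cohort(oc.CohortConfig(seed=17))


def profile_from_states(states, sample_id="s", chrom_length=100 * MB):
    """Build a profile from {chrom: [(start_mb, end_mb, total, major, minor), ...]},
    filling uncovered stretches with diploid segments."""
    segs = []
    for chrom, rows in states.items():
        cursor = 0
        for start_mb, end_mb, t, M, m in sorted(rows):
            start, end = int(start_mb * MB), int(end_mb * MB)
            if start > cursor:
                segs.append(Segment(chrom, cursor, start, 2, 1, 1))
            segs.append(Segment(chrom, start, end, t, M, m))
            cursor = end
        if cursor < chrom_length:
            segs.append(Segment(chrom, cursor, chrom_length, 2, 1, 1))
    return SegmentProfile(sample_id, segs)


def diploid_profile(genome, sample_id="diploid"):
    segs = [Segment(c.name, 0, c.length, 2, 1, 1) for c in genome.chromosomes]
    return SegmentProfile(sample_id, segs)


@pytest.fixture
def make_profile():
    return profile_from_states


def random_profile(rng, genome, max_segments=25, bin_mb=1):
    """Random valid profile on 1-Mb-aligned boundaries, for oracle comparisons."""
    segs = []
    for chrom in genome.chromosomes:
        n_mb = chrom.length // MB
        n_breaks = int(rng.integers(0, max(1, max_segments // len(genome.chromosomes)) + 1))
        cuts = sorted(set(rng.integers(1, n_mb, size=n_breaks).tolist()))
        bounds = [0] + [c * bin_mb for c in cuts] + [n_mb]
        for lo, hi in zip(bounds, bounds[1:]):
            if lo == hi:
                continue
            major = int(rng.integers(0, 4))
            minor = int(rng.integers(0, major + 1))
            segs.append(Segment(chrom.name, lo * MB, hi * MB, major + minor, major, minor))
    return SegmentProfile("random", segs)
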