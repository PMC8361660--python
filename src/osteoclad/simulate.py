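"""Synthetic multi-sample tumor-cohort generator with full ground truth.

The generator emulates a discovery cohort of chemotherapy-naive primaries
with local/distal recurrences: ~12 patients with 2-4 samples each, somatic
SNVs placed on a per-patient clonal phylogeny, clock-like (aging-signature)
mutations accumulating linearly in calendar time, non-clock mutations drawn
from a configurable signature mixture, allele-specific copy-number profiles
with planted LOH/TAI/LST scars and optional chromothripsis/staircase events,
and driver genotypes obeying configured mutual-exclusivity rules.

Timeline convention: months relative to the primary biopsy (month 0). The
tumor originates ``origin_months_before_biopsy`` earlier; the first lineage
divergence happens ``divergence_months_after_origin`` after the origin;
recurrence samples are collected at positive months. Clock mutations on an
edge are Poisson with mean rate x edge duration; non-clock mutations are
assigned uniformly over positive-duration edges. Everything is deterministic
given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InfeasibleConfigError
from .exclusivity import AlterationMatrix
from .genome import MB, Arm, GenomeBuild, toy_build
from .phylo import Topology, leaves_of
from .segments import Segment, SegmentProfile
from .signatures import CHANNELS, SignatureMatrix, builtin_signatures
from .variants import VariantRecord

DRIVER_GENES = ("CCND3", "CDK4", "CDK6", "CCNE1", "RB1", "CDKN2A", "TP53", "MDM2", "BRCA1", "BRCA2")

DEFAULT_EXCLUSIVE_PAIRS = (("CDK4", "RB1"), ("CCND3", "RB1"), ("CCND3", "CCNE1"))


def driver_gene_table(genome: GenomeBuild) -> dict[str, tuple[str, int, int]]:
    """Synthetic driver-gene loci: 1 Mb windows spaced along the p arm of the
    second-to-last autosome (reserved for driver evidence by the simulator)."""
    chrom = genome.autosomes[-2]
    spacing = 4 * MB
    if len(DRIVER_GENES) * spacing > chrom.centromere_start:
        raise InfeasibleConfigError("driver loci do not fit the reserved chromosome arm")
    return {
        g: (chrom.name, k * spacing + MB, k * spacing + 2 * MB)
        for k, g in enumerate(DRIVER_GENES)
    }


@dataclass
class CohortConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults mirror the discovery design: 12 patients, 2-4 samples each,
    a clock rate of 8 mutations/month, origin 9 months before the primary
    biopsy, metastatic divergence 3 months after origin, recurrences
    collected 3-9 months after the primary, and an aging-dominated signature
    mixture. ``snv_count_range`` is a validation band for the expected
    per-sample totals implied by the rates (counts are emergent), matching
    the observed primary-tumor range.
    """

    n_patients: int = 12
    samples_per_patient: tuple[int, int] = (2, 4)
    clock_rate: float = 8.0  # clock mutations / month
    origin_months_before_biopsy: float = 9.0
    divergence_months_after_origin: float = 3.0
    recurrence_month_range: tuple[float, float] = (3.0, 9.0)
    signature_mix: dict[str, float] = field(
        default_factory=lambda: {"AC1": 0.7, "AC3": 0.1, "AC6": 0.1, "AC7": 0.1}
    )
    clock_signature: str = "AC1"
    snv_count_range: tuple[int, int] = (6, 144)
    scar_targets: tuple[int, int, int] = (5, 3, 6)  # (loh, tai, lst) per sample
    driver_rules: tuple[tuple[str, str], ...] = DEFAULT_EXCLUSIVE_PAIRS
    ns_s_ratio: float = 2.5  # planted non-synonymous : synonymous odds
    plant_complex_events: bool = True
    brca_pathogenic_prob: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise InfeasibleConfigError("need at least one patient")
        lo, hi = self.samples_per_patient
        if not (1 <= lo <= hi):
            raise InfeasibleConfigError(f"bad samples_per_patient {self.samples_per_patient}")
        if self.clock_rate <= 0:
            raise InfeasibleConfigError("clock_rate must be positive")
        if self.divergence_months_after_origin < 0 or (
            self.divergence_months_after_origin > self.origin_months_before_biopsy
        ):
            raise InfeasibleConfigError(
                "divergence must fall between origin and the primary biopsy"
            )
        total = sum(self.signature_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise InfeasibleConfigError(f"signature mix must sum to 1 (got {total})")
        if any(v < 0 for v in self.signature_mix.values()):
            raise InfeasibleConfigError("signature proportions must be non-negative")
        if self.signature_mix.get(self.clock_signature, 0.0) <= 0:
            raise InfeasibleConfigError("clock signature must have positive mix weight")
        expected_primary = self.clock_rate * self.origin_months_before_biopsy / self.signature_mix[
            self.clock_signature
        ]
        lo_n, hi_n = self.snv_count_range
        if not (lo_n <= expected_primary <= hi_n):
            raise InfeasibleConfigError(
                f"expected primary SNV total {expected_primary:.0f} outside snv_count_range {self.snv_count_range}"
            )


# ---------------------------------------------------------------------------
# scar planting
# ---------------------------------------------------------------------------

_DIPLOID = (2, 1, 1)  # (total, major, minor)


def _seg(chrom: str, start: float, end: float, state: tuple[int, int, int]) -> Segment:
    t, M, m = state
    return Segment(chrom, int(round(start)), int(round(end)), t, M, m)


def _mirror(arm: Arm, segs: list[tuple[float, float, tuple[int, int, int]]]):
    """Map tip-relative layouts onto the arm; 'tip' is the telomeric end."""
    out = []
    for lo, hi, state in segs:
        if arm.arm == "p":
            out.append((arm.start + lo, arm.start + hi, state))
        else:
            out.append((arm.end - hi, arm.end - lo, state))
    return [(min(a, b), max(a, b), s) for a, b, s in out]


def _fill_arm(arm: Arm, placed: list[tuple[float, float, tuple[int, int, int]]]):
    """Complete an arm's coverage with diploid filler."""
    placed = sorted(placed)
    segs = []
    cursor = arm.start
    for lo, hi, state in placed:
        if lo > cursor:
            segs.append((cursor, lo, _DIPLOID))
        segs.append((lo, hi, state))
        cursor = hi
    if cursor < arm.end:
        segs.append((cursor, arm.end, _DIPLOID))
    return segs


def _max_lst_on_arm(arm: Arm) -> int:
    return max(0, int(arm.length // (10 * MB + 1)) - 1)


def plant_scar_profile(targets: tuple[int, int, int], genome: GenomeBuild,
                       seed: int | None = None,
                       sample_id: str = "planted") -> SegmentProfile:
    """Construct a profile whose scar scores equal ``targets`` exactly.

    The construction allocates chromosome arms to scar units designed not to
    interact: telomere-anchored >11 Mb imbalanced blocks for TAI, interstitial
    >15 Mb copy-neutral LOH blocks isolated by short balanced buffers, and
    alternating >10 Mb state blocks for LST junctions. Raises
    :class:`InfeasibleConfigError` when the targets exceed the build's arm
    capacity.
    """
    profile, _ = _plant_scars(targets, genome, seed=seed, sample_id=sample_id)
    return profile


def _plant_scars(targets, genome, seed=None, sample_id="planted"):
    loh_left, tai_left, lst_left = targets
    if min(targets) < 0:
        raise InfeasibleConfigError("scar targets must be non-negative")
    rng = np.random.default_rng(seed)
    arm_layouts: dict[tuple[str, str], list] = {}
    used_chroms: set[str] = set()

    for arm in genome.arms():
        if tai_left <= 0 and loh_left <= 0 and lst_left <= 0:
            break
        placed: list[tuple[float, float, tuple[int, int, int]]] = []
        tip: list[tuple[float, float, tuple[int, int, int]]] = []
        if tai_left > 0 and arm.length >= 18 * MB:
            u = rng.uniform(0.0, 1.0) * MB
            tip = [(0.0, 12 * MB + u, (3, 2, 1)), (12 * MB + u, 17 * MB + u, (6, 3, 3))]
            tai_left -= 1
            if loh_left > 0 and arm.length >= 39 * MB:
                base = 17 * MB + u
                tip += [(base, base + 16 * MB, (2, 2, 0)), (base + 16 * MB, base + 21 * MB, (4, 2, 2))]
                loh_left -= 1
            placed = _mirror(arm, tip)
        elif loh_left > 0 and arm.length >= 26 * MB:
            u = rng.uniform(0.0, 0.5) * MB
            layout = [(4 * MB + u, 20 * MB + u, (2, 2, 0)), (20 * MB + u, 25 * MB + u, (4, 2, 2))]
            loh_left -= 1
            if loh_left > 0 and arm.length >= 42 * MB:
                layout.append((25 * MB + u, 41 * MB + u, (2, 2, 0)))
                loh_left -= 1
            placed = _mirror(arm, layout)
        elif lst_left > 0 and _max_lst_on_arm(arm) > 0:
            r = min(lst_left, _max_lst_on_arm(arm))
            n_blocks = r + 1
            block = arm.length / n_blocks
            layout = []
            for k in range(n_blocks):
                state = _DIPLOID if k % 2 == 0 else (3, 2, 1)  # tip block balanced
                layout.append((k * block, (k + 1) * block, state))
            lst_left -= r
            placed = _mirror(arm, layout)
        else:
            continue
        arm_layouts[(arm.chrom, arm.arm)] = _fill_arm(arm, placed)
        used_chroms.add(arm.chrom)

    if tai_left > 0 or loh_left > 0 or lst_left > 0:
        raise InfeasibleConfigError(
            f"scar targets {targets} exceed arm capacity of the build "
            f"(unplaced: loh={loh_left}, tai={tai_left}, lst={lst_left})"
        )

    segments: list[Segment] = []
    for chrom in genome.autosomes:
        for arm in (Arm(chrom.name, 0, chrom.centromere_start, "p"),
                    Arm(chrom.name, chrom.centromere_end, chrom.length, "q")):
            layout = arm_layouts.get((arm.chrom, arm.arm)) or [(arm.start, arm.end, _DIPLOID)]
            for lo, hi, state in layout:
                segments.append(_seg(chrom.name, lo, hi, state))
        segments.append(_seg(chrom.name, chrom.centromere_start, chrom.centromere_end, _DIPLOID))
    return SegmentProfile(sample_id, segments), used_chroms


def plant_complex_profile(genome: GenomeBuild, chrom_name: str,
                          base_profile: SegmentProfile | None = None,
                          n_oscillations: int = 12, n_steps: int = 4,
                          sample_id: str = "complex") -> SegmentProfile:
    """Overwrite one chromosome of a profile with a planted chromothripsis-like
    oscillation (q arm) and a telomere-anchored staircase (p arm tip).

    The planted shapes are scar-neutral: oscillation blocks alternate total
    copy 2/3 in short (<10 Mb) segments; the staircase uses allele-balanced
    states (no imbalance, so no TAI) in short segments (no LST).
    """
    chrom = genome[chrom_name]
    segs: list[Segment] = []
    # staircase: strictly decreasing balanced totals away from the p telomere
    step = 3 * MB
    totals = [2 + 2 * (n_steps - k) for k in range(n_steps)]  # e.g. 10,8,6,4
    if step * n_steps >= chrom.centromere_start:
        raise InfeasibleConfigError("staircase does not fit the p arm tip")
    for k, t in enumerate(totals):
        segs.append(_seg(chrom_name, k * step, (k + 1) * step, (t, t // 2, t // 2)))
    segs.append(_seg(chrom_name, n_steps * step, chrom.centromere_end, _DIPLOID))
    # oscillation on the q arm
    n_segs = n_oscillations + 1
    block = (chrom.length - chrom.centromere_end) / n_segs
    if block >= 10 * MB or block < 3 * MB:
        raise InfeasibleConfigError("oscillation blocks must be 3-10 Mb; adjust n_oscillations")
    for k in range(n_segs):
        state = _DIPLOID if k % 2 == 0 else (3, 2, 1)
        segs.append(_seg(chrom_name, chrom.centromere_end + k * block,
                         chrom.centromere_end + (k + 1) * block, state))
    keep = [s for s in (base_profile.segments if base_profile else []) if s.chrom != chrom_name]
    sid = base_profile.sample_id if base_profile else sample_id
    return SegmentProfile(sid, keep + segs)


# ---------------------------------------------------------------------------
# signature draws
# ---------------------------------------------------------------------------


def simulate_signature_mutations(n: int, mix, reference: SignatureMatrix,
                                 seed: int | None = None) -> np.ndarray:
    """Draw ``n`` mutations into 96 channels from a signature mixture
    (multinomial with channel probabilities ``reference @ mix``)."""
    mix = np.asarray(mix, dtype=float)
    if mix.shape != (reference.k,):
        raise InfeasibleConfigError(
            f"mix length {mix.shape} != number of reference signatures {reference.k}"
        )
    if n < 0:
        raise InfeasibleConfigError("n must be >= 0")
    if n == 0:
        return np.zeros(96, dtype=int)
    probs = reference.matrix @ (mix / mix.sum())
    rng = np.random.default_rng(seed)
    return rng.multinomial(n, probs)


# ---------------------------------------------------------------------------
# patient phylogeny + mutation placement
# ---------------------------------------------------------------------------


@dataclass
class _Edge:
    clade: frozenset[int]  # sample indices below this edge
    duration: float
    kind: str  # {"trunk", "internal", "leaf"}


@dataclass
class PatientTruth:
    """Per-patient generative record used as the oracle in recovery tests."""

    patient: str
    samples: list[str]
    sample_months: dict[str, float]
    topology: Topology  # nested tuple over sample indices
    edge_of_variant: dict[str, frozenset[str]]  # variant key -> carrier sample labels
    class_of_variant: dict[str, str]  # trunk / branch / leaf
    signature_of_variant: dict[str, str]
    effect_of_variant: dict[str, str]
    exposures: dict[str, dict[str, int]]  # sample -> signature -> count
    sample_clock_counts: dict[str, int]
    trunk_clock_count: int
    clock_rate: float
    t_origin: float
    t_div: float


@dataclass
class GroundTruth:
    patients: dict[str, PatientTruth]
    scar_targets: dict[str, tuple[int, int, int]]  # sample -> planted targets
    complex_chromosome: str | None
    driver_matrix: AlterationMatrix


@dataclass
class Cohort:
    config: CohortConfig
    genome: GenomeBuild
    variants: dict[str, list[VariantRecord]]  # patient -> records
    segments: dict[str, SegmentProfile]  # sample -> profile
    sample_months: dict[str, dict[str, float]]  # patient -> sample -> month
    alterations: AlterationMatrix
    ground_truth: GroundTruth
    gene_table: dict[str, tuple[str, int, int]] = field(default_factory=dict)


def _simulate_patient_tree(n: int, t_origin: float, t_div: float, months: list[float],
                           rng: np.random.Generator):
    """Random ranked topology over ``n`` samples; returns (topology, edges).

    The first split sits ``t_div`` after the origin; later splits are uniform
    between it and the primary biopsy (month 0), so every split precedes every
    collection date.
    """
    tau1 = -t_origin + t_div
    if n == 1:
        topo: Topology = 0
        edges = [_Edge(frozenset([0]), t_origin + months[0], "trunk")]
        return topo, edges
    extra = sorted(rng.uniform(tau1, 0.0, size=n - 2).tolist()) if n > 2 else []
    split_times = [tau1] + extra
    # active lineages: (birth_time, subtree placeholder id)
    next_id = 0
    lineages: list[tuple[float, int]] = [(tau1, next_id)]
    children: dict[int, list[int]] = {}
    birth: dict[int, float] = {0: tau1}
    for t in split_times:
        idx = int(rng.integers(len(lineages)))
        _, node = lineages.pop(idx)
        kids = []
        for _ in range(2):
            next_id += 1
            birth[next_id] = t
            kids.append(next_id)
            lineages.append((t, next_id))
        children[node] = kids
    # wait: first split splits the root lineage at tau1 itself
    leaf_nodes = [node for _, node in lineages]
    perm = rng.permutation(n).tolist()
    sample_of_node = {node: perm[i] for i, node in enumerate(leaf_nodes)}

    def build(node: int) -> Topology:
        if node in children:
            return (build(children[node][0]), build(children[node][1]))
        return sample_of_node[node]

    topo = build(0)

    edges: list[_Edge] = [_Edge(frozenset(range(n)), t_div, "trunk")]

    def walk(node: int) -> frozenset[int]:
        if node not in children:
            s = frozenset([sample_of_node[node]])
            dur = months[sample_of_node[node]] - birth[node]
            edges.append(_Edge(s, dur, "leaf"))
            return s
        a, b = children[node]
        sa, sb = walk(a), walk(b)
        s = sa | sb
        if node != 0:
            # edge above this internal node: from its birth to its split time
            split_t = birth[children[node][0]]
            edges.append(_Edge(s, split_t - birth[node], "internal"))
        return s

    walk(0)
    return topo, edges


_EFFECT_NONSYN = (("missense", 0.80), ("truncating", 0.15), ("splice", 0.05))


def _draw_effect(rng: np.random.Generator, ns_s_ratio: float) -> str:
    p_syn = 1.0 / (1.0 + ns_s_ratio)
    if rng.random() < p_syn:
        return "synonymous"
    u = rng.random()
    acc = 0.0
    for eff, w in _EFFECT_NONSYN:
        acc += w
        if u < acc:
            return eff
    return "missense"


def _channel_to_variant(channel_idx: int) -> tuple[str, str, str]:
    label = CHANNELS[channel_idx]  # e.g. "A[C>T]G"
    five, rest = label[0], label[2:]
    ref, alt, three = rest[0], rest[2], rest[4]
    return ref, alt, f"{five}{ref}{three}"


def _passing_quality(rng: np.random.Generator) -> dict[str, float]:
    return {
        "qd": float(rng.uniform(11, 35)),
        "mq": float(rng.uniform(41, 60)),
        "fs": float(rng.uniform(0, 25)),
        "sor": float(rng.uniform(0.2, 2.8)),
        "mq_rank_sum": float(rng.normal(0, 1)),
        "read_pos_rank_sum": float(rng.normal(0, 1)),
    }


# ---------------------------------------------------------------------------
# driver genotypes
# ---------------------------------------------------------------------------


def _draw_driver_row(rng: np.random.Generator, brca_prob: float) -> dict[str, str]:
    row = {g: "none" for g in DRIVER_GENES}
    route = rng.choice(["cdk46", "cdk2", "rb1", "none"], p=[5 / 12, 3 / 12, 3 / 12, 1 / 12])
    if route == "cdk46":
        gene = rng.choice(["CCND3", "CDK4", "CDK6"], p=[0.5, 0.35, 0.15])
        row[gene] = "amplification"
    elif route == "cdk2":
        row["CCNE1"] = "amplification"
        if rng.random() < 0.8:
            row["CDKN2A"] = "biallelic_deletion"
    elif route == "rb1":
        row["RB1"] = "truncating" if rng.random() < 0.5 else "biallelic_deletion"
    if rng.random() < 7 / 12:
        if rng.random() < 0.7:
            row["TP53"] = "truncating"
        else:
            row["MDM2"] = "amplification"
    if rng.random() < brca_prob:
        row[rng.choice(["BRCA1", "BRCA2"], p=[0.4, 0.6])] = "truncating"
    return row


def _violates_rules(row: dict[str, str], rules) -> bool:
    return any(row[a] != "none" and row[b] != "none" for a, b in rules)


def _punch_segment(profile: SegmentProfile, punch: Segment) -> SegmentProfile:
    """Replace the punched interval inside an existing profile (splitting any
    overlapping segments)."""
    out: list[Segment] = []
    for s in profile.segments:
        if s.chrom != punch.chrom or s.end <= punch.start or s.start >= punch.end:
            out.append(s)
            continue
        if s.start < punch.start:
            out.append(Segment(s.chrom, s.start, punch.start, s.total_cn, s.major_cn, s.minor_cn))
        if s.end > punch.end:
            out.append(Segment(s.chrom, punch.end, s.end, s.total_cn, s.major_cn, s.minor_cn))
    out.append(punch)
    return SegmentProfile(profile.sample_id, out)


_DRIVER_CNA_STATE = {"amplification": (6, 5, 1), "biallelic_deletion": (0, 0, 0)}


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------


def simulate_cohort(config: CohortConfig | None = None,
                    genome: GenomeBuild | None = None,
                    reference: SignatureMatrix | None = None) -> Cohort:
    """Generate a full synthetic cohort (see module docstring).

    Deterministic given ``config.seed``; the returned :class:`GroundTruth`
    records every variant's true edge, class and signature, per-sample
    exposures and clock counts, planted scar targets, and the driver matrix.
    """
    config = config or CohortConfig()
    config.validate()
    genome = genome or toy_build()
    reference = reference or builtin_signatures()
    for name in config.signature_mix:
        if name not in reference.names:
            raise InfeasibleConfigError(f"signature {name!r} not in reference matrix")
    rng = np.random.default_rng(config.seed)

    mix_names = [n for n in reference.names if n in config.signature_mix]
    clock_sig = config.clock_signature
    m_clock = config.signature_mix[clock_sig]
    nonclock_names = [n for n in mix_names if n != clock_sig]
    nonclock_w = np.array([config.signature_mix[n] for n in nonclock_names], dtype=float)
    nonclock_rate = config.clock_rate * (1.0 - m_clock) / m_clock
    sig_cols = {n: reference.matrix[:, reference.names.index(n)] for n in reference.names}

    variants: dict[str, list[VariantRecord]] = {}
    segments: dict[str, SegmentProfile] = {}
    months_by_patient: dict[str, dict[str, float]] = {}
    truths: dict[str, PatientTruth] = {}
    scar_targets: dict[str, tuple[int, int, int]] = {}
    driver_rows = []
    patients = [f"P{i + 1}" for i in range(config.n_patients)]
    complex_chrom = genome.autosomes[-1].name if config.plant_complex_events else None
    gene_table = driver_gene_table(genome)
    driver_chrom = genome.autosomes[-2].name
    reserved = {complex_chrom, driver_chrom} - {None}

    for patient in patients:
        n_samples = int(rng.integers(config.samples_per_patient[0], config.samples_per_patient[1] + 1))
        rec_months = sorted(rng.uniform(*config.recurrence_month_range, size=n_samples - 1).tolist())
        sample_labels = [f"{patient}_P"] + [f"{patient}_R{k + 1}" for k in range(n_samples - 1)]
        months = [0.0] + rec_months
        months_by_patient[patient] = dict(zip(sample_labels, months))

        topo, edges = _simulate_patient_tree(
            n_samples, config.origin_months_before_biopsy,
            config.divergence_months_after_origin, months, rng,
        )

        # mutation placement
        recs: list[VariantRecord] = []
        edge_of: dict[str, frozenset[str]] = {}
        class_of: dict[str, str] = {}
        sig_of: dict[str, str] = {}
        eff_of: dict[str, str] = {}
        placements: list[tuple[_Edge, str]] = []  # (edge, signature)
        for e in edges:
            n_clock = int(rng.poisson(config.clock_rate * max(0.0, e.duration)))
            placements.extend((e, clock_sig) for _ in range(n_clock))
        total_duration = sum(max(0.0, e.duration) for e in edges)
        n_nonclock = int(rng.poisson(nonclock_rate * total_duration))
        positive_edges = [e for e in edges if e.duration > 0]
        if n_nonclock and not positive_edges:
            positive_edges = edges  # fully degenerate config: put everything on the trunk
        for _ in range(n_nonclock):
            e = positive_edges[int(rng.integers(len(positive_edges)))]
            sig = nonclock_names[int(rng.choice(len(nonclock_names), p=nonclock_w / nonclock_w.sum()))] \
                if nonclock_names else clock_sig
            placements.append((e, sig))

        used_pos: set[tuple[str, int]] = set()
        for e, sig in placements:
            ch = int(rng.choice(96, p=sig_cols[sig]))
            ref, alt, context = _channel_to_variant(ch)
            while True:
                chrom = genome.autosomes[int(rng.integers(len(genome.autosomes)))].name
                pos = int(rng.integers(1, genome[chrom].length))
                if (chrom, pos) not in used_pos:
                    used_pos.add((chrom, pos))
                    break
            effect = _draw_effect(rng, config.ns_s_ratio)
            carriers = frozenset(sample_labels[i] for i in e.clade)
            rec = VariantRecord(
                chrom=chrom, pos=pos, ref=ref, alt=alt,
                gene=f"G{int(rng.integers(1, 500))}",
                effect=effect, context=context,
                quality=_passing_quality(rng),
                presence={s: int(s in carriers) for s in sample_labels},
                clonality="clonal",
            )
            recs.append(rec)
            edge_of[rec.key] = carriers
            class_of[rec.key] = e.kind if e.kind != "internal" else "branch"
            sig_of[rec.key] = sig
            eff_of[rec.key] = effect

        # driver genotype obeying exclusivity rules by construction, with
        # evidence emitted into the variant table (truncal SNVs) and the
        # segment profiles (focal CNAs at the synthetic driver loci)
        for _ in range(100):
            row = _draw_driver_row(rng, config.brca_pathogenic_prob)
            if not _violates_rules(row, config.driver_rules):
                break
        else:  # pragma: no cover - route construction cannot loop forever
            raise InfeasibleConfigError("could not satisfy driver exclusivity rules")
        driver_rows.append(row)
        punches: list[Segment] = []
        for gene, category in row.items():
            chrom, lo, hi = gene_table[gene]
            if category in _DRIVER_CNA_STATE:
                t, M, mn = _DRIVER_CNA_STATE[category]
                punches.append(Segment(chrom, lo, hi, t, M, mn))
            elif category != "none":
                sig = nonclock_names[int(rng.integers(len(nonclock_names)))] if nonclock_names else clock_sig
                ch = int(rng.choice(96, p=sig_cols[sig]))
                ref, alt, context = _channel_to_variant(ch)
                pos = int(rng.integers(lo + 1, hi))
                effect = "truncating" if category == "truncating" else "missense"
                rec = VariantRecord(
                    chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
                    effect=effect, context=context,
                    quality=_passing_quality(rng),
                    scores={"sift": 0.01, "polyphen2": 0.95, "mutation_taster": 0.9,
                            "gerp": 3.0, "cadd": 25.0, "phylop": 1.5},
                    presence={s: 1 for s in sample_labels},
                    clonality="clonal",
                )
                recs.append(rec)
                edge_of[rec.key] = frozenset(sample_labels)
                class_of[rec.key] = "trunk"
                sig_of[rec.key] = sig
                eff_of[rec.key] = effect

        exposures = {
            s: {n: 0 for n in reference.names} for s in sample_labels
        }
        clock_counts = {s: 0 for s in sample_labels}
        for rec in recs:
            for s in rec.samples_present():
                exposures[s][sig_of[rec.key]] += 1
                if sig_of[rec.key] == clock_sig:
                    clock_counts[s] += 1
        trunk_clock = sum(
            1 for rec in recs
            if class_of[rec.key] == "trunk" and sig_of[rec.key] == clock_sig
        )

        variants[patient] = recs
        truths[patient] = PatientTruth(
            patient=patient, samples=sample_labels,
            sample_months=months_by_patient[patient],
            topology=topo, edge_of_variant=edge_of, class_of_variant=class_of,
            signature_of_variant=sig_of, effect_of_variant=eff_of,
            exposures=exposures, sample_clock_counts=clock_counts,
            trunk_clock_count=trunk_clock,
            clock_rate=config.clock_rate,
            t_origin=config.origin_months_before_biopsy,
            t_div=config.divergence_months_after_origin,
        )

        # copy-number profiles with planted scars (+ complex events + driver CNAs)
        for s in sample_labels:
            prof, used = _plant_scars(
                config.scar_targets, genome,
                seed=int(rng.integers(2**31)), sample_id=s,
            )
            if used & reserved:
                raise InfeasibleConfigError(
                    "scar targets occupy chromosomes reserved for complex events / "
                    "driver loci; reduce targets or enlarge the build"
                )
            if complex_chrom is not None:
                prof = plant_complex_profile(genome, complex_chrom, base_profile=prof)
            for punch in punches:
                prof = _punch_segment(prof, punch)
            segments[s] = prof
            scar_targets[s] = config.scar_targets

    driver_matrix = AlterationMatrix(
        patients=patients,
        genes=list(DRIVER_GENES),
        cells=np.array([[r[g] for g in DRIVER_GENES] for r in driver_rows], dtype=object),
    )
    truth = GroundTruth(
        patients=truths,
        scar_targets=scar_targets,
        complex_chromosome=complex_chrom,
        driver_matrix=driver_matrix,
    )
    return Cohort(
        config=config, genome=genome, variants=variants, segments=segments,
        sample_months=months_by_patient, alterations=driver_matrix, ground_truth=truth,
        gene_table=gene_table,
    )
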