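"""Maximum-parsimony tumor phylogenies from binary variant-presence matrices.

Samples (tumors plus one all-zero normal outgroup) are rows and variants are
columns of a 0/1 presence matrix. Trees are rooted at the normal; the tree
length is the total number of character state changes under two-state Fitch
parsimony. Exhaustive search enumerates every rooted topology over the tumor
samples (feasible below ten rows); heuristic search combines seeded
random-addition starts with nearest-neighbor-interchange hill climbing.
Support comes from column (mutation) bootstrap resampling; variants are
assigned to edges by their carrier sets, with the trunk defined as the edge
from the normal-rooted origin to the most recent common ancestor of all
tumor samples.

Topologies are nested tuples over tumor-leaf indices: a leaf is an ``int``,
an internal node a 2-tuple of subtrees. The outgroup sits implicitly above
the root carrying state 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParseError
from .variants import VariantRecord

Topology = int | tuple  # nested 2-tuples of ints

EXHAUSTIVE_ROW_CAP = 10  # tumor rows + outgroup row


# ---------------------------------------------------------------------------
# presence matrix
# ---------------------------------------------------------------------------


@dataclass
class PresenceMatrix:
    """Binary sample x variant matrix with an all-zero outgroup row."""

    samples: list[str]  # tumor samples only (outgroup implicit)
    variant_ids: list[str]
    data: np.ndarray  # (n_samples, n_variants) of 0/1, outgroup row excluded
    outgroup: str = "NORMAL"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.shape != (len(self.samples), len(self.variant_ids)):
            raise ParseError("presence matrix shape mismatch")
        if len(set(self.samples)) != len(self.samples):
            raise ParseError("duplicate sample labels")
        if self.outgroup in self.samples:
            raise ParseError(f"outgroup label {self.outgroup!r} collides with a tumor sample")
        if self.data.size and not self.data.any(axis=0).all():
            bad = [self.variant_ids[i] for i in np.flatnonzero(~self.data.any(axis=0))]
            raise ParseError(f"variant column(s) absent from every tumor sample: {bad}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def carriers(self, j: int) -> frozenset[int]:
        return frozenset(np.flatnonzero(self.data[:, j]).tolist())


def build_presence_matrix(variants: list[VariantRecord], samples: list[str],
                          outgroup_label: str = "NORMAL") -> PresenceMatrix:
    """Build the binary matrix from variant records (presence flags) with an
    appended conceptual all-zero outgroup row."""
    if len(set(samples)) != len(samples):
        raise ParseError("duplicate sample labels")
    data = np.zeros((len(samples), len(variants)), dtype=bool)
    ids = []
    for j, rec in enumerate(variants):
        ids.append(rec.key)
        for i, s in enumerate(samples):
            data[i, j] = bool(rec.presence.get(s, 0))
    return PresenceMatrix(list(samples), ids, data, outgroup=outgroup_label)


# ---------------------------------------------------------------------------
# topology utilities
# ---------------------------------------------------------------------------


def leaves_of(tree: Topology) -> frozenset[int]:
    if isinstance(tree, int):
        return frozenset((tree,))
    return leaves_of(tree[0]) | leaves_of(tree[1])


def canonical(tree: Topology) -> Topology:
    """Order-normalised form (children sorted by minimum leaf index)."""

    def rec(t):
        if isinstance(t, int):
            return t, t
        a, amin = rec(t[0])
        b, bmin = rec(t[1])
        if amin <= bmin:
            return (a, b), amin
        return (b, a), bmin

    return rec(tree)[0]


def enumerate_topologies(n_leaves: int):
    """Yield every rooted binary topology over leaves 0..n_leaves-1.

    There are (2n-3)!! such trees; each corresponds to one unrooted topology
    over the tumor samples plus the outgroup, rooted on the outgroup edge.
    """
    if n_leaves < 1:
        return
    trees: list[Topology] = [0]
    for leaf in range(1, n_leaves):
        trees = [t2 for t in trees for t2 in _insertions(t, leaf)]
    yield from trees


def _insertions(tree: Topology, leaf: int) -> list[Topology]:
    out: list[Topology] = [(tree, leaf)]
    if not isinstance(tree, int):
        a, b = tree
        out.extend((a2, b) for a2 in _insertions(a, leaf))
        out.extend((a, b2) for b2 in _insertions(b, leaf))
    return out


def nni_neighbors(tree: Topology) -> list[Topology]:
    """All nearest-neighbor-interchange rearrangements of a rooted topology."""

    def gen(t) -> list[Topology]:
        """All trees obtained from ``t`` by one NNI somewhere inside it."""
        if isinstance(t, int):
            return []
        a, b = t
        alts: list[Topology] = []
        # exchange a grandchild with its uncle across this node
        if not isinstance(a, int):
            a0, a1 = a
            alts.append(((a0, b), a1))
            alts.append(((a1, b), a0))
        if not isinstance(b, int):
            b0, b1 = b
            alts.append(((a, b0), b1))
            alts.append(((a, b1), b0))
        alts.extend((a2, b) for a2 in gen(a))
        alts.extend((a, b2) for b2 in gen(b))
        return alts

    return sorted({canonical(t2) for t2 in gen(tree)} - {canonical(tree)}, key=repr)


# ---------------------------------------------------------------------------
# Fitch scoring
# ---------------------------------------------------------------------------


def _fitch_column_changes(tree: Topology, data: np.ndarray) -> np.ndarray:
    """Per-column minimum state changes for a rooted tree with an implicit
    outgroup in state 0 above the root. ``data`` is (n_samples, m) bool."""
    m = data.shape[1]
    changes = np.zeros(m, dtype=np.int64)

    def post(t) -> np.ndarray:
        if isinstance(t, int):
            return np.where(data[t], 2, 1).astype(np.uint8)  # bitmask over {0,1}
        left = post(t[0])
        right = post(t[1])
        inter = left & right
        empty = inter == 0
        changes[empty] += 1
        return np.where(empty, left | right, inter).astype(np.uint8)

    root = post(tree)
    changes[(root & 1) == 0] += 1  # outgroup forces state 0 at the root
    return changes


def parsimony_score(tree: Topology, matrix: PresenceMatrix) -> int:
    """Tree length: total Fitch state changes over all variant columns."""
    if leaves_of(tree) != frozenset(range(matrix.n_samples)):
        raise ParseError("tree leaves do not match matrix rows")
    return int(_fitch_column_changes(tree, matrix.data).sum())


def homoplasy_index(tree: Topology, matrix: PresenceMatrix) -> float:
    """HI = 1 - (minimum conceivable changes) / (realized changes).

    For binary presence characters the minimum per column is 1, so the
    numerator is the number of variant columns. HI is 0 exactly when the tree
    explains every variant with a single origin.
    """
    if matrix.n_variants == 0:
        raise ParseError("empty matrix")
    length = parsimony_score(tree, matrix)
    return 1.0 - matrix.n_variants / length


# ---------------------------------------------------------------------------
# tree search
# ---------------------------------------------------------------------------


def search_trees(matrix: PresenceMatrix, mode: str = "exhaustive",
                 n_kept: int = 1000, seed: int | None = None,
                 n_restarts: int = 10) -> tuple[list[Topology], int]:
    """Find shortest trees; returns (topologies, best_length).

    ``exhaustive`` enumerates all rooted topologies and returns EVERY
    minimum-length one (requires at most 10 rows including the outgroup).
    ``heuristic`` runs seeded random-addition starts followed by NNI hill
    climbing and returns the ``n_kept`` shortest distinct topologies found
    (the optimum is not guaranteed but the result is deterministic given the
    seed).
    """
    n = matrix.n_samples
    if n < 1:
        raise ParseError("matrix has no tumor samples")
    if n == 1:
        return [0], int(matrix.n_variants)
    if mode == "exhaustive":
        if n + 1 > EXHAUSTIVE_ROW_CAP:
            raise ParseError(
                f"exhaustive search supports at most {EXHAUSTIVE_ROW_CAP} rows "
                f"(got {n + 1}); use mode='heuristic'"
            )
        best: list[Topology] = []
        best_len: int | None = None
        for t in enumerate_topologies(n):
            score = int(_fitch_column_changes(t, matrix.data).sum())
            if best_len is None or score < best_len:
                best, best_len = [t], score
            elif score == best_len:
                best.append(t)
        return [canonical(t) for t in best], int(best_len)
    if mode != "heuristic":
        raise ValueError(f"unknown mode {mode!r}")

    rng = np.random.default_rng(seed)
    scored: dict[Topology, int] = {}

    def score_of(t: Topology) -> int:
        c = canonical(t)
        if c not in scored:
            scored[c] = int(_fitch_column_changes(c, matrix.data).sum())
        return scored[c]

    for _ in range(n_restarts):
        order = rng.permutation(n).tolist()
        tree: Topology = order[0]
        for leaf in order[1:]:
            candidates = _insertions(tree, leaf)
            tree = min(candidates, key=lambda t: int(_fitch_column_changes(t, matrix.data).sum()))
        current = canonical(tree)
        current_score = score_of(current)
        improved = True
        while improved:
            improved = False
            for nb in nni_neighbors(current):
                s = score_of(nb)
                if s < current_score:
                    current, current_score = nb, s
                    improved = True
                    break
    ranked = sorted(scored.items(), key=lambda kv: (kv[1], repr(kv[0])))
    best_len = ranked[0][1]
    return [t for t, _ in ranked[:n_kept]], int(best_len)


def strict_consensus(trees: list[Topology]) -> set[frozenset[int]]:
    """Tumor-leaf clades present in every tree (non-trivial and trivial)."""
    clade_sets = []
    for t in trees:
        clades = set()

        def rec(node):
            s = leaves_of(node)
            clades.add(s)
            if not isinstance(node, int):
                rec(node[0])
                rec(node[1])

        rec(t)
        clade_sets.append(clades)
    out = clade_sets[0]
    for cs in clade_sets[1:]:
        out &= cs
    return out


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def bootstrap_support(matrix: PresenceMatrix, reps: int = 1000, seed: int | None = None,
                      mode: str | None = None) -> dict[frozenset[int], float]:
    """Column (mutation) bootstrap: resample variants with replacement,
    re-search, and report for each clade of the observed best tree the
    fraction of replicates whose strict consensus of best trees contains it.
    Clade identity is the tumor-leaf set below an edge (outgroup excluded).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if mode is None:
        mode = "exhaustive" if matrix.n_samples + 1 <= 7 else "heuristic"
    rng = np.random.default_rng(seed)
    observed_best, _ = search_trees(matrix, mode=mode, seed=int(rng.integers(2**31)))
    observed_clades = strict_consensus(observed_best[:1])
    hits = {c: 0 for c in observed_clades}
    m = matrix.n_variants
    for _ in range(reps):
        cols = rng.integers(0, m, size=m)
        resampled = PresenceMatrix(
            matrix.samples,
            [f"bs{i}" for i in range(m)],
            matrix.data[:, cols],
            outgroup=matrix.outgroup,
        )
        best, _ = search_trees(resampled, mode=mode, seed=int(rng.integers(2**31)))
        rep_clades = strict_consensus(best)
        for c in hits:
            if c in rep_clades:
                hits[c] += 1
    return {c: h / reps for c, h in hits.items()}


# ---------------------------------------------------------------------------
# edge assignment, trunk, ns/s
# ---------------------------------------------------------------------------


@dataclass
class EdgeAssignment:
    """Variant-to-edge map for one rooted topology.

    Edges are identified by the frozenset of tumor leaves they subtend; the
    trunk is the edge above the common ancestor of all tumor samples
    (subtending every leaf). Homoplastic variants are flagged and placed on
    every change edge of one minimal Fitch labeling.
    """

    edge_variants: dict[frozenset[int], list[str]]
    trunk: frozenset[int]
    homoplastic: set[str] = field(default_factory=set)

    def variant_class(self, variant_id: str) -> str:
        for clade, ids in self.edge_variants.items():
            if variant_id in ids:
                if clade == self.trunk:
                    return "trunk"
                return "leaf" if len(clade) == 1 else "branch"
        raise KeyError(variant_id)


def _node_clades(tree: Topology) -> list[tuple[Topology, frozenset[int]]]:
    out = []

    def rec(t):
        s = leaves_of(t)
        out.append((t, s))
        if not isinstance(t, int):
            rec(t[0])
            rec(t[1])

    rec(tree)
    return out


def assign_variants_to_edges(tree: Topology, matrix: PresenceMatrix) -> EdgeAssignment:
    """Assign each variant column to tree edge(s).

    A non-homoplastic variant (one Fitch change) maps to the unique edge
    subtending exactly its carrier set. A homoplastic one is flagged and
    assigned to all change edges of one minimal Fitch labeling (parent-state
    preference on the top-down pass).
    """
    all_leaves = frozenset(range(matrix.n_samples))
    if leaves_of(tree) != all_leaves:
        raise ParseError("tree leaves do not match matrix rows")
    clade_of_node = {id(node): s for node, s in _node_clades(tree)}
    by_clade: dict[frozenset[int], list[str]] = {s: [] for _, s in _node_clades(tree)}
    changes = _fitch_column_changes(tree, matrix.data)
    homoplastic: set[str] = set()

    # per-column Fitch sets for the top-down pass
    def post_sets(t, col_data, store):
        if isinstance(t, int):
            s = 2 if col_data[t] else 1
        else:
            left = post_sets(t[0], col_data, store)
            right = post_sets(t[1], col_data, store)
            inter = left & right
            s = inter if inter else (left | right)
        store[id(t)] = s
        return s

    for j, vid in enumerate(matrix.variant_ids):
        carriers = matrix.carriers(j)
        if changes[j] == 1:
            by_clade[carriers].append(vid)
            continue
        homoplastic.add(vid)
        col = matrix.data[:, j]
        sets: dict[int, int] = {}
        post_sets(tree, col, sets)

        def down(t, parent_state):
            s = sets[id(t)]
            state = parent_state if (s >> parent_state) & 1 else (0 if s & 1 else 1)
            if state != parent_state:
                by_clade[clade_of_node[id(t)]].append(vid)
            if not isinstance(t, int):
                down(t[0], state)
                down(t[1], state)

        down(tree, 0)  # outgroup side of the root is state 0
    return EdgeAssignment(edge_variants=by_clade, trunk=all_leaves, homoplastic=homoplastic)


@dataclass
class RatioReport:
    """Trunk and branch non-synonymous/synonymous count ratios."""

    trunk_ns: int
    trunk_s: int
    branch_ns: int
    branch_s: int

    @property
    def t_ns_s(self) -> float | None:
        return self.trunk_ns / self.trunk_s if self.trunk_s > 0 else None

    @property
    def b_ns_s(self) -> float | None:
        return self.branch_ns / self.branch_s if self.branch_s > 0 else None


_NONSYNONYMOUS = ("missense", "truncating", "splice")


def ns_s_ratios(assignment: EdgeAssignment, effects: dict[str, str]) -> RatioReport:
    """Count non-synonymous vs synonymous variants on the trunk and pooled
    over all non-trunk edges. A zero denominator yields an undefined ratio
    (``None``), never infinity. Variants with non-coding effects are ignored.
    """
    counts = {"trunk_ns": 0, "trunk_s": 0, "branch_ns": 0, "branch_s": 0}
    for clade, ids in assignment.edge_variants.items():
        where = "trunk" if clade == assignment.trunk else "branch"
        for vid in ids:
            eff = effects.get(vid)
            if eff == "synonymous":
                counts[f"{where}_s"] += 1
            elif eff in _NONSYNONYMOUS:
                counts[f"{where}_ns"] += 1
    return RatioReport(**counts)


# ---------------------------------------------------------------------------
# top-level result object + Newick I/O
# ---------------------------------------------------------------------------


@dataclass
class Phylogeny:
    """Best-tree summary for one patient."""

    matrix: PresenceMatrix
    tree: Topology  # canonical first-best topology
    best_trees: list[Topology]
    tree_length: int
    homoplasy_index: float
    assignment: EdgeAssignment
    supports: dict[frozenset[int], float] = field(default_factory=dict)

    @property
    def samples(self) -> list[str]:
        return self.matrix.samples

    def clade_labels(self, clade: frozenset[int]) -> frozenset[str]:
        return frozenset(self.matrix.samples[i] for i in clade)


def build_phylogeny(matrix: PresenceMatrix, mode: str = "exhaustive",
                    bootstrap_reps: int = 0, seed: int | None = None,
                    n_kept: int = 1000) -> Phylogeny:
    best, best_len = search_trees(matrix, mode=mode, n_kept=n_kept, seed=seed)
    tree = sorted((canonical(t) for t in best), key=repr)[0]
    supports = (
        bootstrap_support(matrix, reps=bootstrap_reps, seed=seed) if bootstrap_reps else {}
    )
    return Phylogeny(
        matrix=matrix,
        tree=tree,
        best_trees=best,
        tree_length=best_len,
        homoplasy_index=homoplasy_index(tree, matrix),
        assignment=assign_variants_to_edges(tree, matrix),
        supports=supports,
    )


def write_tree_newick(phylogeny: Phylogeny, path) -> None:
    """Serialize the best tree as rooted Newick.

    Branch lengths are the number of variants assigned to each edge; internal
    node labels carry bootstrap supports (3 decimals) when available; the
    outgroup label closes the tree as the root. Stable under
    parse -> write -> parse (checked with dendropy).
    """
    mat = phylogeny.matrix
    for s in mat.samples:
        if not s:
            raise ParseError("unlabeled leaf")
    ev = phylogeny.assignment.edge_variants

    def rec(t) -> str:
        clade = leaves_of(t)
        n_var = len(ev.get(clade, []))
        if isinstance(t, int):
            return f"{mat.samples[t]}:{n_var}"
        sup = phylogeny.supports.get(clade)
        label = f"{sup:.3f}" if sup is not None else ""
        return f"({rec(t[0])},{rec(t[1])}){label}:{n_var}"

    trunk_len = len(ev.get(phylogeny.assignment.trunk, []))
    if isinstance(phylogeny.tree, int):
        inner = f"{mat.samples[phylogeny.tree]}:{trunk_len}"
        newick = f"({inner}){mat.outgroup};\n"
    else:
        a, b = phylogeny.tree
        sup = phylogeny.supports.get(phylogeny.assignment.trunk)
        label = f"{sup:.3f}" if sup is not None else ""
        inner = f"({rec(a)},{rec(b)}){label}:{trunk_len}"
        newick = f"({inner}){mat.outgroup};\n"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(newick)


def read_tree_newick(path) -> "dendropy.Tree":
    import dendropy

    return dendropy.Tree.get(path=str(path), schema="newick")
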