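"""Parsimony phylogenetics: Fitch scoring vs a brute-force oracle, exhaustive
vs heuristic search, homoplasy, bootstrap, edge assignment, ns/s ratios."""

import itertools

import numpy as np
import pytest

import osteoclad as oc
from osteoclad.errors import ParseError
from osteoclad.phylo import (
    PresenceMatrix,
    assign_variants_to_edges,
    canonical,
    enumerate_topologies,
    leaves_of,
    nni_neighbors,
    strict_consensus,
)


def _matrix(samples, columns, ids=None):
    ids = ids or [f"v{i}" for i in range(len(columns))]
    data = np.array(columns).T
    return PresenceMatrix(list(samples), ids, data)


# --- oracle: minimal changes per column by enumerating internal states -----


def _internal_nodes(tree, acc):
    if not isinstance(tree, int):
        acc.append(tree)
        _internal_nodes(tree[0], acc)
        _internal_nodes(tree[1], acc)
    return acc


def brute_force_column_changes(tree, column):
    """Minimum state changes over ALL assignments of {0,1} to internal nodes,
    with the root's parent (outgroup side) fixed to state 0."""
    internals = _internal_nodes(tree, [])
    best = None
    for states in itertools.product((0, 1), repeat=len(internals)):
        assigned = {id(node): s for node, s in zip(internals, states)}

        def state_of(node):
            return column[node] if isinstance(node, int) else assigned[id(node)]

        changes = int(state_of(tree) != 0)  # edge to the outgroup-side root
        stack = [tree]
        while stack:
            node = stack.pop()
            if isinstance(node, int):
                continue
            for child in node:
                changes += int(state_of(child) != state_of(node))
                stack.append(child)
        best = changes if best is None else min(best, changes)
    return best


def test_fitch_matches_brute_force_on_random_instances():
    rng = np.random.default_rng(0)
    for _ in range(30):
        n = int(rng.integers(3, 6))
        m = 8
        data = rng.random((n, m)) < 0.5
        data[:, ~data.any(axis=0)] = True  # no empty columns
        mat = _matrix([f"s{i}" for i in range(n)], data.T.astype(int))
        trees = list(enumerate_topologies(n))
        tree = trees[int(rng.integers(len(trees)))]
        from osteoclad.phylo import _fitch_column_changes

        got = _fitch_column_changes(tree, mat.data)
        want = [brute_force_column_changes(tree, mat.data[:, j].astype(int)) for j in range(m)]
        assert got.tolist() == want


def test_private_variant_contributes_one_on_any_tree():
    mat = _matrix("ABCD", [[1, 0, 0, 0]])
    for tree in enumerate_topologies(4):
        assert oc.parsimony_score(tree, mat) == 1


def test_perfect_phylogeny_score_equals_variant_count():
    # generating tree ((A,B),(C,D))
    cols = [[1, 1, 1, 1], [1, 1, 0, 0], [0, 0, 1, 1], [1, 0, 0, 0], [0, 0, 0, 1]]
    mat = _matrix("ABCD", cols)
    tree = ((0, 1), (2, 3))
    assert oc.parsimony_score(tree, mat) == len(cols)
    assert oc.homoplasy_index(tree, mat) == 0.0


def test_tree_length_invariant_under_leaf_order_permutation():
    rng = np.random.default_rng(1)
    data = (rng.random((5, 10)) < 0.4)
    data[:, ~data.any(axis=0)] = True
    mat = _matrix("ABCDE", data.T.astype(int))
    best, length = oc.search_trees(mat, "exhaustive")
    perm = rng.permutation(5)
    mat2 = PresenceMatrix([mat.samples[i] for i in perm], mat.variant_ids, mat.data[perm])
    _, length2 = oc.search_trees(mat2, "exhaustive")
    assert length == length2


# --- presence matrix -------------------------------------------------------


def test_build_presence_matrix_shape_and_outgroup(small_cohort):
    patient = "P1"
    truth = small_cohort.ground_truth.patients[patient]
    recs = small_cohort.variants[patient]
    mat = oc.build_presence_matrix(recs, truth.samples)
    assert mat.n_variants == len(recs)
    assert mat.samples == truth.samples
    # descent: carriers match the generative edge assignment exactly
    for j, rec in enumerate(recs):
        carriers = {truth.samples[i] for i in mat.carriers(j)}
        assert carriers == set(truth.edge_of_variant[rec.key])


def test_all_zero_variant_column_rejected():
    with pytest.raises(ParseError, match="absent from every tumor"):
        _matrix("AB", [[0, 0]])


def test_duplicate_sample_labels_rejected():
    with pytest.raises(ParseError, match="duplicate"):
        _matrix("AA", [[1, 1]])


# --- search ----------------------------------------------------------------


def test_perfect_phylogeny_unique_generating_topology():
    cols = [[1, 1, 1], [1, 1, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]]
    mat = _matrix("ABC", cols)
    best, length = oc.search_trees(mat, "exhaustive")
    assert best == [((0, 1), 2)]
    assert length == len(cols)


def test_star_data_all_resolutions_tie():
    mat = _matrix("ABCD", [[1, 1, 1, 1]] * 4)
    best, length = oc.search_trees(mat, "exhaustive")
    assert length == 4
    assert len(best) == len(list(enumerate_topologies(4)))  # every topology ties


def test_exhaustive_row_cap_enforced():
    data = np.eye(10, dtype=int)
    mat = _matrix([f"s{i}" for i in range(10)], data.T.tolist())
    with pytest.raises(ParseError, match="heuristic"):
        oc.search_trees(mat, "exhaustive")


def test_heuristic_never_beats_exhaustive_and_usually_matches():
    rng = np.random.default_rng(7)
    matches = 0
    trials = 40
    for _ in range(trials):
        n = int(rng.integers(4, 7))
        m = int(rng.integers(6, 14))
        data = rng.random((n, m)) < rng.uniform(0.25, 0.6)
        data[:, ~data.any(axis=0)] = True
        mat = _matrix([f"s{i}" for i in range(n)], data.T.astype(int))
        _, exh = oc.search_trees(mat, "exhaustive")
        _, heu = oc.search_trees(mat, "heuristic", seed=int(rng.integers(2**31)))
        assert heu >= exh  # the optimum is a lower bound, always
        matches += heu == exh
    assert matches >= 0.95 * trials


def test_heuristic_deterministic_given_seed():
    rng = np.random.default_rng(3)
    data = rng.random((6, 12)) < 0.4
    data[:, ~data.any(axis=0)] = True
    mat = _matrix("ABCDEF", data.T.astype(int))
    t1, l1 = oc.search_trees(mat, "heuristic", seed=11)
    t2, l2 = oc.search_trees(mat, "heuristic", seed=11)
    assert t1 == t2 and l1 == l2


# --- homoplasy -------------------------------------------------------------


def test_homoplasy_index_hand_case():
    # 4 taxa; char 1 clean (A,B), char 2 convergent in A and C -> forced 2 changes
    cols = [[1, 1, 0, 0], [1, 0, 1, 0]]
    mat = _matrix("ABCD", cols)
    best, length = oc.search_trees(mat, "exhaustive")
    assert length == 3  # 1 + 2 changes on the best tree
    assert oc.homoplasy_index(best[0], mat) == pytest.approx(1 - 2 / 3)


def test_homoplasy_strictly_increases_with_convergent_column():
    cols = [[1, 1, 0, 0], [0, 0, 1, 1], [1, 0, 0, 0]]
    mat = _matrix("ABCD", cols)
    tree = ((0, 1), (2, 3))
    base = oc.homoplasy_index(tree, mat)
    cols2 = cols + [[1, 0, 1, 0]]  # convergent on this tree
    mat2 = _matrix("ABCD", cols2)
    assert oc.homoplasy_index(tree, mat2) > base


def test_empty_matrix_rejected():
    mat = _matrix("AB", [[1, 1]])
    empty = PresenceMatrix(["A", "B"], [], np.zeros((2, 0)))
    with pytest.raises(ParseError, match="empty"):
        oc.homoplasy_index((0, 1), empty)
    assert oc.homoplasy_index((0, 1), mat) == 0.0


# --- bootstrap -------------------------------------------------------------


def test_bootstrap_high_support_for_well_covered_perfect_phylogeny():
    # ((A,B),(C,D)) with 6 variants on every edge
    edges = [[1, 1, 1, 1], [1, 1, 0, 0], [0, 0, 1, 1],
             [1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0], [0, 0, 0, 1]]
    cols = [c for c in edges for _ in range(6)]
    mat = _matrix("ABCD", cols)
    sup = oc.bootstrap_support(mat, reps=200, seed=5)
    for clade, s in sup.items():
        assert s >= 0.99, (clade, s)


def test_single_variant_support_degenerate():
    mat = _matrix("ABC", [[1, 1, 0]])
    sup = oc.bootstrap_support(mat, reps=50, seed=2)
    assert sup[frozenset({0, 1})] == 1.0


def test_shuffled_labels_give_weak_support():
    rng = np.random.default_rng(9)
    weak = 0
    for _ in range(20):
        data = rng.random((5, 12)) < 0.5
        data[:, ~data.any(axis=0)] = True
        rng.shuffle(data, axis=0)
        mat = _matrix("ABCDE", data.T.astype(int))
        sup = oc.bootstrap_support(mat, reps=60, seed=int(rng.integers(2**31)), mode="heuristic")
        nontrivial = {c: s for c, s in sup.items() if 1 < len(c) < 5}
        if all(s <= 0.9 for s in nontrivial.values()):
            weak += 1
    assert weak >= 15  # structureless data rarely produces confident clades


# --- edge assignment + ratios ---------------------------------------------


def test_trunk_leaf_assignment_rules():
    cols = [[1, 1, 1], [1, 0, 0], [1, 1, 0]]
    mat = _matrix("ABC", cols, ids=["ubiquitous", "private_A", "shared_AB"])
    best, _ = oc.search_trees(mat, "exhaustive")
    asg = assign_variants_to_edges(best[0], mat)
    assert asg.variant_class("ubiquitous") == "trunk"
    assert asg.variant_class("private_A") == "leaf"
    assert asg.variant_class("shared_AB") == "branch"
    assert not asg.homoplastic


def test_assignment_recovers_simulator_ground_truth(small_cohort):
    for patient, truth in small_cohort.ground_truth.patients.items():
        if len(truth.samples) < 2:
            continue
        mat = oc.build_presence_matrix(small_cohort.variants[patient], truth.samples)
        best, _ = oc.search_trees(mat, mode="exhaustive" if len(truth.samples) <= 6 else "heuristic",
                                  seed=1)
        asg = assign_variants_to_edges(best[0], mat)
        for rec in small_cohort.variants[patient]:
            if rec.key in asg.homoplastic:
                continue
            assert asg.variant_class(rec.key) == truth.class_of_variant[rec.key], rec.key


def test_homoplastic_variant_flagged_and_multiply_assigned():
    cols = [[1, 1, 0, 0], [0, 0, 1, 1], [1, 0, 1, 0]]
    mat = _matrix("ABCD", cols, ids=["ab", "cd", "conv"])
    tree = ((0, 1), (2, 3))
    asg = assign_variants_to_edges(tree, mat)
    assert "conv" in asg.homoplastic
    hits = [c for c, ids in asg.edge_variants.items() if "conv" in ids]
    assert len(hits) == 2  # one change per convergent origin
    total = sum(len(ids) for ids in asg.edge_variants.values())
    assert total == mat.n_variants + 1  # duplicates only for the flagged column


def test_ns_s_ratio_arithmetic_and_undefined():
    asg = oc.EdgeAssignment(
        edge_variants={
            frozenset({0, 1}): [f"t{i}" for i in range(12)],
            frozenset({0}): ["b0", "b1"],
        },
        trunk=frozenset({0, 1}),
    )
    effects = {f"t{i}": "missense" for i in range(10)}
    effects.update({"t10": "synonymous", "t11": "synonymous"})
    effects.update({"b0": "missense", "b1": "missense"})
    rep = oc.ns_s_ratios(asg, effects)
    assert rep.t_ns_s == 5.0
    assert rep.b_ns_s is None  # zero synonymous on branches -> undefined


def test_edge_variant_counts_conserve_columns():
    rng = np.random.default_rng(4)
    data = rng.random((5, 15)) < 0.45
    data[:, ~data.any(axis=0)] = True
    mat = _matrix("ABCDE", data.T.astype(int))
    best, _ = oc.search_trees(mat, "exhaustive")
    asg = assign_variants_to_edges(best[0], mat)
    total = sum(len(ids) for ids in asg.edge_variants.values())
    extra = sum(
        len([c for c, ids in asg.edge_variants.items() if v in ids]) - 1
        for v in asg.homoplastic
    )
    assert total == mat.n_variants + extra


def test_nni_neighbors_are_valid_topologies():
    tree = ((0, 1), (2, (3, 4)))
    for nb in nni_neighbors(tree):
        assert leaves_of(nb) == frozenset(range(5))
        assert canonical(nb) != canonical(tree)


def test_strict_consensus_of_ties_keeps_shared_clades():
    trees = [((0, 1), (2, 3)), (((0, 1), 2), 3)]
    clades = strict_consensus(trees)
    assert frozenset({0, 1}) in clades
    assert frozenset({2, 3}) not in clades
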