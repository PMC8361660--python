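"""Mutual-exclusivity testing, FDR adjustment, prevalence arithmetic, and
alteration-matrix construction."""

import warnings

import numpy as np
import pytest

import osteoclad as oc
from osteoclad.cna import CNAEvent
from osteoclad.errors import ParseError
from osteoclad.exclusivity import AlterationMatrix, fit_background
from osteoclad.variants import VariantRecord


def _binary_matrix(binary, patients=None, genes=None):
    binary = np.asarray(binary)
    n, m = binary.shape
    patients = patients or [f"p{i}" for i in range(n)]
    genes = genes or [f"g{j}" for j in range(m)]
    cells = np.where(binary.astype(bool), "missense", "none").astype(object)
    return AlterationMatrix(list(patients), list(genes), cells)


# --- background fit --------------------------------------------------------


def test_background_fit_matches_margins():
    rng = np.random.default_rng(1)
    binary = (rng.random((40, 8)) < 0.3).astype(int)
    p = fit_background(binary)
    assert np.allclose(p.sum(axis=1), binary.sum(axis=1), atol=1e-3)
    assert np.allclose(p.sum(axis=0), binary.sum(axis=0), atol=1e-3)
    assert ((p >= 0) & (p <= 1)).all()


def test_background_fit_handles_degenerate_margins():
    binary = np.zeros((10, 3), dtype=int)
    binary[0] = 1  # one fully altered patient, others empty
    p = fit_background(binary)
    assert p[0].sum() == pytest.approx(3, abs=1e-2)
    assert p[1:].sum() == pytest.approx(0, abs=1e-2)


# --- exclusivity test ------------------------------------------------------


def test_disjoint_exclusive_pair_small_p():
    n = 50
    binary = np.zeros((n, 2), dtype=int)
    for i in range(n):
        binary[i, i % 2] = 1
    m = _binary_matrix(binary)
    res = oc.exclusivity_test(m, ["g0", "g1"], n_sims=10_000, seed=1)
    assert res.coverage_observed == n
    assert res.p_value < 0.05


def test_single_gene_degenerate():
    binary = np.zeros((20, 2), dtype=int)
    binary[:6, 0] = 1
    binary[:5, 1] = 1
    m = _binary_matrix(binary)
    res = oc.exclusivity_test(m, ["g0"], n_sims=1000, seed=0)
    assert res.coverage_observed == 6
    assert res.p_value == 1.0


def test_exclusivity_deterministic_given_seed():
    rng = np.random.default_rng(3)
    binary = (rng.random((60, 10)) < 0.25).astype(int)
    m = _binary_matrix(binary)
    a = oc.exclusivity_test(m, ["g0", "g1"], n_sims=2000, seed=9)
    b = oc.exclusivity_test(m, ["g0", "g1"], n_sims=2000, seed=9)
    assert a.p_value == b.p_value


def test_exact_mode_agrees_on_strong_signal():
    n = 50
    binary = np.zeros((n, 2), dtype=int)
    for i in range(n):
        binary[i, i % 2] = 1
    m = _binary_matrix(binary)
    res = oc.exclusivity_test(m, ["g0", "g1"], method="exact")
    assert res.p_value < 0.05
    assert res.method == "exact"


def test_unknown_group_gene_rejected():
    m = _binary_matrix(np.ones((4, 2), dtype=int))
    with pytest.raises(ParseError):
        oc.exclusivity_test(m, ["nope"], n_sims=1000)


def test_too_few_sims_rejected():
    m = _binary_matrix(np.ones((4, 2), dtype=int))
    with pytest.raises(ValueError):
        oc.exclusivity_test(m, ["g0", "g1"], n_sims=10)


# --- FDR -------------------------------------------------------------------


def test_bh_single_p_unchanged():
    assert oc.fdr_adjust([0.2]) == pytest.approx([0.2])


def test_bh_hand_worked_example():
    q = oc.fdr_adjust([0.01, 0.02, 0.03, 0.9])
    assert q == pytest.approx([0.04, 0.04, 0.04, 0.9])


def test_bh_all_ones():
    assert oc.fdr_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])


def test_bh_q_at_least_p_and_monotone():
    rng = np.random.default_rng(0)
    p = rng.random(30)
    q = oc.fdr_adjust(p)
    assert (q >= p - 1e-12).all()
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        oc.fdr_adjust([0.5, 1.5])


# --- prevalence ------------------------------------------------------------


def test_prevalence_printed_arithmetic():
    binary = np.zeros((78, 1), dtype=int)
    binary[:47] = 1
    m = _binary_matrix(binary)
    assert oc.cohort_prevalence(m, ["g0"]) == (47, 78, 60.2)


def test_prevalence_seven_of_twelve():
    binary = np.zeros((12, 1), dtype=int)
    binary[:7] = 1
    m = _binary_matrix(binary)
    count, total, pct = oc.cohort_prevalence(m, ["g0"])
    assert (count, total, pct) == (7, 12, 58.3)
    assert round(pct) == 58


def test_prevalence_subset_denominator():
    binary = np.zeros((10, 1), dtype=int)
    binary[:4] = 1
    m = _binary_matrix(binary)
    count, total, pct = oc.cohort_prevalence(m, ["g0"], denominator=[f"p{i}" for i in range(8)])
    assert (count, total) == (4, 8)
    assert pct == 50.0


def test_prevalence_errors():
    m = _binary_matrix(np.ones((4, 1), dtype=int))
    with pytest.raises(ValueError):
        oc.cohort_prevalence(m, [])
    with pytest.raises(ValueError):
        oc.cohort_prevalence(m, ["g0"], denominator=[])
    with pytest.raises(ParseError):
        oc.cohort_prevalence(m, ["g0"], denominator=["stranger"])


# --- alteration-matrix construction ----------------------------------------


GENE_TABLE = {"CDK4": ("c1", 0, 1_000_000), "TP53": ("c2", 0, 1_000_000)}


def _var(gene, effect, chrom="c2", pos=500):
    return VariantRecord(chrom, pos, "C", "T", gene=gene, effect=effect,
                         context="ACA", presence={"S": 1})


def test_cna_overlap_records_amplification():
    ev = CNAEvent("c1", 500_000, 800_000, "amplification")
    m = oc.build_alteration_matrix({"pt": []}, {"pt": [ev]}, GENE_TABLE)
    assert m.cell("pt", "CDK4") == "amplification"


def test_severity_order_truncating_over_missense():
    recs = [_var("TP53", "missense"), _var("TP53", "truncating")]
    m = oc.build_alteration_matrix({"pt": recs}, {"pt": []}, GENE_TABLE)
    assert m.cell("pt", "TP53") == "truncating"


def test_cna_outranks_point_mutation():
    recs = [_var("CDK4", "missense", chrom="c1")]
    ev = CNAEvent("c1", 0, 900_000, "amplification")
    m = oc.build_alteration_matrix({"pt": recs}, {"pt": [ev]}, GENE_TABLE)
    assert m.cell("pt", "CDK4") == "amplification"


def test_unknown_gene_skipped_with_notice():
    with pytest.warns(UserWarning, match="skipped"):
        m = oc.build_alteration_matrix({"pt": [_var("MYSTERY", "truncating")]}, {"pt": []}, GENE_TABLE)
    assert m.cell("pt", "TP53") == "none"


def test_simulated_cohort_matrix_recovered(small_cohort):
    events = {}
    prioritized = {}
    for patient, recs in small_cohort.variants.items():
        kept, _ = oc.apply_hard_filters(recs)
        prioritized[patient] = oc.prioritize_pathogenic(kept)
        evs = []
        for s in small_cohort.ground_truth.patients[patient].samples:
            evs.extend(oc.classify_cna_events(small_cohort.segments[s], small_cohort.genome))
        events[patient] = evs
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m = oc.build_alteration_matrix(prioritized, events, small_cohort.gene_table,
                                       patients=list(small_cohort.variants))
    truth = small_cohort.alterations
    got = m.to_frame().loc[truth.patients, truth.genes].to_numpy()
    assert (got == truth.to_frame().to_numpy()).all()


def test_alteration_matrix_round_trip(tmp_path, small_cohort):
    path = tmp_path / "alts.tsv"
    oc.write_alteration_matrix(small_cohort.alterations, path)
    again = oc.read_alteration_matrix(path)
    assert again.patients == small_cohort.alterations.patients
    assert (again.cells == small_cohort.alterations.cells).all()
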