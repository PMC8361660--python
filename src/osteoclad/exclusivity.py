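"""Mutual-exclusivity testing of driver alterations, FDR control, and cohort
prevalence arithmetic.

The exclusivity test follows the margin-constrained coverage idea: per-cell
background alteration probabilities ``p_ij = sigmoid(a_i + b_j)`` are fitted
so that expected patient and gene totals match the observed binary matrix
(iterative proportional fitting on the logistic parameterisation). The test
statistic is group coverage — the number of patients altered in at least one
group gene — and the one-sided p-value asks how often a background-driven
reallocation of the same alterations covers at least as many patients
(mutual exclusivity spreads a fixed number of alterations over MORE
patients).

The default null (``conditional``) holds each group gene's alteration count
fixed at its observed value and redraws WHICH patients carry it, with
per-patient inclusion probabilities tilted by the fitted background
(conditional-Bernoulli sampling). Conditioning on the gene margins is what
keeps the coverage statistic calibrated: the observed coverage is itself a
function of those margins, so a null that lets them refloat (independent
per-cell draws) overstates the null variance and is conservative. That
unconditional variant is retained as ``monte_carlo`` and, via the exact
Poisson-binomial tail of per-patient coverage indicators, as ``exact`` —
both documented as conservative diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._tsv import read_hashed_tsv, write_hashed_tsv
from .errors import ConvergenceError, ParseError

ALTERATION_CATEGORIES = ("none", "amplification", "biallelic_deletion", "truncating", "missense", "fusion")

# severity order for collapsing multiple alterations of one gene in one patient
_SEVERITY = {"amplification": 4, "biallelic_deletion": 4, "truncating": 3, "fusion": 2, "missense": 1, "none": 0}


@dataclass
class AlterationMatrix:
    """Patients x genes categorical alteration matrix."""

    patients: list[str]
    genes: list[str]
    cells: np.ndarray  # dtype object of category strings

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=object)
        if self.cells.shape != (len(self.patients), len(self.genes)):
            raise ParseError("alteration matrix shape mismatch")
        bad = {c for c in self.cells.ravel() if c not in ALTERATION_CATEGORIES}
        if bad:
            raise ParseError(f"unknown alteration categories: {sorted(bad)}")

    def binary(self) -> np.ndarray:
        return (self.cells != "none").astype(int)

    def cell(self, patient: str, gene: str) -> str:
        return self.cells[self.patients.index(patient), self.genes.index(gene)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cells, index=self.patients, columns=self.genes)


def read_alteration_matrix(path) -> AlterationMatrix:
    df = read_hashed_tsv(path, required=("patient",))
    genes = [c for c in df.columns if c != "patient"]
    return AlterationMatrix(
        patients=[str(p) for p in df["patient"]],
        genes=genes,
        cells=df[genes].fillna("none").to_numpy(dtype=object),
    )


def write_alteration_matrix(matrix: AlterationMatrix, path) -> None:
    df = matrix.to_frame().reset_index().rename(columns={"index": "patient"})
    write_hashed_tsv(df, path, preamble=["patient x gene alteration matrix"])


def build_alteration_matrix(prioritized_variants, cna_events_by_patient: dict[str, list],
                            gene_table: dict[str, tuple[str, int, int]],
                            patients: list[str] | None = None) -> AlterationMatrix:
    """Merge prioritized variants with copy-number events into the alteration
    matrix.

    ``prioritized_variants`` maps patient -> list of VariantRecord;
    ``cna_events_by_patient`` maps patient -> list of CNAEvent;
    ``gene_table`` maps gene symbol -> (chrom, start, end) on the build
    (0-based half-open). The recorded category per (patient, gene) is the
    highest-severity alteration: amplification/biallelic deletion from CNA
    overlap, then truncating, then missense. Genes absent from the table are
    skipped with a notice.
    """
    import warnings

    if patients is None:
        patients = sorted(set(prioritized_variants) | set(cna_events_by_patient))
    genes = sorted(gene_table)
    cells = np.full((len(patients), len(genes)), "none", dtype=object)
    gi = {g: j for j, g in enumerate(genes)}

    def bump(i: int, g: str, category: str) -> None:
        j = gi[g]
        if _SEVERITY[category] > _SEVERITY[cells[i, j]]:
            cells[i, j] = category

    skipped: set[str] = set()
    for i, patient in enumerate(patients):
        for rec in prioritized_variants.get(patient, []):
            if rec.gene in (".", "", None):
                continue
            if rec.gene not in gi:
                skipped.add(rec.gene)
                continue
            if rec.effect in ("truncating", "splice"):
                bump(i, rec.gene, "truncating")
            elif rec.effect == "missense":
                bump(i, rec.gene, "missense")
        for ev in cna_events_by_patient.get(patient, []):
            if ev.kind not in ("amplification", "biallelic_deletion"):
                continue
            for g, (chrom, start, end) in gene_table.items():
                if ev.chrom == chrom and ev.start < end and start < ev.end:
                    bump(i, g, ev.kind)
    if skipped:
        warnings.warn(f"build_alteration_matrix: genes not in gene table skipped: {sorted(skipped)}",
                      stacklevel=2)
    return AlterationMatrix(list(patients), genes, cells)


# ---------------------------------------------------------------------------
# margin-constrained background fit
# ---------------------------------------------------------------------------

_CLAMP = 30.0


def _solve_offsets(fixed: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Per-offset Newton solve of  sum_j sigmoid(a_i + fixed_j) = targets_i."""
    a = np.zeros(targets.shape[0])
    for _ in range(60):
        z = a[:, None] + fixed[None, :]
        p = 1.0 / (1.0 + np.exp(-np.clip(z, -_CLAMP, _CLAMP)))
        f = p.sum(axis=1) - targets
        df = (p * (1 - p)).sum(axis=1)
        step = np.where(df > 1e-12, f / np.maximum(df, 1e-12), 0.0)
        a = np.clip(a - step, -_CLAMP, _CLAMP)
        if np.max(np.abs(f)) < 1e-12:
            break
    return a


def fit_background(binary: np.ndarray, tol: float = 1e-8, max_iter: int = 500) -> np.ndarray:
    """Fit p_ij = sigmoid(a_i + b_j) matching patient and gene margins.

    Returns the (n_patients, n_genes) probability matrix. Degenerate margins
    (all-zero or all-one rows/columns) saturate at clamped probabilities.
    Raises :class:`ConvergenceError` if margins are not matched to ``tol``
    (relative to the matrix size) within ``max_iter`` sweeps.
    """
    binary = np.asarray(binary)
    n, m = binary.shape
    row_t = binary.sum(axis=1).astype(float)
    col_t = binary.sum(axis=0).astype(float)
    a = np.zeros(n)
    b = np.zeros(m)
    for _ in range(max_iter):
        a = _solve_offsets(b, row_t)
        b = _solve_offsets(a, col_t)
        z = np.clip(a[:, None] + b[None, :], -_CLAMP, _CLAMP)
        p = 1.0 / (1.0 + np.exp(-z))
        err = max(
            np.max(np.abs(p.sum(axis=1) - row_t)) if n else 0.0,
            np.max(np.abs(p.sum(axis=0) - col_t)) if m else 0.0,
        )
        # saturated (degenerate) margins cannot be matched better than the clamp
        saturated = (row_t == 0).any() or (row_t == m).any() or (col_t == 0).any() or (col_t == n).any()
        if err < tol * max(1.0, n * m) or (saturated and err < 1e-6 * n * m + 1e-3):
            return p
    if err < 1e-4 * max(n, m):
        return p
    raise ConvergenceError(f"background fit did not converge (margin error {err:g})")


@dataclass
class ExclusivityResult:
    group: list[str]
    coverage_observed: int
    coverage_expected: float
    p_value: float
    q_value: float | None = None
    method: str = "monte_carlo"


def _poisson_binomial_tail(q: np.ndarray, k: int) -> float:
    """P(X >= k) for X = sum of independent Bernoulli(q_i), by dynamic
    programming over the exact distribution."""
    pmf = np.array([1.0])
    for qi in q:
        pmf = np.convolve(pmf, [1 - qi, qi])
    return float(pmf[k:].sum())


def _conditional_subset_draws(p: np.ndarray, m: int, n_sims: int,
                              rng: np.random.Generator) -> np.ndarray:
    """Draw ``n_sims`` subsets of exactly ``m`` patients with inclusion
    probabilities proportional to the conditional-Bernoulli model tilted by
    ``p`` (weights p/(1-p)); returns a boolean (n_sims, n) matrix.

    Uses the standard log-space DP over suffix subset-weight sums, then
    sequential sampling vectorised across replicates.
    """
    n = p.size
    p = np.clip(p, 1e-12, 1 - 1e-12)
    logw = np.log(p) - np.log1p(-p)
    # logR[i, k] = log sum over subsets of size k from items i..n-1 of prod w
    logR = np.full((n + 1, m + 1), -np.inf)
    logR[n, 0] = 0.0
    for i in range(n - 1, -1, -1):
        logR[i, 0] = 0.0
        kmax = min(m, n - i)
        take = logw[i] + logR[i + 1, : kmax]  # sizes 1..kmax use k-1 = 0..kmax-1
        logR[i, 1 : kmax + 1] = np.logaddexp(logR[i + 1, 1 : kmax + 1], take)
    out = np.zeros((n_sims, n), dtype=bool)
    k = np.full(n_sims, m, dtype=int)
    for i in range(n):
        active = k > 0
        if not active.any():
            break
        log_num = logw[i] + logR[i + 1, np.maximum(k - 1, 0)]
        with np.errstate(invalid="ignore"):
            prob = np.exp(log_num - logR[i, k])
        prob = np.where(active, np.nan_to_num(prob, nan=0.0), 0.0)
        include = rng.random(n_sims) < prob
        out[:, i] = include
        k = k - include.astype(int)
    return out


def exclusivity_test(matrix: AlterationMatrix, group: list[str], n_sims: int = 10_000,
                     seed: int | None = None, method: str = "conditional") -> ExclusivityResult:
    """Test a gene group for mutual exclusivity via margin-constrained
    coverage (see module docstring).

    The background is fitted on the FULL matrix (all genes), then coverage is
    assessed over the group columns. ``method``:

    * ``conditional`` (default) — Monte-Carlo reallocation of each group
      gene's observed alteration count with background-tilted weights;
      calibrated; deterministic given ``seed``; requires ``n_sims >= 1000``.
    * ``monte_carlo`` — independent per-cell draws with the fitted ``p_ij``;
      conservative (the null lets the gene margins refloat).
    * ``exact`` — exact Poisson-binomial coverage tail of the independent
      null; conservative like ``monte_carlo`` but deterministic, recommended
      for groups of up to three genes.
    """
    missing = [g for g in group if g not in matrix.genes]
    if missing:
        raise ParseError(f"group genes not in matrix: {missing}")
    binary = matrix.binary()
    cols = [matrix.genes.index(g) for g in group]
    observed = int((binary[:, cols].sum(axis=1) > 0).sum())
    p = fit_background(binary)
    pg = p[:, cols]  # (n_patients, |group|)
    q = 1.0 - np.prod(1.0 - pg, axis=1)  # per-patient coverage probability
    expected = float(q.sum())
    if len(group) == 1:
        return ExclusivityResult(list(group), observed, expected, 1.0, method="degenerate")
    if method == "exact":
        pval = _poisson_binomial_tail(q, observed)
        return ExclusivityResult(list(group), observed, expected, min(1.0, pval), method="exact")
    if method not in ("monte_carlo", "conditional"):
        raise ValueError(f"unknown method {method!r}")
    if n_sims < 1000:
        raise ValueError("n_sims must be >= 1000 for the Monte-Carlo tail")
    rng = np.random.default_rng(seed)
    if method == "conditional":
        covered = np.zeros((n_sims, binary.shape[0]), dtype=bool)
        for j, c in enumerate(cols):
            m_j = int(binary[:, c].sum())
            if m_j == 0:
                continue
            covered |= _conditional_subset_draws(pg[:, j], m_j, n_sims, rng)
        hits = int((covered.sum(axis=1) >= observed).sum())
    else:
        hits = 0
        chunk = max(1, min(n_sims, int(5e7 // max(1, q.size))))
        done = 0
        while done < n_sims:
            b = min(chunk, n_sims - done)
            draws = rng.random((b, q.size)) < q[None, :]
            hits += int((draws.sum(axis=1) >= observed).sum())
            done += b
    pval = (1 + hits) / (1 + n_sims)  # add-one for a valid p-value
    return ExclusivityResult(list(group), observed, expected, pval, method=method)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, q >= p)."""
    from scipy.stats import false_discovery_control

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return false_discovery_control(p, method="bh")


def cohort_prevalence(matrix: AlterationMatrix, gene_set: list[str],
                      denominator: str | list[str] = "all",
                      qualifying: tuple[str, ...] = ("amplification", "biallelic_deletion",
                                                     "truncating", "missense", "fusion")) -> tuple[int, int, float]:
    """Count patients with >= 1 qualifying alteration in ``gene_set``.

    ``denominator`` is either ``"all"`` patients or an explicit patient
    subset. Returns (count, total, percent) with percent = 100*count/total
    reported at one decimal, truncated (report convention: 47/78 prints as
    60.2%, not 60.3%).
    """
    if not gene_set:
        raise ValueError("gene_set must be non-empty")
    missing = [g for g in gene_set if g not in matrix.genes]
    if missing:
        raise ParseError(f"genes not in matrix: {missing}")
    if denominator == "all":
        pool = list(matrix.patients)
    else:
        pool = list(denominator)
        unknown = [p for p in pool if p not in matrix.patients]
        if unknown:
            raise ParseError(f"denominator patients not in matrix: {unknown}")
    if not pool:
        raise ValueError("zero denominator")
    cols = [matrix.genes.index(g) for g in gene_set]
    rows = [matrix.patients.index(p) for p in pool]
    sub = matrix.cells[np.ix_(rows, cols)]
    count = int(np.array([[c in qualifying for c in row] for row in sub]).any(axis=1).sum())
    percent = int(1000.0 * count / len(pool) + 1e-9) / 10.0  # truncate at one decimal
    return count, len(pool), percent
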