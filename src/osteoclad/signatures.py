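"""96-channel mutational-signature counting and exposure fitting.

Channels follow the standard pyrimidine convention: labels ``X[R>A]Y`` where
``R`` is the pyrimidine reference base (C or T), ``A`` the alternate, and
``X``/``Y`` the 5'/3' flanking bases, ordered substitution-major
(C>A, C>G, C>T, T>A, T>C, T>G) then 5' flank then 3' flank. Purine-reference
SNVs are mapped by reverse complement.

Exposure fitting treats the channel counts as draws from a multinomial
mixture of fixed reference signatures and estimates the non-negative mixing
weights by expectation-maximisation (count mode: exposures sum to the total
mutation count). A projected non-negative least-squares mode is provided as
an independent cross-check.

The shipped reference table is SYNTHETIC: stylised renditions of the aging
(AC1), homologous-recombination-deficiency (AC3), mismatch-repair (AC6) and
UV (AC7) signatures plus a flat background, constructed in
:func:`builtin_signatures`. They capture the canonical qualitative features
(CpG-focused C>T for aging, a broad near-flat profile for HRD, T>C-heavy MMR,
dipyrimidine C>T for UV) but are NOT the published reference vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._tsv import read_hashed_tsv, write_hashed_tsv
from .errors import ConvergenceError
from .variants import VariantRecord, revcomp

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = ("A", "C", "G", "T")

CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}" for sub in SUBSTITUTIONS for five in BASES for three in BASES
)
_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS)}


def channel_of(ref: str, alt: str, context: str) -> str:
    """Map an SNV with reference-strand trinucleotide ``context`` to its
    pyrimidine-convention channel label."""
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if context[1] != ref:
        raise ValueError(f"context {context} middle base != ref {ref}")
    if ref in "AG":
        ref, alt, context = revcomp(ref), revcomp(alt), revcomp(context)
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


@dataclass
class SignatureMatrix:
    """Reference signatures: 96 channel probabilities per named signature."""

    names: list[str]
    matrix: np.ndarray  # (96, k), columns sum to 1

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (96, len(self.names)):
            raise ValueError(f"signature matrix shape {self.matrix.shape} != (96, {len(self.names)})")
        if (self.matrix < 0).any():
            raise ValueError("signature probabilities must be non-negative")
        sums = self.matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError(f"signature columns must sum to 1 (got {sums})")

    @property
    def k(self) -> int:
        return len(self.names)

    def subset(self, names: list[str]) -> "SignatureMatrix":
        idx = [self.names.index(n) for n in names]
        return SignatureMatrix(list(names), self.matrix[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(CHANNELS), columns=self.names)


def builtin_signatures() -> SignatureMatrix:
    """Construct the shipped synthetic reference signatures (see module docs)."""
    k = {}

    def blank() -> np.ndarray:
        return np.full(96, 1.0)  # unnormalised; flat floor keeps support full

    # AC1 (aging): C>T at NpCpG strongly elevated, other C>T modest.
    v = blank()
    for i, ch in enumerate(CHANNELS):
        if "[C>T]" in ch and ch.endswith("G"):
            v[i] += 140.0
        elif "[C>T]" in ch:
            v[i] += 12.0
    k["AC1"] = v

    # AC3 (HRD): broad, gentle excess of C>G and T>A over the flat floor.
    v = blank()
    for i, ch in enumerate(CHANNELS):
        if "[C>G]" in ch or "[T>A]" in ch:
            v[i] += 4.0
    k["AC3"] = v

    # AC6 (MMR deficiency): T>C dominant with secondary non-CpG C>T.
    v = blank()
    for i, ch in enumerate(CHANNELS):
        if "[T>C]" in ch:
            v[i] += 30.0
        elif "[C>T]" in ch and not ch.endswith("G"):
            v[i] += 10.0
    k["AC6"] = v

    # AC7 (UV): C>T with a 5' pyrimidine (dipyrimidine context).
    v = blank()
    for i, ch in enumerate(CHANNELS):
        if "[C>T]" in ch and ch[0] in "CT":
            v[i] += 60.0
    k["AC7"] = v

    k["background"] = blank()

    names = list(k)
    mat = np.column_stack([k[n] / k[n].sum() for n in names])
    return SignatureMatrix(names, mat)


def load_signature_matrix(path: str | Path) -> SignatureMatrix:
    df = read_hashed_tsv(path, required=("channel",))
    names = [c for c in df.columns if c != "channel"]
    df = df.set_index("channel").astype(float)
    df = df.loc[list(CHANNELS)]
    return SignatureMatrix(names, df.to_numpy())


def write_signature_matrix(sig: SignatureMatrix, path: str | Path,
                           preamble: list[str] | None = None) -> None:
    df = sig.to_frame().reset_index().rename(columns={"index": "channel"})
    write_hashed_tsv(df, path, preamble=preamble or ["96-channel signature probabilities"])


def count_channels_96(variants: list[VariantRecord], sample: str | None = None) -> np.ndarray:
    """Tally SNVs into the 96 channels for one sample (or all records when
    ``sample`` is None). Records without a context are skipped with a notice;
    indels never enter the tally."""
    counts = np.zeros(96, dtype=int)
    skipped = 0
    for rec in variants:
        if sample is not None and not rec.presence.get(sample, 0):
            continue
        if not rec.is_snv:
            continue
        if rec.context is None:
            skipped += 1
            continue
        counts[_CHANNEL_INDEX[channel_of(rec.ref, rec.alt, rec.context)]] += 1
    if skipped:
        import warnings

        warnings.warn(f"count_channels_96: skipped {skipped} SNV(s) without context", stacklevel=2)
    return counts


@dataclass
class ExposureEstimate:
    sample_id: str
    signatures: list[str]
    exposures: np.ndarray  # mutation counts attributed to each signature
    log_likelihood: float
    n_iter: int
    converged: bool
    ll_trace: np.ndarray | None = None

    @property
    def total(self) -> float:
        return float(self.exposures.sum())

    @property
    def proportions(self) -> np.ndarray:
        t = self.total
        return self.exposures / t if t > 0 else np.zeros_like(self.exposures)

    def exposure_of(self, name: str) -> float:
        return float(self.exposures[self.signatures.index(name)])


def fit_exposures(counts: np.ndarray, reference: SignatureMatrix,
                  mode: str = "em", sample_id: str = "sample",
                  tol: float = 1e-8, max_iter: int = 10_000) -> ExposureEstimate:
    """Estimate signature exposures for one sample's 96-channel counts.

    ``em`` (default): multinomial-mixture EM from a uniform initialisation;
    the log-likelihood is non-decreasing by construction and iteration stops
    when its relative change falls below ``tol``. Exposures sum to the total
    count. ``nnls`` solves min ||S w - c||_2, w >= 0 and rescales to the
    count total — an independent cross-check, not the primary estimator.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (96,):
        raise ValueError("counts must be a 96-vector")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    n = counts.sum()
    if n == 0:
        import warnings

        warnings.warn("fit_exposures: zero total count; returning zero exposures", stacklevel=2)
        return ExposureEstimate(sample_id, list(reference.names), np.zeros(reference.k), 0.0, 0, True)

    S = reference.matrix  # (96, k)
    if mode == "nnls":
        from scipy.optimize import nnls

        w, _ = nnls(S, counts / n)
        w = w / w.sum() * n if w.sum() > 0 else w
        probs = S @ (w / n)
        with np.errstate(divide="ignore"):
            ll = float(np.where(counts > 0, counts * np.log(np.maximum(probs, 1e-300)), 0.0).sum())
        return ExposureEstimate(sample_id, list(reference.names), w, ll, 1, True)
    if mode != "em":
        raise ValueError(f"unknown mode {mode!r}")

    w = np.full(reference.k, n / reference.k)  # uniform, deterministic
    prev_ll = -np.inf
    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mix = w / n
        probs = S @ mix  # (96,)
        probs = np.maximum(probs, 1e-300)
        ll = float(np.where(counts > 0, counts * np.log(probs), 0.0).sum())
        if ll + 1e-9 < prev_ll:  # EM guarantee; violation indicates a bug
            raise ConvergenceError(f"EM log-likelihood decreased at iteration {it}")
        trace.append(ll)
        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * max(1.0, abs(prev_ll)):
            converged = True
            break
        prev_ll = ll
        # responsibilities: r_ck = s_ck m_k / sum_k' ; exposure update
        resp = S * mix[None, :] / probs[:, None]  # (96, k)
        w = resp.T @ counts
    return ExposureEstimate(sample_id, list(reference.names), w, trace[-1], it, converged,
                            ll_trace=np.array(trace))
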