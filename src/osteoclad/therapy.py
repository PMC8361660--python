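"""Genomics-guided CDK/PARP therapy decision rules.

The eligibility logic reflects G1 cell-cycle wiring: CDK4/6 inhibition
requires an amplified cyclin D3/CDK4/CDK6 axis with intact Rb and no CCNE1
amplification (CCNE1 amplification phosphorylates Rb through CDK2 and
confers CDK4/6-inhibitor resistance, Rb loss disconnects the axis entirely);
CDK2 inhibition requires CCNE1 amplification with wild-type Rb; PARP
inhibition requires homologous-recombination deficiency, established either
by the composite scar score or a pathogenic BRCA1/BRCA2 mutation. Patients
qualifying for nothing targeted receive standard of care only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .hrd import HRDResult, hrd_classify

CDK46_INHIBITION = "CDK4/6 inhibition"
CDK2_INHIBITION = "CDK2 inhibition"
PARP_INHIBITION = "PARP inhibition"
STANDARD_OF_CARE = "standard-of-care only"

MARKER_FLAGS = (
    "ccnd3_amp",
    "cdk4_amp",
    "cdk6_amp",
    "ccne1_amp",
    "rb1_lof",
    "cdkn2a_del",
    "brca1_path",
    "brca2_path",
)


@dataclass
class Genotype:
    """Binary marker flags plus the HRD result for one patient."""

    ccnd3_amp: int = 0
    cdk4_amp: int = 0
    cdk6_amp: int = 0
    ccne1_amp: int = 0
    rb1_lof: int = 0
    cdkn2a_del: int = 0
    brca1_path: int = 0
    brca2_path: int = 0
    hrd: HRDResult | None = None

    def __post_init__(self) -> None:
        for name in MARKER_FLAGS:
            v = getattr(self, name)
            if v not in (0, 1):
                raise ValueError(f"{name} must be 0 or 1 (got {v!r})")


@dataclass
class TherapyRecommendation:
    patient: str
    options: list[str]
    rule_trace: list[tuple[str, bool]] = field(default_factory=list)


def recommend_therapy(genotype: Genotype, patient: str = "patient",
                      cdkn2a_widens_cdk46: bool = False) -> TherapyRecommendation:
    """Evaluate the therapy decision tree for one genotype.

    ``cdkn2a_widens_cdk46`` optionally lets a CDKN2A deletion stand in for the
    amplification arm of the CDK4/6 gate (off by default: the gate lists
    amplifications only).

    The returned ``rule_trace`` records every evaluated condition in order.
    The function is total over the genotype space and never recommends CDK4/6
    inhibition together with CCNE1 amplification or Rb loss, nor CDK2
    inhibition with Rb loss.
    """
    g = genotype
    trace: list[tuple[str, bool]] = []
    options: list[str] = []

    cdk46_axis = bool(g.ccnd3_amp or g.cdk4_amp or g.cdk6_amp)
    if cdkn2a_widens_cdk46:
        cdk46_axis = cdk46_axis or bool(g.cdkn2a_del)
    trace.append(("CCND3/CDK4/CDK6 axis amplified", cdk46_axis))
    trace.append(("RB1 intact", not g.rb1_lof))
    trace.append(("no CCNE1 amplification", not g.ccne1_amp))
    if cdk46_axis and not g.rb1_lof and not g.ccne1_amp:
        options.append(CDK46_INHIBITION)

    trace.append(("CCNE1 amplified", bool(g.ccne1_amp)))
    if g.ccne1_amp and not g.rb1_lof:
        options.append(CDK2_INHIBITION)

    if g.hrd is not None:
        hrd = g.hrd
        if hrd.positive is None:
            hrd = hrd_classify(hrd, brca_status=hrd.brca_status)
    else:
        brca = "pathogenic" if (g.brca1_path or g.brca2_path) else "wildtype"
        hrd = hrd_classify((0, 0, 0), brca_status=brca)
    if (g.brca1_path or g.brca2_path) and hrd.brca_status != "pathogenic":
        hrd = hrd_classify(hrd.as_tuple(), brca_status="pathogenic")
    trace.append(("HRD positive (scar score or BRCA1/2 route)", bool(hrd.positive)))
    if hrd.positive:
        options.append(PARP_INHIBITION)

    if not options:
        options.append(STANDARD_OF_CARE)
    return TherapyRecommendation(patient=patient, options=options, rule_trace=trace)


def genotype_from_alterations(cells: dict[str, str], hrd: HRDResult | None = None) -> Genotype:
    """Derive marker flags from a patient's alteration-matrix row.

    Amplification flags require category ``amplification``; loss-of-function
    flags accept ``truncating`` or ``biallelic_deletion``; BRCA pathogenicity
    accepts truncating or biallelic deletion.
    """

    def amp(gene: str) -> int:
        return int(cells.get(gene, "none") == "amplification")

    def lof(gene: str) -> int:
        return int(cells.get(gene, "none") in ("truncating", "biallelic_deletion"))

    return Genotype(
        ccnd3_amp=amp("CCND3"),
        cdk4_amp=amp("CDK4"),
        cdk6_amp=amp("CDK6"),
        ccne1_amp=amp("CCNE1"),
        rb1_lof=lof("RB1"),
        cdkn2a_del=int(cells.get("CDKN2A", "none") == "biallelic_deletion"),
        brca1_path=lof("BRCA1"),
        brca2_path=lof("BRCA2"),
        hrd=hrd,
    )
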