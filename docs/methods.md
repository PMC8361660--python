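# Methods

`osteoclad` re-implements, as a tested library, the computational arc of a
longitudinal osteosarcoma genome study: paired primary and recurrence samples
per patient, somatic SNVs and allele-specific copy-number segments per sample,
and downstream analytics — filtering, phylogenetics, genomic-scar scoring,
signature timing, driver exclusivity, and therapy rules. Because such cohort
data are controlled-access, the package carries its own synthetic-cohort
generator with complete ground truth; every analytical claim in the test suite
is checked against that ground truth or an independent oracle.

## Variant filtering and prioritization

Hard site filters use the GATK-style annotations with strict inequalities:
QD > 10, MQ > 40, FS < 30, SOR < 3, MQRankSum > −12.5, ReadPosRankSum > −8.
Boundary values fail. Metrics absent from a record never fail it — rank-sum
annotations are undefined for some genotype configurations, and penalising
missingness would silently bias against homozygous sites.

Prioritization keeps protein-truncating and splice variants unconditionally,
keeps entries on a user-supplied curated list (a file, not a live database
query), and otherwise requires all six in-silico scores to be present and
strictly passing: SIFT < 0.05, PolyPhen2 > 0.7, MutationTaster > 0.7,
GERP++ > 0, CADD > 10, PhyloP > 0. A record missing any score cannot pass the
in-silico route. Hard filters are applied before curated-list rescue; "PhyloP"
is read as a single value (the vertebrate/placental track distinction is not
modelled).

## Maximum-parsimony phylogenies

Samples (tumors plus an all-zero normal outgroup) × variants form a binary
presence matrix. Tree length is two-state Fitch parsimony; the implicit
outgroup forces state 0 at the root. Exhaustive search enumerates all
(2n−3)!! rooted topologies over the n tumor samples (capped at 10 matrix
rows); the heuristic combines seeded random-addition stepwise insertion with
nearest-neighbor-interchange hill climbing, is deterministic given its seed,
and can only over- never under-estimate the optimum. The homoplasy index is
1 − (number of variant columns)/(tree length), i.e. one minus the consistency
index with a per-binary-column minimum of one change.

Bootstrap support resamples variant columns with replacement and reports, for
each clade of the observed best tree, the fraction of replicates whose strict
consensus of best trees contains that clade (tumor-leaf bipartitions;
outgroup excluded). Ties among equally parsimonious trees are all returned in
exhaustive mode; downstream summaries use the canonically first best tree,
with the strict consensus available for tie-aware reporting.

Variants map to edges by carrier set: a single-origin variant sits on the
unique edge subtending exactly its carriers; a homoplastic variant is flagged
and placed on every change edge of one minimal Fitch labeling (parent-state
preference on the top-down pass). The trunk is the edge from the root to the
common ancestor of all tumor samples; trunk variants are exactly those
carried by every sample. The ns/s report is a raw count ratio (trunk and
pooled non-trunk), undefined — never infinite — when the synonymous
denominator is zero; no codon-model correction is attempted.

## Copy-number analytics

All burden and scar computations use autosomes only and a diploid baseline.
Altered fraction is the proportion of autosomal bases at total copy ≠ 2
(uncovered bases count as neutral). Pairwise Jaccard similarity classifies
each base as loss/neutral/gain and divides same-direction altered overlap by
the altered union; two fully neutral profiles are defined as similarity 1
with a notice. Events merge adjacent same-kind segments, call amplification
at total copy ≥ 5 and biallelic deletion at 0, and split focal/broad at the
10 Mb cytogenetic threshold (strictly less is focal).

Complex events are detected on total-copy-merged segments. Chromothripsis: a
maximal contiguous region whose copy sequence switches ≥ 10 times among ≤ 3
distinct total-copy states (both parameters exposed; the defaults are this
package's operating choices — the source analysis was descriptive).
Staircase: ≥ 3 strictly monotonically increasing non-diploid segments whose
highest-copy boundary lies within 1 Mb of a centromere edge (centromeric) or
chromosome end (telomeric); the copy-neutral baseline adjoining an ascent is
not a step.

## HRD genomic-scar scores

Per sample, on autosomes, with strict size cutoffs throughout:

* **LOH** — merged regions with minor copy 0 and ≥ 1 copy retained, longer
  than 15 Mb, excluding whole-chromosome LOH (the original definition's
  exclusion, restorable via a flag since the source's one-line summary omits
  it).
* **TAI** — merged allele-imbalanced regions longer than 11 Mb with one
  boundary at a chromosome end and contained in a single arm. The telomere
  anchor is exact by default; a window parameter accommodates noisy
  segmentations.
* **LST** — within each arm, after merging identical contiguous states,
  deleting segments shorter than 3 Mb, and re-merging identical flanks,
  junctions between two segments each longer than 10 Mb with different
  allele-specific states. Junctions across the centromere are not counted
  (the original definition is arm-wise). Merging identical states *before*
  the small-segment filter is deliberate: it is what makes all three scores
  invariant under arbitrary splitting of segments into identical-state
  pieces, a property the test suite fuzzes.

The composite is the raw sum; positivity at ≥ 42 or via pathogenic
BRCA1/BRCA2 status. (A strictly-greater variant of the threshold is provided
because the source material states the rule both ways; the default follows
its Methods wording.) An optional linear ploidy adjustment of LST
(−2.5 per ploidy unit above 2, interpolating the published near-diploid vs
near-tetraploid cutoffs) is reported alongside, never inside, the composite.

## Signatures and molecular-clock timing

SNVs are tallied into the 96 trinucleotide channels (pyrimidine convention,
purine-reference variants reverse-complemented). Exposures are estimated by
EM for a multinomial mixture with fixed signature columns: uniform
deterministic initialisation, responsibility/weight updates, non-decreasing
log-likelihood asserted at every iteration, convergence at a relative
log-likelihood change below 1e-8 (cap 10,000 iterations), exposures summing
to the sample's mutation count. A projected NNLS fit is kept as an
independent cross-check.

The shipped reference table (`data/signatures_96_synthetic.tsv`, also
constructed by `builtin_signatures()`) is **synthetic**: stylised renditions
of the aging (AC1: CpG-focused C>T), HRD (AC3: broad, mild C>G/T>A excess),
mismatch-repair (AC6: T>C-heavy with non-CpG C>T), and UV (AC7: dipyrimidine
C>T) signatures plus a flat background. They reproduce the canonical
qualitative features and are mutually well-separated, but they are not the
published reference vectors; any user-supplied 96×k table can be used
instead. Consequently, recovery results quantify the estimator, not the
identifiability of the published catalogue.

Timing assumes clonal clock-signature mutations accumulate linearly in
calendar time at rate r per month. Walking backwards: origin = (primary
clonal clock count)/r months before the primary biopsy; divergence =
(trunk-shared clock count)/r months after origin. r is the least-squares
slope of clonal clock count against collection month — per patient by
default, or pooled across patients by within-patient fixed-effects regression
(`estimate_cohort_clock_rate`) when a shared clock is the modelling
assumption. The pooled mode exists because a Poisson error analysis shows a
single patient with four samples cannot pin r much better than ~10%, which
propagates to roughly a month of origin uncertainty; sharing the rate across
a cohort removes most of that term. Uncertainty intervals come from Poisson
resampling of the counts with a fixed seed. A non-positive slope raises an
explicit clock-violation error rather than returning a meaningless date.

## Mutual exclusivity

Background alteration probabilities p_ij = sigmoid(a_i + b_j) are fitted by
alternating per-row/per-column Newton steps so that expected patient and gene
totals match the observed binary matrix. The statistic is group coverage
(patients hit in ≥ 1 group gene); exclusivity pushes coverage high for fixed
gene totals. The default null holds each group gene's alteration count at its
observed value and redraws its carriers by conditional-Bernoulli sampling
tilted by p_ij (log-space dynamic programming over suffix subset weights,
vectorised across replicates); the p-value is the add-one Monte-Carlo tail,
deterministic given the seed.

Conditioning on the gene margins is essential: the observed coverage is a
function of those margins, and a null of fully independent per-cell draws
(retained as the `monte_carlo` and exact-Poisson-binomial `exact` modes)
inflates the null variance by letting the margins refloat — measured on
independent-gene simulations, that version essentially never rejects at
α = 0.05. Calibration of the conditional test depends on how well per-patient
loads are estimated, hence on matrix width: measured type-I at α = 0.05 is
≈ 0.077 with a 20-gene background, ≈ 0.04–0.05 with 50 genes, drifting
conservative (≈ 0.03) by 200 genes. The test is designed for driver-panel- to
genome-scale matrices; results on very narrow matrices should be read with
that bias in mind. Benjamini–Hochberg adjustment is delegated to
`scipy.stats.false_discovery_control`.

Cohort prevalence reports counts and a percentage truncated at one decimal —
the truncation (not rounding) matches the report convention of the source
figures (47/78 prints as 60.2, not 60.3).

## Therapy decision rules

CDK4/6 inhibition requires an amplified cyclin-D3/CDK4/CDK6 axis, intact Rb,
and no CCNE1 amplification (CCNE1 drives Rb phosphorylation through CDK2 and
confers CDK4/6-inhibitor resistance; Rb loss disconnects the axis). CDK2
inhibition requires CCNE1 amplification with wild-type Rb. PARP inhibition
requires HRD positivity by composite score or BRCA1/2 route. CDKN2A deletion
does not open the CDK4/6 gate by default (an opt-in flag widens it). PALB2 is
reportable annotation, not a PARP gate. The function is total over the
genotype space and emits an ordered rule trace; an exhaustive truth-table
test verifies totality and the non-contradiction invariants.

## Synthetic cohort generator

The generator emulates the discovery design: 12 patients, 2–4 samples each
(primary at month 0, recurrences at 3–9 months), clock rate 8
mutations/month, origin 9 months before the primary biopsy, first divergence
3 months after origin, later splits uniform before the biopsy. Clock
mutations are Poisson per edge (rate × duration, attributed to the aging
signature); non-clock mutations are drawn at the complementary rate from the
remaining mixture (default aging-dominated: 0.7/0.1/0.1/0.1 over
AC1/AC3/AC6/AC7) and assigned uniformly over positive-duration edges.
Per-sample presence follows tree descent, so simulated matrices are perfect
phylogenies — homoplasy enters only through downstream resampling, which is
what makes exact ground-truth recovery a meaningful oracle. The
`snv_count_range` field validates that the configured rates imply a primary
burden inside the observed 6–144 band; counts themselves are emergent.

Copy-number profiles plant exact scar counts by construction: telomeric
> 11 Mb imbalanced blocks for TAI, interstitial > 15 Mb copy-neutral LOH
blocks isolated by short balanced buffers, and alternating > 10 Mb state
blocks for LST junctions, allocated across chromosome arms with capacity
checks (infeasible targets raise). One chromosome is reserved for a planted
chromothripsis-like oscillation and telomeric staircase (both scar-neutral by
construction); a second carries ten synthetic driver loci where the drawn
driver genotypes — routes over the CDK4/6, CCNE1/CDKN2A and RB1 axes with
configurable exclusivity rules, plus independent TP53/MDM2 and BRCA draws at
discovery-cohort frequencies — are emitted as truncal SNVs and focal CNA
segments, closing the loop for alteration-matrix reconstruction.

What the generator does **not** emulate: subclonality (all variants clonal,
as the timing method assumes), sequencing noise and coverage dropout,
segmentation error, indel signatures, rearrangement breakpoints, branch-rate
heterogeneity (available as an explicit stressor only by configuring
per-patient rates). Passing recovery tests therefore demonstrates
correctness of the estimators under their stated models, not robustness to
real-data artefacts.

## Problem sizes and numerics

Test and acceptance runs use the 10×100 Mb toy genome, 12-patient cohorts,
500-profile scar-oracle sweeps, 100-instance parsimony comparisons,
100-replicate signature recovery at n = 1000, 200-patient clock recovery, and
400–1000-matrix exclusivity calibration at 1000–10,000 null draws — sizes
chosen so the full suite completes in minutes on one core while keeping
Monte-Carlo standard errors well inside the asserted tolerances. All
randomness flows through `numpy.random.default_rng` seeds; EM tolerance is
1e-8 relative, the background-fit margin tolerance 1e-8 per cell with clamped
(±30 logit) saturation for degenerate margins. Ties in tree search are broken
canonically (lexicographic topology order) for determinism.
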