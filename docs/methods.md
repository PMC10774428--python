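# Methods

This note documents the model choices, numerical conventions and known
limitations of `tapkit`'s implementation of structure-based antibody
developability profiling.

## Structure ingestion

Inputs are IMGT-numbered two-chain Fv PDB files. Ingestion drops
hydrogens, waters and hetero records, keeps the first alternate-location
conformer (altloc blank or "A"), and assigns van der Waals radii by
element (C 1.70, N 1.55, O 1.52, S 1.80 Å; 1.70 Å fallback). Radii are
config-entries, not constants, because exposure calls near the 7.5 %
boundary are sensitive to them. Non-canonical residues are a hard error by
default (`noncanonical: skip` drops them instead): the metrics are defined
only over the 20 canonical amino acids. When a model deposit encodes
per-residue backbone predicted error in the B-factor column (as
ABodyBuilder2 does), the reader stores the mean over N/CA/C/O as the
residue's predicted error; residues with incomplete backbones carry none,
and confidence operations refuse to run rather than guess.

## Solvent-accessible surface area

SASA uses the Shrake–Rupley construction with a 1.4 Å probe. Test points
are a deterministic golden-spiral (Fibonacci) lattice, 960 points per atom
by default — no random number generator, so results are exactly
reproducible and independent of atom order. The neighbour search is pruned
with a k-d tree at radius r_i + r_j + 2·probe. Convergence: doubling the
lattice changes total SASA on test fixtures by < 0.5 %, and an isolated
sphere reproduces 4π(r+p)² to < 0.5 %. An independent Monte-Carlo
estimator (random sphere sampling, brute-force occlusion, standard errors
reported) lives in the fixtures module purely as a cross-check; the two
implementations share no code and agree within 2 % on peptide fixtures.

SASA is always computed on the paired Fv, both chains together, because
exposure must reflect burial at the VH/VL interface.

## Exposure and the theoretical maximum SASA

A residue X is exposed when SASA(X) ≥ 7.5 % (inclusive) of its theoretical
maximum. The maxima are defined operationally as the central-residue SASA
of an extended (φ = −120°, ψ = +120°) ideal-geometry Ala-X-Ala tripeptide
computed by the same SASA routine, shipped as
`src/tapkit/data/max_sasa.csv` and regenerable by
`scripts/regenerate_max_sasa.py`. "Open-chain" reference geometries vary
between published SASA scales; tying the table to the package's own
generator and quadrature keeps the exposure ratio internally consistent.
Absolute exposure calls near the boundary may therefore differ from
implementations using other reference tables — the fraction, probe and
lattice density are all configurable for calibration.

## Regions, anchors, vicinity

CDRs are IMGT position ranges (27–38, 56–65, 105–117 per chain), applied
to both chains, insertion codes included. Anchor sets extend each CDR by
two residues per side *in chain order* (sequence index, not IMGT
arithmetic — IMGT numbering has gaps, and "two flanking residues" should
survive them); chains truncate silently at termini. The CDR vicinity adds
every exposed residue whose minimum heavy-atom distance to an anchor is
≤ 4.5 Å, in a single pass (no transitive growth: the shell is defined
relative to the anchors, not to itself). Anchors are members regardless of
their own exposure; exposure gating happens at metric evaluation. Residue
distance defaults to the minimum over heavy-atom pairs (the most inclusive
natural reading of "within 4.5 Å"); a Cβ mode is available.

## Patch kernel

The published protocol lineage does not restate the exact hydrophobic/
charge-patch functional form, so the kernel here is an explicit design
choice: Σ over unordered exposed vicinity pairs of w_i·w_j/d², with a
7.5 Å pair cutoff and minimum heavy-atom distances. The inverse-square
decay makes close packing dominate while keeping every retained pair's
term finite and positive; the cutoff, exponent and distance mode are
config values so the kernel can be recalibrated against an external
reference model set without code changes. Kyte–Doolittle hydrophobicity is
affinely rescaled to [1, 2]: strictly positive weights keep components
non-negative (hence rankable) and the map is order-preserving. Charges are
formal: R/K +1, D/E −1, histidine +0.1 by default — a fractional His
charge is plausible at formulation pH and two-decimal reference thresholds
suggest fractional sums, but it is genuinely uncertain and configurable.
SFvCSP sums run over all exposed residues of each V-domain (not only the
vicinity; a vicinity-restricted mode exists).

Every patch score carries its full component list; the decomposition
identity (score = Σ components, to numerical precision) is enforced by
construction and asserted in tests. Rankings break contribution ties
lexicographically on residue identity for reproducible reports. Adjacent
pairs are same-chain neighbours in sequence order (|Δ seq_index| = 1).

## Thresholds and flags

Percentiles use sorted linear interpolation (numpy's "linear" method); the
0th/100th percentiles are the observed minimum/maximum. Conventions
differ in the second decimal at cohort sizes of a few hundred, which is
why the method is pinned and documented. Amber boundaries are inclusive
and red requires strictly exceeding the observed extreme, which makes a
reference cohort flagged against its own thresholds produce exactly zero
reds and ≈ 5 % amber per flagged tail (plus tie effects for integer-valued
L_tot). Sidedness is fixed per metric: L_tot and PSH two-sided, PPC/PNC
upper-only, SFvCSP lower-only.

## Confidence filtering and ensembles

CDRH3 RMS predicted error is √(Σ PE²/L). When a percentile is requested
instead of an absolute threshold, the percentile is taken over the cohort
*after* removing a user-supplied exclusion list (antibodies whose
structures are solved need no model-confidence proxy and would bias the
distribution), and the resulting threshold is then applied to the full
cohort, inclusively.

Repeat-run ensembles report per-metric means and population variances
(divisor n — the three-run variance is a descriptive statistic, not an
estimator) and a consensus flag equal to the severity maximum over runs:
an antibody is formally flagged if any repeat flags it. Inter-run
agreement adds pairwise Pearson correlations and the percentage of
antibodies whose single-run flag differs from the consensus.

## Cohort reports

Flag rates per group are reported in two modes (amber-only and
amber-or-worse) because published figures are ambiguous between them.
Standard deviations default to divisor n−1 (configurable). Gene labels
are consumed verbatim from metadata; a family is the text before the
first hyphen (IGLV2-14*01 → IGLV2). The red:green usage ratio uses an
infinity sentinel when a gene is absent from the green population and NaN
when absent from both.

## Superposition

Region RMSDs use a Kabsch least-squares fit (SVD with a proper-rotation
sign correction) on the backbone atoms (N, CA, C, O) of framework
residues common to both structures — matched by IMGT identity, never by
sequence alignment — for one chain at a time, then evaluate each region's
backbone RMSD under that single transform without re-fitting. Residues
missing backbone atoms are skipped with a warning (crystal references
have gaps); fewer than three common framework residues is an error.

## Synthetic structures

The fixture generator builds ideal-geometry backbones (N–CA 1.46, CA–C
1.52, C–N 1.33 Å, trans peptide bonds) at configurable φ/ψ with
simplified side chains: correct heavy-atom counts and element types laid
out as an extended zig-zag from Cβ. A mini-Fv places two such chains
antiparallel 4.2 Å apart so the CDR vicinity gains genuine cross-chain
members. Numbering plans honour the IMGT CDR ranges, including 111A/111B…
insertions for long CDRH3s. Everything is fully determined by (spec,
seed); optional Gaussian jitter emulates repeat-modelling noise.

These fixtures exercise the full pipeline but are not physically
realistic folds: every residue of an extended chain is solvent-exposed,
there is no hydrophobic core, and side-chain geometry is schematic.
Passing tests therefore demonstrate correctness of the computational
protocol (distances, quadrature, bookkeeping, statistics), not agreement
of absolute metric values with real Fv models — the latter requires the
external ABodyBuilder2 model deposit wired into the acceptance tests.

## Problem sizes

The acceptance script profiles a 36-antibody synthetic cohort once plus a
10-antibody subset in triplicate (66 full SASA/metric evaluations, ~1 s
each), sizes chosen to exercise every statistic on a desk-scale run. The
Monte-Carlo SASA cross-check uses 2·10⁴ samples per atom on a 10-residue
peptide.

## Known limitations

- The patch-kernel functional form is a documented default, not a
  published constant; absolute PSH/PPC/PNC values are only comparable
  between runs with identical config.
- Exposure maxima are generator-specific (see above).
- No protonation-state modelling; charges are formal and pH-independent.
- mmCIF, antigen chains and constant domains are out of scope; numbering
  and germline labels are consumed as input, never computed.
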