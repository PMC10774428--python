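# tapkit

Structure-based developability profiling of antibody Fv models.

Antibody engineers screening therapeutic candidates need early warnings of
aggregation- and viscosity-prone molecules. A well-established family of
red-flag criteria scores an antibody's variable region (Fv = VH + VL) by
five structure-derived metrics and compares each score against the
distribution observed across clinical-stage therapeutics (CSTs): a score
inside an extreme 5 % tail earns an **amber** flag, a score beyond anything
ever observed in the reference earns a **red** flag. `tapkit` implements
that protocol for IMGT-numbered Fv models (e.g. ABodyBuilder2 outputs),
plus the surrounding analyses: pairwise decomposition of patch scores,
model-confidence filtering, repeat-run ensembles, and cohort comparisons
such as κ- vs λ-light-chain flag rates.

## The five metrics

For an Fv with IMGT-numbered chains H and L (CDR1 = positions 27–38,
CDR2 = 56–65, CDR3 = 105–117 on each chain):

- **L_tot** — total residue count over the six CDRs.
- **PSH / PPC / PNC** — surface patch scores over the *CDR vicinity*
  (CDR residues ± 2 sequence flanks, plus every surface-exposed residue
  within 4.5 Å of one of those). Over unordered pairs (i, j) of exposed
  vicinity residues:

  score = Σ_{d_ij ≤ 7.5 Å} w_i · w_j / d_ij²

  with w = Kyte–Doolittle hydrophobicity rescaled to [1, 2] (PSH), the
  positive formal charge (PPC: R, K = +1, H = +0.1) or the magnitude of
  negative formal charge (PNC: D, E = 1). d_ij is the minimum heavy-atom
  distance. Every pair's term is retained, so a score decomposes exactly
  into ranked residue-pair contributions.
- **SFvCSP** — (Σ charge over exposed VH residues) × (Σ over exposed VL
  residues); large negative values mean strongly opposite chain charges.

Surface exposure uses an in-house Shrake–Rupley implementation (1.4 Å
probe, deterministic 960-point golden-spiral lattice): a residue X is
exposed when its SASA ≥ 7.5 % of the theoretical maximum for X (the
residue SASA of X in an extended Ala-X-Ala tripeptide, shipped in
`src/tapkit/data/max_sasa.csv` and regenerable with
`scripts/regenerate_max_sasa.py`).

Flag thresholds are percentiles of a reference score collection: amber
bands are [min, 5th] and/or [95th, max] percentile depending on the metric
(L_tot and PSH flag on both tails, PPC/PNC on the upper tail only, SFvCSP
on the lower tail only); red means strictly beyond the reference min/max.

Model-confidence filtering summarises the per-residue backbone predicted
error (read from the PDB B-factor column) over CDRH3 as
√(Σ PE² / L_CDRH3) and retains models at or below a threshold, optionally
derived as a percentile of the cohort's own distribution.

## Worked example

```bash
tapkit fixtures --n 6 --seed 100 --outdir fx     # synthetic mini-Fv cohort
tapkit profile fx -o profiles.csv
tapkit thresholds profiles.csv -o thresholds.yaml
tapkit flag profiles.csv thresholds.yaml -o flags.csv
tapkit cohort flags.csv fx/metadata.csv --profiles profiles.csv
```

`profiles.csv` then contains one row per antibody, e.g.

```
id,l_tot,psh,ppc,pnc,sfvcsp,cdrh3_len,cdrl3_len
fv0100,44,111.74...,0.25...,1.15...,-0.96,10,9
```

— this antibody has 44 CDR residues in total, a hydrophobic-patch score of
~112 (unitless pair-sum), small charge-patch scores, and a mildly negative
charge-symmetry product. `flags.csv` grades each score against the
thresholds fitted from `profiles.csv`; flagging a reference against its own
thresholds yields no red flags and ~5 % amber per flagged tail by
construction. `tapkit decompose` writes the ranked residue-pair
contributions behind any patch score, and `tapkit ensemble` merges repeat
runs of the same antibody into a consensus flag (an antibody is flagged if
any repeat flags).

All numeric constants (probe radius, exposure fraction, vicinity and pair
cutoffs, kernel exponent, charge assignments, percentile convention) live
in a YAML-overridable `RunConfig`; every output embeds the config hash.

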