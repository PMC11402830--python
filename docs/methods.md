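# Methods

## Scope and model

The package scores the structural damage of hPADI6 genotypes and
discriminates clinical phenotypes from those scores, alongside the
coordinate-level and conservation analyses used to characterise the
hPADI6 dimer. Stability changes (ΔΔG) for all possible missense variants
are *inputs* (any per-substitution predictor producing kcal/mol values in
two structural contexts will do); the package does not compute molecular
mechanics energies.

### Rank-normalised damage (ΔΔG_rank)

For each structural context (full dimer; isolated monomer) the table of
per-substitution ΔΔG values is converted to ranks of |ΔΔG| (ascending,
average ranks for ties) and min–max scaled so the least damaging variant
scores exactly 0 and the most damaging exactly 1. Choices:

* **Ranking key |ΔΔG|** (default): strongly stabilising substitutions are
  treated as damaging, since large stability shifts in either direction
  disrupt folding equilibria. `key="signed"` ranks raw values instead.
* **Tie handling**: average (fractional) ranks — deterministic and
  permutation-invariant.
* **Scaling**: min–max over the average ranks (default) guarantees the
  0/1 endpoints even with ties at the extremes; `scale="fractional"`
  ((rank−1)/(N−1)) is available where endpoint ties should dilute the
  extreme scores.
* Dimer and monomer contexts are ranked independently, each over its own
  full variant set, so the two scores are separately interpretable.

### Allele and biallelic scores

Wild type and synonymous alleles score 0, truncating (stop-gain,
frameshift, start-loss) alleles score 1, missense alleles take their
ΔΔG_rank. A genotype scores the arithmetic mean of its two alleles;
homozygotes use two copies of the same allele, and single-variant
carriers without phasing information are treated as heterozygous with a
wild-type second allele. Missense variants at residues absent from the
modelled structure (disordered loops) have no ΔΔG; the default policy
imputes the midpoint 0.5 and sets a `missing` flag (policy `exclude`
drops the subject from statistics with a warning). The midpoint is
unbiased and the flag prevents silent use.

### Discrimination

ROC AUC is computed by the exact Mann–Whitney pair-counting identity
(ties ½), not curve integration; it is tie-robust and satisfies
AUC(pos,neg) + AUC(neg,pos) = 1 exactly. Group shifts use the
Mann–Whitney U test — the scores are bounded rank-derived quantities, so
a rank test is the natural choice; the test is exact when the pooled
sample is tie-free and n·m ≤ 10 000, otherwise tie-corrected normal
approximation. Positive class: infertility; negative class: MLID. No
multiple-testing correction is applied: the AUC table is descriptive,
one point estimate per scorer on the identical subject subset (subjects
dropped for missing coverage under any scorer are dropped from all, so
the comparison is paired). No confidence intervals in this version.

## Structural metrics

* **Parsing** (gemmi): PDB and mmCIF; alternate locations resolved to the
  highest-occupancy conformer (ties → alphabetically first); waters and
  heteroatoms tagged but retained, excluded from B-factor/SASA work by
  default.
* **Superposition**: Kabsch closed-form least squares via SVD with the
  determinant correction (reflections excluded). Degenerate (collinear)
  point sets are rejected.
* **Cα RMSD between chains**: residue pairing by global sequence
  alignment (BLOSUM62, affine gaps open 10 / extend 0.5), Kabsch fit,
  then up to 5 refinement cycles each discarding pairs deviating more
  than 2.0 Å post-fit and refitting. Both parameters are exposed: they
  emulate the refinement loop of molecular-graphics aligners, whose exact
  rejection rule varies between programs, so printed pair counts are
  method-sensitive at the few-residue level.
* **B-factors**: arithmetic means over inclusive author-numbered residue
  ranges; main chain = {N, CA, C, O}.
* **SASA**: Shrake–Rupley with a golden-spiral point lattice (default 960
  points, 1.4 Å probe) and vdW radii C 1.70, N 1.55, O 1.52, S 1.80,
  H 1.20, P 1.80, Se 1.90 Å; unknown elements are an error. Hydrogens
  absent from X-ray models are simply not counted. Because the lattice is
  fixed in space, totals are exactly translation-invariant but rotation-
  invariant only to sampling precision (≈0.1–0.3% at 960 points); doubling
  the point count halves that. Interface buried area is
  (SASA_A + SASA_B − SASA_AB)/2; a residue is "at the interface" when its
  summed per-atom buried area exceeds 0.1 Å² (configurable — published
  interface residue counts depend on the counting rule, so a ±few-residue
  spread against other tools is expected).
* **Inter-structure distances** are measured after whole-chain Cα
  superposition, in the reference frame of the first structure. Where a
  published displacement does not name the atom, this package uses Cα.

## Conservation

Columns of a pre-built orthologue alignment are mapped to hPADI6 residue
positions by counting non-gap reference characters. Conservation counts
report matches out of *all* aligned sequences, while logo frequencies are
computed over non-gap characters only — both conventions are standard and
the asymmetry is deliberate. Information content is log₂20 − H (bits);
the small-sample entropy correction is off by default (negligible at
n = 80) and switchable. Sequence quality filtering excludes sequences
with ≥2 internal stop characters ("multiple stop codons"; threshold
configurable to ≥1) or a gap/X run longer than 30 columns (configurable):
the exact exclusion criteria used to curate published alignments are
rarely stated, so the filter is parameterised rather than hard-coded.

## Synthetic data: what it emulates and what it does not

The generators provide the statistical *shape* the analysis assumes, with
known injected effects, so recovery can be measured:

* **ΔΔG landscape**: gamma-distributed magnitudes per residue class
  (buried: shape 2.0, scale 1.6; surface: shape 1.2, scale 0.7 kcal/mol)
  with an 8% sign-flip probability (stabilising variants exist) — the
  skewed, mostly-destabilising shape of empirical deep mutational ΔΔG
  scans. The dimer context equals the monomer plus a 3 kcal/mol excess at
  interface residues (10.5% of positions, matching the fraction of the
  modelled hPADI6 sequence at the dimer interface) and N(0, 0.1) context
  noise elsewhere. Real ΔΔG landscapes have residue-level correlation
  structure and predictor-specific biases that these independent draws do
  not reproduce.
* **Cohorts**: per-allele, independently: a truncating allele with the
  group's null probability (infertility 0.2, HM allele 1 0.1, others 0),
  else a draw from the top decile of dimer ΔΔG_rank with the group's
  enrichment probability, else a uniform background missense. Enrichment
  defaults: infertility (0.9, 0.9) — biallelic damage, a recessive-loss
  model; HM (0.6, 0.3); MLID (0.3, 0.0) — fertile carriers, so at most
  one enriched allele; controls 0 with gnomAD heterozygotes getting one
  background variant plus wild type and the homozygote sets two copies of
  one draw. Group sizes default to the study scale (26 infertility, 3 HM,
  9 MLID). The `interface_targeted` switch restricts infertility damaging
  draws to interface residues, injecting the dimer-specific signal.
  Passing calibration tests therefore demonstrates that the pipeline
  recovers effects of this structure and magnitude at these sample sizes —
  not that real cohorts carry such effects.
* **Toy structures**: zig-zag CA-bead chains with a designed contact
  patch (bead geometry chosen so exactly the designed residues fall
  within surface-burial reach), plus an ideal-helix trace; these exercise
  geometry code, not protein realism.
* **Toy alignments**: independent per-column substitutions around a
  random reference with designed exact-conservation columns and optional
  planted stop codons / missing runs.

Determinism: every generator draws from `default_rng([seed, stream])`
with a fixed stream id per generator, so outputs are byte-identical under
a fixed seed and adding a generator never shifts the others' draws.

## Problem sizes and numerical choices

Calibration runs (the acceptance script and acceptance tests) use a
250-residue landscape (4 750 variants per context) and 500 simulated
cohorts per scenario — large enough that the Monte-Carlo error on the
reported rates is a few percent, small enough to run in seconds. Rank
tables are deterministic; AUC and the exact U test involve no randomness.
Superposition tolerances: rotation orthonormality to 1e−10; the
collinearity guard rejects point sets whose second singular value is
below 1e−10 of the first.

## Known limitations

* ΔΔG quality bounds everything downstream; the package inherits any
  bias of the upstream stability predictor.
* Biallelic averaging ignores dominance and compound-effect epistasis.
* The interface residue count and buried area depend on the counting
  rule and radii table; agreement with other tools is expected at the
  percent, not decimal, level.
* Cα-convention inter-structure displacements understate side-chain
  movements when the published measurement used a side-chain atom.
* The cohort generator does not imitate real allele-frequency spectra
  beyond het/hom mechanics, and phasing is never modelled.
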