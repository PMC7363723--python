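# Methods

This note documents the models, conventions, and design choices behind
`linkscan`, and what its synthetic-data tests do and do not establish about
real sequence data.

## Family model and synthetic generator

The generator emulates an aligned family of two-domain p-loop ATPases
(Kti12/PSTK-like). Its defaults are the study conditions the package
targets:

- **Domains.** NTD of 120 residues and CTD of 80 residues (free choices —
  real Kti12 NTDs are ~180 residues, but only the relative geometry matters
  for the analysis). The Walker A motif template `[AG]-x(4)-G-K-[ST]` is
  imposed at residues 8–15 with the variable signature position at residue
  14; classes plant K, L, or I there.
- **Linker populations.** Class length ranges default to 18–22 residues
  ("regular", K14) and 55–60 residues ("elongated", L14), with a
  three-population variant adding a ~30-residue plant/yeast-type class.
  Lengths are uniform integers on the class range.
- **Coupling.** Each sequence carries its class's p-loop symbol with
  probability `coupling_prob` (default 1.0), otherwise a symbol drawn from
  the other classes. With perfect coupling the planted column co-segregates
  exactly with the length classes.
- **Alignment by construction.** Domain columns are shared; linkers are
  right-aligned against the CTD and left-padded with gaps to the longest
  configured linker. No aligner is invoked, so the planted column index
  (14) is exact. A consequence worth knowing: columns of the linker block
  where every regular sequence is gapped and every elongated one has a
  residue also separate the classes perfectly (gap treated as a symbol).
  These construction artifacts rank after column 14 (ties break by
  ascending column index) and are asserted to be the only other perfect
  columns.
- **Sequence model.** One family-wide consensus is drawn uniformly over the
  20 amino acids; each sequence is substituted at `mutation_rate` (default
  0.05 per site, a typical within-family divergence) at all positions
  except the four motif-template sites. `class_divergence` (default 0)
  resamples that fraction of non-motif consensus sites per class, giving
  classes distinct backbones; it is 0 by default so that the planted column
  is the only systematic class difference, and set to ~0.3 in phylogenetic
  tests where class monophyly is the point.
- **Composition.** Linker residues are drawn i.i.d. from a per-class
  frequency vector. The default elongated-class vector doubles Thr and
  halves Lys relative to the background vector (average globular-protein
  frequencies), a factor chosen to be comfortably detectable at n = 100 per
  class while remaining a qualitative, not quantitative, emulation of the
  threonine-rich long linkers seen in nature.

What the generator does **not** emulate: phylogenetic autocorrelation
(sequences are exchangeable within class, not generated along a tree),
indels inside domains, alignment error, or compositional heterogeneity
along the linker. Passing tests therefore demonstrate correctness of the
analysis machinery under the declared statistical structure, not robustness
to misalignment or to confounded phylogenetic signal — the screen is
deliberately a naive per-column association, with no phylogenetic
correction, matching the analysis it re-implements.

## Linker delimitation and statistics

Boundaries are reference-anchored: the NTD-end and CTD-start residues of a
named reference (1-based on its ungapped sequence, e.g. 183/214 for an
ScKti12-style reference, giving the 184–213 linker of length 30) are mapped
to alignment columns, and each sequence's linker is its ungapped residue
count strictly between those columns. Lengths are counted on ungapped
sequences, not as column spans, so all-gap columns are invariant. A
motif-based fallback (`find_walker_a`, pattern `[AG]-x(4)-G-[KLIVA]-[ST]`)
locates the p-loop when no reference is available.

The elongated threshold defaults to 45 residues — the midpoint of the empty
band between the ~30 and 55–60 populations — with `length >= threshold`
classed elongated. Group comparison uses Welch's unequal-variance two-tailed
*t* test (the safer default when only "unpaired two-tailed t test" is
specified). Composition ratios add a pseudocount of 0.5 per residue before
the log2 elongated/regular ratio, keeping unobserved residues finite.

## Co-segregation screen

For one column with symbols s and binary classes, the best achievable
classification accuracy over all symbol→class assignments is reached by the
per-symbol majority: `acc = Σ_s max(n_s,0, n_s,1)/n`. This exact statistic
is deterministic and upper-bounds any single-column classifier, which makes
it preferable to a solver-dependent SVM as the primary statistic; the
linear-kernel SVM (C = 10⁶) on the one-hot column encoding is retained as a
cross-check and agrees with the exact optimum on every tested column.
Majority ties are assigned to the regular class (conservative against
declaring perfect separation). The association strength *r* is the Matthews
correlation coefficient of the induced prediction's 2×2 confusion table,
0.0 when a margin is zero. Columns with gap fraction > 0.5 are excluded;
within kept columns the gap is an ordinary 21st symbol. Sequence order is
shuffled under the given seed before scoring — the statistic is
order-invariant and tested as such; no train/test split is used, because
the screen measures co-segregation on the full family rather than
generalisation.

## Phylogenetics

Distances: pairwise deletion removes, per pair, columns with a gap or X in
either sequence; p = mismatches / remaining sites; Poisson correction
d = −ln(1 − p) (error at p = 1, "saturated pair"). NJ follows Saitou–Nei
with Q = (N−2)d(i,j) − r_i − r_j; exact Q ties are broken by the smallest
taxon-index pair, and a negative branch-length estimate is clamped to zero
with the deficit moved to its sibling, so construction is fully
deterministic. On additive matrices the generating topology and lengths are
recovered exactly (tested against a path-length oracle and scikit-bio's
implementation). Bootstrap: columns resampled with replacement, pairwise
deletion re-applied per replicate; replicates containing an incomparable or
saturated pair are dropped with a warning and the support denominator
shrinks accordingly. Supports are fractions by default (percentages behind
a flag). Newick writing is native (supports as internal-node labels);
parsing goes through dendropy.

## Assay models

**Binding.** The one-site fit uses the simple hyperbola by default even
though a 1 µM probe is not negligible next to a ~1.5 µM Kd; the simulator
and fitter share the model, so recovery is self-consistent, and the exact
quadratic ligand-depletion form is available behind a flag for real data.
Fitting is nonlinear least squares with multi-start Kd initialisation at
the min/geometric-mean/max concentration; standard errors come from the fit
covariance. A fit is censored ("Kd > max tested") when the Kd estimate
exceeds the highest concentration or when the fitted amplitude is within
5 residual standard deviations of zero (flat titration).

**Melt.** Tm is the midpoint of a four-parameter Boltzmann sigmoid fitted
on the ascending segment up to the fluorescence maximum, truncating any
post-peak aggregation decline; when that fit fails, the maximum of the
5-point-smoothed first derivative is used and the method is recorded. The
simulated ramp is 4–98 °C at 0.5 °C per reading; ΔTm propagates errors in
quadrature.

**ATPase.** Relative activity is the ratio of blank-subtracted endpoint
means with quotient error propagation from the standard errors of the two
means; endpoints are modelled as rate × duration plus Gaussian noise.

Noise is Gaussian and independent per data point throughout the simulators
— the simplest defensible error model in the absence of replicated raw
traces.

## Numerical and scale choices

Simulation sizes in the tests and the acceptance script (200-sequence
screens, 12 × 3-point titrations, ~190-point melt ramps, 50–100 bootstrap
replicates on ≤ 10 taxa) were chosen as the smallest sizes at which each
statistical claim is stable; all complete in seconds. All generators and
the bootstrap are bit-reproducible under a fixed seed. Coordinates are
1-based inclusive on ungapped sequences (matching residue numbering such as
K14 and linker 184–213); alignment columns are 1-based.

## Known limitations

- The screen has no correction for phylogenetic non-independence; shared
  ancestry can masquerade as trait association on real families.
- NJ is the only tree method; no rate heterogeneity or model-based
  distances beyond the Poisson correction.
- The binding fit assumes a single site and, by default, no ligand
  depletion; Kd values near or below the probe concentration should be fit
  with the depletion flag on real data.
- Tm from a Boltzmann midpoint can differ by a degree or more from a
  derivative-maximum definition on asymmetric transitions; the method used
  is always recorded.
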