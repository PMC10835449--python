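# Methods

This note documents the models implemented in `synsel`, their
assumptions, the defaults of the synthetic-data generator, and the design
choices made where several constructions were defensible.

## Singleton-proportion calibration (MAPS / TRAPS)

The observation unit of the calibration is the mutational context: the
strand-normalised trinucleotide context of the site, the (normalised)
alternate allele, and a methylation bin for CpG sites.  Contexts are
normalised so the middle reference base is a pyrimidine; mutation rates
are reverse-complement symmetric, so this halves the key space without
losing information, while codon fields stay on the coding strand.  The
three mutational classes — CpG transitions, non-CpG transitions,
transversions — partition the 192 possible (context, alt) pairs.

For context *c* with n_c observed variants, s_c of them singletons
(allele count 1) and relative mutability μ_c, the calibration is the
weighted least squares fit

    ps_c = s_c / n_c  ≈  α + β · t(μ_c),   weights n_c,

with t the identity (MAPS) or the square root (TRAPS).  The transform
applies to every context class at both fit and prediction time.  Under an
infinite-sites model ps would not depend on μ at all; in a deeply
sequenced cohort recurrence saturates the most mutable contexts and ps
falls with μ, non-linearly.  If the true saturation law is closer to
affine-in-√μ than affine-in-μ, the identity fit leaves a convex residual
pattern: it under-predicts singletons in the least mutable (transversion)
contexts and thereby fabricates apparent selection there.  The √
recalibration removes this, which is exactly the pattern the quartile
diagnostic displays (and the acceptance suite verifies).

The selection score of a variant subset S is

    score(S) = (obs(S) − exp(S)) / |S|,
    exp(S) = Σ_c n_c(S) · clamp(α + β t(μ_c), 0, 1).

Because the fit contains an intercept and uses weights n_c, the score of
the entire calibration set is exactly zero (to floating-point precision);
this identity is asserted at 1e-10.  Predicted proportions are clamped to
[0, 1]; clamping does not occur under the default generator conditions.

**Confidence intervals.** Score error bars are binomial; we use
the Wilson score interval of the observed singleton proportion, shifted
by the expected proportion, treating the calibration as fixed.  With
calibration sets one to two orders of magnitude larger than scored
subsets, calibration uncertainty is second order; the empirical coverage
requirement (94–96% at n = 1000, p = 0.1) is part of the test suite.

**Group comparisons.** Welch two-sample *t* tests on per-context residuals
ps_c(S) − p̂_c.  The observation unit is not stated in the source
analyses; per-context residuals weight each context once and are robust
to the dominance of a few huge contexts.  Contexts with fewer than 20
variants are excluded by default (5 for the small per-amino-acid and
splice-class groups); Bonferroni adjustment uses the number of
comparisons reported together in the same table.

## Codon metrics

* **CSC** — Pearson correlation, across transcripts, between a codon's
  per-thousand frequency in the transcript and the transcript's mRNA
  half-life (hours, untransformed).  Codons with zero frequency variance
  are flagged missing.  Requires ≥ 3 transcripts and non-degenerate
  half-lives.
* **tAI** — per codon, W = Σ over decoding anticodons of
  (1 − s) × gene copies, tAI = W / max W.  The Watson-Crick anticodon has
  s = 0; one wobble anticodon per codon contributes with the
  literature-standard penalties s(G:U) = 0.41, s(I:C) = 0.28,
  s(I:A) = 0.9999, s(U:G) = 0.68 (configurable).  The generic pairing
  rules are applied uniformly to all 61 sense codons.  Codons with W = 0
  receive the geometric mean of nonzero tAI values, the standard
  convention.
* **ΔGC** — GC(alt codon) − GC(ref codon) ∈ {−1, 0, +1} for any SNV.
* **Optimality label** — sign of ΔCSC: reducing (< 0), increasing (> 0),
  neutral (= 0, excluded from contrasts).  Classifying by the delta sign
  avoids the ambiguity of an absolute optimal/non-optimal split for amino
  acids whose codons all have negative CSC (e.g. histidine).
* **Usage bias** — per amino acid with k ≥ 2 codons,
  (max usage fraction − 1/k) / (1 − 1/k) ∈ [0, 1].  "Average codon usage
  bias" has no unique operational definition; this rescaled max-fraction
  excess is one defensible reading (0 = uniform, 1 = exclusive use) and
  is flagged as a choice.
* **ΔtAI / ΔCSC as predictors** are signed deltas (alt − ref); a
  positive-part reading of "gain" is available by transforming the design
  matrix, but the signed version is the default.

## Downstream analyses

All analyses are pure functions of (variant table, fitted calibration)
and reproduce byte-identically under a fixed seed.  Notable choices:

* **Saturation baseline** — the expected fraction of optimality-reducing
  variants for an amino acid is the mutability-weighted share of reducing
  opportunities among all possible synonymous changes in the sequence
  universe.  The source construction of the "expected level" is not
  spelled out; opportunity share is the natural neutral baseline.
* **Constrained genes** — lowest 30% of per-gene LOEUF, ⌈0.3·G⌉ genes by
  stable sort.
* **Splice classes** — the four SpliceAI delta scores are thresholded at
  0.5 independently; unannotated variants are excluded.
* **Predictor quartiles** — quartiles on the annotated subset, ties broken
  by first-occurrence rank, left-inclusive boundaries.
* **ClinVar-like groups** — pathogenic + likely pathogenic and benign +
  likely benign are merged; differences are reported against the
  benign-like reference.

## LASSO decomposition

Variant-level TRAPS is undefined (the score is a group statistic), so the
unit of observation is the substitution class: one distinct
ref→alt codon pair (optionally stratified by mutational class), kept when
it holds ≥ 20 variants.  The response is the class score; predictors are
ΔtAI, ΔCSC, ΔGC, degeneracy and the class's mean transformed mutability;
rows are weighted by variant count and predictors standardised to zero
weighted mean and unit weighted variance, making selection invariant to
affine predictor rescaling.  The penalty path is cross-validated
(10 folds, fixed seed); λ_min is used for estimation and variance
explained, λ_min + 1SE for which-predictors-survive statements.  Neither
the λ rule nor standardisation is stated in the source; both choices are
the glmnet-style defaults.

A structural caveat the recovery experiments exposed: ΔGC is a
deterministic function of the (ref, alt) base pair, and synonymous CpG
transitions always have ΔGC = −1.  Any GC-directed selection therefore
correlates with mutability across contexts, and the *refitted* neutral
curve absorbs a μ-correlated share of it — leaving class residuals with a
small genuinely nonzero partial effect of mean mutability.  With enough
data the LASSO correctly retains that term.  Recovery experiments that
ask "are the decoys dropped?" must therefore score classes against the
generator's *known* neutral curve, under which degeneracy and mutability
are exactly null; the package supports this by constructing a
`CalibrationResult` directly from known coefficients.

## Synthetic-data generator

The generator emulates the statistical structure of a saturated exome
cohort at desk scale; defaults are the study conditions used throughout
the tests.

* **Reference**: 200 genes × 300 codons drawn from a usage table with
  within-amino-acid bias (degeneracy-proportional amino-acid mass;
  skewed fractions per amino acid, glutamine given an extreme 0.86/0.14
  split to emulate its outlier usage).
* **Mutability**: log-uniform per class — transversions 0.2–0.6, non-CpG
  transitions 0.6–2.0, CpG transitions 30–120 (× methylation-bin factors
  0.25/0.55/1.0) — putting CpG transitions ~100-fold above the non-CpG
  centre.  CpG sites receive methylation bins with probabilities
  0.15/0.25/0.60.
* **Observation**: each possible synonymous change is observed with
  probability 1 − exp(−rate·μ) (rate 1.0), a saturating,
  mutability-dependent ascertainment giving ~6 × 10⁴ observed variants
  and near-complete saturation of CpG sites.
* **Neutral curve**: P(singleton) = clamp(0.62 − 0.045·√μ, ε, 1−ε),
  spanning ≈ 0.59 for transversions down to ≈ 0.25–0.35 for methylated
  CpGs.  Affine-in-√μ means the TRAPS calibration is correctly specified
  and the MAPS calibration is misspecified — the mechanism behind the
  quartile-bias pattern.
* **Selection**: δ(class) = 0.03·(−ΔtAI) + 0.05·(−ΔCSC) + 0.015·(−ΔGC)
  plus offsets: +0.10 for high splice-loss, +0.03 for high splice-gain
  classes (1% of variants per class scored ≥ 0.5; 10% unannotated),
  +0.02/+0.06 for VUS/pathogenic-like labels, +0.02 in the lowest-LOEUF
  30% of genes, and an optional random planted subset for recovery
  experiments.  These magnitudes sit on the scale of published
  singleton-excess differences between synonymous variant classes.
* **Planted metrics**: per-codon CSC values are evenly spaced within each
  amino acid (half-spread 0.2–0.35, small per-amino-acid offset), giving
  two-codon amino acids |ΔCSC| ≥ 0.4 so their contrasts are resolvable at
  desk scale; tRNA copies are assigned so the higher-CSC codon has the
  better-supplied Watson-Crick anticodon (CSC and tAI agree within
  two-codon amino acids).  The codon-frequency matrix is built with the
  residual component orthogonalised against the half-life in sample, so
  `compute_csc` recovers the planted values essentially exactly; ground
  truth tAI is defined by the generated copy numbers, so recovery is
  exact by construction.
* **External scores**: GERP ~ N(0,1) + 1.0 for optimality-reducing
  variants; CADD and synVep are affine in the variant's true δ plus
  noise.  Non-singleton allele counts follow a shifted geometric; only
  the singleton indicator enters any statistic, so this shape is
  inconsequential.
* **Determinism**: all draws come from `numpy` Generators seeded with
  (seed, stream-id) pairs; identical seeds give byte-identical tables.

**What the generator does not emulate**: linkage and gene-level
clustering of variants, demographic allele-frequency structure beyond the
singleton indicator, sequence-context autocorrelation of methylation,
correlated external scores (GERP/CADD/synVep are conditionally
independent given δ), and real codon-usage/optimality joint structure.
Passing tests therefore demonstrate the correctness and calibration of
the estimators under the stated generative assumptions, not the empirical
magnitudes expected on a real cohort, which depend on dataset-specific
saturation and selection.

## Problem sizes

Test and acceptance runs use 60–240 k codon tables (≈ 3 × 10⁴ – 2.5 × 10⁵
observed variants), 200 replicates per planted-offset level, 50 seeds for
the quartile-bias and LASSO-recovery rates and 20 for the GERP rank
tests; these sizes give each check comfortable statistical resolution at
the planted effect magnitudes.

## Known limitations

* Only the singleton/non-singleton margin of the site-frequency spectrum
  is modelled; no full SFS or mixed calibration models.
* The Welch observation unit and the saturation baseline are reasonable
  readings of under-specified constructions; both are isolated behind
  single functions and easy to swap.
* The wobble rule set is applied uniformly; organism-specific special
  cases (e.g. bacterial lysidine at AUA) are representable only through
  custom penalty weights.
* Consequence severity filtering trusts the input's most-severe-
  consequence annotation; the package does not re-annotate from a
  reference genome.
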