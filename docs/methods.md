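# Methods

## The test

Selection on a polygenic trait moves many allele frequencies a little, each
far below the detection threshold of any per-locus scan. The Ghat test
aggregates these movements across the whole marker panel:

    Ghat = sum_j  Delta_j * alpha_j

where `Delta_j` is the change in the counted-allele frequency of marker `j`
between an early and a late sample of the same population, and `alpha_j` is
the marker's estimated allele-substitution effect (trait units per allele
copy). Under drift alone, frequency changes carry no systematic relation to
effects, so Ghat fluctuates around zero; directional selection on the trait
drags trait-increasing alleles upward and pushes Ghat away from zero in the
direction of selection. Both vectors must be oriented to the same counted
allele per marker; every statistic in the package is invariant under a
joint orientation flip (dosage -> 2 - dosage, alpha -> -alpha,
Delta -> -Delta), and `io.align_effects_and_change` enforces this before
any test runs.

## Significance: the LD-aware permutation null

The null is built by permuting the effect vector against the fixed change
vector and recomputing the statistic (`perms` = 1,000 by default). A normal
approximation (mean and standard deviation of the permuted statistics)
yields the p-value. Permutation treats markers as exchangeable, which they
are not under linkage disequilibrium: both `alpha_hat` and `Delta` are
autocorrelated along the genome (ridge-type estimators smear effects across
LD neighbours; linked loci drift together), so the observed statistic is
over-dispersed relative to the permutation null. Three corrections are
offered:

- **scale** (default): widen the null standard deviation by
  `sqrt(m / num_eff)`, where `num_eff` is the effective number of
  independent genome segments. The variance-inflation reading of the
  correction is the reason the p-value uses the normal approximation rather
  than the empirical permutation rank — a rank cannot absorb a variance
  factor.
- **trim**: retain every `blocksize`-th marker in map order (systematic,
  seed-free thinning) and run the uncorrected test on the thinned vectors.
  An empirical p-value `(r + 1) / (perms + 1)` is reported alongside.
- **naive**: no correction; valid only for effectively independent markers.

A two-sided test is used throughout; the direction of selection is the sign
of Ghat when the p-value clears the declared level (default 0.05).
Confidence intervals are back-calculated from the p-value: the standard
error is `|Ghat| / z` with `z = |Phi^-1(p/2)|`, and a symmetric normal
interval is placed around the estimate. The interval is undefined (and
flagged) when `p >= 1` or the estimate is exactly zero.

## Effective number of independent markers

Two estimators of `num_eff` are provided.

**simpleM** (default in the simulation pipeline): per chromosome,
eigendecompose the marker correlation matrix and count the smallest number
of leading eigenvalues whose sum reaches `var_fraction` (default 0.995) of
the total; sum over chromosomes. Chromosomes beyond 2,000 markers are split
into contiguous blocks whose counts are summed — block overlap was
deliberately avoided because overlapping eigen-counts double-count markers
with no principled recombination rule.

**ld_decay**: per chromosome, bin pairwise genotype r² by inter-marker
distance (bin width = span/100), smooth the binned means by isotonic
non-increasing regression (raw binned means are noisy and non-monotone),
and find the smallest distance `d*` at which the smoothed mean drops below
`max_r2` (default 0.03, roughly the chance r² at a few hundred samples plus
margin). The chromosome then counts `ceil(span / d*)` segments, capped at
its marker count and floored at 1 (with a warning when LD never decays
below the threshold).

The two estimators answer slightly different questions — eigenvalue
dimensionality versus decay-length block counts — and can differ severalfold
on the same data; which one feeds the scale correction is a configuration
choice, with simpleM used by the simulation-based validation herein.

## Marker-effect estimation

**RR-BLUP.** The mixed model `y = Xb + Zu + e`, `u ~ N(0, I s2_u)`,
`e ~ N(0, I s2_e)`, with `Z` the column-centered dosage matrix (no variance
standardization, keeping effects in trait units per allele copy as the
statistic requires). Fixed effects beyond the intercept (year, environment)
are absorbed by least-squares projection. REML reduces to a 1-D
optimization over `lambda = s2_e / s2_u` after one eigendecomposition of
the genotype cross-product; the BLUP of `u` gives the effects. Because the
eigendecomposition scales cubically in records while the ridge solve does
not, fits beyond `reml_max_n` records (default 800) estimate `lambda` —
a population-level variance ratio — on a random subsample and then solve
the full-data ridge system matrix-free by conjugate gradients (the system
is well conditioned because whole-genome `lambda` is large). The exact
spectral path and the CG path agree to solver tolerance at equal `lambda`.

**BayesC.** A Gibbs sampler in which a fixed fraction `pi` (default 0.95)
of markers has exactly zero effect and included markers share one effect
variance. Priors are scaled-inverse-chi-square with `nu = 4` and
data-derived scales: the prior genetic variance is half the phenotypic
variance spread over the expected included markers, the prior residual
variance the other half. Effects are posterior means over the post-burn-in
draws (defaults: 10,000 iterations, 2,000 burn-in, fixed seed, all recorded
with the estimates); posterior inclusion probabilities are reported. `pi`
is fixed rather than estimated, the original form of the method. `pi = 1`
short-circuits to zero effects; `pi = 0` keeps every marker and approaches
the ridge solution.

Missing dosages are mean-imputed per marker before estimation; allele
frequencies are always computed from non-missing calls only, so `Delta`
remains an unbiased sample frequency contrast.

## The simulator

`ghatpy.sim` emulates a divergent-selection validation design from cattle
breeding:

1. **Historical phase.** A locus pool (2.5x the requested panel, uniform
   positions, initial frequencies uniform on (0,1), linkage-equilibrium
   start) drifts through 100 generations of random mating at population
   size `hist_n` (default 100, an effective size typical of commercial
   cattle). Recombination follows Haldane's model — Poisson crossovers,
   no interference — on 100-cM chromosomes.
2. **Ascertainment.** Markers are drawn uniformly among post-drift loci
   with MAF >= 0.05 (array-like common-variant ascertainment); QTL are
   drawn from the remaining polymorphic loci. QTL effects are standard
   normal, rescaled so the founder-generation additive variance equals h²
   (residual noise variance 1 - h²; founder phenotypic variance ~1).
3. **Breeding phase.** Two populations share founders, panel,
   generation-0 genotypes and generation-0 phenotypes bit-for-bit, then
   diverge: population A mates at random for 20 generations; population B
   undergoes truncation selection (top `selected_fraction` = 0.2 by
   phenotype) each generation. Parents are drawn uniformly (two distinct
   per offspring) from the eligible pool.

What the generator does **not** emulate: mutation, dominance or epistasis,
structured mating designs (sire/dam hierarchies), overlapping generations,
pedigree-based selection, genotyping error, or ascertainment toward
intermediate frequencies. Passing tests therefore demonstrate the
machinery's operating characteristics under an idealized additive
random-mating regime, not performance on real livestock data.

## Validation program and problem sizes

The full validation design in the source studies used 30 chromosomes and
1,000 replicates per condition. The package's test suite and
`scripts/acceptance.py` run a desk-scale version chosen to fit a single
CPU: 5 chromosomes x 100 cM, 2,000 markers, 150 QTL, h² = 0.5, n = 400 per
generation, 20 breeding generations; 200 replicates for the baseline
regime and 60 per level for the heritability {0.3, 0.6, 0.9}, QTL-number
{30, 240, 1920} and marker-density {300, 3000} sweeps. Effects are
estimated by RR-BLUP from all 21 recorded generations (8,400 records);
the frequency contrast is generations 15 to 20; `num_eff` comes from
simpleM on the pooled contrast samples; the test is the scale method at
1,000 permutations, significance at p < 0.01. Acceptance bands are the
binomial uncertainty of the reduced replicate counts around the full-scale
rates.

Two desk-scale behaviours deserve note. First, null calibration depends on
the effect-estimation sample: with heavily subsampled training data the
LD-structured estimation noise in `alpha_hat` covaries with the
drift-structured `Delta` and over-disperses the statistic beyond the
simpleM correction; training on all recorded generations (as the design
prescribes) restores calibration. Second, power is limited by the design itself wherever selection exhausts
the trait's variance before the tested window: under strong truncation
most large-effect QTL (the 30-QTL regime) and much of a high-heritability
trait's variance (h² = 0.9) are fixed before generation 15, so little
signal remains in the generation-15..20 contrast, and ridge estimates
(unlike sparse-prior estimators, which are strongest exactly when few
loci matter) cannot fully compensate. Testing an earlier window or the
full 20-generation contrast restores power in these regimes.

## Numerical choices and degenerate inputs

- Dosage matrices are float32 in bulk pipelines; REML eigenvalue problems
  run in float64 on float32 cross-products; the CG ridge solve runs
  float32 matvecs with a float64 Krylov iteration (rtol 1e-4, which leaves
  the solution error far below the statistical noise of the effect
  estimates and changes permutation p-values only in the fourth
  significant digit).
- Permutation p-values are floored at 1e-300; a degenerate null
  (`sd = 0`, e.g. an all-zero change vector) returns p = 1 with a warning.
- REML optimizes log10(lambda) on [-8, 8] by bounded scalar minimization;
  a zero-variance phenotype skips estimation and returns zero effects with
  a warning.
- Monomorphic markers are skipped in r² tables and simpleM (they carry no
  LD information) and naturally contribute zero to Ghat.
- `frequency_change` refuses an early == late contrast; markers with no
  calls in either group are flagged missing and excluded pairwise.
- The trim method thins deterministically (every k-th marker in map
  order) so results are reproducible without a thinning seed.
- All simulator randomness flows from one integer seed through split
  generator streams; populations A and B consume identical streams up to
  the selection step.
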