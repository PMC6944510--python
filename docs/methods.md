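# Methods

## The design being modeled

Two-sample Mendelian randomization treats genetic variants as instrumental
variables: variant–exposure associations (γ̂_j, σ_Xj) come from one set of
GWAS samples, variant–outcome associations (Γ̂_j, σ_Yj) from another, and
the ratio structure Γ_j = θ γ_j identifies the causal effect θ of the
exposure on the outcome when the instruments are valid (relevant,
independent of confounders, and affecting the outcome only through the
exposure). The *cis* variant of the design restricts instruments to a gene
region encoding a drug target, so θ approximates the effect of
pharmacologically modulating that target, at the cost of having few,
mutually correlated instruments — which is why the package carries both an
LD-clumping path and an estimator that models correlation explicitly.

The identifying assumptions this package takes as given: summary statistics
come from non-overlapping exposure and outcome samples of the same
ancestry; effects are per-allele on a standardized (SD-unit) or ln-scale
exposure and a log-odds outcome; and the reference panel's LD is a usable
stand-in for the GWAS samples' LD.

## Pipeline stages and their rules

**Variant identity.** A variant is keyed by (chromosome, GRCh37 position,
unordered allele pair), with the pair reduced modulo reverse complement so
records reported on opposite strands still match. rsIDs are carried as
metadata only; annotation vintages differ too much across consortia to
join on them. Palindromic pairs (A/T, C/G) are their own complement, so
nothing is conflated by the reduction.

**Multi-source merging.** Exposure sources are appended, never
meta-analyzed: overlapping consortium memberships would double-count
samples. Where sources share a variant, the record from the largest n is
kept; ties go to the earlier source in the user-supplied order, a missing
n is treated as 0 (never preferred), and a cross-source effect-allele
frequency discrepancy greater than 0.2 triggers a warning but not removal.

**Region selection.** [start − flank, stop + flank], inclusive at both
ends, on 1-based coordinates; BED input is converted from 0-based
half-open on read. Default flank 1 kb (primary), 100 kb for sensitivity
analyses.

**Harmonization.** Exposure and outcome records are intersected on the
variant key and the outcome oriented to the exposure's effect allele:
swapped alleles negate Γ̂ and complement the frequency; strand complements
are resolved before declaring a mismatch. Palindromic variants carry no
strand information in their alleles, so they are aligned by frequency —
the outcome orientation is chosen so its effect-allele frequency falls on
the same side of 0.5 as the exposure's — and dropped as ambiguous when the
minor-allele frequency lies in the closed band [0.4, 0.5], or is missing,
in either dataset. A strict mode drops all palindromes. Every decision is
written to an audit table (kept / flipped / dropped_palindromic /
dropped_mismatch); kept + dropped always equals the intersection size.
Because the variant key is already strand-insensitive and allele-pair
aware, a non-palindromic pair mismatch cannot survive the join, so the
dropped_mismatch category is structurally zero under key-joined input; it
is retained in the audit schema for observability.

**Clumping.** Variants are sorted by exposure p-value (ties: larger |β̂|,
then lexicographic key, making the result independent of input order) and
retained greedily iff their r² with every already retained variant is at
or below the threshold. Default threshold 0.6; 0.2 and 0.01 reproduce the
"independent instruments" settings. Clumping runs on the harmonized set by
default, so exposure and outcome availability both constrain the
instrument list; a flag moves it to the exposure stage instead.

**LD.** Signed Pearson correlation of effect-allele dosages in a reference
panel, with per-variant mean imputation of missing genotypes and a hard
error on monomorphic variants. Matrices can also be supplied directly as
delimited text.

## Estimators

All confidence intervals are Wald-type with the normal quantile 1.959964;
p-values are two-sided normal. No small-sample t corrections are applied.

- **Wald ratio** θ̂ = Γ̂/γ̂ with first-order SE σ_Y/|γ̂|; the
  second-order term in γ̂ is deliberately omitted.
- **IVW** is computed in moment form (no per-variant division), fixed
  effects only; random-effects variants are out of scope.
- **MR-Egger** orients γ̂_j ≥ 0 (Egger regression is not invariant to
  allele relabeling; the exposure-raising orientation is the standard
  choice) and solves the 2×2 weighted normal equations in closed form.
  The reported SEs use the fixed-effect covariance (XᵀWX)⁻¹ without
  residual-variance scaling, matching the IVW convention; an exactly
  collinear design (all γ̂ equal after orientation) is refused.
  I²_GX = (Q_GX − (J−1))/Q_GX with Q_GX the precision-weighted
  heterogeneity of the γ̂_j, floored at 0 and reported as a percentage.
- **Weighted median**: ratios ordered ascending, cumulative weights
  s_j = Σ_{i≤j} w_i − w_j/2 with w_j ∝ γ̂_j²/σ_Yj², linear interpolation
  at s = 0.5. The SE is a parametric bootstrap (default 1,000 draws,
  user-seeded) resampling γ̂* ~ N(γ̂, σ_X²), Γ̂* ~ N(Γ̂, σ_Y²).
- **PC-generalized IVW**: Φ = D ρ D with D = diag(γ̂_j/σ_Yj) is
  eigendecomposed; the smallest k whose leading eigenvalue sum reaches κ
  of the total is kept (defaults κ = 0.99; 0.9 and 0.999 for sensitivity).
  Components with eigenvalue below 1e−10 × the largest are never selected,
  even at κ = 1, to guarantee invertibility of the projected covariance
  Ω' = WᵀΩW; a singular Ω' raises an error suggesting a smaller κ. With
  identity LD and κ = 1 the estimator reduces exactly to IVW, and a
  perfectly correlated duplicate variant contributes no information.

**Meta-analysis** is fixed-effects inverse-variance pooling with Cochran's
Q (undefined, reported missing, for a single input). Heterogeneity is
reported but never used to switch models. Printed odds ratios are ingested
by assuming a log-symmetric 95% CI, which limits round-trips of
two-decimal published values to about ±0.01.

**Presentation.** Estimates are multiplied by −1 (per SD *lower*
exposure), −ln 2 (per halving, valid only for ln-unit exposures) or +1
before exponentiation; CI bounds swap when the multiplier is negative.

## The synthetic-study generator

The generator emulates the *statistical layout* of a multi-consortium
cis-MR study, not any real genetic architecture:

- J variants (default 50) on one chromosome at 1 kb spacing, MAF uniform
  on [0.05, 0.5], ~15% palindromic allele pairs so harmonization paths are
  exercised; a third of outcome records are reported for the opposite
  allele to force sign flips.
- True effects |γ_j| ~ |N(0, 0.02²)| on a standardized exposure. The
  effect allele is labeled as the exposure-raising allele (γ_j ≥ 0), a
  pure relabeling that makes directional pleiotropy well defined for
  Egger-style analyses.
- Outcome truth Γ_j = θ γ_j + α_j with α_j = 0 (none), N(0, s²)
  (balanced), N(s, (s/2)²) (directional), or equal to s for a random
  fraction of variants (invalid_fraction).
- Observed statistics add independent Gaussian noise at the asymptotic
  SEs: σ_Xj = (n·2f_j(1−f_j))^(−1/2) for the quantitative exposure and the
  same form with n_eff = 4/(1/n_cases + 1/n_controls) for the case–control
  outcome. Statistics are drawn directly from this model rather than by
  regressing simulated individuals, keeping thousands of replicates cheap.
- Three exposure sources share the truth but have independent noise,
  sample-size fractions (1.0, 0.34, 0.047) of n_exposure (default
  100,000) and variant densities (100%, 60%, 30%) — the spread seen across
  lipid consortia. Two outcome samples are independent; the second
  defaults to (12.45%, 35.15%) of the first's cases and controls,
  mirroring a register-based replication sample beside a large
  case–control consortium (defaults 20,000/40,000).
- The reference panel (default 503 individuals) thresholds two latent
  lag-1 autoregressive Gaussian haplotypes at each variant's frequency
  quantile, giving Hardy-Weinberg dosages with tunable adjacent-variant
  LD; MAFs follow a Gaussian copula with the same lag-1 correlation so
  tightly linked neighbours have similar frequencies. Dichotomization
  still attenuates dosage-scale r² below the latent correlation, as it
  does in real data.
- `embed_pleiotropic_locus` adds a constant direct outcome effect to a
  contiguous block — the situation a strongly pleiotropic gene near a
  biomarker locus creates — and returns the block's keys so exclusion-list
  efficacy can be verified.

What passing tests on this generator do **not** show: robustness to
exposure–outcome sample overlap, population stratification, real LD
complexity (the AR(1) panel has no long-range structure), winner's-curse
selection of instruments, or non-collapsibility subtleties of the
log-odds scale. The generator treats overlapping consortium sources as
sharing truth with independent noise; real overlap correlates their errors.

## Weak instruments and known attenuation

At the default generator settings the mean instrument F-statistic is ~15,
so two-sample regression dilution attenuates the IVW estimate by roughly
5–7% toward the null (visible in the acceptance script's recovery value of
~0.35 for a truth of 0.37); the null-calibration coverage is exact because
under θ = 0 the outcome noise is independent of the estimated weights.
MR-Egger is affected more strongly (its slope regresses on the γ̂
dispersion *around the weighted mean*; the accompanying I²_GX makes the
attenuation visible), and its intercept under directional pleiotropy is
pulled toward zero by the small fraction of variants whose observed γ̂
flips sign. The weighted median inherits ratio-level noise and shifts
upward when 30% of instruments push in one direction, while remaining far
closer to the truth than IVW in that regime. These are properties of the
estimators at finite instrument strength, not implementation artifacts;
the recovery checks therefore compare means against the across-replicate
sampling SD rather than asserting exact unbiasedness.

## Numerical choices and degenerate inputs

- Rows violating basic invariants (non-ACGT alleles, se ≤ 0, p outside
  (0, 1], position < 1) are dropped at read time with a logged count;
  missing SEs are never re-imputed from p-values.
- Input dialect (tab/comma) is sniffed from the header; floats are parsed
  in round-trip mode and written at 17 significant digits, so
  write-then-read is bit-exact and pipeline re-runs are byte-identical.
- Wald/weighted-median/funnel refuse γ̂ = 0; IVW's moment form tolerates
  it (zero weight).
- Eigen-floor 1e−10 (relative) in the PC estimator; LD matrices are
  validated square/symmetric with unit diagonal; empirical panel LD is
  PSD up to −1e−8.
- All simulation and bootstrap randomness flows through
  `numpy.random.default_rng` seeded from explicit configuration fields;
  replicate streams are split with `SeedSequence.spawn`.

## Problem sizes used in the checks

The test-suite calibration and recovery runs use the generator defaults
(50 variants, exposure n = 100,000, 20,000/40,000 cases/controls) with
2,000 replicates for null coverage, 500 for IVW and Egger recovery and 200
for the weighted-median breakdown check — enough for the Monte-Carlo SEs
the assertions rely on while keeping the whole suite in a few minutes on a
single core. The acceptance script uses the same sizes with 300/200
recovery replicates.
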