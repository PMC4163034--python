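# Methods

## The liability threshold model

All binary-trait machinery assumes a latent liability `L ~ N(0, 1)` per
individual; disease status is `L > T` with `T = Φ⁻¹(1 − K)` for
prevalence `K`. Derived scalars: `z = φ(T)` (density at the threshold)
and `i = z/K` (mean liability of affected individuals). SNP effects are
additive on standardized genotypes, so a causal variant's liability
heritability equals its squared standardized effect regardless of allele
frequency — consistent with the centred/scaled allelic-correlation
kinship used throughout.

Variance explained estimated on the observed 0/1 scale in a sample with
case fraction `p` converts to the liability scale by
`h²_L = h²_O · K²(1−K)²/(p(1−p)z²)`; the transformation is linear, its
inverse divides by the same factor, and for an unascertained sample
(`p = K`) it reduces to `K(1−K)/z²`. If a fraction `c` of controls are
unrecognised cases, the estimate is attenuated by `(1−c)²` (about 1% at
`c = 0.005`).

### Familial heritability

`familial_h2` maps prevalence and sibling relative risk `λ_s` to total
liability heritability. Writing `K_s = λ_s K`, `T_s = Φ⁻¹(1 − K_s)`, the
default estimator is the Reich-James-Morris corrected Falconer form

    h²_T = 2[T − T_s √(1 − (T² − T_s²)(1 − T/i))] / [i + T_s²(i − T)] ,

which accounts for the curvature of the truncated-normal regression of
sibling liability on proband liability. The first-order form
`2(T − T_s)/i` is available via `reich_correction=False`; it is ~1 point
lower for rare traits (e.g. 31% vs 32% at `K = 0.005, λ_s = 3.3`). The
corrected form is the default because it reproduces the classical
published benchmark values for this estimator family. Confidence
intervals transform the `λ_s` interval endpoint-wise; the estimator is
strictly increasing in `λ_s`, so this is exact given the interval for
`λ_s`. Normal quantiles come from `scipy.stats.norm` (|error| well below
1e-10).

## Synthetic data

The generators produce exactly the structure the estimators assume:

* `simulate_genotypes` — SNPs independent (no LD), Hardy-Weinberg
  dosages `Binomial(2, f)`, frequencies uniform on a configurable range
  (default 0.01-0.5, mirroring a common-variant MAF filter).
* `simulate_liability_trait` — per-variant heritabilities drawn from one
  of four families (equal, uniform, exponential, Gamma(0.5)) and rescaled
  to the target `h²`; effects `±√v_j` with random sign; environmental
  noise `N(0, 1−h²)`, so liability variance is 1 in the generating
  population.
* `simulate_ascertained_cohort` — cases are rare (`1/K` population draws
  per case), so the population is screened in batches of 50 000 using
  only the causal genotypes; non-causal SNPs are filled in afterwards for
  the selected individuals. With independent SNPs this is statistically
  identical to screening full genomes and makes prevalence-0.005
  ascertainment cheap. Controls may be split across several labelled
  cohorts.
* `inject_genotype_errors` — cohort-specific errors: each dosage of the
  named cohort is independently replaced with probability `rate` by a
  Hardy-Weinberg draw at frequency `f + freq_shift`. The frequency shift
  (default 0.01) is the knob that sweeps inflation magnitudes in
  validation experiments; small shifts at realistic rates produce
  artefacts far below the detection limit of small simulated cohorts, so
  validation runs use larger shifts (see below).
* `simulate_correlated_traits` — two traits sharing a causal set with
  effect-size correlation `ρ`; `ρ = ±1` reproduces exactly identical
  (mirrored) effect vectors, not merely identical in distribution.

What the generators do **not** emulate: linkage disequilibrium and
uneven tagging (the kinship here is the unweighted allelic-correlation
form; a per-SNP `weights` hook accepts externally computed tagging
weights), imputation dosage uncertainty, sex chromosomes, and
age/sex-structured prevalence. Passing tests therefore demonstrate
correctness of the estimators under the idealised architecture, not
robustness to LD or platform effects in real cohorts.

## REML

With a single kinship `K`, `V = σ_g²K + σ_e²I`. `GREML` projects the
model onto the orthogonal complement of the covariates (QR), eigendecomposes
the projected kinship once, and profiles the total variance out of the
restricted likelihood, leaving a 1-D bounded optimisation of
`h = σ_g²/(σ_g² + σ_e²)` on [0, 1] (tolerance 1e-9; both boundary values
are also evaluated explicitly, so non-negativity constraints are exact and a
boundary optimum is reported as converged). The standard error comes
from the curvature of the profile restricted log-likelihood at the
optimum. An AI-REML iteration (`ai_reml_univariate`) is kept as an
independent cross-check; tests confirm both engines agree to 1e-5.

`BivariateGREML` couples two traits on *disjoint* sample sets (NaN marks
unmeasured samples) through the cross-block kinship, maximising the joint
restricted likelihood over (σ_g1², σ_g2², ρ, σ_e1², σ_e2²) with L-BFGS-B
(each trait standardised first; variances bounded below at 1e-6, ρ at
±0.99999). Likelihood-ratio tests refit with ρ fixed at 0 and at 1; the
ρ = 1 test sits on the parameter boundary, so its χ²₁ p-value is halved.
Shared-sample residual covariance is not modelled, hence the disjointness
requirement.

The association scan's default engine is the linear score test
(phenotype and genotypes residualised on covariates;
`χ²_j = (n−q) r_j²/(1−r_j²)` for the squared partial correlation
`r_j²`), which matches per-SNP logistic regression closely for balanced
designs and modest effects; the logistic engine falls back to the score
statistic (flagged) on separation. `λ_GC` is the median χ² over 0.4549.

## Inflation corrections

**Population structure** — `structure_profile` refits the REML with
0, …, k leading principal axes as fixed effects. The structure fraction
is the relative drop from the 0-axis estimate to the plateau, defined as
the first axis count where the successive change falls below 2% of the
0-axis estimate; non-monotone (noisy) profiles are smoothed with pairwise
means and flagged.

**Cohort-specific genotyping errors** — with two control cohorts A and B
genotyped separately, the A-vs-B label acquires a spurious
"pseudo-heritability" that probes the artefact. Two estimators:

1. *Closed form* (`relabel_exclusion_delta`). Model the artefactual
   genetic component as `u = αb + η` (`b` the cohort-B indicator). The
   control-only REML fixes `Var(η)` in terms of the pseudo-heritability;
   relabeling to the case-control phenotype `y` gives the artefact's
   explained variance
   `p²q_B² / [q_B(1−q_B) + p_B(1−p_B)(1−ph)/ph]` with `p = n_case/n`,
   `q_B = n_B/n`, `p_B = n_B/(n_A+n_B)`, `ph` the pseudo-heritability.
   First-order REML perturbation analysis shows this effect-level
   transfer is exact in the genome-scale regime (SNPs ≫ samples, where
   the kinship noise spectrum is narrow and an artefact direction is
   fully resolved). At simulation scales (SNPs ≈ samples) the realized
   REML response to a cohort artefact is attenuated severalfold by
   kinship-spectrum and GRM-diagonal effects that cohort sizes alone
   cannot capture; the closed form then over-predicts and should be read
   as an upper bound.
2. *Mechanism-matched bootstrap* (`estimate_error_inflation`), the
   estimator the pipeline uses and the one validated against planted
   errors. The error model's two parameters are identified from cohort
   moments: the mean dosage frequency difference gives `m1 = rate·shift`,
   and the mean dosage variance excess obeys
   `ν = 2m1(1−2f̄) + 2m1·shift − 4m1²` (exact for the replacement
   mixture), so `shift = (ν − 2m1(1−2f̄) + 4m1²)/(2m1)` and
   `rate = m1/shift`. The estimated mechanism is replayed on a small
   number of simulated clean cohorts of the same shape (same cohort
   sizes, SNP count, prevalence, and a polygenic trait at the analysis's
   own liability-scale estimate so the REML operates at a comparable
   point); the mean induced change in the case-control estimate is the
   predicted inflation. This mirrors a proof-by-simulation validation
   strategy while remaining a pure estimator (it sees only observed
   data).

Corrections are subtracted multiplicatively:
`h²_C = h²_L (1 − Σ fractions)` — matching the arithmetic
31% − (9% + 8%) → 26%.

## Power and causal-variant counts

The 1-df statistic of a variant explaining `v_L` of liability variance is
noncentral χ²₁ with `NCP = n·v_O`, `v_O = v_L·p(1−p)z²/(K²(1−K)²)`;
power at level α is the exact tail
`Φ(√NCP − √c) + Φ(−√NCP − √c)` with `c = χ²₁⁻¹(1−α)`. This
reconstruction reproduces the classical anchors (80% power at 0.46% of
liability variance and 50% at 0.35% for n = 6387, α = 5e-8) and is fixed
as the package's definition; whether `NCP` should carry a `1/(1−v_O)`
factor is numerically irrelevant at these magnitudes.

Spectra are deterministic mid-quantiles `v_j ∝ F⁻¹((j−0.5)/m)` of the
family's base distribution, rescaled to the total — reproducible without
seeds. The zero-discovery probability is `∏(1 − power_j)` (independent
variants); it increases with m, and the causal-count point estimate
(lower bound) is the smallest m on a step-10 grid with probability ≥ 0.5
(0.05). Discovery projections at larger n report `Σ power_j` and
`Σ power_j v_j` at α = 5e-8 with the case:control ratio held fixed.
With our normal-tail constants the equal-family point estimate lands at
860 rather than the published 870 (the zero-discovery probability at 870
is 0.506, i.e. the crossing is just below the published grid point);
all families agree with the published counts within 2%.

## Prediction

Score and liability are bivariate standard normal with correlation
`√r²_L`. Screening AUC integrates
`Φ(r(l₁−l₂)/√(2(1−r²)))` over truncated case/control liabilities
(`scipy.integrate.quad`, liability range ±9); top-quantile risk is a
bivariate-normal orthant probability. Triage conditions the case score on
`L > T`; the non-recurrent ("control") liability distribution is either
the general population (best case) or degenerate at the threshold
(worst case, `G | L = T`); a truncation-window variant `(T−ε, T)` is
available since the degenerate construction is one of several plausible
formalisations — the worst-case AUC is therefore not pinned to any
published value. `prev1`, the epilepsy prevalence among single-seizure
patients, defaults to 0.45 (midpoint of the cited 40-50% range); it
moves only PPV/sensitivity, never the ROC. `required_r2` inverts the
(monotone) AUC by bisection to 1e-4. A Monte-Carlo engine cross-checks
every printed quantity to < 0.002.

## Numerical and design choices

* Allele frequencies for the GRM are estimated from the pooled analysis
  sample (cases + controls); monomorphic SNPs are dropped with a warning.
* Relatedness filtering is greedy max-degree removal (ties: drop the
  larger sample index) against a one-sided kinship threshold, default
  2.6%. The pipeline auto-raises the threshold to `max(0.026, 6/√m)`
  because at small simulated SNP counts kinship sampling noise
  (sd ≈ 1/√m) exceeds 2.6% and the literal cutoff would remove nearly
  all samples; genuine duplicates and first-degree pairs are still far
  above the raised cutoff.
* Principal axes use a deterministic sign convention (largest-magnitude
  loading positive).
* Eigenvalues of the projected kinship are clipped at zero; a negative
  eigenvalue beyond -1e-6·λ_max raises a numeric error.
* The pipeline writes JSON/TSV artefacts per stage, embeds the package
  version, seed and a SHA-256 config hash, rejects unknown config keys,
  and tags failures with the stage name while retaining partial outputs.
  CLI exit codes: 0 ok, 2 config error, 3 data-format error, 4 numerical
  failure.

## Problem sizes used in the validation suite

Simulation calibrations run at scaled-down sizes chosen so Monte-Carlo
error is small against each stated tolerance: univariate recovery at
n = 2000, m = 5000 over 50 seeds; bivariate ρ recovery at 2×300 samples,
m = 1000, 10 seeds per ρ; ascertainment-bias replication at 200 cases /
800 controls, m = 1000, 50 replicates (the mean liability-scale recovery
ratio falls in [0.80, 0.97], consistent with the transformation's known
~10% underestimation at K = 0.005); genotyping-error tracking at
300/300/300 samples, m = 1200, error rate 0.04 with frequency shift 0.25
— strong enough for the planted inflation to dominate REML seed noise at
these sizes, per the variance analysis above.

## Known limitations

* No LD or tagging weights in the generators; the LDAK-style weighting
  entry point is a hook only.
* The bivariate optimiser uses numerical gradients; for very small
  samples the ρ̂ likelihood is flat and single-dataset estimates are wide
  (SE is reported from the profile curvature).
* The closed-form genotyping-error transfer is regime-dependent (see
  above); outside the genome-scale regime use the bootstrap estimator.
* The structure-fraction plateau rule assumes the profile stabilises
  within the axis counts provided; profiles that keep falling return the
  last point as the plateau, flagged.
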