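# Methods

## The proxy G×E MR design

Gene-by-environment Mendelian randomization exploits an instrument whose
effect on the exposure is confined to one environmental stratum. Here
the instrument is a smoking-heaviness variant (dosage *G* ∈ {0,1,2}
smoking-increasing alleles, additive coding) that increases
cigarettes/day among smokers but does nothing in never smokers. If
maternal smoking heaviness in pregnancy causally affects an offspring
outcome, the per-allele association of the *maternal* dosage with that
outcome should be present in the maternal-smoking stratum and absent in
the non-smoking stratum; heterogeneity between the stratum slopes is the
test statistic.

When the maternal (G0) genotype is untyped, the participant's (G1) own
dosage proxies it. Under random mating the offspring dosage is one
Bernoulli(G0/2) maternal allele plus one Bernoulli(p) paternal allele,
so E[G1 | G0] = G0/2 + p and Var(G1) = Var(G0) = 2p(1−p) at
Hardy–Weinberg equilibrium. For any outcome Y that depends on the
genotype only through G0 with slope β,

    cov(Y, G1) = β · cov(G0, G1) = β · Var(G0)/2,

so the proxy regression slope is exactly β/2: half the offspring
instrument is paternal noise. This dilution is the central quantitative
fact of the design — it is what the attenuation estimator measures and
what halves the noncentrality (quarters the effective effect size) of
the proxy interaction test.

## Generative model

`generate_cohort` draws, per family:

1. **Genotypes.** G0 dosage ~ Binomial(2, p), default p = 0.33
   (European-range frequency for this class of instrument). G1 receives
   one maternal allele (recorded) plus one paternal allele ~ Bernoulli(p).
   A test-only `clone_transmission` switch copies the maternal genotype
   and must drive the attenuation ratio to 1.
2. **Confounder.** One standard-normal family variable *U* loading on
   every smoking propensity (log-odds `confounder_smoking`, default 0.3)
   and on every continuous outcome (`confounder_outcome`, default 0.1
   outcome units/SD).
3. **Smoking.** Status from a logistic model; G1 uptake odds are
   multiplied by `intergen_smoking_or` (default 1.5) when G0 smoked.
   Among smokers, cigarettes/day = max(0, Normal(15 + 1·dosage, 8));
   never smokers have exactly 0. The point mass at zero attenuates the
   realized per-allele cigarette effect by Φ(mean/sd) ≈ 0.977; unit
   tests therefore check the simulated dosage contrast against the
   truncated-normal closed form, not the pre-truncation coefficient.
   An `or_gene_smoker` knob (default 1.0, i.e. a clean G×E instrument)
   lets bias studies implant a genotype→smoking-status association of
   the kind observed in real cohorts.
4. **Birthweights.** G1 birthweight = 3.4 kg − 0.02·(G0 pregnancy
   cigarettes/day) − 0.12·female + 0.1·U + Normal(0, 0.5 kg); G2
   birthweight analogous with G1 pregnancy cigarettes and an optional
   grandmaternal term (`beta_g0cigs_g2`, default 0). Effect sizes are
   package defaults chosen so the per-allele stratum effect
   (−0.02 kg/allele direct, −0.01 proxy) is of the order seen in
   population cohorts; all are configurable and echoed in output
   metadata.
5. **Life course.** Baseline age ~ Uniform{40..69}; 85% of women have a
   first birth at an integer age ~ Normal(26, 4) clipped to [16, 38]
   (the upper clip guarantees rule-consistent smoking ages exist below
   the baseline age). Among ever-smoking mothers, pregnancy smoking is
   Bernoulli(`p_g1_preg_smoker` = 0.35); defining this probability
   conditional on ever smoking makes never-smokers pregnancy
   non-smokers by construction. Start/stop ages are then drawn from the
   integer windows that make the whole-year derivation (below)
   determinate and equal to the true flag — so derivation accuracy on
   simulated data is a logic check, not a statistical one. Real data
   contain indeterminate histories; the simulator's mothers do not.
6. **Adult outcomes.** Each configured outcome is linear (Gaussian),
   binary (logistic) or ordinal (proportional-odds latent logistic cut
   at equal baseline probabilities; happiness uses 6 levels), with its
   own cigarettes/day effects for the participant and the mother.
   Defaults implant established own-smoking effects (lower BMI, lower
   FEV1) and zero maternal effects — the null the interaction tests are
   calibrated against.
7. **Bias operators.** `apply_reporting_error` flips reported G0/G1
   smoking indicators with given probabilities, preserving the truth
   columns; `apply_selection` retains rows by a logistic participation
   model over arbitrary cohort columns. Both are off by default.

All randomness flows through one `numpy` Generator; a fixed seed makes
`generate_cohort` bit-reproducible.

## Pregnancy-smoking derivation

With ages recorded in whole years and a first birth at age *b*, a woman
is a **non-smoker in pregnancy** if she (i) never smoked, (ii)/(iii)
currently/formerly smoked but started at *b*+1 or later, or (iv)
formerly smoked but stopped at *b*−2 or earlier; a **smoker** if she
(i) currently smokes and started at *b*−1 or earlier, or (ii) formerly
smoked, started at *b*−1 or earlier and stopped at *b*+1 or later.
Boundaries are taken literally; everything else — start at exactly *b*,
former smokers stopping at *b*−1 or *b*, missing start ages — is
indeterminate. Indeterminate women are excluded from pregnancy-smoking
strata (their counts are always reported) but remain in ever/never
strata. An exhaustive truth-table test over offsets ±10 years checks
the implementation against an independent predicate oracle.

Sensitivity re-stratification for outcomes fixed around puberty uses
"ever smoked before age X": X = 17 (men) / 15 (women) for adult height,
and the woman's own reported age at menarche for menarche.

## Estimators

Per-stratum fits delegate to statsmodels (OLS; Logit; proportional-odds
`OrderedModel` with logit link), returning the exposure coefficient —
per-allele when the exposure is a dosage — with covariates partialled
out. Conventions: 95% CIs as β ± 1.96·SE and two-sided normal p-values
in every family (at the sample sizes of interest t vs normal is
immaterial); crude and adjusted models both emitted for the
proof-of-principle analysis; covariate sets are sex + 10 PCs for G1
birthweight, age + sex + 10 PCs for adult outcomes (sex omitted for
women-only outcomes), 10 PCs for G2 birthweight. Strata below 50 usable
rows are skipped with a logged reason. Separation or non-convergence
yields a flagged estimate (`converged=False`), never a silent failure;
a constant exposure raises. No multiple-testing adjustment is applied;
summaries always record the number of tests performed.

Interaction statistics are computed in-package:

- **Cochran's Q**: weights w = 1/SE², Q = Σw(β−β̄)², chi-square with
  k−1 df. For k = 2 this is algebraically the squared z-difference —
  asserted to machine precision in tests, so either formulation matches
  published interaction p-values.
- **Stratum difference**: Δ = β₁−β₂, SE² = SE₁²+SE₂², normal z.
- **Difference of differences**: the same contrast applied to two
  stratum differences from disjoint strata (variance = sum of the four
  stratum variances), testing whether maternal (G1) pregnancy smoking
  modulates the grandmaternal (G0) effect on G2 birthweight.
- **Confounder scan**: dosage association with each candidate variable
  (logistic for 0/1 variables, linear otherwise), flagging |z| > 3.

## Power, calibration and attenuation studies

`run_power_study` simulates replicate cohorts per (n, effect) grid cell
and computes the two-stratum interaction p-value using the maternal
(direct) and offspring (proxy) dosage on the *same* cohorts, giving a
paired comparison; power is the rejection fraction with binomial
Monte-Carlo SE. Fits in these loops are crude: the simulated PCs and sex
are independent noise, so adjustment would only add runtime. Replicate
seeds are spawned from the master seed with `SeedSequence`, so any cell
is reproducible in isolation. Default grids: n ∈ {10 000, 50 000,
200 000}, effect ∈ {0, −0.01, −0.02, −0.04} kg per cigarette/day,
500 replicates, α = 0.05.

`type1_error_study` requires every maternal-effect parameter to be zero
and reports the rejection rate with an exact Clopper–Pearson CI.

`attenuation_estimate` averages the replicate-level ratio of proxy to
direct slope in the exposed stratum, excluding (and counting)
replicates whose direct slope has |z| < 2, where the ratio is
uninformative noise. At the default effect a single 200,000-family
cohort yields a ratio with Monte-Carlo SD ≈ 0.14, so the acceptance
script averages 100 replicates (MC SE ≈ 0.014, i.e. ≈ 1.4 percentage
points on the attenuation percentage) in under a minute.

## Problem sizes and numerical choices

The shipped validation suite uses: 30 replicates of 200,000 families for
the attenuation check; 2 000 replicate cohorts of 10 000 families for
null calibration of the interaction test (observed rate 0.048); 500
cohorts of 50 000 families for CI coverage of the implanted −0.02
kg/allele effect (observed 95.8%, band 93–97%); a 2 × 3 power grid
(n ∈ {5 000, 20 000} × effect ∈ {0, −0.02, −0.04}) at 200 replicates for
the design-ordering and monotonicity checks. These sizes keep the whole
suite at a few minutes while leaving every check's Monte-Carlo error
well inside its tolerance.

Degenerate inputs are handled explicitly: allele frequencies 0/1 are
allowed in the low-level samplers (forced transmission tests) but
rejected in configs; never smokers always carry zero cigarettes and no
ages; empty or constant-exposure strata are skipped, not fitted.

## Limitations

- The simulator emulates the *statistical structure* of a UK-Biobank-like
  cohort, not its content: no assortative mating, sibling structure,
  X-linkage, polygenic instruments, gestation-length or
  trimester-specific exposure windows, and one child per woman. Passing
  tests show the estimators behave correctly under the assumed causal
  structure; they cannot validate that structure in real data.
- Smoking ages of simulated mothers are rule-consistent by construction,
  so the derivation's indeterminate path is exercised only by synthetic
  edge cases and user data.
- Per-allele associations are reported as such; no Wald-ratio scaling to
  per-cigarette causal effects is attempted.
- Real-cohort headline estimates depend on access-controlled data and
  are outside what simulation can reproduce; the package's quantitative
  anchor is the analytic 50% proxy attenuation.
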