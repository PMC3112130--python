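# Methods

## The model

`twinliab` implements the classical five-group twin design for a binary
phenotype under the liability-threshold model. Each individual's phenotype
is the dichotomization of an unobserved liability *L* ~ N(0, 1): the
individual is "affected" when *L* exceeds a threshold τ, so the population
prevalence *p* fixes τ through Φ(τ) = 1 − *p*. For a twin pair the two
liabilities are standard bivariate normal with a correlation ρ that depends
on zygosity, sex composition and, in this design, birth cohort.

The liability variance is decomposed into additive genetic (A), common
(shared) environmental (C) and unique environmental (E) components with
standardized path coefficients *a, c, e* per sex *s* and cohort *k*, under
the unit-variance constraint *a*² + *c*² + *e*² = 1. The implied twin
correlations are

| group | ρ |
|---|---|
| MZ same-sex | *a*² + *c*² |
| DZ same-sex | ½ *a*² + *c*² |
| DZ opposite-sex (DOS) | ½ *a*<sub>M</sub>*a*<sub>F</sub> + R<sub>c,dos</sub> *c*<sub>M</sub>*c*<sub>F</sub> |

R<sub>c,dos</sub> is the correlation between the shared-environment factors
of the male and female co-twin; R<sub>c,dos</sub> = 1 means the same shared
environment acts in both sexes (no qualitative sex difference). The DOS
additive-genetic correlation is fixed at ½; qualitative sex differences are
modelled on C only.

Fitting uses full-information maximum likelihood on raw pair records: a
complete pair contributes the bivariate-normal joint-outcome probability of
its cell, a singleton twin the Bernoulli margin of its own threshold.
Because the data are binary, the raw-data log-likelihood reduces exactly to
the per-group 2×2 concordance tables plus singleton margins, which is what
the optimizer consumes — fitting cost is independent of sample size.

Thresholds are always free per sex × zygosity × cohort (8 for two cohorts)
in every model of the ladder; prevalence differences between cohorts are
tested separately on the descriptive surface, not inside the ACE ladder.

## The model ladder

Eight nested models are compared by likelihood-ratio tests with a fixed
topology (sub vs parent: 2 vs 1; 3, 4, 5 vs 2; 6 vs 5; 7, 8 vs 6):

1. Full ACE: *a, c, e* free per sex per cohort; R<sub>c,dos</sub> free per cohort.
2. R<sub>c,dos</sub> = 1 (no qualitative sex differences).
3. / 4. / 5. A, C, E equal across cohorts for men / women / both —
   the gene-by-environment (cohort-moderation) question.
6. No quantitative sex differences (one A, C, E triple).
7. / 8. Drop A / drop C from model 6.

Twice the log-likelihood difference is referred to a central χ² with df
equal to the difference in model df; a sub-model is retained when p ≥ 0.01.
Degrees of freedom follow the raw-data convention
df = n<sub>individuals</sub> − n<sub>free parameters</sub> + n<sub>constraints</sub>,
counting *a, c, e* all as free with one unit-variance constraint per
sex × cohort (4 constraints for two cohorts). This is the only accounting
that reproduces the conventional df column for this design (e.g. the full
model at n = 5008 has 12 paths + 8 thresholds + 2 R<sub>c,dos</sub> = 22
free parameters and df = 5008 − 22 + 4 = 4990); internally the optimizer
eliminates *e* by reparameterization.

## Numerical choices

**Bivariate normal orthant probabilities.** `bvn_upper_tail` evaluates
P(X > τ₁, Y > τ₂) with two fixed-node rules: for |ρ| ≤ 0.925, 20-point
Gauss–Legendre quadrature on the arcsine single-integral form
P = Φ̄(τ₁)Φ̄(τ₂) + (2π)⁻¹ ∫₀^{asin ρ} exp(−(τ₁² − 2τ₁τ₂ sin u + τ₂²)/(2cos²u)) du;
for |ρ| > 0.925, a tanh–sinh (double-exponential) rule on the complementary
tail form obtained by integrating Plackett's identity from the comonotone
limit, whose integrand has an essential singularity at the ρ → 1 endpoint
that the DE node clustering absorbs. Validated absolute error is below
1e-13 over ρ ∈ (−1, 1) (tests compare against adaptive quadrature); the
limits ρ = ±1 within 1e-12 short-circuit to closed forms. Analytic
derivatives (∂/∂τ by differentiation under the integral, ∂/∂ρ by Plackett's
identity) feed the likelihood gradient, so no finite differencing occurs
inside optimization.

**Parameterization and optimizer.** Variance shares use stick-breaking on
the simplex, A = σ(u), C = (1 − A)σ(v), keeping every share in (0, 1) and
the variance exactly 1; thresholds are unconstrained; the tetrachoric
correlation uses Fisher's z. Optimization is L-BFGS-B with the analytic
gradient, relative ftol 2e-12 (≈1e-8 absolute on a deviance of a few
thousand) and five deterministic starts, (A₀, C₀, R₀) ∈ {(.45,.25,.8),
(.60,.15,.8), (.20,.45,.8), (.35,.35,.2), (.55,.30,−.2)}, with thresholds
started at the observed prevalence quantiles. Ties between starts are broken
by lowest deviance, then lowest start index; two starts agreeing within
1e-4 stop the schedule early. Ladder fits warm-start from their parent's
estimates. Cell probabilities are floored at 1e-12 so the gradient stays
finite when the optimizer probes a region that makes an observed cell
impossible; legitimate cells at plausible thresholds sit many orders of
magnitude above the floor.

**R<sub>c,dos</sub> range.** The likelihood depends on R<sub>c,dos</sub>
only through the implied DOS correlation, which must lie in (−1, 1) — the
parameter itself need not. It is therefore parameterized as 4·tanh(w) ∈
(−4, 4), wide enough that the binding constraint is the implied-correlation
clamp (the natural information boundary) rather than an arbitrary cap.
This makes the R<sub>c,dos</sub> = 1 null hypothesis an interior point: its
likelihood-ratio test is then a regular χ², where a hard [−1, 1] bound
would turn it into a boundary (chi-bar-square) problem and distort the
test's type-I calibration. A second, finite-sample caveat remains: when a
nuisance share (e.g. the small male shared-environment share) collapses to
its 0 boundary, R<sub>c,dos</sub> becomes locally unidentified and the test
turns conservative. At the study's own sample sizes this happens often
enough to shift the null p-value distribution visibly upward; at ten times
those sizes the test is well calibrated (χ² mean ≈ 2, p-values uniform),
which is the scale the calibration experiments use. Reported profile
intervals for
R<sub>c,dos</sub> are still truncated to [−1, 1], the interpretable range of
a factor correlation. Implied DOS correlations outside ±0.999999 are
clamped during optimization.

**Profile-likelihood intervals.** 95% CIs are likelihood-based: the bound is
the component value at which the re-optimized deviance exceeds the minimum
by 3.84 (χ²₀.₉₅,₁), found by root bracketing to 1e-4 on the parameter
scale, truncated at [0, 1] for variance shares and [−1, 1] for
correlations. Components pinned by a model (e.g. A in the drop-A model)
have no interval.

**Tetrachoric estimation.** Per group, (r, τ) maximize the multinomial
likelihood with singletons contributing margins; same-sex groups share one
threshold between co-twins, DOS tables carry a male and a female threshold.
When cohorts are pooled ("combined" column) the default keeps
cohort-specific thresholds and shares only r, since the cohorts' prevalences
differ strongly; a flag forces fully pooled tables instead. Degenerate
tables (no discordant or mixed pattern, or a margin with a single outcome)
are rejected as unidentified rather than returned at a boundary.

**LRT clamping.** Deviance differences more negative than −1e-3 raise a
non-nesting error; smaller negatives (optimizer noise) are clamped to zero
and flagged. Displayed p-values use 4 decimals, round-half-even, with values
below 0.00005 shown as "< 0.0001".

## The synthetic-data generator

The generator draws, per pair, two standard-normal liabilities at the
group's model-implied correlation and dichotomizes them at the configured
thresholds; singletons are univariate draws. One RNG stream per
group × cohort is derived from the master seed, so changing one group's
counts never perturbs another group's draws.

The `paper-combined` preset emulates the two Netherlands Twin Register
young-adult survey cohorts (1993-1995 and 2009-2010) whose raw records are
not publicly deposited. Pair counts follow the published cohort
description, per-cell prevalences the published counts, and the generating
ACE shares are the published combined-cohort per-sex estimates
(men A=.66/C=.14/E=.20, women A=.21/C=.57/E=.22), equal across cohorts with
R<sub>c,dos</sub> = 1. Two reconciliations were needed because the published
per-group figures are not mutually consistent at the margin: (i) the
published group counts sum to 2667 and 2341 individuals while the cohort
totals are given as 2669 and 2339 — the two-individual residual per cohort
is absorbed in the DOS singleton counts; (ii) the published pooled shares
0.55 + 0.23 + 0.21 sum to 0.99 (printed rounding) — E absorbs the remainder
(0.22) to restore unit variance.

What the generator does *not* emulate: survey non-response structure,
item-level responses, age heterogeneity within 18-25, household clustering
beyond the twin pair, or any misfit of the liability-threshold model
itself. Passing recovery and calibration tests therefore demonstrates the
correctness of the estimation machinery under the model's own assumptions,
not robustness of the design to violations of them.

## Problem sizes used in the test suite

Simulation-based checks use sizes chosen to bound Monte-Carlo error at the
precision each assertion needs: parameter recovery uses 20,000 pairs per
group (SE of  ≈ 0.005), CI-coverage and LRT-calibration experiments run
200-300 replications at the study's own sample sizes, and the ladder
decision check uses ten times those sizes over 20 seeds.

## Known limitations

* No ADE models, continuous moderators, ordinal (>2 category) liabilities,
  or covariates on thresholds.
* Variance shares are constrained to [0, 1]; negative components are out of
  model, so a DZ correlation far above the MZ correlation is absorbed at a
  boundary rather than estimated as negative A.
* Asymptotic χ² reference for all LRTs; no bootstrap null.
* The descriptive prevalence comparison offers both the Pearson χ² and the
  threshold-equality LRT; the two agree closely at these sample sizes and
  neither is privileged.
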