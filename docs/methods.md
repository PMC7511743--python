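# Methods

## Subject-level model of lesion load

Total WMH load is a voxel count with a strongly right-skewed marginal, so
it is modelled on the natural-log scale by a normal linear model

    Y_i ~ N(mu_i, sigma^2),   mu_i = x_i' beta,

with confounders age, sex, age × sex and head-size scaling factor, plus
risk terms. Discrete covariates use treatment contrasts against level 0
(k-level factors expand to k−1 dummies), so each coefficient is the effect
of that level relative to the baseline category; `exp(beta)` is the
multiplicative fold change in load. Confidence intervals use t quantiles
with df = N − P (at cohort-scale N this is indistinguishable from the
normal approximation). Goodness of fit is adjusted R²,
`1 − (1−R²)(N−1)/(N−P)`. The per-term **partial adjusted R²** is defined as

    1 − [SSE_full/(N−P_full)] / [SSE_reduced/(N−P_reduced)],

where the reduced model drops the term's entire contrast block (both
dummies of a 3-level factor jointly). There is no single canonical
"partial adjusted R²"; this adjusted-SSE-ratio form was chosen because it
reduces to the classical partial R² without adjustment and is testable
against an explicit reduced-model refit, which the test suite uses as its
oracle.

The loess smoother is the classical tricube-weighted local polynomial: at
each evaluation point the nearest `ceil(span · n)` observations are fitted
by weighted polynomial regression and the fitted value at the point is
returned. Span defaults to 0.2 (each window holds 20% of the data) and
degree to 1; degree is configurable (0–2) because local-constant and
local-quadratic variants are all in routine use.

## Voxel-wise probability model and bias-reduced estimation

At each voxel s_j inside the analysis mask, lesion presence is modelled as

    Y_i(s_j) | p_i(s_j) ~ Bernoulli(p_i(s_j)),
    p_i(s_j) = Phi(x_i' beta(s_j)),          (probit; logit supported)

fitted independently per voxel with a shared subject-level design. The
analysis mask keeps voxels with at least `min_count = 4` lesioned subjects
(inside the brain mask): below that, even bias-reduced estimates carry
little information and the mass of uninformative tests would distort FDR
correction.

Maximum likelihood is computed by Fisher scoring (IWLS). Its failure mode
here is **separation**: at low-incidence voxels some covariate combination
perfectly splits lesioned from non-lesioned subjects and the MLE diverges.
The default estimator is therefore the **mean bias-reduced (BR)** one,
which solves the adjusted score equations

    sum_i (w_i / d_i) x_i [ y_i − mu_i + h_i d'_i / (2 w_i) ] = 0,

with d_i = dmu/deta, working weights w_i = d_i²/v_i, v_i = mu_i(1−mu_i),
and h_i the leverages of the W-weighted hat matrix. The adjustment term
subtracts the first-order bias of the estimator at each scoring step; it
keeps estimates finite under complete separation and shrinks
finite-sample bias. For the logit link the equations are exactly the
stationarity conditions of the Jeffreys-prior penalised log-likelihood
(Firth), which gives two independent correctness contracts used by the
tests: the intercept-only closed form `logit((k+1/2)/(n+1))` and agreement
with a generic optimiser of the penalised likelihood.

Numerical choices:

- start values: weighted least squares on the working response of the
  half/half-smoothed outcome `mu_0 = (y + 1/2)/2`;
- convergence: max-norm of the (adjusted) score below `tol = 1e−8`,
  `max_iter = 100`;
- line search: up to 10 step-halvings per iteration. ML and logit-BR halve
  on decrease of their exact objective (log-likelihood, resp. penalised
  log-likelihood). The probit-BR adjusted score is not the gradient of any
  simple objective, so halving there only guards against divergence (a
  >10× jump of the score norm); demanding monotone score decrease was
  observed to stall convergence on well-behaved voxels;
- the linear predictor is clipped at |eta| = 30 and fitted probabilities at
  1e−10 for numerical stability; an ML iteration whose predictor saturates
  is reported as non-converged (diverging) with the last iterate retained;
- standard errors always come from the expected (not observed) information
  at the returned estimates; Wald p-values are two-sided normal.

Separation is additionally detectable by a linear-feasibility search
(maximise the margin sum subject to sign constraints, solved as an LP);
this is a diagnostic only — BR fitting proceeds regardless — and it is
skipped inside bulk voxel loops for speed.

## Multiple testing

p-value maps are corrected by Benjamini–Hochberg step-up across in-mask
voxels, **separately per coefficient map** (matching per-predictor
significant-voxel reporting; a joint scope across predictors would couple
unrelated maps). Adjusted q-values use the cumulative-minimum form, so
q ≥ p everywhere and significance = (q ≤ α), α = 0.05 by default. Voxels
whose fit did not converge are excluded from the correction and counted in
the map set rather than entered with an imputed p = 1, which would bias
the BH threshold; with BR fitting such voxels are rare to absent.
Voxel fits are independent; execution is serial and deterministic, so
results do not depend on scheduling.

## Mediation analysis

For treatment X (log load), mediator M and outcome Y (reaction time), with
shared covariates (age, sex, age × sex, head size, years of education):

    M = a X + covariates + e_M
    Y = c' X + b M + covariates + e_Y

ACME = a·b, ADE = c', and the total effect (from Y ~ X + covariates)
equals their sum *exactly* in the all-linear case (a consequence of OLS
projection algebra; asserted to 1e−10). Binary mediators use a BR binary
GLM and the potential-outcome composition
ACME = b · mean[P(M=1|X=x+1) − P(M=1|X=x)] for a one-unit treatment
increment (one unit of log load). Uncertainty comes from resampling whole
subject rows — the nonparametric bootstrap, default B = 10,000 — with
percentile CIs. The bootstrap p-value is `2·min(#(est* ≤ 0), #(est* ≥ 0))
+ 1)/(B + 1)` (two-sided with continuity correction; bootstrap p-values
have no unique definition and this one is conservative and
reproducibility-friendly). The point estimate of the proportion mediated
is full-sample ACME/total; the median of resample-wise ratios is reported
alongside, because the two need not agree and the ratio's bootstrap
distribution is heavy-tailed when the total effect is near zero (flagged
undefined at total = 0).

## Risk-variable derivation

- Hypertension risk: mean of the two readings per channel; positive if
  mean systolic > 140 **or** mean diastolic > 90 **or** on BP medication.
  The rule is strict ("over"), so exactly 140/90 codes 0. Three-valued
  logic: the indicator is 0 only when every condition is known false;
  otherwise missing conditions propagate to the missing marker.
- Pack-years = (cigarettes/day ÷ 20) × years smoked, with recorded
  abstinence subtracted when it exceeds half a year; smoking score 0/1/2
  with breakpoints at exactly 10 and 50 pack-years.
- WHR indicator: ≥ 0.9 (men) / ≥ 0.85 (women), inclusive per WHO
  convention, with a configurable strictness flag.
- APOE status counts ε4 alleles (0/1/2). The ε2/ε4 diplotype carries one
  ε4 allele and defaults to status 1; a policy option excludes such
  subjects instead, since heterozygous status is sometimes defined as
  ε3/ε4 only.
- Education years map from qualification categories onto the six observed
  levels {7, 10, 13, 15, 19, 20}.
- Missing values are explicit NaN sentinels end to end; the complete-case
  filter removes rows and reports per-column missingness counts (a row
  missing several variables counts once in the total).

## Synthetic cohort generator

The generator's defaults reproduce the reference cohort's published
marginals: n = 13,680; age ~ N(62.9, 7.4²) truncated to [45.1, 80.7];
7,236/13,680 female; head size ~ N(1.3, 0.1²); risk prevalences
hypertension 6,408/13,680, hypercholesterolemia 2,781/13,680, diabetes
663/13,680, smoking levels (11,291, 2,238, 151)/13,680, APOE levels
(10,226, 3,150, 304)/13,680; education years sampled at the published
frequencies; WHR ~ N(0.9, 0.1²) with the indicator derived through the
sex-specific thresholds. Raw fields (reading pairs symmetric about their
channel mean, smoking histories whose derived pack-years land in the
intended band, genotype strings, qualification categories) are constructed
so that re-deriving the risk variables through `risk_factors` reproduces
the intended levels exactly — the round-trip is a tested invariant. Note
one emergent property: with the mean-0.9/sd-0.1 WHR rule the indicator
prevalence comes out near 0.60 rather than the cohort's observed 0.47;
matching both the published WHR mean and the published indicator
prevalence simultaneously would require sex-specific WHR distributions the
source tables do not provide, and the continuous-WHR marginal was kept.

Risk factors are independent by default (their true joint distribution in
the cohort is unpublished); a Gaussian-copula option adds pairwise latent
correlations (e.g. hypertension–WHR) for stress-testing confounding, which
the pipeline tests use to reproduce the marginal-vs-joint attenuation
direction.

Log load is the published coefficient set — intercept 2.19, age 0.06,
female −0.48, age × female 0.01, head size −0.29, CVR score 0.14 — plus
N(0, 0.86²) noise; 0.86 was chosen once so the model's adjusted R² lands
near the published 0.26 given the generated covariate spread. The voxel
count is `round(exp(log load))` floored at 3 voxels (the smallest load the
cohort contains), keeping the log transform defined.

Lesion stacks draw Y_i(s) ~ Bernoulli(Phi(beta0(s) + effects)) with a
smooth Gaussian-bump baseline field (floor −1.6 ≈ 5.5% background
probability, peak −0.1 ≈ 46% at a central "periventricular" core) and
spherical effect regions of constant probit amplitude whose ground-truth
fields are returned for recovery checks. The default test grid is
20 × 20 × 10 voxels; the full 91 × 109 × 91 standard grid is supported but
not required by the suite.

The reaction-time outcome reproduces the published *path structure* —
direct effect 2.55 per unit log load, mediation paths a = 0.11 (treatment
to mediator) and b = 0.05 (mediator to outcome) — with unit-scale noise on
the mediator and outcome. Unit noise keeps the a·b = 0.0055 mediated
effect recoverable at n ≈ 2,000; with noise matched to the raw
reaction-time spread (sd ≈ 105 ms) the published path coefficients are
mutually inconsistent in scale, so the synthetic outcome's marginal
dispersion is not calibrated to milliseconds and should not be read as
such.

What the generator does *not* emulate: realistic lesion shapes and
spatial autocorrelation of lesion occurrence (voxels are conditionally
independent given the probability field), the cohort's missingness
mechanism, scanner/site effects, and the true joint distribution of risk
factors. Passing recovery tests therefore demonstrates correctness of the
estimators under the assumed model, not robustness to violations of it.

## Problem sizes used by the test and acceptance runs

Chosen as the package's test-design points: estimator-bias simulation at
n = 50 with 1,000 replicates; null FDR calibration on a 12 × 12 × 6 grid,
n = 200, 20 seeds; blob recovery on 20 × 20 × 10, n = 500, amplitude 0.8;
mediation CI coverage over 200 replicates at n = 600 with B = 500;
load-model recovery over 100 seeds at the reference n = 13,680.

## Known limitations

- Probit BR convergence is declared on the adjusted-score norm without a
  matching objective; pathological designs could in principle cycle,
  though the divergence guard and iteration cap make this visible
  (`converged=False`) rather than silent.
- The LP-based separation check certifies weak separation; it does not
  distinguish complete from quasi-complete separation.
- Mediation inference assumes sequential ignorability; no sensitivity
  analysis is provided.
- The pipeline starts from binary masks on a common grid: registration,
  segmentation and anatomical (deep vs periventricular) labelling are out
  of scope.
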