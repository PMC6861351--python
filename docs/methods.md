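# Methods

## Problem and scope

`smokesig` implements the development and internal validation of blood
DNA-methylation classifiers of tobacco-smoking habit and history. The
procedure it codifies: candidate CpGs are ascertained from published EWAS
evidence; participants are quality-filtered; a finite marker panel is
selected by backward elimination on |z| with a chi-squared stopping rule;
binary and multinomial logit models are fitted for current-smoking status,
current/former/never status, cessation time, pack-years, and a combined
five-category lifetime outcome; models are internally validated by
fivefold cross-validation and bootstrap optimism correction; the binary
model is compared against the 50 ng/mL plasma-cotinine rule; and the
frozen adult model is applied to child cohorts under five prenatal-smoking
exposure recodings.

Cohort-level methylation data for this problem are access-restricted, so
the package ships a synthetic cohort generator that reproduces the
statistical structure the analysis assumes, and every stage is exercised
on generated cohorts. Array preprocessing, cell-count estimation and
external-cohort harmonisation are out of scope.

## Models

All classifiers are maximum-likelihood logit models over a marker panel
(beta values as predictors, plus optional covariates):

* **Binary**: `P(current | x) = expit(b0 + b'x)`, fitted as a binomial GLM
  with logit link; calls are positive at probability strictly greater than
  a threshold (0.5 for the habit and pack-year models).
* **Multinomial**: baseline-category logits with reference category
  "never" (three-category model) or category 1 (five-category model);
  prediction is the row-argmax of the class probabilities.
* **Cessation models** (former smokers, horizons 5/10/15 years) use fixed
  decision thresholds 0.8733, 0.7650 and 0.6397. These constants are part
  of the published procedure; their derivation is not stated, so they are
  treated as given and are overridable per call.

z-statistics are coefficient / standard error from the observed-information
covariance. Nested models are compared with the likelihood-ratio
chi-squared test (`chi2 = 2 (ll_full − ll_reduced)`, df = parameter-count
difference); for nested GLMs this is the same comparison as a deviance
table. Convergence uses the fitting library's IRLS/Newton iterations
(max 100); (quasi-)separation is detected post hoc as any |coefficient|
above 15 on the logit scale and surfaced as a warning with the fit flagged,
because near-perfect synthetic classifiers are a realistic hazard here.
Rank-deficient designs raise immediately.

## Marker selection

From the full candidate model, the marker with the smallest |z| is removed
(ties broken lexicographically by CpG id, making the elimination order a
pure function of the cohort), the reduced model is refitted, its apparent
AUC recorded, and consecutive models are compared by the LRT. This repeats
down to one marker, yielding the cumulative-AUC profile. The stop walks
removals in order and keeps the set in place immediately before the first
removal with p < alpha (default 0.05; the significance level is not stated
in the source procedure and is exposed in configuration). Covariates are
fitted but never eliminated. If no removal is significant the final
single-marker set is returned with a warning. A fit failure at the initial
full model raises; a failure at a later step is recorded as a flagged
terminal step and the trace halts.

## Evaluation and validation

AUC is the Mann–Whitney probability that a random positive outscores a
random negative with ties credited 1/2. Accuracy confidence intervals are
exact Clopper–Pearson binomial intervals. Multiclass reports are
one-vs-rest: sensitivity/specificity from the argmax confusion matrix, AUC
from the category's own probability column. Undefined ratios (empty
denominators) are reported as NaN with an explicit flag, never silently
dropped. Calibration uses equal-width probability bins with the accuracy
of the 0.5-threshold call per bin.

Fivefold cross-validation partitions the cohort at random into folds
differing in size by at most one (unstratified, matching the random-split
description of the source scheme; stratification is available as an
option), re-randomising up to 100 times if a training fold lacks a class.
Bootstrap optimism draws B resamples with replacement, refits on each,
scores the refit on its own resample (apparent) and on the original cohort
(test), and estimates optimism as mean(apparent − test); the adjusted AUC
subtracts this from the original fit's apparent AUC. Per-replicate random
streams are spawned deterministically from the master seed so B can be
reduced without changing earlier replicates.

## Synthetic cohort generator

Beta values are logit-normal: each sample's value at CpG j is
`expit(logit(m0_j) + shift_ij / (m0_j (1 − m0_j)) + shared_i + e_ij)`,
clipped to [1e-6, 1 − 1e-6]. Shifts are specified on the beta scale
(`smoker_delta`, fixed sign per CpG, |delta| ≥ 0.10 for informative
markers) and converted to the logit scale by the local derivative at the
baseline, which keeps the "≥ 10% beta difference" ascertainment criterion
directly expressible. Expected shifts:

* current smokers: `delta_j · g(PY_i)`, with the saturating dose response
  `g(PY) = PY / (PY + 10)` (no functional form is published; saturation in
  lifetime dose is the conventional choice);
* former smokers: `delta_j · exp(−t_i / tau_j)` with cessation time `t`
  and a per-CpG reversion timescale `tau` (6–19 years across the default
  panel, slowest for the AHRR markers);
* never smokers and decoy CpGs: zero.

Two realism extensions create the inter-CpG correlation real smoking
effects show: a per-smoker gamma susceptibility multiplier with mean 1
(default shape 4, CV 0.5) scaling all of a sample's shifts, and a shared
per-sample logit-scale noise component (default SD 0.25) added to every
CpG alongside idiosyncratic noise (default SD 0.35). Both can be disabled,
which reduces the model to an independent logit-normal per CpG — the form
used by the generator's analytical oracle tests.

Phenotypes: ages N(50, 12) clipped to [20, 80]; smoking histories drawn so
pack-years and cessation times follow from cigarettes/day (1–40), start
age (14–25) and stop age; plasma cotinine log-normal with medians
200 ng/mL (true current smokers) and 2 ng/mL (others); three cell-type
proportions (granulocyte/lymphocyte/monocyte, Dirichlet (30, 15, 5))
independent of smoking; 5% of true current smokers self-report "never"
(misreporting), with their smoking-history fields blanked. The defaults
use 3764 participants with class mix 12.4% current / 45.3% former / 42.3%
never — the sizes and composition of the modelled study. The generator can
also plant missing statuses, missing betas and beta outliers (recorded in
the truth table) to exercise the exclusion rules.

Child cohorts are all never-smokers whose methylation carries an
attenuated current-smoker shift according to prenatal exposure (sustained
maternal smoking, default attenuation 0.5; stopped-when-aware 0.15;
passive 0.0) and, for cord blood, a per-CpG additive logit offset for the
tissue difference. The default maternal exposure prevalences (14.5%
sustained, 9% stopped, 25% passive) follow a birth-cohort setting.

The default operating point gives an apparent binary AUC near 0.83 at
n = 3764 — somewhat below the ~0.90 of the modelled study — because the
generator's recently quit former smokers retain near-full methylation
shifts and are genuine hard negatives. What the generator does not emulate:
probe-level array artefacts, batch effects, cell-composition confounding
(cell proportions are independent of smoking by construction, so
covariate-augmentation tests are null by design), genetic effects, and
real inter-individual reversion-rate variation. Passing tests therefore
demonstrate the correctness of the procedure, not the field performance of
any marker panel.

## The marker-recovery study

The recovery study asks whether backward elimination plus the chi-squared
stop retrieves 13 planted informative CpGs from among 7 decoys at
n = 3764. This question is only well-posed when each planted marker
carries *conditionally* independent information: under the correlated
default generator, shifts are deterministic functions of a low-dimensional
latent (status, dose, cessation), so most markers are conditionally
redundant — the selection correctly discards them, exactly as a real
20-to-13 reduction discards redundant markers. The recovery study
therefore uses a dedicated frozen configuration
(`synthetic.recovery_study_params`): independent logit-normal noise
(SD 1.0 on the logit scale), current vs never smokers only (prevalence
12.4%), no misreporting. In that noise-limited regime classification is
bounded by measurement noise, every planted marker contributes measurable
conditional information, and the cumulative-AUC profile plateaus beyond
the selected size.

## Numerical choices and degenerate inputs

* Exclusion order: missing status, then missing betas, then per-CpG
  outliers outside mean ± 4 SD with moments computed once on the
  post-missingness set. One pass mirrors the single published exclusion
  step; it is *not* a strict fixed point for heavy-tailed betas —
  re-applying the filter recomputes tighter moments and may remove a few
  more samples (<1% in practice). Documented rather than iterated.
* Two boundary conventions coexist deliberately: the standalone history
  models code `value ≥ cutoff` as 1, while the five-category coding puts
  former smokers with cessation ≤ 10 years in the recent-quit category;
  both are implemented exactly as printed.
* A zero EWAS delta has no direction and fails the sign-consistency
  criterion; the magnitude criterion is inclusive at 0.10.
* `chisq_stop` with alpha = 1 stops at the first removal (any p < 1), so
  nothing is eliminated.
* AUC ties get 1/2 credit; positive calls are strictly-greater-than the
  threshold; identical nested models give chi-squared 0 on 0 df with p = 1.
* Beta clipping epsilon 1e-6; GLM log-likelihood tolerance 1e-8, max 100
  iterations; separation threshold |coef| > 15.

## Problem sizes used by the test suite and acceptance script

Simulation sizes were chosen to make each check statistically decisive at
interactive cost: recovery studies run 20 seeds (tests) or 5 seeds
(acceptance script) at n = 3764; bootstrap studies use B = 200 (small-n
overfitting at n = 200 with 13 predictors; vanishing optimism at
n = 20 000 with 2 predictors); null calibrations use n = 1000 cohorts and
3-standard-error bands from the Mann–Whitney null variance. The
printed-count reference fixtures (the 488-participant cotinine comparison,
the child call counts, the reported optimism pair) are exact arithmetic
and independent of the seed.

## Known limitations

* The headline synthetic AUCs characterise the generator, not any real
  cohort; external validation is out of scope by design.
* The cessation thresholds are constants with unstated provenance; if
  they encode class prevalences of the original data, refitting them on
  other data would be more appropriate than reusing the constants.
* Multiclass specificity is defined from the argmax confusion matrix
  (one-vs-rest); probability-thresholded per-class variants would differ.
* The bootstrap validates the fixed model specification; marker selection
  itself is not re-run inside the bootstrap, so selection optimism is not
  captured — same as the procedure being modelled.
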