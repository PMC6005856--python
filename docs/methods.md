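# Methods

## The frailty index and its scoring rules

The instrument has 31 items: 29 ordinal clinical items scored 0 / 0.5 / 1
(absent / mild / severe) and two measured items — body weight (g) and body
surface temperature (°C) — scored by the absolute z-distance from a
young-adult reference mean. The default z-bin map scores |z| ≤ 1 as 0 and
adds 0.25 per further SD up to 1 (edges 1, 2, 3, 4 SD; a z exactly on an
edge falls in the lower bin). The published instrument states the
SD-scoring principle but not the bin table, so the map is a configurable
catalog property; the default was chosen to give graded sub-unit scores
consistent with counting standard deviations. The FI is the mean item
score over items actually assessed: missing items leave both numerator and
denominator (standard deficit-accumulation practice). The shipped catalog
names the 29 ordinal items of the widely used mouse clinical frailty
instrument grouped by body system; item semantics never enter any
computation, so labs can substitute their own catalog YAML. The weight and
temperature reference statistics in the default catalog (31 ± 3 g,
36.5 ± 0.5 °C) are placeholders consumed by the simulator; real analyses
must supply lab-specific values.

Frailty strata use the clinical cutoff FI ≥ 0.21 (high) vs < 0.21 (low).

## Trajectory model and estimation

Expected FI follows an exponential trajectory with a submaximal ceiling:

    f(age) = min( f0 · exp(m · age/10), f_ceiling ),   f_ceiling = 0.70.

The rate of deficit accumulation is estimated by OLS of ln FI on age/10
(`fit_loglinear`), with FI = 0 floored at 1/62 before the log — half the
smallest whole-deficit contribution 1/31; the floor is configurable and is
shared between the simulator calibration and the analysis so the two stay
self-consistent. Slopes are reported per 10 days of age: per-day slopes of
the published magnitude (0.02–0.035) would imply e²⁴-fold growth over a
lifespan and per-month slopes would be far too small, so the 10-day unit is
the only dimensionally consistent reading, and it reproduces realistic FI
ranges.

Group comparison of rates (`compare_slopes`) fits
`ln FI ~ group + age/10 + group:age/10` and tests the interaction block by
extra-sum-of-squares F against the common-slope model (the ANCOVA
homogeneity-of-slopes test); per-group slopes from this model equal the
separately fitted slopes. Pairwise slope contrasts are Bonferroni-adjusted.

Age-band summaries use half-open bands [0, 300), [300, 600), [600, ∞) days
(the half-open convention resolves the ambiguity of "300–600" at the
edges). Factorial effects of sex, genotype and age band are tested with
Type III sums of squares under sum-to-zero contrasts — the convention of
the mainstream point-and-click statistics packages this kind of study is
analysed with — verified in the tests against a brute-force
model-comparison oracle; interaction terms containing empty design cells
are dropped with a warning because their Type III hypotheses are not
estimable. Bonferroni-adjusted cell-mean contrasts are available as post
hocs.

## Survival analysis

Kaplan–Meier estimation and the k-sample log-rank test are implemented
from their defining sums rather than delegated to a library (an
independent survival library serves as a test oracle only). At tied times
deaths are processed before censorings, the standard convention. The
log-rank statistic uses per-event-time hypergeometric expectations and
variances; the quadratic form over k−1 groups is referred to χ²(k−1).
Pairwise tests report raw and Bonferroni-adjusted p side by side, since
published pairwise survival comparisons often leave the adjustment
unstated. A permutation p-value (exhaustive over label arrangements when
their number is ≤ 200,000, else Monte Carlo with an add-one correction) is
available for small samples where the χ² approximation is doubtful.

Two clocks are exposed: age at death/censoring (origin at birth, no
delayed entry — group curves are conventionally plotted this way even
though assessment happens mid-life), and days post assessment with low/high
FI strata. Mice with unknown vital status are kept for frailty analyses
and excluded from survival, with exclusion counts logged. A mouse whose
follow-up ends on its assessment day gets a half-day survival credit so
times stay positive.

## The cohort simulator

The generator emulates a cross-sectional design: one assessment per mouse
at an age drawn uniformly on the group's integer age window, then follow-up
to death or censoring.

**Item noise.** Given f = f(age), each ordinal item scores
0.5·(B₁+B₂) with B₁,B₂ ~ Bernoulli(f) (support {0, 0.5, 1}); each measured
item scores 0.25·Binomial(4, f), and its raw measurement is placed
uniformly inside the |z| bin that maps back to the drawn score with a
random sign, so re-scoring a simulated assessment reproduces the drawn FI
exactly. Consequently E[FI | age] = f(age) with no approximation.

**Mortality.** Death times follow the hazard

    h(t) = λ₀ · exp(γ·t) · exp(β · f(t)),

a Gompertz baseline scaled by current expected frailty, discretised to
daily death probabilities 1 − exp(−h(u+½)) and sampled by inverse
transform on the discrete survival curve, conditional on survival to the
assessment age (left truncation, chosen over rejection resampling for
unbiasedness and speed). The free shape defaults are γ = 0.005/day
(mortality-rate doubling ≈ 139 days, demographically plausible for
laboratory mice) and β = 4 (hazard ratio ≈ 2.3 between FI 0 and the 0.21
cutoff). Censoring occurs with group-specific probability at a uniform day
between assessment and death; a further group-specific fraction of mice
loses vital status entirely ("unknown"), mirroring real husbandry
bookkeeping.

**Calibration.** Each group is specified by three published targets —
regression slope, mean FI of mice assessed at 300–600 days, and mean
uncensored lifespan — plus fixed γ, β, ceiling and age window:

1. *Latent rate.* The log of a noisy FI is biased low, and more so at
   young ages where FI is small (Jensen curvature of ln, plus the floor on
   zero scores), so the OLS slope *over-recovers* the latent trajectory
   rate by 4–7% under the item-noise model above. The calibration
   therefore root-finds the latent m whose OLS *estimand* — computed
   exactly from the binomial FI distribution at every integer age in the
   window, with the shared floor — equals the target slope. Without this
   step the simulator would systematically mis-reproduce the quantity it
   is calibrated to.
2. *Intercept.* f0 follows analytically from the uniform-age band-mean
   integral of f0·exp(m·t/10) over [300, 600] (raw FI is unbiased, so no
   correction is needed here).
3. *Baseline hazard.* λ₀ is root-found so the exact mean of the discrete
   death process (Σₜ S(t), the same grid the sampler uses) equals the
   target mean lifespan.

The shipped targets are: slopes 0.023 / 0.035 / 0.020 / 0.031 per 10 days,
band means 0.15 / 0.21 / 0.12 / 0.10, mean lifespans 571.3 / 386.9 /
548.1 / 517.1 days, censoring 85.5 / 66.7 / 86.9 / 83.3% and unknown-status
fractions 9.5 / 5.7 / 7.7 / 12.9% for male WT / male TG / female WT /
female TG; assessment windows (30, 900) / (30, 560) / (30, 950) / (30, 870)
days, chosen so the uniform-age means match the published group means of
age at assessment. Calibration runs at import of `default_groups()` (a few
seconds, cached per process).

## What the simulator does and does not emulate

It reproduces: exponential FI growth at group-specific recoverable rates, a
submaximal FI ceiling, band-mean frailty levels, frailty-dependent
mortality with realistic group lifespan gaps, heavy censoring, and
unknown-status exclusions. It does **not** emulate: correlation between
items (real deficits cluster within systems; simulated items are
conditionally independent given age, so simulated ln FI–age correlations,
r ≈ 0.8–0.9, are tighter than the r ≈ 0.6–0.75 typical of real cohorts),
inter-rater variation, seasonal or batch effects, longitudinal repeated
measures (the design is strictly cross-sectional), or competing causes of
death. Passing the recovery suite therefore demonstrates correctness of
the estimators under the stated model, not robustness to these real-data
features.

## Numerical choices and degenerate inputs

* Survival horizon extends in powers of four until S < 10⁻¹² (cap 2²⁰
  days); mean-lifespan sums and sampling share the same grid, so the
  Monte-Carlo mean converges to the calibration oracle exactly.
* Root-finding uses Brent's method: latent rate bracketed at (0.3, 1.5)×
  target slope; log₁₀ λ₀ in (−9, −0.5); bracket failures raise a
  calibration error with the endpoint gaps.
* Zero age variance, < 3 assessments, all-missing assessments, zero-event
  log-rank inputs and overlapping bands raise typed errors rather than
  returning NaN; a constant response yields exact zero slopes/F statistics.
* The OLS slope CI uses the classic SE; under the simulator's
  heteroscedastic log-FI noise its empirical 95% coverage measures ≈ 93–96%
  at n = 500 (verified in the tests at 95 ± 3).

## Validation problem sizes

The test suite recovers slopes at n = 500 per cohort (150 replicates per
group for the unbiasedness/coverage check, 25 seeds for the acceptance
check), band means at n = 500, lifespans at n = 10⁴ draws against an exact
oracle, survival estimates against the reference library on 100 random
small datasets, permutation p on an 8-subject exhaustive fixture, and
power checks at 40–50 seeds. These sizes keep the whole suite under a
minute after the one-off calibration while leaving Monte-Carlo error well
below every asserted tolerance.
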