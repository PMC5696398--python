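# Methods

`broodsync` implements a complete analysis chain for quantifying avian
incubation behaviour from in-nest temperature loggers and relating it to
spring temperature cues and to hatching synchrony with a caterpillar food
peak.  This note records the models, the synthetic world behind the test
suite, the numerical choices, and the known limitations.

## The measurement model: nightly-calibrated threshold detection

An in-nest logger does not read egg temperature directly: conductivity,
burial and day-to-day movement shift its readings.  The detector therefore
recalibrates nightly.  Incubating birds sit through the night, so readings
from c. 19:00–24:00 that exceed the same-hour local ambient temperature by
more than 4 °C are taken as incubating temperatures; their minimum is the
nest-and-position-specific threshold for the following active day
(07:00–19:00).  Active-day readings strictly above the threshold count as
incubating; the day's *intensity* is the incubating fraction of the 36
twenty-minute active-day readings; and the *onset of full incubation* is
the first day with intensity ≥ 50%.  Each in-nest reading is paired with
the clock-hour mean of the nearest ambient logger (Euclidean distance on
projected coordinates; ties to the lexicographically smaller id).  Nests
qualify only if a clean non-incubating day (no nocturnal incubation,
intensity below the rule) falls strictly between logger placement and the
onset; otherwise the placement may have missed the start of incubation.

Conventions where the operational definition is ambiguous: "midnight" is
exclusive (a 00:00 reading belongs to the next day); temperature
comparisons at the threshold are strict (`>`), the 50% rule is inclusive
(`≥`); the onset is the literal first crossing with no persistence
requirement (`DetectionConfig.onset_fraction` exposes the rule); a day
whose preceding night has no data at all is flagged unclassifiable rather
than interpolated.

## Behaviour traits and their models

Per nest: relative onset = onset − clutch completion (completion =
initiation + clutch size − 1, one egg per day); duration = hatch − onset;
mean intensity = mean daily intensity from the onset to the day before
hatching (the hatch day is excluded — loggers come out of the nest then).
`relative_onset + duration = hatch − completion` holds identically.

The trait inter-relation models are a binomial GLM of intensity on
relative onset (with clutch size and initiation date) and an OLS of
duration on intensity, relative onset and clutch size.  The intensity GLM
is fitted on the aggregated per-nest counts (incubating slots, total
slots) rather than on the unweighted proportion: the counts carry the
per-nest information content.  Wald two-sided p-values throughout; no
multiplicity correction.

`max_alteration` summarises how far hatch date could move if onset and
duration varied independently over their observed ranges, against a
baseline of onset at completion with the expected duration:
advance = E[dur] − (onset_min + dur_min), delay = (onset_max + dur_max) −
E[dur].

## Sliding-window cue selection

Twelve windows: window 1 spans clutch initiation to the onset (the
nest-specific "laying period"); windows 2–11 extend the start 1–10 days
before initiation; window 12 (duration analysis only) spans onset to
hatch.  Within a window, four measures from the paired logger's daily
statistics: mean, mean daily minimum (MMin), mean daily maximum (MMax)
and mean daily range (Trange), each computed per calendar day from all
readings and then averaged over the window's (inclusive) days.

Candidates for relative onset: every window–measure variable in four
configurations (T; T + initiation; T × initiation; T + clutch) plus two
temperature-free nulls (initiation; initiation + clutch) — 178 linear
models.  Duration candidates add relative onset to every model (nulls
included) and the four window-12 measures in the temperature-only
configuration — 182 models.  Daily-intensity candidates are binomial
mixed models (below) of per-day incubating counts on incubation day and
one daily temperature variable in four configurations plus one null — 17
models.  Ranking is by maximum-likelihood AIC (the Gaussian AIC counts
the error variance as a parameter, matching R's `logLik.lm`); models
within 2 units of the best form the equivalence set; exact ties break by
(window, measure, configuration).  In the interaction configuration the
covariates are centred at their sample means so the temperature main
effect is the slope at the average initiation date; centring does not
change the fit or the AIC.

### The binomial mixed model

No maximum-likelihood binomial GLMM with AIC is available in the
installed Python stack (statsmodels' mixed binomial model is Bayesian),
so `broodsync.glmm` implements one: a single scalar random intercept
integrated out by *adaptive* Gauss–Hermite quadrature (nodes recentred at
each group's posterior mode and rescaled by its curvature — the lme4
`glmer(nAGQ=k)` approach), maximised by BFGS over the fixed effects and
log random-effect SD, with observed-information standard errors from a
central-difference Hessian.  Non-adaptive quadrature is not an option
here: one nest-day table contributes hundreds of Bernoulli trials per
nest, so the integrand is far narrower than the prior.  The test suite
cross-checks the fit against `lme4::glmer` (fixed effects, random-effect
SD, and the log-likelihood after aligning lme4's saturated-model-relative
binomial scale).

Marginal effects of incubation day and temperature are reported on the
proportion scale at the sample-mean covariates with the random effect at
zero: p(1−p)·(∂η/∂x).

## Synchrony and fitness

Raw synchrony = hatch date − the year's caterpillar peak (median descent
date).  A +13-day offset (configurable) shifts the index so 0 marks the
optimum implied by the long-term fitness analysis; squaring gives an
unsigned distance.  Null expectations: completion + 14 days (long-term
null, fixed incubation period); completion + observed duration (no onset
adjustment); completion + relative onset + the focal year's mean duration
of 12 days (no duration adjustment).  The focal-year no-onset comparison
uses the unsquared index; the long-term comparison squares it.  The two
focal-year variance comparisons are two-sided F tests oriented
var(null)/var(observed); the annual-variance comparison of initiation,
completion and hatch dates is a linear model of per-year variances on
event type with year as a categorical effect.  Reproductive success is a
Poisson log-link GLM of fledglings on hatching synchrony, its square,
clutch size, initiation synchrony, its square and woodland section; the
vertex −b₁/(2b₂) of the hatch-synchrony quadratic is reported as the
implied optimum only when b₂ < 0.  (The vertex of the published point
estimates is ≈ −22 days; the fixed +13 offset is the number the source
analysis carried, and the two are reported separately, asserting
neither.)

## The synthetic world

The generator is the test bed: every downstream stage is validated by
parameter and selection recovery against known truth.

**Ambient field.** Each logger's temperature is a seasonal trend
(0.06 °C/day around a 10 °C mid-season base) plus a smooth spatial field
(SD 0.7 °C over a 3 km woodland), a shared AR(1) day-to-day anomaly
(SD 1.0, ρ = 0.3), a logger-specific daily anomaly (SD 1.3 °C), and a
diurnal sinusoid (daily maximum 15:00, minimum 03:00) whose amplitude
varies by day and logger (8 ± ~1.5 °C, truncated to 4–10 °C), plus
0.2 °C instrument noise.  The logger-level daily
variation is what makes a *single season* informative about which window
and measure drive behaviour: with purely woodland-wide weather, the
effective sample for discriminating adjacent windows is the number of
distinct laying dates, not the number of nests.  The magnitudes were
chosen so the across-nest spread of laying-period mean temperature
(~0.6–0.9 °C) is consistent with the published effect size and the
observed onset range.

**Breeding schedule.** Initiation ~ N(day 115, 5²) rounded; clutch size
8.5 − 0.25·(initiation − mean) + noise, truncated to 5–13 eggs, so
completion dates are less variable than initiation dates.

**Onset cue.** Relative onset = 4.5 − 5.03·(T − T̄) + 0.3·(T − T̄)·
(initiation − mean) + ε, ε ~ N(0, 1.5²), rounded and truncated to
[−3, 12] by resampling (equivalently, a per-nest truncated-normal
residual), where T is the mean daily temperature from 7 days before
laying to the *expected* onset (completion + 4 days).  Using the expected
rather than realized endpoint keeps the cue exogenous; the measured
window-8 variable is its closest observable proxy.  The cue is centred on
the realized cohort means: the published slope is a within-season
contrast, and a shared warm spring should advance the cohort without
piling it against the truncation bounds.  Truncation to the observed
range attenuates the recovered slope a few percent; the recovery test
tolerance is the published model's standard error.

**Duration.** 11.5 − 0.45·(relative onset − 4.5) + N(0, 1.5²), rounded,
truncated to [7, 19].  Temperature-independent by construction, so the
duration candidate scan should prefer the nulls (see Limitations).

**Daily intensity.** logit p = a + b_day·day + b_T·Tmax + b_int·day·Tmax
+ u_nest + e_day, with u ~ N(0, 0.35²), e ~ N(0, 0.25²), b_int = −0.008,
and (a, b_day, b_T) calibrated so the proportion-scale marginals at the
reference covariates (day 6.25 = the expected mean incubation day,
climatological Tmax) equal 5%/day and 2%/°C at a 70% mean intensity.
Counts are round(p·36) slots.  In the trace world each nest's ramp is
shifted along the day axis so it crosses the 50% rule exactly on the
cue-determined onset (the measured onset *is* the crossing), preceded by
a sub-50% transition of growing daytime bouts capped at ~1/3 of the
active day.  The shift is a per-nest constant, leaving the within-nest
slopes the mixed model estimates untouched.

A structural fact worth stating plainly: the published triplet — onset
day ≥ 50% by definition, a ~5%/day marginal at mid-incubation under a
logit-linear day term, and a 70% mean intensity — cannot hold
simultaneously (a logit-linear ramp with that marginal must start near
45% on day 1).  The generator therefore anchors the ramp at the onset
rule and accepts a trace-world mean intensity of ~0.72–0.75; and the
marginal-recovery study draws nest-day counts directly from the latent
model (`generate_intensity_counts`), where the GLMM recovers ~4.9%/day
and ~1.9%/°C.  Day-indexing from the detected crossing instead compresses
the day gradient to ~3.8%/day — a real feature of the measurement, not a
bug.

**Traces.** Incubated slots read a fixed contrast (default 10 °C, always
> the 4 °C rule) above the *daily ambient level* of the paired logger —
the sitting bird buffers the diurnal cycle — with a slow warming ramp
over each 19:00-to-19:00 stint (1.5 °C/cycle) and a 0.3 °C nocturnal
depression; the night preceding an active day shares that day's level.
This makes the nightly recalibration exact on noise-free traces by
construction, which a naive "instantaneous ambient + contrast" model
cannot achieve (a cold morning after a warm night would defeat the
threshold).  Non-incubated slots track instantaneous local ambient.
Nocturnal incubation ramps to full over the three nights from seven
nights before completion; hot slots fill contiguously from the start of
each period.  Logger placement precedes the intensity ramp by ≥ 2 days so
the clean-day exclusion rule is satisfiable.

**Fitness and synchrony.** Fledglings ~ Poisson with log-linear
coefficients (−0.074, −0.0017, 0.05, 0.036, −0.00012) on raw hatching
synchrony, its square, clutch size, initiation synchrony and its square,
plus small section effects; counts are not capped at clutch size so the
surface-recovery test is unbiased.  The focal-year caterpillar peak is
placed 13 days after the mean hatch date.  The long-series mode
(default 1960–2014, 212 nests/year) generates records and caterpillar
dates only: annual laying tracks the peak with 3-day error, and the
post-completion interval removes 30% of each nest's remaining timing
error — producing var(hatch) < var(completion) < var(initiation) and a
significant observed-vs-null synchrony improvement.

## Problem sizes

The default test and acceptance runs use: 93 nests (the field sample
size) for trace-level recovery; 50 seeds × 500 nests (ground-truth
onsets feeding the candidate stage) for the window-selection study, under
its strong-cue/low-noise condition (onset residual SD 0.5); 50 seeds ×
93 nests for the duration null scan; ~5 replicate seeds for the reported
slope and marginal-effect estimates; and 1000 replicates for the F-test
calibration.

## Known limitations

* The duration candidate scan prefers some temperature model over the
  nulls by ≥ 2 AIC in most seeds even when duration is generated with no
  temperature dependence: the best of ~180 correlated candidates
  over-fits by 3–6 AIC (winner's curse).  A null-inside-the-equivalence-
  set rate of ≥ 80% is not achievable with this candidate count; judging
  the preferred model's temperature term by its Wald p-value (as the
  source analysis did) gives the expected null result.
* Windows that end at the detected onset mechanically encode the onset
  through their span; with a single shared weather realization this lets
  neighbouring windows compete with the true cue.  The selection study
  documents the conditions under which the true window is reliably
  identified.
* The generator has no egg-cooling biophysics, no logger loss or
  abandonment, no hatching asynchrony within clutches, and spatial
  structure limited to a smooth field plus independent daily microclimate
  — passing tests show the pipeline recovers what it measures, not that
  real nests behave this simply.
* Fledgling counts can exceed clutch size (uncapped Poisson), a
  deliberate unrealism for unbiased surface recovery.
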