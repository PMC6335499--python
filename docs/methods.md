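# Methods

## Cohort model

One record per subject: diagnosis date, age at diagnosis, exit date
(death, loss to follow-up, or administrative study end), vital status and
time-fixed covariates.  Subjects are left-truncated at their entry age —
they contribute no exposure below the age at diagnosis — and follow-up is
measured in exact real years, converting calendar day counts with
365.2425 days/year.  No integer-age rounding anywhere: rounding creates
band-edge artifacts at exactly the ages the method partitions on.

Eligibility requires a known diagnosis date strictly before the death
date, and an age at diagnosis of at least 20 (configurable).  Exclusions
are tallied per reason with a fixed precedence
(`missing_diagnosis_date > diagnosis_not_before_death > under_age_minimum
> malformed_record`) so audit reports are deterministic.  A censored
record with zero-length follow-up is retained (with a warning): it
contributes zero person-years and no information, but excluding it would
silently change denominators elsewhere (counts by covariate, medians).

## Imputation

Missing sex and age are filled by a *single seeded hot-deck*: sex is drawn
from the observed sex distribution within the same transmission-route
category (falling back to the whole cohort), age from the observed age
distribution within the same — possibly just-imputed — sex.  Imputation
runs before eligibility filtering, so age eligibility is judged on imputed
ages.  If either variable is missing in more than 10% of records the
imputer aborts with the measured fraction: single imputation understates
uncertainty, and that understatement stops being ignorable well before
10%.  This is a deliberate simplification relative to EM-based multiple
imputation; the between-imputation variance component is a documented
omission, not an oversight.

## Exposure

Age bands are half-open `[start, start + n)`; a death at exactly age 25.0
belongs to the 25–29 band.  Person-years are computed by exact interval
intersection of `[entry_age, exit_age)` with the bands, so per-record
conservation (`Σ_band py = exit_age − entry_age`) holds to floating-point
precision, and the exposure of a cohort equals the band-wise sum over any
partition of it.  An independent day-grid accumulator
(`brute_force_person_years`) walks the same interval one day at a time and
must agree to better than 1/365 person-year per band; it exists purely as
an oracle and is deliberately naive.

## Life table

Chiang's abridged construction, with these concrete choices:

* **Rate → probability.** `q = n·m / (1 + n·(1−a)·m)`, clamped at 1.
  `a = 0.5` for all closed bands by default (configurable per band); with
  no information on within-band death timing, the midpoint assumption is
  the standard default.
* **Terminal band.** The open band is treated as exponential:
  `q_w = 1`, `L_w = l_w / m_w`, `e_w = 1/m_w`.  A fixed terminal
  expectancy (`terminal_e_fixed`) can be supplied instead to emulate
  conventions that pin the open-band value.
* **Variance.** `S²(p_j) = q_j² p_j / D_j`, zero when `D_j = 0` (the
  continuous limit: no deaths means `q_j = 0` and the term vanishes, so no
  0/0).  The accumulation
  `Var(e_i) = l_i^{-2} Σ_{j=i}^{w-1} l_j² [(1−a_j)n_j + e_{j+1}]² S²(p_j)`
  is extended with a terminal term `(l_w/l_i)²·Var(e_w)`,
  `Var(e_w) = 1/(m_w² D_w)` by the delta method on a Poisson death count.
  Without it the SE is understated at ages near the open band; with the
  fixed-terminal convention the term is zero.  Confidence intervals are
  `e ± 1.96·SE` at the 95% level (the conventional rounded multiplier,
  matching how such intervals are reported in practice; other levels use
  the exact normal quantile).
* **Degenerate inputs.**  If some `q` clamps to 1 the synthetic cohort is
  extinct below that band; subsequent rows are inert (zero flow, NaN `e`)
  and do not constrain the input — so "everyone dies in the first band"
  yields `e_1 = a·n` without demanding impossible data for bands nobody
  reaches.  A closed band that *is* reached but has zero person-years is a
  hard error (merge bands); a reached terminal band with zero deaths is a
  hard error too (`1/m_w` undefined; extend the open band).
* **Radix.** 100,000 by default; every reported quantity (`m, q, e, SE,
  CI`) is invariant to it, which is tested.

## Comparisons, trends, YLL, correlations

Strata are time-fixed at diagnosis (treatment ever received, baseline
biomarker band, diagnosis period); missing covariate values form an
`unknown` stratum so strata always partition the cohort.  This ignores
time-varying exposure — the usual immortal-time caveat for "ever treated"
groupings applies.  Group contrasts use a two-sample z-test on the
independent Chiang estimates, `z = (e_1 − e_2)/√(SE_1² + SE_2²)`; the
same contrast can be computed from published summaries by recovering SEs
from CI half-widths.  Period trends stratify by the period containing the
*diagnosis* date (the alternative — period life tables cross-classifying
attained calendar time — is out of scope).  Years of life lost weight each
death by a reference remaining life expectancy at the band of the age at
death; the bundled default reference is the Iranian general-population
2015 table, and any per-band table can be supplied.  Ecological
correlations are plain Pearson r across group aggregates.

## Synthetic cohorts

The generator emulates a registry cohort: staggered diagnoses uniform
over 1986–2016, entry ages from a banded mixture concentrated at 20–44
(with a thin tail to 75), piecewise-constant baseline age hazards
multiplied by per-subject covariate hazard ratios (defaults: 84% male,
female hazard ratio 0.55, treatment 34%/HR 0.35, TB 4%/HR 2.0),
exponential loss to follow-up (0.02/yr), administrative censoring at
2016-12-30, and 3% missingness of sex and age.  The default baseline
hazards rise with age and end at 0.4/yr in the open band (≈2.5 years of
remaining life there).  Death ages are drawn by inverse-transform sampling
of the piecewise-exponential cumulative hazard; one `numpy` generator
seeded from the config drives every draw, so a config reproduces its
cohort byte for byte.  Exit dates are rounded to whole days, as a registry
would store them (a ≤0.5-day perturbation per record).

Because the generating law is piecewise-exponential on the same bands the
estimator uses, `true_life_expectancy` integrates the survival curve in
closed form, giving an exact truth for bias and coverage checks.  What the
generator does **not** emulate: under-registration and death
misclassification, informative censoring, time-varying treatment,
calendar-period improvements in survival, record-linkage noise, or
heaped/integer ages.  Passing validation therefore demonstrates that the
estimator and its variance are correct *under the stated sampling model*,
not that any particular registry's estimates are unbiased.

## Validation problem sizes

Point recovery uses one cohort of 50,000 subjects (constant hazard
0.04/yr, and a piecewise 0.1/0.05 law), where the Monte-Carlo error is
well inside the 2% check band.  Coverage and SE calibration use 500
replicate cohorts of 5,000; the empirical 95%-CI coverage must land in
[92.5%, 97.5%] and the mean formula SE within 15% of the empirical SD of
the estimate.  The oracle comparison uses 1,000 random records.  These
sizes keep the whole validation suite comfortably fast while leaving each
check statistically sharp.

## Known limitations

* Chiang's `q` conversion is exact for linear within-band deaths, not for
  exponential ones; with `a = 0.5` the first-band error for a constant
  hazard is below 2% up to roughly 0.08–0.1/yr and essentially cancels
  over a full table at moderate rates.  Steeply rising hazards within a
  band would need band-specific `a`.
* Single hot-deck imputation ignores between-imputation variance.
* The two-sample z-test assumes independent strata; it is anti-
  conservative for overlapping or matched groups.
* All covariates are treated as fixed at diagnosis.
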