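# cohortlife

Abridged (Chiang) life tables, life expectancy and its confidence
intervals, computed directly from individual-level cohort follow-up
records — the kind of one-row-per-person extract a disease registry
produces (date of diagnosis, date of death or censoring, vital status,
sex, and clinical covariates).

It is written for epidemiologists analysing retrospective cohorts such as
national HIV registries, where the question is "how many further years can
a patient diagnosed at age *x* expect to live?", stratified by treatment,
co-infection, stage, region or calendar period.

## The method

Follow-up runs from diagnosis (left truncation at the entry age) to death,
loss to follow-up, or the administrative study end.  Each person's
follow-up is split across 5-year age bands 20–24 … 60–64 plus an open 65+
band (a Lexis expansion), giving deaths `D_j` and person-years `PY_j` per
band.  The life table then follows Chiang's construction:

* age-specific death rate `m_j = D_j / PY_j`;
* probability of dying in the band
  `q_j = n_j m_j / (1 + n_j (1 − a_j) m_j)`, clamped at 1, with `n_j` the
  band width and `a_j` (default 0.5) the average fraction of the band
  lived by those who die in it; the open band has `q_w = 1`;
* a synthetic cohort `l_1 = radix`, `l_{j+1} = l_j (1 − q_j)`,
  `L_j = n_j (l_{j+1} + a_j l_j q_j)`, terminal `L_w = l_w / m_w`,
  `T_j = Σ_{k≥j} L_k`, and remaining life expectancy `e_j = T_j / l_j`;
* sampling variance
  `S²(p_j) = q_j² p_j / D_j` and
  `Var(e_i) = l_i^{-2} Σ_{j≥i} l_j² [(1−a_j) n_j + e_{j+1}]² S²(p_j)`,
  plus a delta-method term `(l_w/l_i)² / (m_w² D_w)` for the open band;
  95% limits are `e ± 1.96·SE`.

Around this core the package provides eligibility filtering with an audit
trail, seeded hot-deck imputation of missing sex/age, stratified tables,
two-sample z contrasts, calendar-period trends, years-of-life-lost
tallies against a reference table, ecological (group-level) correlations —
and a synthetic-cohort generator with piecewise-exponential mortality
whose life expectancy is known in closed form, so the whole pipeline is
validated against analytic truth.

## Worked example

```sh
cohortlife simulate --n 10000 --seed 7 --out demo.csv
cohortlife build --cohort demo.csv --out demo_out \
    --stratify-by art --period-breaks 1986,2001,2011,2017
```

The build step prints (abridged):

```
records analyzed: 10000
total person-years: 90230.4
median follow-up (years): 7.3
deaths: 3945
crude mortality rate: 43.7 per 1,000 person-years

life expectancy at 20 (band 20-24): 23.3 years (95% CI, 22.4 to 24.2)

stratified by art:
  no: e=19.4 (95% CI, 18.4 to 20.4)
  yes: e=33.2 (95% CI, 31.6 to 34.8)

period trend (by diagnosis period):
  1986-2000: e=24.3 (95% CI, 23.2 to 25.4)
  2001-2010: e=22.9 (95% CI, 21.2 to 24.5)
  2011-2016: e=21.3 (95% CI, 18.5 to 24.2)
```

A patient from this simulated registry diagnosed at age 20 can expect
23.3 further years of life; treated patients gain roughly 14 years over
untreated ones (the generator's treatment hazard ratio is 0.35).  The
period estimates are statistically flat, as they should be: this fixture's
hazards do not change over calendar time.  `demo_out/` holds the full
life-table CSVs, a summary CSV, the exclusion report and the text report.

The same works from Python:

```python
from cohortlife import (SyntheticConfig, simulate_cohort, filter_eligible,
                        aggregate_exposure, build_life_table)

cohort, _ = filter_eligible(simulate_cohort(SyntheticConfig(n=10_000, seed=7)))
lt = build_life_table(aggregate_exposure(cohort))
print(lt.e0, lt.ci_low[0], lt.ci_high[0])
```

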