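# casecross

Time-stratified case-crossover analysis of daily ambient temperature and
fatal police violence.

`casecross` is a tested, reusable implementation of the statistical pipeline
used to ask: *are fatal police encounters more likely on unusually hot (or
cold) days, and does neighborhood structural deprivation modify that
association?*  It is aimed at environmental-epidemiology and urban-health
researchers working with point-located event records (e.g., Mapping Police
Violence exports), daily gridded weather (PRISM-style 4-km cells), and
census-tract ACS tables.

## The design and model

**Case-crossover matching.**  Each event day (the *case day*) is compared
with its own *control days*: every other date in the same calendar month and
year falling on the same day of the week, at the same grid cell.  A case on
Thursday, July 6 is matched to the other Thursdays of that July.  This
time-stratified referent scheme yields 3–4 controls per case, excludes no
cases, and conditions out every confounder that is constant within a
location-month — including all characteristics of the person involved.

**Conditional logistic regression.**  With m<sub>s</sub> control days in
stratum *s* and linear predictor η = **x**′β, each stratum contributes the
probability that its case day is the event day:

    ℓ(β) = Σ_s [ η_case(s) − log Σ_j exp(η_j(s)) ]

maximized by guarded Newton–Raphson (analytic gradient and Hessian,
step-halving, separation detection).  The temperature term DT_max (daily
maximum, °C) enters either linearly or as a natural cubic spline with 2–4
degrees of freedom; the parameterization is chosen by AIC.  Odds ratios are
anchored at a referent temperature (23.5 °C for DT_max, 17.1 °C for the
DT_mean sensitivity analysis) and reported at the 5th…99th percentiles of
the case-day temperature distribution with delta-method 95% CIs.  Models
adjust for US federal holidays and, optionally, a three-level rainfall
category (0 mm / below the 2.68 mm mean / at or above it).

**Effect modification.**  Census tracts are scored with the Index of
Concentration at the Extremes, ICE = (A − P)/T, for four dimensions
(income, racialized income, homeownership, education), cut into national
terciles (tercile 1 = most deprived), and the model is refit within each
tercile; cross-tercile heterogeneity of the log-ORs at the extreme
percentiles is tested with Cochran's Q.

**Synthetic data.**  `casecross.synthetic` generates seeded weather, event,
and tract tables from a known ground truth (log-linear temperature effect on
a per-cell-day Bernoulli hazard), so the entire pipeline is testable —
parameter recovery, CI coverage, type-I error — without any external data.

## Worked example

```python
import datetime as dt
from casecross import (SyntheticConfig, generate_all, build_strata, link,
                       us_federal_holidays, ModelSpec, select_parameterization,
                       fit_model, exposure_percentiles, or_table)

cfg = SyntheticConfig(seed=1, n_cells=120, n_tracts=300,
                      date_start=dt.date(2021, 1, 1), date_end=dt.date(2022, 12, 31),
                      beta_temp=0.006, baseline_rate=0.04)
data = generate_all(cfg)
strata = build_strata(data["events"])
linked = link(strata, data["weather"], us_federal_holidays(range(2021, 2023)))

candidates = [ModelSpec(covariates=("holiday",))] + [
    ModelSpec(form="spline", df=df, covariates=("holiday",)) for df in (2, 3, 4)]
best, fits = select_parameterization(linked, candidates)
res, design = fit_model(linked, best)
print(f"events: {len(data['events'])}, selected: {best.label()}")
print(f"beta_dtmax = {res.beta[0]:.5f} per degC (SE {res.se[0]:.5f}), truth 0.006")
pct = exposure_percentiles(linked.loc[linked.role == "case", "dtmax_c"])
print(or_table(res, design, pct)[["percentile", "temp_c", "or", "ci_low", "ci_high"]]
      .round(3).to_string(index=False))
```

prints

```
events: 3326, selected: linear
beta_dtmax = 0.01564 per degC (SE 0.00599), truth 0.006
 percentile  temp_c    or  ci_low  ci_high
       0.05  -0.073 0.692   0.524    0.912
       0.10   2.913 0.725   0.569    0.923
       0.25   8.622 0.792   0.665    0.944
       0.50  16.668 0.899   0.829    0.974
       0.75  24.195 1.011   1.003    1.019
       0.90  29.978 1.107   1.026    1.194
       0.95  32.829 1.157   1.037    1.291
       0.99  37.337 1.242   1.055    1.461
```

AIC picks the linear term (the generative truth), and the fitted slope —
0.0156 per °C with standard error 0.0060 — is within sampling error of the
true 0.006.  Odds ratios below 1 at cold percentiles and above 1 at hot
percentiles are the log-linear curve anchored at 1 at the 23.5 °C referent:
on this draw, a day at the 99th percentile of case-day temperature carries
1.24 times the odds of the referent day.

The same workflow runs from the shell:

```bash
casecross all --outdir run1 --seed 1      # synthetic end-to-end
casecross all --config my_study.yaml      # events/weather/tracts from CSV
```

writing `strata.csv`, `linked.csv`, `fit.json`, `or_table.csv`, `curve.csv`,
`ice.csv`, `tercile_summary.csv`, `stratified.csv`, `qtests.csv`, and
`run_report.json` (stage timings, counts, selected parameterization) into
the output directory.  Identical config + seed reproduces every file
byte-for-byte.

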