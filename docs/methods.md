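# Methods

This note documents the statistical machinery in `casecross`, the choices
made where conventions genuinely differ, and what the synthetic-data tests
do and do not establish about real data.

## Matched-stratum construction

The time-stratified case-crossover referent scheme defines, for a case on
date *d*, the control set as every other date in the same calendar month and
year with the same weekday.  The scheme partitions the month's same-weekday
dates (4 or 5 of them), is symmetric (if *d₂* is a control for *d₁* then
*d₁* is a control for *d₂*), and never drops a case.  Both properties are
asserted over random dates against a brute-force calendar scan.

"Same location" is operationalized as the same weather grid cell: the sole
purpose of matching on location is that case and control days share one
weather series, and exposure is constant within a cell-day.  Civil dates are
taken at face value (no time-zone arithmetic).  Two events on the same
cell-day yield two separate strata — each case conditions its own stratum.

## Exposure linkage

Events carry a grid cell either from generation (synthetic data) or by
nearest cell center in great-circle (haversine) distance, ties broken toward
the smallest cell id.  Linkage copies temperatures bit-exactly; the pipeline
reads CSVs with round-trip float parsing so the file interface preserves
this.  A stratum missing weather on any of its days is dropped whole, with a
logged count: a partial stratum cannot contribute to the conditional
likelihood.

Rainfall is categorized 0 (dry), 1 (0 < p < mean), 2 (p ≥ mean) with the
mean fixed at 2.68 mm as a configuration constant rather than recomputed per
dataset, for reproducibility of the cut-off.  The boundary p = mean goes to
category 2 so category 1 stays strictly interior.  Holidays default to the
11 US federal holidays with observed-date shifting (Juneteenth from 2021);
any list can be supplied as a file of ISO dates.

## Conditional logistic regression

The conditional log-likelihood, gradient, and Hessian are exact and
analytic; strata are rendered to a dense stacked design (stratum sizes are
at most 5 rows, so density costs nothing).  Newton–Raphson starts at β = 0
with step-halving (at most 30 halvings per step); since the conditional
log-likelihood is concave, this is globally convergent whenever a finite
maximum exists.  Convergence is declared at |Δℓ| < 1e−10 or max-norm of the
gradient below 1e−8, within 50 iterations.  Any coefficient exceeding 50 in
absolute value during iteration is reported as separation, naming the
offending column — an odds ratio of e⁵⁰ per unit has no finite-data meaning.
The covariance is the inverse negative Hessian at the optimum.

Columns constant within every stratum (an intercept, anything varying only
between months or cells) are non-identifiable and rejected before fitting.
Strata with no control rows are dropped with a warning.  The exposure is
centered at the referent before basis construction; the conditional
likelihood is translation-invariant, so this only improves conditioning.

The implementation is cross-checked in the test suite against statsmodels'
`ConditionalLogit` (agreement below 1e−6 in the coefficients) and against a
derivative-free Nelder–Mead search of the same likelihood on small random
datasets; statsmodels is never on the runtime path.

## Spline parameterization and AIC selection

The natural cubic spline basis places boundary knots at the min/max of the
observed exposure and df−1 interior knots at equally spaced quantiles
(df ∈ {2, 3, 4}); the truncated-power natural construction makes the curve
exactly linear beyond the boundary knots.  Quantile knot placement is this
package's documented convention — reasonable alternatives exist, and the
fitted curve (not the coefficients) is the meaningful object; a test
verifies that an independently constructed basis spanning the same function
space reaches the identical maximized log-likelihood.

Candidate parameterizations (linear, spline 2–4, covariates held fixed
across candidates) are compared by AIC = −2ℓ + 2p over converged fits; ties
within 1e−9 go to fewer parameters, then linear over spline.  On
linear-truth synthetic data AIC selects the linear term in the majority of
replicates; it cannot do so always — a spline's extra degree of freedom
clears the 2-unit AIC penalty with roughly the probability that a χ²₁
exceeds 2.

## Odds-ratio contrasts and heterogeneity

For temperature *t* and referent *r*, the contrast is c = basis(t) −
basis(r), zero-padded over covariate columns; log OR = c′β̂ with
delta-method standard error √(c′Σ̂c) and Wald 95% CIs (z = 1.96).  At the
referent the OR is exactly 1 with zero width.  Percentiles are computed from
the case-day exposure distribution (the natural base when the percentile
table describes the cases); the probabilities are configurable.

Stratified analyses refit the full model within each stratum label (tercile
or region) — no interaction terms — and Cochran's Q is computed on the
stratum log-ORs at the 99th- and 5th-percentile contrasts, with weights
1/se², against χ² with k−1 degrees of freedom.  For a linear exposure term
the contrast scale cancels from Q, so both contrasts give identical Q; they
differ under spline parameterizations.

## ICE and terciles

ICE = (A − P)/T per tract and dimension.  Tercile cutpoints are the 1/3 and
2/3 empirical quantiles (linear interpolation of order statistics) of the
unweighted national tract-level distribution — tracts, not persons, are the
distributional unit.  Boundaries are lower-closed: a value exactly at a
cutpoint falls in the lower (more deprived) tercile; with all values
identical every tract is tercile 1.  Tercile incidence rates pool cases and
population (10⁵ · Σcases / Σpop) rather than averaging per-tract rates:
pooling is the standard incidence definition and is stable to very small
tracts.  Quantile convention and tie rules are deliberate choices, stated
here because no single convention is canonical.

## Synthetic-data generator

The generator emulates the *structure* of the three study inputs, not their
full realism:

* **Weather** — per-cell mean DT_max drawn uniform on 8–24 °C, a seasonal
  sinusoid of amplitude 12 °C peaking July 15, Gaussian day-to-day noise
  (SD 3 °C), DT_mean fixed at DT_max − 8 °C, rainfall zero with probability
  0.6 and otherwise exponential with mean 4 mm.
* **Events** — one Bernoulli draw per cell-day with
  logit p = logit(baseline_rate) + β·(DT_max − 23.5) + γ·holiday.
  Bernoulli (not Poisson) keeps each event day unambiguous for matching,
  which is exactly what the conditional likelihood conditions on.  Defaults
  β = 0.006 per °C and γ = 0.10; baseline_rate defaults to 0.05 per
  cell-day, chosen for test power (hundreds of events from one simulated
  year) rather than realism — real fatal-encounter rates are orders of
  magnitude lower, which affects only how many cell-days one must simulate,
  not the estimand.
* **Tracts** — extreme-group counts constructed from a target ICE uniform on
  (−0.85, 0.85), guaranteeing all three national terciles are populated and
  privileged + deprived never exceeds the population.

Cells are fixed to one tract and one census region at generation, mirroring
a spatial join.  Event time-of-day is ignored; linkage is by date and cell.
All randomness flows from a single integer seed through independent
numpy `SeedSequence` streams per table, so identical configs produce
byte-identical CSVs.

What the generator deliberately omits: spatial autocorrelation in weather
noise, realistic PRISM grid topology, within-cell exposure heterogeneity,
victim demographics (descriptive tables tally whatever attributes are
supplied), and temporal confounding structure beyond season and holidays.
Passing calibration tests therefore establish that the estimator is correct
*under the stated generative model* — unbiasedness, nominal CI coverage and
type-I error, Q-test p-value uniformity — not that real linked MPV/PRISM/ACS
data satisfy those assumptions.

## Problem sizes and numerical tolerances

Calibration suites run at sizes chosen to give each check adequate power at
reasonable cost: parameter recovery uses 100 replicates of ≈880 events
(40 cells × 1 year, baseline rate 0.065); type-I error uses 400 null
replicates of ≈270 events; Q calibration simulates 200 replicates of three
120-stratum groups directly at the matched-design level (the statistical
object is identical to the full pipeline's, without regenerating weather);
AIC selection uses 20 replicates.  The acceptance script reports one
two-year, 120-cell run (≈3,300 events), where the true slope is resolved at
about 2.6 standard errors.

Tolerances: Newton vs brute-force log-likelihood agreement 1e−8; analytic
vs finite-difference gradient 1e−6; closed-form fixtures 1e−8; delta-method
SE vs parametric simulation 5% relative.  Degenerate inputs — empty cell
sets, all-identical ICE values, constant exposures, strata without controls,
dates outside holiday coverage — raise informative errors or follow the
documented boundary rules above.

## Known limitations

* Wald inference only; no exact conditional or permutation inference for
  sparse strata.
* Same-day exposure only — no distributed-lag structure.
* Nearest-cell linkage; no interpolation or area weighting.
* The separation bound (|β| > 50) is a pragmatic guard, not a test for the
  existence of the MLE; near-separated data may converge with enormous
  standard errors instead of erroring.
* Holiday effects are a single shared indicator, not holiday-specific.
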