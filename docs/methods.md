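# Methods

## Model structure

The package implements a comparative static (steady-state) policy model:
each tax scenario is evaluated against an unchanged baseline, with no
time dynamics beyond the stated equilibration horizons (3 years for
weight, cohort lifespan for diabetes). The chain is strictly sequential —
price → consumption → energy → weight → BMI → diabetes — and each stage is
a pure function of the previous stage's output plus its own parameters,
which is what makes parameter-level Monte Carlo propagation exact and
cheap.

Key simplifying assumptions, inherited from the modelling tradition this
package belongs to:

* a single constant own-price elasticity (−1.14) across beverage
  categories, population groups and time;
* no cross-price substitution to diet drinks, water or untaxed beverages,
  and no industry reformulation response;
* the same per-capita energy decrease applies to every adult regardless
  of individual consumption (the model works on means);
* heights fixed when re-computing BMI after weight change;
* diabetes burden as a one-shot steady-state calculation with no
  discounting, mortality or incidence dynamics.

## Market calibration

The proprietary category-level market volumes and retail prices behind
the published scenarios are not public. `calibrate_market` therefore
inverts the smallest scenario's published outcome: a 5% average price
rise decreasing consumption by 171.3 million litres/year and
2.6 L/person/year gives

* baseline volume V = 171.3/(0.05 × 1.14) ≈ 3,005.3 million litres/year,
* market population 171.3e6/2.6 ≈ 65.9 million people,
* mean sugar density from the per-capita sugar (or energy) decrease.

Two notes on internal consistency:

* The implied population (65.9 M) is what makes the published total and
  per-capita rows mutually consistent; it is smaller than the census
  population the source tables nominally reference (~93 M aged 2+). The
  calibrated value is the default because internal consistency of the
  scenario table is what downstream stages inherit; it is configurable.
* The published per-capita sugar decrease (0.8 g/day) is rounded to one
  decimal; multiplying it by 16.7 kJ/g gives 13.4 kJ/day, not the
  published 13.7. Supplying `energy_decrease_s1=13.7` (as the shipped
  baseline config does) derives the sugar decrease as 13.7/16.7 ≈ 0.82
  g/day instead, which reproduces the published energy row — and hence
  the published adult weight-change block — exactly.
* The middle scenarios' published totals (334.0 and 641.0 ML/yr at 11%
  and 19%) are not exact linear multiples of the smallest scenario,
  reflecting unpublished category-level price heterogeneity; with the
  aggregate calibration the model yields 376.9 and 650.9 ML/yr. The
  largest scenario (20%) is linear by construction and matches
  (685.2 vs 684.9, display rounding).

The specific-sugar tax rate is interpreted as VND per gram of sugar
contained per litre (density in g/100 ml × 10): a 60 VND/g rate on a
11 g/100 ml carbonate carries 6,600 VND/L of tax, consistent with the
design producing a 19% price rise where the 7,000 VND/L volumetric design
produces 20%.

## Energy to weight

Equilibrium coefficients by age band, all sign-preserving and linear in
the energy change:

| group | coefficient | units |
|---|---|---|
| men 18+ | 93.0 | kJ·day⁻¹ per kg |
| women 18+ | 72.3 | kJ·day⁻¹ per kg |
| boys 2–5 | 216 | kJ·day⁻¹ per kg |
| girls 2–5 | 204 | kJ·day⁻¹ per kg |
| boys 6–17 | 68 − 2.5·age | kcal·day⁻¹·kg⁻¹ |
| girls 6–17 | 62 − 2.2·age | kcal·day⁻¹·kg⁻¹ |

kcal→kJ uses 4.184 for the age-6–17 equations (they are stated in kcal);
the 16.7 kJ/g sugar constant implies 4.175 kJ/kcal but the difference is
<0.3% and the two constants serve different stages. The full equilibrium
change is reported at the 3-year horizon (95% of equilibrium is attained
by then); `maturity_fraction` (default 1.0) lets users apply a 0.95
factor instead. Child population averages use uniform single-year age
weights 2–17 by default — the census age weights behind the published
child rows are unpublished; uniform weights reproduce them at the printed
precision (0.08/0.09 kg for the smallest scenario).

## Synthetic cohort

The generator emulates a national risk-factor survey of adults aged
18–69: per-row age, sex, weight, height and survey weight. It targets the
published *survey-weighted BMI class structure*, not the survey itself:

* Per sex, a base log-normal BMI distribution is fitted by least squares
  to the three WPRO cut-off exceedance probabilities (male targets
  19.2/13.1/1.7%, female 16.5/14.2/5.1%). A two-parameter log-normal
  cannot satisfy all three class shares at once — the observed structure
  has a narrow overweight band next to a thin obesity-II tail — so each
  person's class is drawn exactly at the target probabilities and BMI is
  then drawn from the base log-normal truncated to the class interval.
  Class shares are exact in expectation; the within-class shape stays
  smooth.
* A one-dimensional root-find on a common log-location shift sets the
  expected weighted mean BMI to 21.96 kg/m². (That target is itself
  reconstructed: the published post-tax mean 21.89 plus the smallest
  scenario's reduction 0.07; treat it as soft.)
* Heights are auxiliary — normal per sex with synthetic means 1.62 m
  (men) / 1.53 m (women), SD 0.06 m, plausible for the population but
  not estimated from data — and weight is reconstructed as BMI·height².
* Survey weights are i.i.d. gamma with mean 1 (shape 10), exercising
  weighted estimators without replicating the survey's unpublished
  cluster/stratum design.
* The 50/50 sex split makes the per-sex targets aggregate to the
  published both-sex baseline (17.85/13.65/3.4% vs 17.9/13.6/3.4%).

What passing tests on this cohort do **not** show: behaviour under real
survey design effects (our linearized standard errors omit clustering and
will be smaller than design-based ones), age–BMI correlation (ages are
uniform and independent of BMI), and any real height–weight covariance.

## Prevalence estimation

WPRO classes are right-half-open ([23, 25), [25, 30), [30, ∞)); boundary
values are classified upward (BMI 25.0 is obesity I). Point estimates are
weighted shares Σw·1[class]/Σw; standard errors use the linearized
weighted-ratio variance Σw²(x−p̂)²/(Σw)² without design terms. "Both
sexes" pools the strata under survey weights rather than averaging the
sex-specific estimates.

## Diabetes burden

Dose-response is linear proportional scaling rrr·ΔBMI/2 from the 27% RRR
per 2 BMI units (the multiplicative alternative 1−0.73^(ΔBMI/2) is a
config switch; its initial slope −ln(0.73)/2 ≈ 0.157 exceeds the linear
0.135, so it gives ~16% relatively larger reductions at small ΔBMI —
linear is the default for transparency). Applied to the 4.1% baseline
prevalence and 67 million adults. The complication share (0.5) and the
two unit costs (10.5 M / 4.812 M VND) are synthetic placeholders
calibrated so the blended cost is 7.656 M VND per avoided case, which
reproduces the published pairing of avoided cases with VND and USD
savings (342 USD/case at 22,370 VND/USD); real claims-database costs
belong in user configuration. The published sex-specific prevalence
reductions cannot be reproduced from published inputs (sex-specific
baseline prevalences are unpublished), so per-sex baseline overrides are
exposed and the package's own checks on that block are property-based
(monotonicity, linearity, cost-per-case constancy) rather than
value-matching.

## Uncertainty analysis

Monte Carlo resamples at parameter level per iteration (not per person):
model 1 the per-sex conversion factors (normal), model 2 additionally the
RRR (beta with mean fixed at 0.27 and concentration fitted by least
squares to the 95% CI (0.23, 0.30); moment matching on (hi−lo)/3.92 is
the alternative). Conversion-factor SDs are unpublished; the default 5%
CV reproduces the scale of the published weight-change SDs (e.g. 0.59
(0.03) kg) and is overridable. Non-positive normal draws are rejected and
redrawn (counted on the result). Conversion factors are drawn before the
RRR from a single seeded generator, so models 1 and 2 share identical
weight-change draws at the same seed and model 2's SDs on diabetes
outputs are never smaller. With zero-SD distributions the Monte Carlo
mean equals the deterministic chain bit-for-bit (same code path).

One-way elasticity analysis calibrates the market once at the base
elasticity (−1.14) and re-evaluates the demand response at −1.0 and −0.8,
so every output scales exactly by ε/ε_base.

## Numerical choices and problem sizes

* Cohort BMI draws use inverse-CDF sampling of the truncated log-normal;
  uniforms are clipped to [1e−12, 1−1e−12] and BMI to [13, 58] so
  reconstructed weights stay inside physical bounds.
* The root-find for the mean-BMI shift is Brent's method on [−0.5, 0.5]
  (xtol 1e−10); an empty bracket raises a calibration error reporting the
  attainable mean range.
* Default problem sizes: cohort n = 3,856 (mirroring the source survey)
  for pipeline runs, n = 50,000 for calibration-recovery checks
  (prevalence sampling SE ≈ 0.17 pp); Monte Carlo 10,000 iterations by
  default, 2,000 in convergence tests (4·SE criterion). All are
  fractions of a second on one core.

## Known limitations

Beyond the inherited model assumptions above: the middle scenarios'
consumption totals are reproducible only approximately without the
unpublished category price table; standard errors understate design-based
uncertainty; treatment costs are calibrated placeholders; children
contribute weight-change projections only (no BMI classification, since
height growth invalidates a child BMI projection); and the published
both-sex diabetes prevalence reductions (0.12 pp at the largest
scenarios) sit below the closed-form 4.1% × 27% × ΔBMI/2 ≈ 0.155 pp,
implying an unpublished sex- or age-specific application that this
package does not attempt to force.
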