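# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the design decisions behind `oacrab`, in the spirit of the
methods documentation of statsmodels or msprime. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Mortality model

Cohorts are censused once per day, so event times are interval-censored:
a death detected at the day-*d* check occurred in (*d*−1, *d*]. Under a
constant daily hazard *r* (day⁻¹), survival is S(t) = e^(−rt) and the
likelihood contributions are S(d−1) − S(d) for a death and S(last day) for
a crab alive at the end of the experiment (sacrifice at the end is
censoring, not an event). An equivalent per-day Bernoulli formulation
(survive each day with probability e^(−r)) is provided as an alternative
mode; the two are algebraically identical for constant hazards and the
tests assert this.

The likelihood factorizes over hazard-parameter groups into
ℓ(r) = D·log(1 − e^(−r)) − r·T₀, where D is the group's death count and T₀
its fully-survived exposure days. This has the closed-form maximizer
r̂ = log(1 + D/T₀) and analytic observed information
I(r) = D·e^(−r)/(1 − e^(−r))², which we use directly rather than a
numerical optimizer — it is exact, deterministic, and the tests verify it
against both exhaustive grid search (step 10⁻⁵) and a bounded scalar
optimizer. A group with zero deaths gets r̂ = 0 with an undefined SE and a
flag rather than an exception. A closed-form exact-time estimator
(deaths / subject-days) is available as a cross-check mode.

Three treatment structures are compared: one shared rate (K = 1), control
vs. acidified (K = 2), and one rate per treatment (K = 3), ranked by AICc
with Akaike weights. Models within ΔAICc < 2 are reported as co-best.

**AICc sample size.** The effective n is the number of crabs (independent
subjects) by default, configurable to crab-days. For the wet-mass growth
ladder the default is instead the number of observations, because the
parameter count includes one intercept per crab and therefore exceeds the
number of crabs, which would make the small-sample correction's
denominator negative.

**Known property.** The exponential-hazard MLE carries the usual O(1/n)
upward bias, roughly r/(expected deaths); at n = 30 this is ~2–4% of the
true rate depending on the censoring fraction. The recovery tests
characterize this: relative bias stays below 5% at the study's sample
sizes, but it is resolvable by large simulation ensembles (it exceeds two
Monte-Carlo standard errors of a 500-replicate mean at the highest rate).

## Growth models

**Degree-day clock.** Thermal time is the cumulative sum of daily mean
temperatures above a base of 0 °C (configurable); degree-days over
(start, end] are additive over adjacent intervals. At the experiment's mean
of 9.1 °C, 192 days correspond to 1747.2 °C·day.

**Carapace length.** CL is linear in degree-days. The ANCOVA crosses
Treatment with Time and adds crab-within-treatment intercepts; crabs with
fewer than three measurements are excluded, as is the initial (pre-molt)
size, whose molt-cycle stage is unknown. A significant Treatment × Time
interaction (α = 0.05) triggers separate per-treatment regressions (Time
plus crab intercepts); the reported intercept is the mean of the crab
intercepts.

**Wet mass.** WM = a_crab · e^(bt) with additive Gaussian errors on the
mass scale and the residual SD a fitted parameter. Per-crab intercepts are
always free; for fixed b the intercepts and residual variance profile out
in closed form (a_i = Σy·g / Σg², g = e^(bt)), leaving a one-dimensional
search per b parameter (bounded scalar minimization on (−0.005, 0.02),
xatol 10⁻¹³; estimates at the search boundary are flagged as
non-converged). Masses are timestamped at the degree-days of molt + 7 days,
when wet mass is actually measured.

Four variants are ranked: {a,b}, {a(T),b}, {a,b(T)}, {a(T),b(T)}. Because
the free per-crab intercepts absorb any treatment-level intercept, the a(T)
variants are structurally confounded with their a counterparts: they refit
identically, are flagged `confounded`, and share the parameter count
K = n_crabs + n_b + 1. Ties in the ranking are therefore expected and are
reported as co-best.

**Fixed-effects machinery.** The ANCOVA and the PC-score model use custom
design matrices — treatment/molt dummies, crab-within-treatment columns
coded sum-to-zero within each treatment so they are not collinear with the
treatment effect — and Type-II F tests via nested OLS model comparisons
with the error mean square from the full model. On balanced designs this
agrees with Type I/III; the null-calibration tests confirm the interaction
F holds its nominal size.

## Morphometrics

Landmark columns are standardized (mean 0, SD 1, n−1 denominator) and
decomposed by eigendecomposition of the correlation matrix; scores are the
projections of the standardized rows. Signs are fixed deterministically —
each component is flipped so the majority of its loadings are negative,
ties broken by making the first loading non-positive — which makes results
bit-reproducible and gives PC1 the "bigger crab scores lower" orientation
natural for size-dominated juvenile landmarks. Molt stages reached by fewer
than 20% (configurable) of any treatment's crabs are dropped before the
score model, and treatments whose animals rarely survive to molt (the pH
7.5 red king crabs) should be excluded by the caller, otherwise
single-observation crabs saturate the design (the model then raises on zero
residual df). Fisher LSD contrasts of treatments within each molt are
computed only where the within-molt omnibus F is significant.

## Endpoints

Condition index = dry mass / length³ (g·mm⁻³), with carapace length as the
reference length for red king crab and carapace width for Tanner crab.
Endpoint comparisons are gated by Levene's test (mean-centered, α = 0.05):
homogeneous variances → one-way ANOVA with Fisher LSD post hoc; otherwise →
Kruskal-Wallis with pairwise two-sided rank-sum (Mann-Whitney) post hoc,
since no LSD analogue is defined for the rank test. Percent differences are
100·(mean_A/mean_B − 1) of arithmetic group means. The Kruskal-Wallis
p-value uses the chi-square approximation by default (matching the
era-typical software); an `exact=True` option computes the permutation
p-value, which matters below ~5 values per group where the chi-square
approximation is off by several hundredths.

Tanner-crab growth is deliberately not fit as a trajectory: too few animals
molt often enough. Instead sizes and masses are compared cross-sectionally
per molt, and intermolt degree-day durations per consecutive molt pair,
with the same gated tests.

## Carbonate system

pH (free scale) and DIC determine the CO₂ system in closed form: [H⁺]_free
comes from the measured pH, is converted to the total scale via
(1 + S_T/K_S), and partitions DIC exactly among CO₂*, HCO₃⁻ and CO₃²⁻.
pCO₂ = [CO₂*]/K₀; TA = [HCO₃⁻] + 2[CO₃²⁻] + [B(OH)₄⁻] + [OH⁻] − [H⁺]_free;
Ω = [Ca²⁺][CO₃²⁻]/K_sp with [Ca²⁺] = 0.010285·S/35 mol/kg. Constants:
Lueker et al. (2000) K₁/K₂ (total scale), Dickson (1990) K_B and K_S,
Millero (1995) K_W, Weiss (1974) K₀, Mucci (1983) aragonite/calcite
solubility. Tests pin each constant to its published check value at
T = 25 °C, S = 35 to 4 significant figures, and an independent TA/DIC
root-finding oracle recovers the input pH to ±0.001. Nutrient alkalinity
terms are omitted (unmeasured in this kind of experiment); K_W is the
seawater-scale form, whose contribution to TA through [OH⁻] is below
10⁻⁷ mol/kg at these temperatures. Salinity is rarely printed in
experimental reports; the default is 32 (coastal Gulf of Alaska) and the
saturation-state classifications are insensitive to it across 30–33.
Saturation classification uses a ±0.15 band around Ω = 1
(undersaturated / near-saturation / supersaturated).

## Synthetic cohort generator

The generator is first-class, tested code: it defines the study conditions
that every recovery and calibration test runs under.

* **Design**: 3 treatments × 30 crabs, 192 days (red king crab) or 199
  (Tanner), all quantities drawn from a single seeded generator, so a fixed
  config is byte-reproducible.
* **Temperature**: piecewise-cosine through 9.3 °C (start), 11.9 °C
  (~day 100) and 4.4 °C (end) plus optional daily jitter (SD 0.3 °C);
  the 192-day mean is ~9.4 °C.
* **Mortality**: exponential death times at per-treatment hazards
  (defaults 0.0023/0.0047/0.025 day⁻¹ for red king crab,
  0.0010/0.0023/0.0050 for Tanner), discretized to the daily census;
  survivors censored at the end.
* **Molting**: cumulative degree-days cross successive truncated-normal
  intermolt draws (450 ± 119 °C·day for red king crab, 873 ± 198 for
  Tanner; truncation floors 150 and 300 °C·day). The Tanner preset caps
  molts at 3. A config whose truncation removes essentially all mass
  raises rather than silently shifting the distribution.
* **Size and mass**: CL at molt is linear in degree-days (control slope
  0.000737 mm/°C·day, intercept 2.34 mm; pH 7.8 slope 0.000506,
  intercept 2.38) with 0.1 mm Gaussian noise; WM is a_crab·e^(bt) with
  a = 0.00667 g, b = 0.000829 (control) / 0.000557 (pH 7.8), per-crab
  intercepts lognormal (CV 10%), relative mass noise 5%, measured 7 days
  post-molt. The pH 7.5 growth parameters are unobservable in such an
  experiment (those crabs die early); plausibly slower values (slope
  0.00040, b 0.00045) are used.
* **Morphometrics**: each landmark is a fixed proportion of CL with 2.5%
  relative measurement/shape noise, so a single size axis carries ~90% of
  the standardized variance, as observed for juvenile carapaces.
* **Endpoints**: survivors get condition index from a treatment-multiplied
  baseline (red king crab: control 25% above the acidified treatments,
  lognormal CV 10%), %Ca (Tanner preset: control 10–11% above acidified)
  and %Mg (0.83 ± 0.03% for red king crab, 1.2 ± 0.1% for Tanner).

**What the generator does not emulate**, and hence what passing recovery
tests do not show about real data: death and molting are independent (no
moribund-slowdown coupling); hazards are time-constant (real cohorts can
diverge between treatments only after a lag); growth noise is
homoscedastic within its model; there is no tank/cell spatial structure,
no measurement attrition, and molt detection is perfect.

## Numerical and reporting conventions

* Hazard/SE reporting follows the (rate ± SE) day⁻¹ convention; ranking
  tables use the Model/K/AICc/ΔAICc/Likelihood/Weights layout.
* Percent contrasts are 100·(A/B − 1); for the shared-intercept exponential
  the contrast reduces to e^((b_A−b_B)t) − 1 and is independent of a.
* CLI exit codes: 0 success, 2 validation error, 3 convergence/estimation
  flag present. Reports embed the seed and a config hash.
* Simulation ensemble sizes in the test and acceptance suites — 500
  replicates for hazard recovery, 200 for model-selection rates, 2000 for
  type-I calibration — were chosen so Monte-Carlo SEs are a few tenths of
  a percentage point on selection rates while the full suite runs in a few
  minutes on one CPU.

## Known limitations

* The per-treatment hazard model has no covariates or time-variation;
  Kaplan–Meier estimation is out of scope.
* a(T) wet-mass variants are identifiable only through their shared-K
  bookkeeping, not the fit itself (see above); analyses that need a
  treatment-level intercept should model crab intercepts hierarchically,
  which is out of scope here.
* The carbonate solver fixes one family of constants; no user-selectable
  alternatives, no pressure correction, no nutrient alkalinity.
* Type-II F tests are reported for the nested fixed-effects models;
  strongly unbalanced designs may warrant Type-III with explicit contrast
  coding.
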