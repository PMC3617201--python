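# oacrab

Statistical machinery for long-term ocean-acidification rearing experiments
on juvenile crabs: censored exponential mortality modelling with AICc model
selection, degree-day growth models, morphometric PCA, terminal
condition/calcification endpoints, and seawater carbonate-system chemistry —
plus a seeded synthetic-cohort generator that reproduces the statistical
structure every fitter assumes.

The package is aimed at crustacean ecologists and biostatisticians analyzing
individually-reared cohort experiments (three pH treatments × ~30 animals ×
~200 days, censused daily), and at anyone who wants a tested, reusable
implementation of this analysis chain on their own census/molt/assay tables.

## The models

**Mortality.** Each crab is checked daily, so a death observed on day *d*
is interval-censored into (*d*−1, *d*]. With constant daily hazard *r* the
survival function is *S*(*t*) = e^(−*rt*); a death contributes
*S*(*d*−1) − *S*(*d*) and a survivor *S*(duration) to the likelihood (this
factorizes identically as a per-day Bernoulli survival model). Three hazard
structures — one shared rate, control vs. acidified, one rate per
treatment (*K* = 1, 2, 3) — are fit by maximum likelihood and ranked by

AICc = −2 ln *L* + 2*K* + 2*K*(*K*+1)/(*n*−*K*−1),

with Akaike weights *w_i* ∝ exp(−Δ_i/2); models within Δ < 2 are
reported as co-best.

**Growth.** Time runs on a thermal clock of degree-days (sum of daily mean
°C above a 0 °C base). Carapace length grows linearly, CL = *a* + *bt*,
tested by an ANCOVA with Treatment crossed with Time and crab-within-
treatment intercepts; a significant Treatment × Time interaction means the
growth rates differ. Wet mass grows exponentially,
WM = *a*_crab · e^(*bt*) with additive Gaussian errors; four variants
(letting *a* and/or *b* vary with treatment, crab intercepts always free)
are ranked by AICc.

**Morphometrics.** Carapace landmarks (5 for red king crab, 8 for Tanner
crab) are standardized and decomposed by PCA on the correlation matrix.
PC1 is a size axis; the sign convention flips components so the majority of
loadings are negative (bigger crab → lower PC1 score). Treatment/molt
effects on scores use a fixed-effects Treatment × Molt model with nested
crab intercepts and Fisher-LSD contrasts within molts.

**Endpoints.** Condition index = dry mass (g) / length³ (mm³). Endpoints
are compared across treatments behind a Levene gate: one-way ANOVA (plus
Fisher LSD) when variances are homogeneous, Kruskal-Wallis otherwise.

**Carbonate system.** From measured pH (free scale), DIC, temperature and
salinity the solver computes pCO₂, [CO₂*], [HCO₃⁻], [CO₃²⁻], total
alkalinity and Ω_aragonite/Ω_calcite = [Ca²⁺][CO₃²⁻]/K_sp in closed form,
using the standard constant formulations (Lueker 2000 K₁/K₂, Dickson 1990
K_B and K_S, Weiss 1974 K₀, Mucci 1983 solubility products).

## Worked example

Simulate a red-king-crab cohort at the default study conditions (daily
hazards 0.0023 / 0.0047 / 0.025 in ambient, pH 7.8 and pH 7.5 water) and
ask which mortality structure the data support:

```python
from oacrab import (CohortConfig, compare_structures, rate_percent_increase,
                    records_from_census, simulate_cohort)

exp = simulate_cohort(CohortConfig.red_king_crab(seed=0))
ranking, fits = compare_structures(records_from_census(exp.census))
print(ranking.table[["model", "k", "aicc", "delta_aicc", "weight"]])
```

```
            model  k   aicc  delta_aicc  weight
    All Different  3 684.59        0.00    1.00
Control<Acidified  2 705.87       21.29    0.00
         All Same  1 721.50       36.92    0.00
```

The three-rate model carries essentially all the Akaike weight: mortality
differs among all treatments. The fitted hazards for this cohort are
0.0023, 0.0043 and 0.0181 day⁻¹ (±0.0007, 0.0010, 0.0034), i.e. the pH 7.8
hazard is +87% over ambient and pH 7.5 is +684% in this realization
(generating values +104% and +987%). The `examples/` directory has one
short script per capability (simulation, survival, growth, PCA, endpoints,
carbonate chemistry); each prints the numbers it computes and what they
mean.

A thin CLI wires the same steps together for shell use:

```sh
oacrab simulate --seed 0 --out run/
oacrab fit-survival --census run/census.csv --out run/
oacrab fit-growth   --molts  run/molts.csv  --out run/
oacrab carbonate    --water  run/water.csv  --out run/
```

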