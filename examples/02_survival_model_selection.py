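"""Fit the three mortality structures and rank them by AICc.

Each crab contributes an interval-censored exponential survival term (daily
checks). The candidate models let the daily hazard be shared, split control
vs. acidified, or differ in all three treatments; Akaike weights say how
decisively the data pick a structure.
"""

from oacrab import CohortConfig, compare_structures, rate_percent_increase, \
    records_from_census, simulate_cohort

exp = simulate_cohort(CohortConfig.red_king_crab(seed=0))
records = records_from_census(exp.census)

ranking, fits = compare_structures(records)
print(ranking.table[["model", "k", "aicc", "delta_aicc", "weight"]]
      .to_string(index=False, float_format=lambda v: f"{v:.2f}"))

best = fits["all_different"]
print("\nper-treatment daily hazards (day^-1):")
for tr in ("control", "ph78", "ph75"):
    print(f"  {tr:8s} {best.rate_for(tr):.4f} +/- {best.se_for(tr):.4f}")
ctrl = best.rate_for("control")
print(f"\nhazard increase vs control: "
      f"pH 7.8 {rate_percent_increase(best.rate_for('ph78'), ctrl):+.0f}%, "
      f"pH 7.5 {rate_percent_increase(best.rate_for('ph75'), ctrl):+.0f}%")
# the generating hazards are 0.0023 / 0.0047 / 0.025, i.e. +104% and +987%
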