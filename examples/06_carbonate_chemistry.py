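"""Carbonate speciation of the treatment water from measured pH and DIC.

From pH (free scale), DIC, temperature and salinity the solver computes
pCO2, the carbonate species, total alkalinity, and the aragonite/calcite
saturation states Omega; Omega < 1 favors shell dissolution.
"""

from oacrab import (WaterSample, classify_saturation, generate_water_samples,
                    solve_speciation, treatment_table)

# one representative sample per treatment at the experiment's mean 9.1 degC
for label, ph, dic_mmol in [("control", 8.04, 1.93), ("pH 7.8", 7.80, 2.01),
                            ("pH 7.5", 7.50, 2.08)]:
    st = solve_speciation(WaterSample(ph, dic_mmol * 1e-3, 9.1, 32.0))
    print(f"{label:8s} pCO2 {st.pco2_uatm:7.1f} uatm  "
          f"CO3 {st.co3 * 1e3:.3f} mmol/kg  "
          f"Omega_arag {st.omega_aragonite:.2f} ({classify_saturation(st.omega_aragonite)})")

# or summarize a whole table of weekly samples
water = generate_water_samples(seed=0)
print()
print(treatment_table(water).loc[:, "mean"].to_string(float_format=lambda v: f"{v:.3f}"))
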