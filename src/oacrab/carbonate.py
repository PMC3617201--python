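"""Seawater CO2-system speciation from measured pH (free scale) and DIC.

Given pH on the free hydrogen-ion scale, dissolved inorganic carbon,
temperature and salinity, this module computes the carbonate speciation
([CO2*], [HCO3-], [CO3 2-]), pCO2, total alkalinity, and the aragonite and
calcite saturation states Omega = [Ca2+][CO3 2-]/Ksp. Because pH and DIC
determine the system in closed form, no iterative solve is needed.

Equilibrium constants use the standard formulations adopted by the
community CO2-system packages: K1/K2 from Lueker et al. (2000, total
scale), KB from Dickson (1990), KS (bisulfate) from Dickson (1990), KW from
Millero (1995), K0 (CO2 solubility) from Weiss (1974), and calcite /
aragonite solubility products from Mucci (1983). Calcium is scaled with
salinity as [Ca2+] = 0.010285 S/35 mol/kg. Nutrient (phosphate/silicate)
alkalinity terms are omitted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "WaterSample",
    "CarbonateState",
    "equilibrium_constants",
    "solve_speciation",
    "classify_saturation",
    "treatment_table",
]


@dataclass(frozen=True)
class WaterSample:
    """One water sample: pH (free scale), DIC (mol/kg), T (degC), salinity."""

    ph_free: float
    dic: float  # mol/kg-solution
    temp_c: float
    salinity: float

    def __post_init__(self) -> None:
        if not (0.0 < self.salinity < 45.0):
            raise ValueError(f"salinity {self.salinity} outside (0, 45)")
        if not (6.0 < self.ph_free < 9.0):
            raise ValueError(f"pH {self.ph_free} outside (6, 9)")
        if self.dic <= 0:
            raise ValueError("DIC must be positive")


@dataclass
class CarbonateState:
    """Full speciation for one water sample (concentrations in mol/kg)."""

    pco2_uatm: float
    co2_star: float
    hco3: float
    co3: float
    alkalinity: float
    omega_aragonite: float
    omega_calcite: float
    ph_free: float
    dic: float


def equilibrium_constants(
    temp_c: float, salinity: float, *, total_sulfate: float | None = None
) -> dict:
    """Thermodynamic constants of the CO2 system at surface pressure.

    Returns a dict with K0 (mol/kg/atm), K1, K2, KB (total scale), KW, KS
    (free scale, mol/kg-H2O basis), the aragonite/calcite solubility
    products, total boron and sulfate, and ``free_to_total`` — the factor
    (1 + S_T/K_S) converting free-scale [H+] to total scale. Setting
    ``total_sulfate=0`` makes the two scales coincide.
    """
    if not (0.0 <= temp_c <= 35.0) or not (19.0 <= salinity <= 43.0):
        warnings.warn(
            f"T={temp_c} degC, S={salinity} outside the fitted range of the "
            "constant formulations; values are extrapolated"
        )
    T = temp_c + 273.15
    S = salinity
    sqS = math.sqrt(S)
    lnT = math.log(T)

    ln_k0 = (
        93.4517 * (100.0 / T)
        - 60.2409
        + 23.3585 * math.log(T / 100.0)
        + S * (0.023517 - 0.023656 * (T / 100.0) + 0.0047036 * (T / 100.0) ** 2)
    )
    pk1 = 3633.86 / T - 61.2172 + 9.67770 * lnT - 0.011555 * S + 0.0001152 * S**2
    pk2 = 471.78 / T + 25.9290 - 3.16967 * lnT - 0.01781 * S + 0.0001122 * S**2
    ln_kb = (
        (-8966.90 - 2890.53 * sqS - 77.942 * S + 1.728 * S**1.5 - 0.0996 * S**2) / T
        + 148.0248
        + 137.1942 * sqS
        + 1.62142 * S
        + (-24.4344 - 25.085 * sqS - 0.2474 * S) * lnT
        + 0.053105 * sqS * T
    )
    ln_kw = (
        148.9802
        - 13847.26 / T
        - 23.6521 * lnT
        + (118.67 / T - 5.977 + 1.0495 * lnT) * sqS
        - 0.01615 * S
    )
    ion = 19.924 * S / (1000.0 - 1.005 * S)
    ln_ks = (
        -4276.1 / T
        + 141.328
        - 23.093 * lnT
        + (-13856.0 / T + 324.57 - 47.986 * lnT) * math.sqrt(ion)
        + (35474.0 / T - 771.54 + 114.723 * lnT) * ion
        - (2698.0 / T) * ion**1.5
        + (1776.0 / T) * ion**2
        + math.log(1.0 - 0.001005 * S)
    )
    log10_ksp_cal = (
        -171.9065
        - 0.077993 * T
        + 2839.319 / T
        + 71.595 * math.log10(T)
        + (-0.77712 + 0.0028426 * T + 178.34 / T) * sqS
        - 0.07711 * S
        + 0.0041249 * S**1.5
    )
    log10_ksp_arag = (
        -171.945
        - 0.077993 * T
        + 2903.293 / T
        + 71.595 * math.log10(T)
        + (-0.068393 + 0.0017276 * T + 88.135 / T) * sqS
        - 0.10018 * S
        + 0.0059415 * S**1.5
    )
    st = (0.14 / 96.062) * (S / 1.80655) if total_sulfate is None else total_sulfate
    bt = 0.0004157 * S / 35.0
    ks = math.exp(ln_ks)
    k1, k2 = 10.0**-pk1, 10.0**-pk2
    if not k1 > k2:
        raise AssertionError("acid-dissociation ordering violated: K1 <= K2")
    return {
        "K0": math.exp(ln_k0),
        "K1": k1,
        "K2": k2,
        "KB": math.exp(ln_kb),
        "KW": math.exp(ln_kw),
        "KS": ks,
        "Ksp_aragonite": 10.0**log10_ksp_arag,
        "Ksp_calcite": 10.0**log10_ksp_cal,
        "total_boron": bt,
        "total_sulfate": st,
        "free_to_total": 1.0 + st / ks,
        "calcium": 0.010285 * S / 35.0,
    }


def solve_speciation(sample: WaterSample) -> CarbonateState:
    """Closed-form speciation of the CO2 system from (pH, DIC, T, S).

    [H+] on the free scale comes directly from the measured pH and is
    converted to the total scale for use with the total-scale constants.
    DIC is partitioned exactly among CO2*, HCO3- and CO3 2-; total
    alkalinity is assembled as HCO3- + 2 CO3 2- + B(OH)4- + OH- - H+(free).
    """
    k = equilibrium_constants(sample.temp_c, sample.salinity)
    h_free = 10.0 ** (-sample.ph_free)
    h_tot = h_free * k["free_to_total"]
    denom = h_tot**2 + k["K1"] * h_tot + k["K1"] * k["K2"]
    co2 = sample.dic * h_tot**2 / denom
    hco3 = sample.dic * k["K1"] * h_tot / denom
    co3 = sample.dic * k["K1"] * k["K2"] / denom
    boh4 = k["total_boron"] * k["KB"] / (k["KB"] + h_tot)
    oh = k["KW"] / h_tot
    ta = hco3 + 2.0 * co3 + boh4 + oh - h_free
    return CarbonateState(
        pco2_uatm=co2 / k["K0"] * 1e6,
        co2_star=co2,
        hco3=hco3,
        co3=co3,
        alkalinity=ta,
        omega_aragonite=k["calcium"] * co3 / k["Ksp_aragonite"],
        omega_calcite=k["calcium"] * co3 / k["Ksp_calcite"],
        ph_free=sample.ph_free,
        dic=sample.dic,
    )


def classify_saturation(omega: float, *, band: float = 0.15) -> str:
    """Classify a saturation state relative to Omega = 1 with a tolerance band."""
    if omega < 0:
        raise ValueError("omega must be non-negative")
    if omega < 1.0 - band:
        return "undersaturated"
    if omega > 1.0 + band:
        return "supersaturated"
    return "near-saturation"


def treatment_table(samples: pd.DataFrame, *, default_salinity: float = 32.0) -> pd.DataFrame:
    """Per-treatment mean and SE of the derived CO2-system quantities.

    Expects columns treatment, ph_free, dic_mmol_kg, temp_c and optionally
    salinity (falling back to ``default_salinity``). DIC is supplied in
    mmol/kg as in routine lab reports and converted internally to mol/kg;
    derived concentrations are reported back in mmol/kg.
    """
    df = samples.copy()
    if "salinity" not in df.columns:
        df["salinity"] = default_salinity
    df["salinity"] = df["salinity"].fillna(default_salinity)
    rows = []
    for _, rec in df.iterrows():
        state = solve_speciation(
            WaterSample(
                ph_free=rec["ph_free"],
                dic=rec["dic_mmol_kg"] * 1e-3,
                temp_c=rec["temp_c"],
                salinity=rec["salinity"],
            )
        )
        rows.append(
            {
                "treatment": rec["treatment"],
                "pH_free": state.ph_free,
                "pCO2_uatm": state.pco2_uatm,
                "HCO3_mmol_kg": state.hco3 * 1e3,
                "CO3_mmol_kg": state.co3 * 1e3,
                "DIC_mmol_kg": state.dic * 1e3,
                "alkalinity_mmol_kg": state.alkalinity * 1e3,
                "omega_aragonite": state.omega_aragonite,
                "omega_calcite": state.omega_calcite,
            }
        )
    per = pd.DataFrame(rows)
    g = per.groupby("treatment")
    mean = g.mean()
    se = g.sem()
    out = pd.concat({"mean": mean, "se": se}, axis=1)
    out["classification", "aragonite"] = [
        classify_saturation(v) for v in mean["omega_aragonite"]
    ]
    out["classification", "calcite"] = [
        classify_saturation(v) for v in mean["omega_calcite"]
    ]
    return out
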