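"""Published cross-biome reference statistics for broadleaved forests.

Zone-level means (tropical / temperate / boreal) from a global plot network
of mature broadleaved forests: foliar production, herbivory, gross and net
insect-mediated element fluxes, resorption efficiencies, and the labile
reference inputs (atmospheric N and P deposition, bedrock-weathered P).
These values serve two purposes: as default calibration targets for the
synthetic plot-network generator, and as worked-example inputs for the
reference-comparison calculations.

All fluxes g m^-2 y^-1; percentages as printed (e.g. herbivory 5.4 = 5.4 %).
"""

ZONES = ("tropical", "temperate", "boreal")

#: number of plots per zone in the reference network (74 total, 40 sites)
N_PLOTS = {"tropical": 33, "temperate": 32, "boreal": 9}
N_SITES = {"tropical": 16, "temperate": 18, "boreal": 6}

#: observed zone means of foliar biomass production (g m^-2 y^-1)
FP_OBSERVED = {"tropical": 539.3, "temperate": 323.4, "boreal": 158.8}

#: rank-model summary means of FP as tabulated alongside the group tests
FP_TABLE = {"tropical": 513.0, "temperate": 321.6, "boreal": 231.9}

#: herbivory rate, % leaf area removed
H_PCT = {"tropical": 5.4, "temperate": 3.3, "boreal": 2.4}
H_GLOBAL_PCT = 4.1
INCIDENCE_GLOBAL_PCT = 48.8
H_PLOT_RANGE_PCT = (0.6, 13.6)

#: gross insect-mediated element fluxes H_c (g m^-2 y^-1) by element and zone
HC = {
    "C": {"tropical": 15.87, "temperate": 5.41, "boreal": 1.65},
    "N": {"tropical": 0.600, "temperate": 0.231, "boreal": 0.082},
    "P": {"tropical": 0.034, "temperate": 0.016, "boreal": 0.006},
    "Si": {"tropical": 0.178, "temperate": 0.178, "boreal": 0.029},
}

#: net insect-mediated fluxes H_i (g m^-2 y^-1)
HI = {
    "N": {"tropical": 0.26, "temperate": 0.11, "boreal": 0.05},
    "P": {"tropical": 0.022, "temperate": 0.009, "boreal": 0.003},
}
HI_GLOBAL = {"C": 1.7, "N": 0.17, "P": 0.014}

#: labile reference inputs (g m^-2 y^-1) by zone
ATM_N = {"tropical": 0.38, "temperate": 1.03, "boreal": 0.49}
ATM_P = {"tropical": 0.005, "temperate": 0.004, "boreal": 0.003}
BEDROCK_P = {"tropical": 0.054, "temperate": 0.045, "boreal": 0.069}

#: resorption efficiency (%): zone values where reported, else global
RE_PCT = {
    "C": {"global": 19.7},
    "N": {"tropical": 46.5, "boreal": 61.8},
    "P": {"tropical": 66.5, "temperate": 57.9, "boreal": 55.2},
}

#: study-design ranges used as synthetic-generator defaults
MAT_RANGE_C = (-1.4, 26.9)
DRYNESS_RANGE = (0.21, 1.30)
TRAPS_PER_PLOT = (9, 25)
TRAP_AREA_M2 = (0.1, 0.5)


def reference_table():
    """Zone-scoped reference-input table in the bundle's CSV layout."""
    import pandas as pd

    return pd.DataFrame({
        "scope": list(ZONES),
        "atm_n": [ATM_N[z] for z in ZONES],
        "atm_p": [ATM_P[z] for z in ZONES],
        "bedrock_p": [BEDROCK_P[z] for z in ZONES],
    })
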