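"""Published family-of-four market-basket tables for a TFP 2021-style
pork/beef separation analysis, used as fixed inputs for aggregation checks.

Values are weekly quantities as consumed (lbs) and costs (USD) for a
reference family of four (one male and one female each of 20-50 y and
4-13 y), for five optimization models: M1 (pooled meat, replicating the TFP
2021), M2 (pork/beef separated, cost and meat amount pegged to M1), M3
(separated, lowest cost), M4 (pork only), and M5 (beef only).

In the M1 column of the protein table the fresh-meat row carries pooled red
meat (beef and pork together); the pork entry is ``None``.
"""

MODELS = ("M1", "M2", "M3", "M4", "M5")

#: family-of-four (lbs/week, USD/week) by market-basket category
FAMILY_BASKETS = {
    "vegetables":    {"M1": (24.73, 41.31), "M2": (24.16, 40.20), "M3": (24.68, 41.27), "M4": (24.28, 40.71), "M5": (24.95, 42.36)},
    "fruits":        {"M1": (22.79, 27.62), "M2": (23.66, 27.72), "M3": (22.71, 27.46), "M4": (22.47, 27.54), "M5": (20.90, 26.45)},
    "grains":        {"M1": (18.74, 29.06), "M2": (19.02, 28.20), "M3": (18.21, 28.33), "M4": (17.21, 27.24), "M5": (18.14, 31.66)},
    "dairy":         {"M1": (41.57, 27.54), "M2": (36.11, 29.11), "M3": (41.41, 27.65), "M4": (41.74, 27.21), "M5": (43.43, 26.74)},
    "protein foods": {"M1": (14.18, 48.13), "M2": (14.33, 46.68), "M3": (14.46, 47.42), "M4": (14.09, 47.53), "M5": (14.00, 77.73)},
    "miscellaneous": {"M1": (16.35, 16.22), "M2": (17.30, 17.96), "M3": (16.33, 15.68), "M4": (17.33, 18.34), "M5": (16.33, 15.64)},
}

#: printed totals of the table above
FAMILY_TOTALS = {
    "M1": (138.36, 189.88), "M2": (134.59, 189.87), "M3": (137.81, 187.81),
    "M4": (137.11, 188.57), "M5": (137.75, 220.58),
}

#: family-of-four (lbs/week, USD/week) by protein food category; in M1 the
#: beef row is pooled red meat and the pork row is blank
FAMILY_PROTEIN = {
    "beef":           {"M1": (2.05, 9.00), "M2": (0.00, 0.00), "M3": (0.00, 0.00), "M4": (0.00, 0.00), "M5": (7.92, 56.11)},
    "pork":           {"M1": None,         "M2": (2.05, 6.90), "M3": (3.40, 11.48), "M4": (7.92, 26.71), "M5": (0.00, 0.00)},
    "cured meat":     {"M1": (0.00, 0.00), "M2": (0.00, 0.00), "M3": (0.00, 0.00), "M4": (0.00, 0.00), "M5": (0.00, 0.00)},
    "poultry":        {"M1": (5.37, 17.27), "M2": (5.67, 18.26), "M3": (4.52, 14.54), "M4": (0.00, 0.00), "M5": (0.00, 0.00)},
    "eggs":           {"M1": (2.08, 3.43), "M2": (1.99, 3.28), "M3": (1.93, 3.17), "M4": (1.51, 2.50), "M5": (1.60, 2.66)},
    "seafood":        {"M1": (2.72, 13.38), "M2": (2.72, 13.38), "M3": (2.72, 13.38), "M4": (2.72, 13.38), "M5": (2.72, 13.38)},
    "nuts-seeds-soy": {"M1": (1.97, 5.05), "M2": (1.89, 4.86), "M3": (1.89, 4.85), "M4": (1.93, 4.94), "M5": (1.75, 5.58)},
}

#: printed "All categories" totals of the protein table
FAMILY_PROTEIN_TOTALS = {
    "M1": (14.18, 48.13), "M2": (14.33, 46.68), "M3": (14.46, 47.42),
    "M4": (14.09, 47.53), "M5": (14.00, 77.73),
}

#: total market-basket cost (USD/week) per age-gender group and model; the
#: benchmark column is the corresponding published TFP 2021 estimate (absent
#: for the 4-13 y bands, whose stratification differs)
GROUP_COSTS = {
    "F4-13":  {"benchmark": None,  "M1": 40.21, "M2": 40.25, "M3": 39.70, "M4": 39.83, "M5": 47.09},
    "F14-19": {"benchmark": 48.77, "M1": 48.72, "M2": 48.73, "M3": 47.88, "M4": 48.38, "M5": 60.64},
    "F20-50": {"benchmark": 47.86, "M1": 47.81, "M2": 47.80, "M3": 47.39, "M4": 47.86, "M5": 56.29},
    "F51-70": {"benchmark": 44.42, "M1": 44.37, "M2": 44.37, "M3": 43.89, "M4": 44.66, "M5": 52.51},
    "M4-13":  {"benchmark": None,  "M1": 42.08, "M2": 42.05, "M3": 41.58, "M4": 41.73, "M5": 49.50},
    "M14-19": {"benchmark": 61.32, "M1": 61.45, "M2": 61.47, "M3": 60.62, "M4": 60.61, "M5": 78.18},
    "M20-50": {"benchmark": 59.65, "M1": 59.78, "M2": 59.77, "M3": 59.14, "M4": 59.15, "M5": 67.70},
    "M51-70": {"benchmark": 52.43, "M1": 52.36, "M2": 52.36, "M3": 51.52, "M4": 51.38, "M5": 60.05},
}

#: protein-foods cost (USD/week) per age-gender group and model
GROUP_PROTEIN_COSTS = {
    "F4-13":  {"benchmark": None,  "M1": 10.30, "M2": 9.76,  "M3": 10.40, "M4": 10.39, "M5": 16.93},
    "F14-19": {"benchmark": 12.14, "M1": 12.17, "M2": 11.44, "M3": 11.95, "M4": 12.02, "M5": 19.96},
    "F20-50": {"benchmark": 12.03, "M1": 12.40, "M2": 11.87, "M3": 12.00, "M4": 12.00, "M5": 19.71},
    "F51-70": {"benchmark": 11.53, "M1": 11.70, "M2": 11.22, "M3": 11.51, "M4": 11.55, "M5": 17.91},
    "M4-13":  {"benchmark": None,  "M1": 10.58, "M2": 10.09, "M3": 10.78, "M4": 10.78, "M5": 17.80},
    "M14-19": {"benchmark": 15.38, "M1": 15.04, "M2": 14.47, "M3": 18.01, "M4": 17.69, "M5": 31.45},
    "M20-50": {"benchmark": 14.49, "M1": 14.85, "M2": 14.96, "M3": 14.24, "M4": 14.36, "M5": 23.29},
    "M51-70": {"benchmark": 14.27, "M1": 14.72, "M2": 14.54, "M3": 14.40, "M4": 14.45, "M5": 23.18},
}
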