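"""Treatment-level reference statistics from the motivating field trial.

A five-year randomized-block experiment compared maize monoculture (MM)
against six maize-legume cover-crop intercropping systems (MI1 red clover,
MI2 sesbania, MI3 soybean, MI4 hairy vetch, MI5 common vetch, MI6 yellow
sweet clover), three replicate plots each.  Wet sieving split each soil
sample into four aggregate size classes (>2 mm, 0.25-2 mm, 0.053-0.25 mm and
<0.053 mm), and organic-carbon concentration was measured per class and in
bulk soil.

The published per-treatment means and standard deviations (n = 3) recorded
here serve two roles:

* default targets and noise levels for the synthetic-data generator, so the
  simulated study has the same location/scale structure as the field data;
* inputs for the desk-scale identity and contrast checks (macroaggregate
  shares, cross-table carbon-distribution reconstruction, group contrasts).

All mass proportions and carbon distributions are percentages that sum to
~100 across the four classes within a treatment; concentrations are
g C per kg of the respective fraction (or bulk soil).
"""

from __future__ import annotations

import pandas as pd

TREATMENTS = ("MM", "MI1", "MI2", "MI3", "MI4", "MI5", "MI6")

#: Treatment groupings that emerged from the aggregate-mass response: the two
#: taproot legumes vs the four fibrous-root legumes.  These are findings of
#: the study, configurable in the pipeline, not inputs.
GROUP1 = ("MI1", "MI2")
GROUP2 = ("MI3", "MI4", "MI5", "MI6")

SIZE_CLASS_LABELS = (">2mm", "0.25-2mm", "0.053-0.25mm", "<0.053mm")

_mass_rows = {
    "MM":  [10.16, 22.01, 55.06, 12.77],
    "MI1": [7.43, 29.57, 27.71, 35.29],
    "MI2": [10.16, 28.38, 33.82, 27.64],
    "MI3": [16.05, 34.20, 37.73, 12.02],
    "MI4": [19.74, 36.85, 27.96, 15.45],
    "MI5": [16.72, 38.67, 31.64, 12.98],
    "MI6": [16.12, 42.14, 30.20, 11.55],
}
_mass_sd_rows = {
    "MM":  [3.00, 1.42, 3.95, 1.93],
    "MI1": [2.87, 3.50, 3.54, 6.51],
    "MI2": [1.64, 1.19, 4.46, 2.28],
    "MI3": [4.80, 4.00, 3.58, 1.48],
    "MI4": [3.97, 3.55, 1.29, 0.92],
    "MI5": [3.51, 3.81, 4.48, 2.63],
    "MI6": [1.52, 5.42, 4.05, 2.24],
}

#: Mass proportion (%) of each wet-sieved size class, per treatment (mean, n=3).
MASS_PROPORTION_MEAN = pd.DataFrame.from_dict(
    _mass_rows, orient="index", columns=SIZE_CLASS_LABELS
).loc[list(TREATMENTS)]

#: Standard deviation of the mass proportions (n=3).
MASS_PROPORTION_SD = pd.DataFrame.from_dict(
    _mass_sd_rows, orient="index", columns=SIZE_CLASS_LABELS
).loc[list(TREATMENTS)]

#: Published macroaggregate mass share (R0.25-mass, %), per treatment.
R025_MASS = pd.Series(
    {"MM": 32.17, "MI1": 37.00, "MI2": 38.54, "MI3": 50.25,
     "MI4": 56.59, "MI5": 55.38, "MI6": 58.25}
).loc[list(TREATMENTS)]

_conc_rows = {
    "MM":  [19.63, 21.39, 16.37, 12.97],
    "MI1": [26.22, 28.40, 23.28, 15.88],
    "MI2": [30.97, 26.63, 23.31, 17.51],
    "MI3": [24.81, 24.14, 23.70, 15.52],
    "MI4": [24.65, 25.07, 20.97, 15.90],
    "MI5": [24.36, 24.84, 21.45, 16.02],
    "MI6": [26.39, 25.44, 22.67, 14.49],
}
_conc_sd_rows = {
    "MM":  [0.68, 0.34, 1.25, 1.48],
    "MI1": [2.52, 0.81, 0.45, 2.22],
    "MI2": [2.33, 1.60, 0.42, 1.98],
    "MI3": [2.66, 0.22, 1.74, 0.64],
    "MI4": [0.06, 0.51, 0.74, 0.24],
    "MI5": [0.10, 0.97, 0.31, 0.12],
    "MI6": [2.81, 1.22, 1.11, 0.94],
}

#: SOC concentration (g C kg^-1 of fraction) per size class, per treatment.
SOC_CONCENTRATION_MEAN = pd.DataFrame.from_dict(
    _conc_rows, orient="index", columns=SIZE_CLASS_LABELS
).loc[list(TREATMENTS)]

SOC_CONCENTRATION_SD = pd.DataFrame.from_dict(
    _conc_sd_rows, orient="index", columns=SIZE_CLASS_LABELS
).loc[list(TREATMENTS)]

#: Bulk-soil total SOC (g C kg^-1), per treatment.
TOTAL_SOC_MEAN = pd.Series(
    {"MM": 16.43, "MI1": 21.18, "MI2": 20.84, "MI3": 20.42,
     "MI4": 21.18, "MI5": 21.26, "MI6": 21.19}
).loc[list(TREATMENTS)]

TOTAL_SOC_SD = pd.Series(
    {"MM": 0.87, "MI1": 0.99, "MI2": 0.19, "MI3": 0.52,
     "MI4": 0.88, "MI5": 0.60, "MI6": 0.39}
).loc[list(TREATMENTS)]

_cdist_rows = {
    "MM":  [11.44, 27.12, 51.88, 9.56],
    "MI1": [8.75, 37.38, 28.66, 25.22],
    "MI2": [13.05, 32.49, 33.77, 20.69],
    "MI3": [16.86, 35.99, 39.04, 8.10],
    "MI4": [21.71, 41.23, 26.11, 10.95],
    "MI5": [18.09, 42.54, 30.14, 9.24],
    "MI6": [18.01, 45.64, 29.29, 7.06],
}
_cdist_sd_rows = {
    "MM":  [0.32, 1.27, 4.02, 1.84],
    "MI1": [3.74, 4.49, 2.83, 7.71],
    "MI2": [0.65, 2.15, 2.57, 0.98],
    "MI3": [3.47, 6.37, 6.57, 1.01],
    "MI4": [4.44, 4.66, 0.26, 0.56],
    "MI5": [3.85, 2.63, 4.33, 1.87],
    "MI6": [0.23, 5.68, 5.14, 0.74],
}

#: Aggregate-associated C distribution (%) per size class, per treatment:
#: the share of the total aggregate-held organic carbon stock residing in
#: each class.
C_DISTRIBUTION_MEAN = pd.DataFrame.from_dict(
    _cdist_rows, orient="index", columns=SIZE_CLASS_LABELS
).loc[list(TREATMENTS)]

C_DISTRIBUTION_SD = pd.DataFrame.from_dict(
    _cdist_sd_rows, orient="index", columns=SIZE_CLASS_LABELS
).loc[list(TREATMENTS)]

#: Published macroaggregate carbon share (R0.25-SOC, %), per treatment.
R025_SOC = pd.Series(
    {"MM": 38.56, "MI1": 46.13, "MI2": 45.54, "MI3": 52.86,
     "MI4": 62.93, "MI5": 60.63, "MI6": 63.65}
).loc[list(TREATMENTS)]
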