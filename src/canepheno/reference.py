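"""Published reference values for the ROC22 x Yacheng 9446 F1 study population.

The original 135-hybrid trial data are not publicly deposited, but the study's
published summary statistics, principal-component bookkeeping and selection
table are reusable inputs: they calibrate the synthetic trial generator and
let the composite-selection arithmetic be recomputed exactly.

All values are transcribed from the published study tables:

* :data:`TRAIT_CALIBRATION` -- per-trait descriptive statistics of the
  genotype means pooled over the 2020/2021 seasons (mean, SD, range,
  skewness, broad-sense heritability).
* :data:`PC_EIGENVALUES`, :data:`PC_PROPORTIONS`, :data:`PC_LOADINGS` --
  correlation-matrix PCA of the 11 traits (population + check parent).
* :data:`SELECTION_TABLE` -- PC scores F1..F4 and comprehensive value F of
  the 24 selected hybrids and the check parent ROC22.
* :data:`PUBLISHED_EQUATION` -- the stepwise sucrose-yield estimation model.
"""

from __future__ import annotations

import pandas as pd

#: Canonical trait order used throughout the package.
TRAITS = ["TR", "ETR", "SN", "SD", "IL", "SH", "B", "SW", "SC", "Y", "SY"]

#: Traits simulated directly (Y and SY are products, SC is tied to Brix).
BASE_TRAITS = ["TR", "ETR", "SN", "SD", "IL", "SH", "B", "SW"]

#: Long names and units, for report headers.
TRAIT_LABELS = {
    "TR": "Tillering ratio (%)",
    "ETR": "Effective tillering ratio (%)",
    "SN": "Stalk number (/m2)",
    "SD": "Stalk diameter (cm)",
    "IL": "Internode length (cm)",
    "SH": "Stalk height (m)",
    "B": "Brix (%)",
    "SW": "Stalk weight (kg)",
    "SC": "Sucrose content (%)",
    "Y": "Yield (t/ha)",
    "SY": "Sucrose yield (t/ha)",
}

# Per-trait genotype-mean statistics of the study population:
# (min, max, mean, sd, CV, skewness, excess kurtosis, H', h2).
_CAL_ROWS = {
    "TR": (1.61, 10.00, 3.89, 1.20, 0.31, 1.40, 4.49, 2.77, 0.81),
    "ETR": (0.94, 7.59, 2.51, 1.07, 0.43, 1.86, 5.06, 2.64, 0.75),
    "SN": (1.30, 9.30, 5.07, 1.44, 0.28, -0.09, 0.61, 2.92, 0.78),
    "SD": (1.95, 3.39, 2.61, 0.28, 0.11, 0.40, 0.32, 2.92, 0.80),
    "IL": (9.43, 16.78, 13.32, 1.41, 0.11, -0.02, -0.20, 2.96, 0.84),
    "SH": (2.10, 4.31, 3.16, 0.36, 0.12, 0.30, 0.69, 2.96, 0.83),
    "B": (16.54, 30.31, 20.87, 1.82, 0.09, 1.16, 5.57, 2.86, 0.80),
    "SW": (0.74, 2.92, 1.72, 0.41, 0.24, 0.53, 0.47, 2.90, 0.82),
    "SC": (10.20, 18.71, 14.89, 1.97, 0.13, 1.16, 5.57, 2.86, 0.80),
    "Y": (18.75, 142.35, 77.25, 24.00, 0.31, 0.00, 0.16, 2.98, 0.75),
    "SY": (2.10, 21.75, 11.55, 4.06, 0.35, 0.12, 0.23, 2.98, 0.80),
}

TRAIT_CALIBRATION = pd.DataFrame.from_dict(
    _CAL_ROWS,
    orient="index",
    columns=["min", "max", "mean", "sd", "cv", "skewness", "kurtosis", "shannon", "h2"],
).loc[TRAITS]

#: Eigenvalues of the first four PCs of the 11-trait correlation matrix.
PC_EIGENVALUES = [3.31, 2.88, 1.43, 1.28]

#: Variance proportions (%) of the first four PCs.
PC_PROPORTIONS = [30.11, 26.19, 12.97, 11.66]

#: Published cumulative proportion (%) of the four retained PCs.
PC_CUMULATIVE = 80.93

#: Eigenvector (loading) matrix of the four retained PCs, trait x PC.
PC_LOADINGS = pd.DataFrame(
    {
        "PC1": [0.19, 0.30, 0.40, -0.15, 0.23, 0.15, 0.41, -0.04, 0.41, 0.33, 0.42],
        "PC2": [-0.29, -0.27, -0.08, 0.46, 0.10, 0.29, -0.07, 0.54, -0.07, 0.37, 0.30],
        "PC3": [-0.30, -0.38, -0.30, -0.03, -0.01, 0.11, 0.53, 0.01, 0.53, -0.31, -0.14],
        "PC4": [-0.23, -0.02, 0.19, 0.24, -0.64, -0.58, 0.12, -0.07, 0.12, 0.17, 0.19],
    },
    index=TRAITS,
)

#: Identifier of the high-yield check parent.
CHECK_PARENT = "ROC22"

# PC scores F1..F4 and published comprehensive value F of the 24 hybrids
# selected over the check parent, plus the check parent itself.
_SELECTION_ROWS = [
    ("F1-2", "Group2", 65.83, 42.62, -20.78, 17.76, 37.51),
    ("F1-5", "Group1", 66.38, 52.41, -25.36, 19.44, 40.40),
    ("F1-9", "Group1", 64.26, 45.21, -20.99, 17.21, 37.66),
    ("F1-13", "Group2", 63.43, 41.99, -17.76, 15.66, 36.59),
    ("F1-15", "Group2", 62.12, 40.15, -15.48, 14.43, 35.70),
    ("F1-22", "Group1", 63.47, 46.51, -20.67, 14.06, 37.38),
    ("F1-23", "Group1", 72.23, 37.50, -8.52, 14.52, 39.73),
    ("F1-43", "Group2", 71.76, 47.57, -26.58, 18.28, 40.47),
    ("F1-59", "Group1", 76.43, 57.54, -28.87, 20.94, 45.45),
    ("F1-71", "Group1", 67.94, 49.56, -22.29, 17.97, 40.33),
    ("F1-73", "Group2", 66.58, 45.47, -21.40, 15.47, 38.29),
    ("F1-76", "Group2", 64.62, 45.50, -19.48, 15.96, 37.94),
    ("F1-84", "Group1", 78.27, 59.97, -30.78, 22.12, 46.78),
    ("F1-85", "Group1", 64.90, 47.41, -19.41, 17.18, 38.85),
    ("F1-86", "Group1", 66.94, 49.02, -24.39, 15.17, 39.04),
    ("F1-89", "Group1", 73.61, 56.37, -26.28, 20.84, 44.42),
    ("F1-92", "Group2", 70.40, 49.96, -25.74, 19.13, 40.99),
    ("F1-93", "Group1", 59.67, 42.24, -16.60, 16.10, 35.53),
    ("F1-99", "Group2", 62.33, 42.47, -17.56, 15.02, 36.28),
    ("F1-102", "Group2", 66.11, 44.26, -18.27, 16.21, 38.33),
    ("F1-110", "Group1", 60.72, 43.78, -18.93, 15.66, 35.98),
    ("F1-115", "Group2", 65.73, 45.10, -22.61, 17.18, 37.90),
    ("F1-124", "Group1", 62.45, 42.94, -16.88, 17.18, 36.90),
    ("F1-129", "Group2", 63.64, 41.55, -16.95, 15.56, 36.65),
    ("ROC22", "", 60.04, 41.40, -14.84, 14.63, 35.47),
]

SELECTION_TABLE = pd.DataFrame(
    _SELECTION_ROWS,
    columns=["genotype", "group", "F1", "F2", "F3", "F4", "F"],
).set_index("genotype")

#: Stepwise sucrose-yield estimation model: SY = sum(coef * trait) + intercept.
PUBLISHED_EQUATION = {
    "SN": 2.01,
    "SD": 8.32,
    "B": 0.79,
    "SH": 3.44,
    "Intercept": -47.64,
}

#: Alternative three-trait model reported alongside the main one; evaluated at
#: the population trait means it is far from the observed mean sucrose yield,
#: so it is provided for completeness only.
ALTERNATIVE_EQUATION = {
    "SN": 1.97,
    "B": 0.80,
    "SW": 6.38,
    "Intercept": -34.03,
}
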