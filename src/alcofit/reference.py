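"""Published gamma-fit estimates for US drinkers, NESARC 2001-2002.

The table below reproduces the published stratum-level parameter estimates
for the gamma model of grams-ethanol-per-day among current drinkers in the
2001-2002 US National Epidemiologic Survey on Alcohol and Related Conditions
(NESARC), together with the corresponding upshifted distributions (mean
matched to adult per-capita consumption, SD predicted from a mean + sex
regression).  Columns per row:

    sex, ethnicity, age group,
    original shape k, original scale theta (g/day),
    shifted mean (g/day), shifted SD (g/day),
    shifted shape k, shifted scale theta (g/day)

The rows serve two purposes in this package: they are the calibration data
from which the default SD-regression coefficients are recovered by least
squares (see :func:`alcofit.triangulation.fit_sd_regression`), and they
anchor the moment-relation tests (shape = mean^2/SD^2, scale = SD^2/mean).
"""

from __future__ import annotations

import pandas as pd

MEN = "men"
WOMEN = "women"

#: sex, ethnicity, age, k, theta, shifted mean, shifted SD, shifted k, shifted theta
NESARC_SHIFT_TABLE: tuple[tuple, ...] = (
    (MEN, "White", "All Ages", 0.436, 48.132, 40.268, 47.275, 0.726, 55.501),
    (MEN, "White", "18 - 34", 0.450, 58.550, 50.586, 59.388, 0.726, 69.721),
    (MEN, "White", "35 - 54", 0.441, 46.951, 38.993, 45.778, 0.726, 53.743),
    (MEN, "White", "55+", 0.430, 37.486, 29.713, 34.883, 0.726, 40.953),
    (MEN, "Black", "All Ages", 0.387, 65.821, 49.570, 58.195, 0.726, 68.321),
    (MEN, "Black", "18 - 34", 0.380, 65.850, 47.957, 56.301, 0.726, 66.098),
    (MEN, "Black", "35 - 54", 0.406, 65.155, 52.860, 62.058, 0.726, 72.856),
    (MEN, "Black", "55+", 0.362, 66.530, 44.642, 52.410, 0.726, 61.529),
    (MEN, "Native", "All Ages", 0.354, 88.399, 56.528, 66.363, 0.726, 77.911),
    (MEN, "Native", "18 - 34", 0.354, 111.130, 70.687, 82.987, 0.726, 97.427),
    (MEN, "Native", "35 - 54", 0.376, 87.400, 58.111, 68.223, 0.726, 80.094),
    (MEN, "Native", "55+", 0.345, 46.584, 27.412, 32.181, 0.726, 37.781),
    (MEN, "Asian/Pac. Islander", "All Ages", 0.417, 28.224, 22.544, 26.467, 0.726, 31.072),
    (MEN, "Asian/Pac. Islander", "18 - 34", 0.460, 27.784, 26.022, 30.549, 0.726, 35.865),
    (MEN, "Asian/Pac. Islander", "35 - 54", 0.412, 30.006, 22.784, 26.749, 0.726, 31.403),
    (MEN, "Asian/Pac. Islander", "55+", 0.345, 17.665, 11.801, 13.854, 0.726, 16.265),
    (MEN, "Hispanic", "All Ages", 0.426, 40.756, 40.726, 47.812, 0.726, 56.131),
    (MEN, "Hispanic", "18 - 34", 0.422, 43.417, 36.148, 42.438, 0.726, 49.823),
    (MEN, "Hispanic", "35 - 54", 0.433, 40.633, 52.215, 61.300, 0.726, 71.967),
    (MEN, "Hispanic", "55+", 0.426, 31.678, 23.517, 27.609, 0.726, 32.413),
    (WOMEN, "White", "All Ages", 0.391, 19.778, 14.785, 18.361, 0.648, 22.801),
    (WOMEN, "White", "18 - 34", 0.399, 23.009, 17.353, 21.376, 0.659, 26.330),
    (WOMEN, "White", "35 - 54", 0.410, 18.282, 14.224, 17.702, 0.646, 22.030),
    (WOMEN, "White", "55+", 0.366, 17.852, 12.495, 15.672, 0.636, 19.657),
    (WOMEN, "Black", "All Ages", 0.316, 27.729, 20.069, 24.565, 0.668, 30.066),
    (WOMEN, "Black", "18 - 34", 0.311, 30.996, 19.844, 24.299, 0.667, 29.756),
    (WOMEN, "Black", "35 - 54", 0.326, 27.461, 22.642, 27.585, 0.674, 33.607),
    (WOMEN, "Black", "55+", 0.310, 19.494, 12.313, 15.459, 0.634, 19.408),
    (WOMEN, "Native", "All Ages", 0.295, 54.514, 33.405, 40.221, 0.690, 48.427),
    (WOMEN, "Native", "18 - 34", 0.297, 87.190, 49.135, 58.688, 0.701, 70.098),
    (WOMEN, "Native", "35 - 54", 0.304, 42.472, 27.347, 33.109, 0.682, 40.084),
    (WOMEN, "Native", "55+", 0.336, 20.350, 19.866, 24.326, 0.667, 29.787),
    (WOMEN, "Asian/Pac. Islander", "All Ages", 0.318, 24.855, 14.464, 17.984, 0.647, 22.360),
    (WOMEN, "Asian/Pac. Islander", "18 - 34", 0.311, 42.172, 24.428, 29.682, 0.677, 36.065),
    (WOMEN, "Asian/Pac. Islander", "35 - 54", 0.441, 6.702, 5.460, 7.413, 0.542, 10.065),
    (WOMEN, "Asian/Pac. Islander", "55+", 0.360, 5.835, 2.430, 3.856, 0.397, 6.118),
    (WOMEN, "Hispanic", "All Ages", 0.341, 17.855, 18.482, 22.701, 0.663, 27.883),
    (WOMEN, "Hispanic", "18 - 34", 0.325, 23.545, 15.423, 19.109, 0.651, 23.677),
    (WOMEN, "Hispanic", "35 - 54", 0.377, 12.815, 24.680, 29.977, 0.678, 36.411),
    (WOMEN, "Hispanic", "55+", 0.330, 13.513, 10.682, 13.544, 0.622, 17.173),
)

COLUMNS = (
    "sex",
    "ethnicity",
    "age_group",
    "k",
    "theta",
    "shifted_mean",
    "shifted_sd",
    "shifted_k",
    "shifted_theta",
)


def load_reference_strata(age_specific_only: bool = False) -> pd.DataFrame:
    """Return the published stratum table as a DataFrame.

    Parameters
    ----------
    age_specific_only
        If True, drop the "All Ages" summary rows and keep the
        30 sex x ethnicity x age-group strata.
    """
    df = pd.DataFrame(list(NESARC_SHIFT_TABLE), columns=COLUMNS)
    if age_specific_only:
        df = df[df["age_group"] != "All Ages"].reset_index(drop=True)
    return df
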