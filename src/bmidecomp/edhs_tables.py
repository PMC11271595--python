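"""Published summary estimates from the Ethiopian DHS women's BMI analyses.

These are the printed, survey-weighted summary numbers for the 2000–2016
EDHS rounds (restricted to non-pregnant, non-puerperal women with measured
BMI): national mean BMI with standard errors, the national/urban/rural WHO
band percentages, and the per-subgroup underweight and overweight
percentages for 2000 and 2016 with their printed percentage-point
differences.  The underlying microdata are registration-gated at the DHS
program, so these tables are the desk-reproducible inputs: the trend
operations of :mod:`bmidecomp.trend_metrics` applied to them reproduce the
published change metrics (0.88 kg/m² national BMI rise, underweight:
overweight ratios 8.95 → 2.99 nationally and 2.06 → 0.72 in urban areas,
and the subgroup percentage-point differences).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "YEARS",
    "BMI_MEAN_SE",
    "PREVALENCE",
    "SUBGROUP_PPT",
    "prevalence_percent",
    "bmi_mean",
]

YEARS = ("2000", "2005", "2011", "2016")

#: National weighted mean BMI (kg/m^2) with standard error, by survey year.
BMI_MEAN_SE = {
    "2000": (19.74, 0.02),
    "2005": (20.11, 0.04),
    "2011": (20.20, 0.03),
    "2016": (20.62, 0.03),
}

#: WHO band percentages by stratum and year (overweight pools obese).
_PREV_ROWS = [
    # stratum, year, normal, underweight, overweight(merged)
    ("national", "2000", 65.26, 31.25, 3.49),
    ("national", "2005", 68.10, 27.34, 4.56),
    ("national", "2011", 66.47, 27.72, 5.81),
    ("national", "2016", 69.08, 23.18, 7.74),
    ("urban", "2000", 65.20, 23.43, 11.38),
    ("urban", "2005", 66.11, 19.24, 14.65),
    ("urban", "2011", 64.68, 20.38, 14.93),
    ("urban", "2016", 63.58, 15.24, 21.18),
    ("rural", "2000", 65.28, 33.19, 1.54),
    ("rural", "2005", 68.59, 29.35, 2.05),
    ("rural", "2011", 67.09, 30.24, 2.68),
    ("rural", "2016", 70.76, 25.62, 3.63),
]
PREVALENCE = pd.DataFrame(
    _PREV_ROWS, columns=["stratum", "year", "normal", "underweight", "overweight"]
)

#: Subgroup underweight/overweight percentages, 2016 and 2000, with the
#: printed percentage-point differences (kept for cross-validation; the
#: package recomputes differences from the level columns).
_PPT_ROWS = [
    # group_var, level, uw_2016, uw_2000, uw_diff, ow_2016, ow_2000, ow_diff
    ("region", "Tigray", 35.24, 36.20, -0.96, 5.96, 1.22, 4.74),
    ("region", "Afar", 40.44, 41.69, -1.25, 8.05, 4.67, 3.38),
    ("region", "Amhara", 23.64, 32.80, -9.16, 3.48, 1.84, 1.64),
    ("region", "Oromia", 25.52, 29.68, -4.16, 7.63, 3.51, 4.12),
    ("region", "Somali", 31.67, 48.79, -17.12, 15.02, 4.16, 10.86),
    ("region", "Benishangul-Gumz", 20.75, 39.53, -18.78, 7.68, 2.01, 5.67),
    ("region", "SNNP", 15.76, 32.09, -16.33, 5.86, 2.79, 3.07),
    ("region", "Gambela", 31.43, 39.90, -8.47, 8.72, 1.06, 7.66),
    ("region", "Harari", 21.49, 25.37, -3.88, 20.49, 10.38, 10.11),
    ("region", "Addis Ababa", 13.80, 18.08, -4.28, 29.42, 16.59, 12.83),
    ("region", "Dire Dawa", 22.94, 27.76, -4.82, 21.40, 13.25, 8.15),
    ("head_sex", "male", 23.67, 31.86, -8.19, 6.73, 2.87, 3.86),
    ("head_sex", "female", 21.79, 29.29, -7.50, 10.83, 5.64, 5.19),
    ("age_group", "15-19", 29.42, 38.85, -9.43, 3.66, 2.19, 1.47),
    ("age_group", "20-24", 21.15, 23.96, -2.81, 5.58, 3.30, 2.28),
    ("age_group", "25-29", 18.90, 25.16, -6.26, 8.10, 4.06, 4.04),
    ("age_group", "30-34", 19.92, 24.83, -4.91, 10.75, 3.95, 6.80),
    ("age_group", "35-39", 22.60, 30.66, -8.06, 10.72, 4.94, 5.78),
    ("age_group", "40-44", 22.68, 31.92, -9.24, 11.86, 4.90, 6.96),
    ("age_group", "45-49", 25.33, 39.10, -13.77, 9.45, 3.36, 6.09),
    ("education", "none", 24.18, 32.24, -8.06, 4.85, 2.11, 2.74),
    ("education", "primary", 24.54, 31.07, -6.53, 7.42, 4.60, 2.82),
    ("education", "secondary", 16.99, 24.68, -7.69, 12.63, 11.19, 1.44),
    ("education", "higher", 19.94, 18.23, 1.71, 22.94, 27.29, -4.35),
    ("contraceptive", "no method", 24.91, 31.82, -6.91, 7.25, 2.91, 4.34),
    ("contraceptive", "any method", 18.95, 23.62, -4.67, 9.09, 11.72, -2.63),
    ("residence", "urban", 15.24, 23.43, -8.19, 21.25, 11.42, 9.83),
    ("residence", "rural", 25.62, 33.19, -7.57, 3.66, 1.58, 2.08),
    ("household_members", "<5", 22.13, 28.74, -6.61, 8.85, 3.67, 5.18),
    ("household_members", ">=5", 23.77, 32.35, -8.58, 7.20, 3.47, 3.73),
    ("children_under5", "<=1", 23.02, 31.09, -8.07, 8.48, 4.09, 4.39),
    ("children_under5", ">1", 23.78, 31.65, -7.87, 5.30, 2.15, 3.15),
    ("children_ever_born", "<=2", 23.12, 31.78, -8.66, 7.89, 3.73, 4.16),
    ("children_ever_born", ">2", 23.26, 30.59, -7.33, 7.65, 3.28, 4.37),
    ("births_last5y", "<=1", 23.22, 32.33, -9.11, 8.35, 3.81, 4.54),
    ("births_last5y", ">1", 22.98, 26.54, -3.56, 4.38, 2.32, 2.06),
    ("religion", "orthodox", 22.84, 30.29, -7.45, 8.97, 3.87, 5.10),
    ("religion", "muslim", 27.35, 33.74, -6.39, 6.55, 3.20, 3.35),
    ("religion", "others", 19.17, 30.16, -10.99, 7.06, 3.14, 3.92),
    ("union", "never", 25.53, 35.89, -10.36, 6.02, 3.71, 2.31),
    ("union", "currently", 22.09, 29.15, -7.06, 8.03, 3.10, 4.93),
    ("union", "formerly", 22.61, 30.09, -7.48, 11.48, 4.89, 6.59),
    ("working", "no", 24.99, 33.95, -8.96, 5.52, 3.76, 1.76),
    ("working", "yes", 19.87, 29.27, -9.40, 11.95, 3.36, 8.59),
    ("earnings", "not paid", 22.53, 32.44, -9.91, 4.96, 1.74, 3.22),
    ("earnings", "cash only", 17.67, 25.93, -8.26, 15.35, 6.30, 9.05),
    ("earnings", "cash and in-kind", 18.60, 33.09, -14.49, 8.65, 1.34, 7.31),
    ("earnings", "in-kind only", 25.92, 29.18, -3.26, 5.29, 1.02, 4.27),
]
SUBGROUP_PPT = pd.DataFrame(
    _PPT_ROWS,
    columns=[
        "group_var",
        "level",
        "uw_2016",
        "uw_2000",
        "uw_diff_printed",
        "ow_2016",
        "ow_2000",
        "ow_diff_printed",
    ],
)


def prevalence_percent(stratum: str, year: str, category: str) -> float:
    """Published band percentage for one (stratum, year)."""
    row = PREVALENCE[(PREVALENCE.stratum == stratum) & (PREVALENCE.year == year)]
    if row.empty or category not in ("normal", "underweight", "overweight"):
        raise KeyError((stratum, year, category))
    return float(row.iloc[0][category])


def bmi_mean(year: str) -> float:
    """Published national weighted mean BMI for one survey year."""
    return BMI_MEAN_SE[year][0]
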