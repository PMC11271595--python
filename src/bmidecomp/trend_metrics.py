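"""Survey-weighted descriptive and trend statistics.

Prevalence of the WHO BMI bands (and the merged overweight view), weighted
means with linearized standard errors, percentage-point differences between
survey rounds, the underweight:overweight ratio used as a double-burden
progress proxy, and long-format trend tables stratified by residence or any
categorical covariate.  All estimates apply the individual sampling weights
and are invariant to positive rescaling of the weights; internal chaining
keeps full precision and rounds only at presentation (2 decimals, matching
survey-report convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_records import (
    BmiCategory,
    ConfigurationError,
    SurveyWave,
    classify_bmi_array,
    dichotomize_array,
)

__all__ = [
    "UndefinedEstimateError",
    "weighted_prevalence",
    "ppt_difference",
    "uw_ow_ratio",
    "weighted_mean",
    "category_prevalences",
    "trend_table",
    "prevalence_z_test",
    "PrevalenceTable",
]

CATEGORIES = ("underweight", "normal", "overweight", "obese")


class UndefinedEstimateError(ValueError):
    """The requested estimate has an empty or zero-weight denominator."""


def _stratum_mask(wave: SurveyWave, stratum_filter) -> np.ndarray:
    if stratum_filter is None:
        return np.ones(wave.n, dtype=bool)
    if callable(stratum_filter):
        return np.asarray(stratum_filter(wave.frame), dtype=bool)
    if isinstance(stratum_filter, tuple) and len(stratum_filter) == 2:
        stratum_filter = {stratum_filter[0]: stratum_filter[1]}
    if isinstance(stratum_filter, Mapping):
        mask = np.ones(wave.n, dtype=bool)
        for name, label in stratum_filter.items():
            if name not in wave.frame.columns:
                raise ConfigurationError(f"unknown stratum covariate {name!r}")
            mask &= (wave.frame[name].astype(str) == str(label)).to_numpy()
        return mask
    raise ConfigurationError(f"unsupported stratum filter {stratum_filter!r}")


_BAND_BOUNDS = {
    "underweight": (-np.inf, 18.5),
    "normal": (18.5, 25.0),
    "overweight": (25.0, 30.0),
    "obese": (30.0, np.inf),
}


def _indicator(bmi: np.ndarray, outcome) -> np.ndarray:
    if isinstance(outcome, BmiCategory) or (
        isinstance(outcome, str) and outcome in CATEGORIES
    ):
        classify_bmi_array(bmi)  # validates measured & plausible
        lo, hi = _BAND_BOUNDS[BmiCategory(outcome).value]
        return ((bmi >= lo) & (bmi < hi)).astype(float)
    if outcome in ("underweight_binary", "overweight_merged"):
        return dichotomize_array(bmi, outcome.replace("_binary", ""))
    raise ConfigurationError(f"unknown outcome/category {outcome!r}")


def weighted_prevalence(
    wave: SurveyWave, outcome, stratum_filter=None
) -> float:
    """Weighted percentage, 100 · Σ w·1[condition] / Σ w, over the filtered
    records.

    ``outcome`` is a 4-level :class:`BmiCategory` (or its label) or the
    merged binary view ``"overweight_merged"``.  An empty or zero-weight
    stratum raises :class:`UndefinedEstimateError` — never a silent zero.
    """
    mask = _stratum_mask(wave, stratum_filter)
    w = wave.weights[mask]
    if w.size == 0 or w.sum() <= 0:
        raise UndefinedEstimateError(
            f"stratum {stratum_filter!r} empty/zero-weight in wave {wave.year}"
        )
    bmi = wave.frame["bmi"].to_numpy(dtype=float)[mask]
    ind = _indicator(bmi, outcome)
    return float(100.0 * (w @ ind) / w.sum())


def ppt_difference(p_late: float, p_early: float) -> float:
    """Percentage-point change, later minus earlier, reported to 2 decimals."""
    return round(float(p_late) - float(p_early), 2)


def uw_ow_ratio(p_underweight: float, p_overweight: float) -> float:
    """Underweight:overweight prevalence ratio (2 decimals), a proxy for
    progress against the double burden — large when underweight dominates,
    below 1 once overweight overtakes it."""
    if not (p_overweight > 0):
        raise UndefinedEstimateError(
            f"overweight prevalence must be positive, got {p_overweight}"
        )
    return round(float(p_underweight) / float(p_overweight), 2)


def weighted_mean(
    wave: SurveyWave, variable: str = "bmi", stratum_filter=None
) -> tuple[float, float]:
    """Weighted mean of a numeric field with its linearized standard error.

    SE uses the weighted-ratio (Taylor) estimator
    sqrt(Σ w_i^2 (v_i − m)^2) / Σ w_i; both the mean and the SE are invariant
    to rescaling all weights by a positive constant.
    """
    mask = _stratum_mask(wave, stratum_filter)
    if variable not in wave.frame.columns:
        raise ConfigurationError(f"unknown variable {variable!r}")
    v = pd.to_numeric(wave.frame[variable], errors="coerce").to_numpy(dtype=float)[mask]
    w = wave.weights[mask]
    ok = np.isfinite(v)
    v, w = v[ok], w[ok]
    if w.size == 0 or w.sum() <= 0:
        raise UndefinedEstimateError(
            f"stratum {stratum_filter!r} empty for {variable!r} in wave {wave.year}"
        )
    sw = w.sum()
    m = float((w @ v) / sw)
    se = float(np.sqrt(np.sum((w * (v - m)) ** 2)) / sw)
    return m, se


def category_prevalences(wave: SurveyWave, stratum_filter=None) -> dict[str, float]:
    """All four WHO band percentages for one (sub)population; sums to 100."""
    return {
        cat: weighted_prevalence(wave, cat, stratum_filter) for cat in CATEGORIES
    }


def prevalence_z_test(
    wave_a: SurveyWave, wave_b: SurveyWave, outcome, stratum_filter=None
) -> tuple[float, float]:
    """Design-naive two-sample weighted-proportion z test for a trend change.

    Caveat: treats weighted proportions as if from independent simple random
    samples of the (weight-based) effective sizes; it ignores clustering and
    will overstate precision on clustered designs.  Offered as a rough
    screen only.
    """
    out = []
    for wave in (wave_a, wave_b):
        mask = _stratum_mask(wave, stratum_filter)
        w = wave.weights[mask]
        if w.size == 0 or w.sum() <= 0:
            raise UndefinedEstimateError("empty stratum in z test")
        bmi = wave.frame["bmi"].to_numpy(dtype=float)[mask]
        p = float((w @ _indicator(bmi, outcome)) / w.sum())
        n_eff = float(w.sum() ** 2 / (w @ w))  # Kish effective size
        out.append((p, n_eff))
    (p1, n1), (p2, n2) = out
    pool = (p1 * n1 + p2 * n2) / (n1 + n2)
    se = np.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
    if se == 0:
        raise UndefinedEstimateError("degenerate pooled proportion")
    z = (p1 - p2) / se
    return float(z), float(2 * stats.norm.sf(abs(z)))


@dataclass
class PrevalenceTable:
    """Long-format prevalence rows per (stratum, wave, category) plus
    first-to-last percentage-point differences per stratum and category."""

    frame: pd.DataFrame
    differences: pd.DataFrame

    def validate_partition(self, tol: float = 0.05) -> None:
        """The four category percentages sum to 100 within rounding
        tolerance in every defined (stratum, wave) cell."""
        defined = self.frame[
            self.frame["defined"] & self.frame["category"].isin(CATEGORIES)
        ]
        sums = defined.groupby(["stratum_var", "stratum_level", "year"])["percent"].sum()
        bad = sums[(sums - 100.0).abs() > tol]
        if len(bad):
            raise AssertionError(f"category percentages do not partition: {bad}")


def trend_table(
    waves: Sequence[SurveyWave], strata: Sequence[str] | None = None
) -> PrevalenceTable:
    """Category prevalence per wave, nationally and within each level of the
    requested stratifying covariates, with percentage-point differences
    between the first and last wave.

    A stratum level absent (or zero-weight) in some wave keeps its row,
    flagged ``defined=False`` with NaN percent, rather than being dropped.
    """
    if len(waves) < 2:
        raise ConfigurationError("trend_table needs at least two waves")
    schema0 = waves[0].schema
    for wave in waves[1:]:
        for cov in schema0:
            other = wave.schema.get(cov.name)  # raises SchemaError if absent
            if other.categories != cov.categories:
                from .core_records import SchemaError

                raise SchemaError(
                    f"covariate {cov.name!r} categories differ across waves"
                )
    layers: list[tuple[str, str, object]] = [("national", "all", None)]
    for name in strata or ():
        cov = schema0.get(name)
        layers.extend((name, cat, (name, cat)) for cat in cov.categories)
    rows = []
    for wave in waves:
        for var, level, filt in layers:
            for cat in CATEGORIES + ("overweight_merged",):
                try:
                    pct = weighted_prevalence(wave, cat, filt)
                    mask = _stratum_mask(wave, filt)
                    denom = float(wave.weights[mask].sum())
                    defined = True
                except UndefinedEstimateError:
                    pct, denom, defined = np.nan, 0.0, False
                rows.append(
                    {
                        "stratum_var": var,
                        "stratum_level": level,
                        "year": wave.year,
                        "category": cat if isinstance(cat, str) else cat.value,
                        "percent": pct,
                        "denominator": denom,
                        "defined": defined,
                    }
                )
    frame = pd.DataFrame(rows)
    first, last = waves[0].year, waves[-1].year
    diff_rows = []
    for (var, level, cat), grp in frame.groupby(
        ["stratum_var", "stratum_level", "category"], sort=False
    ):
        by_year = grp.set_index("year")
        p_first = by_year.loc[first]
        p_last = by_year.loc[last]
        ok = bool(p_first["defined"]) and bool(p_last["defined"])
        diff_rows.append(
            {
                "stratum_var": var,
                "stratum_level": level,
                "category": cat,
                "year_early": first,
                "year_late": last,
                "ppt_difference": (
                    ppt_difference(p_last["percent"], p_first["percent"])
                    if ok
                    else np.nan
                ),
                "defined": ok,
            }
        )
    return PrevalenceTable(frame=frame, differences=pd.DataFrame(diff_rows))
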