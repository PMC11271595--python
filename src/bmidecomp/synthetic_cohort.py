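"""Synthetic two-wave survey cohorts with known decomposition ground truth.

The generator emulates the statistical skeleton of a DHS-style women's
survey: fully categorical covariates drawn from wave-specific compositions,
a binary nutrition outcome generated from wave-specific logit coefficients,
gamma-distributed individual sampling weights, enumeration-area clusters
(optionally with a logit-scale random intercept), and pregnancy/puerperium/
missing-BMI flags at configurable rates so the eligibility filter has work
to do.  Records carry a BMI drawn uniformly from the band implied by the
generated outcome, so classification and dichotomization round-trip.

``population_truth`` evaluates the decomposition identity exactly, by
enumerating the joint covariate cells of each wave: no sampling, no model
fitting — it is the independent oracle the estimation pipeline is tested
against.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

from .core_records import (
    ConfigurationError,
    Covariate,
    CovariateSchema,
    SchemaError,
    SurveyWave,
)
from .weighted_logit import DesignSpec, NormalizedFit, normalize_categorical
from .decomposition import yun_detailed as _yun_detailed
from . import decomposition as _decomp

__all__ = [
    "WaveConfig",
    "ScenarioConfig",
    "PopulationTruth",
    "generate_wave",
    "population_truth",
    "make_scenario",
    "PRESETS",
]


@dataclass(frozen=True)
class WaveConfig:
    """Generator truth for one survey wave.

    ``composition`` maps covariate name -> {category: probability}
    (covariates drawn independently unless the scenario supplies a joint
    table).  ``coefficients`` maps design-column name (``intercept`` or
    ``name[category]``; reference categories implicitly 0) -> logit-scale
    coefficient.  ``weight_model`` is ``("equal",)`` or
    ``("gamma", shape, scale)``; ``exclusion_rates`` are the probabilities of
    the pregnant / puerperal / missing-BMI flags.
    """

    year: str
    n: int
    composition: Mapping[str, Mapping[str, float]]
    coefficients: Mapping[str, float]
    weight_model: tuple = ("equal",)
    n_clusters: int = 100
    cluster_sigma: float = 0.0
    exclusion_rates: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigurationError("wave n must be >= 1")
        for name, probs in self.composition.items():
            total = float(sum(probs.values()))
            if abs(total - 1.0) > 1e-12:
                raise ConfigurationError(
                    f"composition of {name!r} sums to {total}, not 1"
                )


@dataclass(frozen=True)
class ScenarioConfig:
    """A fully specified two-wave scenario: schema, per-wave truth, outcome
    and the BMI emission bands consistent with that outcome."""

    name: str
    outcome: str
    schema: CovariateSchema
    wave_a: WaveConfig            # later survey
    wave_b: WaveConfig            # earlier survey
    bmi_emission: Mapping[int, tuple[float, float]]
    joint: Mapping[str, Mapping[tuple, float]] | None = None

    def __post_init__(self) -> None:
        names = set(self.schema.names)
        for wc in (self.wave_a, self.wave_b):
            if set(wc.composition) != names:
                raise ConfigurationError(
                    f"wave {wc.year}: composition covariates "
                    f"{sorted(wc.composition)} != schema {sorted(names)}"
                )
            valid = {"intercept"}
            for cov in self.schema:
                if set(wc.composition[cov.name]) != set(cov.categories):
                    raise ConfigurationError(
                        f"wave {wc.year}: composition categories of "
                        f"{cov.name!r} do not match the schema"
                    )
                valid.update(
                    f"{cov.name}[{c}]" for c in cov.categories if c != cov.reference
                )
            unknown = set(wc.coefficients) - valid
            if unknown:
                raise ConfigurationError(
                    f"wave {wc.year}: coefficients for unknown design columns "
                    f"{sorted(unknown)}"
                )

    @property
    def spec(self) -> DesignSpec:
        return DesignSpec.from_schema(self.schema)

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        def wave_dict(wc: WaveConfig) -> dict:
            return {
                "year": wc.year,
                "n": wc.n,
                "composition": {k: dict(v) for k, v in wc.composition.items()},
                "coefficients": dict(wc.coefficients),
                "weight_model": list(wc.weight_model),
                "n_clusters": wc.n_clusters,
                "cluster_sigma": wc.cluster_sigma,
                "exclusion_rates": list(wc.exclusion_rates),
            }

        return {
            "name": self.name,
            "outcome": self.outcome,
            "schema": self.schema.to_dict(),
            "wave_a": wave_dict(self.wave_a),
            "wave_b": wave_dict(self.wave_b),
            "bmi_emission": {str(k): list(v) for k, v in self.bmi_emission.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScenarioConfig":
        def wave(dd: Mapping) -> WaveConfig:
            return WaveConfig(
                year=str(dd["year"]),
                n=int(dd["n"]),
                composition={k: dict(v) for k, v in dd["composition"].items()},
                coefficients=dict(dd["coefficients"]),
                weight_model=tuple(dd.get("weight_model", ["equal"])),
                n_clusters=int(dd.get("n_clusters", 100)),
                cluster_sigma=float(dd.get("cluster_sigma", 0.0)),
                exclusion_rates=tuple(dd.get("exclusion_rates", [0.0, 0.0, 0.0])),
            )

        return cls(
            name=str(d["name"]),
            outcome=str(d["outcome"]),
            schema=CovariateSchema.from_dict(d["schema"]),
            wave_a=wave(d["wave_a"]),
            wave_b=wave(d["wave_b"]),
            bmi_emission={int(k): tuple(v) for k, v in d["bmi_emission"].items()},
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class PopulationTruth:
    """Exact population-level decomposition of a scenario.

    ``D = E_A[F(x'βA)] − E_B[F(x'βB)]``, ``E = E_A[F(x'βA)] − E_B[F(x'βA)]``,
    ``C = E_B[F(x'βA)] − E_B[F(x'βB)]`` computed by enumerating the joint
    covariate cells; ``detail`` apportions E and C with the same Yun weights
    (on normalized coefficients) as the estimator.
    """

    D: float
    E: float
    C: float
    p_a: float
    p_b: float
    p_counterfactual: float
    detail: pd.DataFrame
    outcome: str

    def to_json(self, path=None) -> str:
        payload = {
            "outcome": self.outcome,
            "D": self.D,
            "E": self.E,
            "C": self.C,
            "p_a": self.p_a,
            "p_b": self.p_b,
            "p_counterfactual": self.p_counterfactual,
            "detail": self.detail.to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def _coef_vector(scenario: ScenarioConfig, wc: WaveConfig) -> tuple[np.ndarray, tuple[str, ...]]:
    cols = scenario.spec.columns
    beta = np.array([wc.coefficients.get(c, 0.0) for c in cols], dtype=float)
    return beta, cols


def generate_wave(scenario: ScenarioConfig, which: str, seed: int) -> SurveyWave:
    """Draw one synthetic wave (``which`` in {"a", "b"}) from its generator
    truth; identical (scenario, which, seed) gives an identical wave.

    Each wave consumes its own named RNG stream derived from ``seed``, so the
    two waves of a scenario are independent but jointly reproducible.
    """
    if which not in ("a", "b"):
        raise ConfigurationError("which must be 'a' or 'b'")
    wc = scenario.wave_a if which == "a" else scenario.wave_b
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(0 if which == "a" else 1,))
    )
    n = wc.n
    frame = pd.DataFrame(
        {"id": [f"{wc.year}-{which}-{i:07d}" for i in range(n)]}
    )
    # covariates, independently by marginal composition
    lp = np.zeros(n)
    beta, cols = _coef_vector(scenario, wc)
    coef = dict(zip(cols, beta))
    lp += coef["intercept"]
    cov_values: dict[str, np.ndarray] = {}
    for cov in scenario.schema:
        probs = np.array([wc.composition[cov.name][c] for c in cov.categories])
        draws = rng.choice(len(cov.categories), size=n, p=probs)
        values = np.array(cov.categories, dtype=object)[draws]
        cov_values[cov.name] = values
        for cat in cov.categories:
            if cat == cov.reference:
                continue
            b = coef.get(f"{cov.name}[{cat}]", 0.0)
            if b:
                lp += b * (values == cat)
    # clusters: equal systematic allocation, optional random intercept
    cluster_idx = rng.integers(0, wc.n_clusters, size=n)
    if wc.cluster_sigma > 0:
        effects = rng.normal(0.0, wc.cluster_sigma, size=wc.n_clusters)
        lp = lp + effects[cluster_idx]
    y = (rng.random(n) < expit(lp)).astype(int)
    lo1, hi1 = scenario.bmi_emission[1]
    lo0, hi0 = scenario.bmi_emission[0]
    bmi = np.where(
        y == 1,
        rng.uniform(lo1, hi1, size=n),
        rng.uniform(lo0, hi0, size=n),
    )
    # sampling weights
    if wc.weight_model[0] == "equal":
        weights = np.ones(n)
    elif wc.weight_model[0] == "gamma":
        shape, scale = float(wc.weight_model[1]), float(wc.weight_model[2])
        weights = rng.gamma(shape, scale, size=n)
        weights = np.maximum(weights, 1e-6)
    else:
        raise ConfigurationError(f"unknown weight model {wc.weight_model!r}")
    # eligibility flags (independent of the outcome)
    r_preg, r_puerp, r_miss = wc.exclusion_rates
    u = rng.random(n)
    pregnant = u < r_preg
    puerperal = (~pregnant) & (u < r_preg + r_puerp)
    months = np.where(
        puerperal, rng.integers(0, 2, size=n).astype(float),
        rng.integers(2, 60, size=n).astype(float),
    )
    nulliparous = (~puerperal) & (rng.random(n) < 0.3)
    months = np.where(nulliparous, np.nan, months)
    missing_bmi = rng.random(n) < r_miss
    bmi = np.where(missing_bmi, np.nan, bmi)

    frame["bmi"] = bmi
    frame["pregnant"] = pregnant
    frame["months_since_last_birth"] = months
    frame["weight"] = weights
    frame["cluster_id"] = np.array([f"ea{j:04d}" for j in range(wc.n_clusters)])[cluster_idx]
    frame["stratum_id"] = None
    for cov in scenario.schema:
        frame[cov.name] = cov_values[cov.name]
    return SurveyWave(year=wc.year, frame=frame, schema=scenario.schema)


# ---------------------------------------------------------------------------
# Exact oracle
# ---------------------------------------------------------------------------

def _cell_enumeration(scenario: ScenarioConfig, wc: WaveConfig):
    """Joint cells (product of marginals) with probabilities, the cell linear
    predictor under a wave's coefficients, and the expanded cell indicators."""
    covs = scenario.schema.covariates
    cats = [cov.categories for cov in covs]
    cells = list(itertools.product(*cats))
    probs = np.array(
        [
            float(np.prod([wc.composition[cov.name][cell[i]] for i, cov in enumerate(covs)]))
            for cell in cells
        ]
    )
    return cells, probs


def _cell_lp(scenario: ScenarioConfig, cells, wc: WaveConfig) -> np.ndarray:
    beta, cols = _coef_vector(scenario, wc)
    coef = dict(zip(cols, beta))
    covs = scenario.schema.covariates
    lp = np.full(len(cells), coef["intercept"])
    for k, cell in enumerate(cells):
        for i, cov in enumerate(covs):
            if cell[i] != cov.reference:
                lp[k] += coef.get(f"{cov.name}[{cell[i]}]", 0.0)
    return lp


def _population_xbar_full(scenario: ScenarioConfig, wc: WaveConfig) -> np.ndarray:
    """Population category shares aligned with DesignSpec.full_columns."""
    out = [1.0]
    for cov in scenario.schema:
        out.extend(wc.composition[cov.name][cat] for cat in cov.categories)
    return np.array(out)


def _truth_normalized(scenario: ScenarioConfig, wc: WaveConfig) -> NormalizedFit:
    from .weighted_logit import LogitFit  # local import to avoid cycle noise

    beta, cols = _coef_vector(scenario, wc)
    fit = LogitFit(
        params=beta, columns=cols, vcov=None, converged=True, n_iter=0,
        n=0, total_weight=0.0, loglik=0.0,
    )
    return normalize_categorical(fit, scenario.spec)


def population_truth(scenario: ScenarioConfig) -> PopulationTruth:
    """Exact (D, E, C) and detailed shares by joint-cell enumeration.

    Only categorical covariates with finite joint support are admitted; the
    oracle involves no sampling and no model fitting, so the telescoping
    identity E + C = D holds to machine precision.
    """
    cells_a, probs_a = _cell_enumeration(scenario, scenario.wave_a)
    cells_b, probs_b = _cell_enumeration(scenario, scenario.wave_b)
    lp_a_a = _cell_lp(scenario, cells_a, scenario.wave_a)
    lp_b_a = _cell_lp(scenario, cells_b, scenario.wave_a)
    lp_b_b = _cell_lp(scenario, cells_b, scenario.wave_b)
    p_a = float(probs_a @ expit(lp_a_a))
    p_cf = float(probs_b @ expit(lp_b_a))      # B composition, A coefficients
    p_b = float(probs_b @ expit(lp_b_b))
    D = p_a - p_b
    E = p_a - p_cf
    C = p_cf - p_b

    # detailed shares with the estimator's Yun weights on normalized truth
    na = _truth_normalized(scenario, scenario.wave_a)
    nb = _truth_normalized(scenario, scenario.wave_b)
    xbar_a = _population_xbar_full(scenario, scenario.wave_a)
    xbar_b = _population_xbar_full(scenario, scenario.wave_b)
    s_e = na.params * (xbar_a - xbar_b)
    s_c = xbar_b * (na.params - nb.params)
    e_k = _decomp._apportion(s_e, E, "characteristics (E)", strict=False)
    c_k = _decomp._apportion(s_c, C, "coefficients (C)", strict=False)
    detail = pd.DataFrame(
        {
            "term": list(scenario.spec.full_columns),
            "share_E": s_e,
            "share_C": s_c,
            "E": e_k,
            "C": c_k,
        }
    )
    return PopulationTruth(
        D=D, E=E, C=C, p_a=p_a, p_b=p_b, p_counterfactual=p_cf,
        detail=detail, outcome=scenario.outcome,
    )


# ---------------------------------------------------------------------------
# Shipped scenario presets
# ---------------------------------------------------------------------------

_SCHEMA = CovariateSchema(
    covariates=(
        Covariate("region", ("Amhara", "Oromia", "SNNP", "Addis Ababa"), "Amhara"),
        Covariate("residence", ("rural", "urban"), "rural"),
        Covariate("age_group", ("15-24", "25-34", "35-49"), "15-24"),
        Covariate("education", ("none", "primary", "secondary+"), "none"),
        Covariate("religion", ("orthodox", "muslim", "other"), "orthodox"),
        Covariate("contraceptive", ("none", "any"), "none"),
    )
)

# Compositions loosely calibrated to the published 2000 and 2016 EDHS
# respondent tables (education expansion, urbanisation, contraceptive uptake).
_COMP_EARLY = {
    "region": {"Amhara": 0.30, "Oromia": 0.40, "SNNP": 0.24, "Addis Ababa": 0.06},
    "residence": {"rural": 0.82, "urban": 0.18},
    "age_group": {"15-24": 0.44, "25-34": 0.31, "35-49": 0.25},
    "education": {"none": 0.73, "primary": 0.17, "secondary+": 0.10},
    "religion": {"orthodox": 0.51, "muslim": 0.29, "other": 0.20},
    "contraceptive": {"none": 0.93, "any": 0.07},
}
_COMP_LATE = {
    "region": {"Amhara": 0.29, "Oromia": 0.39, "SNNP": 0.24, "Addis Ababa": 0.08},
    "residence": {"rural": 0.78, "urban": 0.22},
    "age_group": {"15-24": 0.40, "25-34": 0.31, "35-49": 0.29},
    "education": {"none": 0.47, "primary": 0.35, "secondary+": 0.18},
    "religion": {"orthodox": 0.46, "muslim": 0.29, "other": 0.25},
    "contraceptive": {"none": 0.71, "any": 0.29},
}

# Underweight-risk coefficients: baseline is a rural, never-schooled,
# orthodox, non-contracepting 15-24 Amhara woman.  Intercepts are set so the
# population underweight margins match the published national levels
# (31.25% in the early wave, 23.18% in the late one).
_UW_COEF_EARLY = {
    "intercept": -0.4820013579464211,
    "region[Oromia]": -0.10,
    "region[SNNP]": 0.00,
    "region[Addis Ababa]": -0.40,
    "residence[urban]": -0.50,
    "age_group[25-34]": -0.30,
    "age_group[35-49]": -0.10,
    "education[primary]": -0.10,
    "education[secondary+]": -0.50,
    "religion[muslim]": 0.10,
    "religion[other]": 0.00,
    "contraceptive[any]": -0.20,
}
_UW_COEF_LATE = {
    "intercept": -0.6231158434764487,
    "region[Oromia]": -0.20,
    "region[SNNP]": -0.50,
    "region[Addis Ababa]": -0.60,
    "residence[urban]": -0.70,
    "age_group[25-34]": -0.25,
    "age_group[35-49]": -0.05,
    "education[primary]": -0.15,
    "education[secondary+]": -0.45,
    "religion[muslim]": 0.25,
    "religion[other]": 0.00,
    "contraceptive[any]": -0.25,
}

# Overweight(-merged)-risk coefficients: rare at baseline, concentrated in
# urban, educated, older and contracepting groups; both margins rise late.
# Intercepts match the published national merged-overweight margins
# (3.49% early, 7.74% late).
_OW_COEF_EARLY = {
    "intercept": -4.43371776812471,
    "region[Oromia]": 0.10,
    "region[SNNP]": 0.00,
    "region[Addis Ababa]": 0.80,
    "residence[urban]": 1.60,
    "age_group[25-34]": 0.40,
    "age_group[35-49]": 0.60,
    "education[primary]": 0.30,
    "education[secondary+]": 0.80,
    "religion[muslim]": 0.00,
    "religion[other]": -0.10,
    "contraceptive[any]": 0.60,
}
_OW_COEF_LATE = {
    "intercept": -4.191309746596142,
    "region[Oromia]": 0.15,
    "region[SNNP]": 0.00,
    "region[Addis Ababa]": 0.90,
    "residence[urban]": 1.90,
    "age_group[25-34]": 0.45,
    "age_group[35-49]": 0.70,
    "education[primary]": 0.30,
    "education[secondary+]": 0.90,
    "religion[muslim]": 0.05,
    "religion[other]": -0.10,
    "contraceptive[any]": 0.50,
}

_UW_EMISSION = {1: (16.0, 18.45), 0: (18.55, 24.9)}
_OW_EMISSION = {1: (25.1, 33.0), 0: (18.55, 24.9)}

#: Default per-wave sample size, weight model, cluster count and flag rates
#: shared by all presets (DHS-like: ~600 enumeration areas per round,
#: unit-mean gamma weights, ~8%/8%/4% pregnant/puerperal/unmeasured).
_N = 50_000
_WEIGHTS = ("gamma", 4.0, 0.25)
_CLUSTERS = 600
_EXCL = (0.08, 0.08, 0.04)

PRESETS = (
    "composition_shift_only",
    "coefficient_shift_only",
    "mixed_underweight_decline",
    "urban_overweight_rise",
)


def _wave(year, comp, coefs, n=_N):
    return WaveConfig(
        year=year, n=n, composition=comp, coefficients=coefs,
        weight_model=_WEIGHTS, n_clusters=_CLUSTERS, exclusion_rates=_EXCL,
    )


def make_scenario(preset: str, n: int | None = None) -> ScenarioConfig:
    """One of the shipped two-wave scenarios.

    - ``composition_shift_only``: identical coefficients, shifted composition
      (so the true C component is exactly zero).
    - ``coefficient_shift_only``: identical composition, shifted coefficients
      (true E exactly zero).
    - ``mixed_underweight_decline``: both shift; underweight prevalence falls
      from the early to the late wave (true D < 0).
    - ``urban_overweight_rise``: merged-overweight outcome; urbanisation and
      steeper urban/education effects drive a rise (true D > 0).
    """
    nn = _N if n is None else int(n)
    if preset == "composition_shift_only":
        a = _wave("2016", _COMP_LATE, _UW_COEF_EARLY, nn)
        b = _wave("2000", _COMP_EARLY, _UW_COEF_EARLY, nn)
        outcome, emission = "underweight", _UW_EMISSION
    elif preset == "coefficient_shift_only":
        a = _wave("2016", _COMP_EARLY, _UW_COEF_LATE, nn)
        b = _wave("2000", _COMP_EARLY, _UW_COEF_EARLY, nn)
        outcome, emission = "underweight", _UW_EMISSION
    elif preset == "mixed_underweight_decline":
        a = _wave("2016", _COMP_LATE, _UW_COEF_LATE, nn)
        b = _wave("2000", _COMP_EARLY, _UW_COEF_EARLY, nn)
        outcome, emission = "underweight", _UW_EMISSION
    elif preset == "urban_overweight_rise":
        a = _wave("2016", _COMP_LATE, _OW_COEF_LATE, nn)
        b = _wave("2000", _COMP_EARLY, _OW_COEF_EARLY, nn)
        outcome, emission = "overweight_merged", _OW_EMISSION
    else:
        raise ConfigurationError(
            f"unknown preset {preset!r}; available: {PRESETS}"
        )
    return ScenarioConfig(
        name=preset, outcome=outcome, schema=_SCHEMA,
        wave_a=a, wave_b=b, bmi_emission=emission,
    )
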