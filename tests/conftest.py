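"""Shared fixtures: tiny hand-built waves and small generated cohorts."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.special import logit

from bmidecomp.core_records import Covariate, CovariateSchema, SurveyWave, WomanRecord
from bmidecomp.synthetic_cohort import (
    ScenarioConfig,
    WaveConfig,
    generate_wave,
    make_scenario,
)

# BMI values that land squarely inside each WHO band
BMI_UNDER, BMI_NORMAL, BMI_OVER, BMI_OBESE = 17.0, 21.0, 27.0, 32.0


@pytest.fixture(scope="session")
def binary_schema() -> CovariateSchema:
    return CovariateSchema(
        covariates=(Covariate("x", ("0", "1"), "0"),)
    )


def make_wave(year, rows, schema, **defaults):
    """Build a wave from (bmi, weight, {covariate: label}) or richer tuples.

    Each row: dict with optional keys bmi, weight, pregnant, months,
    cluster, and one entry per covariate (default reference level).
    """
    records = []
    for i, row in enumerate(rows):
        cov = {c.name: row.get(c.name, c.reference) for c in schema}
        records.append(
            WomanRecord(
                id=row.get("id", f"{year}-{i:04d}"),
                bmi=row.get("bmi", BMI_NORMAL),
                pregnant=row.get("pregnant", False),
                months_since_last_birth=row.get("months", 24),
                weight=row.get("weight", 1.0),
                cluster_id=row.get("cluster", "c1"),
                covariates=cov,
            )
        )
    return SurveyWave.from_records(year, records, schema)


@pytest.fixture(scope="session")
def two_cell_scenario(binary_schema) -> ScenarioConfig:
    """Saturated one-binary-covariate scenario whose exact decomposition is
    D=0.145, E=0.075, C=0.07 (cell enumeration: pA=0.425, pB=0.28,
    counterfactual E_B[F(x'betaA)]=0.35)."""
    wave_b = WaveConfig(
        year="2000",
        n=1000,
        composition={"x": {"0": 0.6, "1": 0.4}},
        coefficients={
            "intercept": float(logit(0.2)),
            "x[1]": float(logit(0.4) - logit(0.2)),
        },
    )
    wave_a = WaveConfig(
        year="2016",
        n=1000,
        composition={"x": {"0": 0.3, "1": 0.7}},
        coefficients={
            "intercept": float(logit(0.25)),
            "x[1]": float(logit(0.5) - logit(0.25)),
        },
    )
    return ScenarioConfig(
        name="two_cell",
        outcome="underweight",
        schema=binary_schema,
        wave_a=wave_a,
        wave_b=wave_b,
        bmi_emission={1: (16.0, 18.45), 0: (18.55, 24.9)},
    )


def exact_cell_wave(year, cells, schema):
    """Wave whose weighted cell proportions are exact: one record per
    (covariate-pattern, outcome) with weight = cell prob x outcome prob."""
    rows = []
    for labels, p_cell, p_y in cells:
        rows.append({**labels, "weight": p_cell * p_y, "bmi": BMI_UNDER})
        rows.append({**labels, "weight": p_cell * (1 - p_y), "bmi": BMI_NORMAL})
    return make_wave(year, rows, schema)


@pytest.fixture(scope="session")
def exact_two_cell_waves(binary_schema):
    """Sample-level realisation of the two-cell scenario with exact weighted
    cell frequencies, so the saturated fit reproduces the cell probabilities."""
    wave_b = exact_cell_wave(
        "2000", [({"x": "0"}, 0.6, 0.2), ({"x": "1"}, 0.4, 0.4)], binary_schema
    )
    wave_a = exact_cell_wave(
        "2016", [({"x": "0"}, 0.3, 0.25), ({"x": "1"}, 0.7, 0.5)], binary_schema
    )
    return wave_a, wave_b


@pytest.fixture(scope="session")
def small_mixed_waves():
    """Modest generated cohort from the mixed preset (n=4000/wave), with the
    eligibility filter applied — shared across tests for speed."""
    from bmidecomp.core_records import apply_exclusions

    scenario = make_scenario("mixed_underweight_decline", n=4000)
    wave_a, _ = apply_exclusions(generate_wave(scenario, "a", 42))
    wave_b, _ = apply_exclusions(generate_wave(scenario, "b", 42))
    return scenario, wave_a, wave_b
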