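"""Domain records for women's anthropometry surveys.

This module defines the individual-level record (one woman per row), the
survey-wave container with its categorical covariate schema, WHO BMI
classification and the two dichotomous views used for trend and
decomposition analysis, the eligibility filter (pregnant, puerperal and
unmeasured-BMI women are excluded), and CSV input/output in two dialects:
``plain`` (BMI and weight stored as decimals) and ``dhs`` (DHS individual
recode conventions: BMI stored x100 with sentinel codes for missing,
sampling weight stored x1,000,000).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BMI_PLAUSIBLE",
    "BmiCategory",
    "OUTCOMES",
    "Covariate",
    "CovariateSchema",
    "WomanRecord",
    "SurveyWave",
    "ExclusionTally",
    "classify_bmi",
    "classify_bmi_array",
    "dichotomize",
    "dichotomize_array",
    "apply_exclusions",
    "read_survey_csv",
    "write_survey_csv",
    "SchemaError",
    "DataError",
    "ConfigurationError",
    "UnmeasuredBmiError",
    "ImplausibleBmiError",
]

#: Plausibility bounds for a measured adult BMI (kg/m^2).  Values outside the
#: open interval are treated as keying errors, not as extreme physiology.
BMI_PLAUSIBLE = (10.0, 60.0)

#: Names of the two dichotomous outcome views.
OUTCOMES = ("underweight", "overweight_merged")

#: Base (non-covariate) columns of a survey-wave frame, in canonical order.
BASE_COLUMNS = (
    "id",
    "bmi",
    "pregnant",
    "months_since_last_birth",
    "weight",
    "cluster_id",
    "stratum_id",
)


class SchemaError(ValueError):
    """A record or file does not conform to the declared covariate schema."""


class DataError(ValueError):
    """A record carries an invalid value (e.g. a non-positive weight)."""


class ConfigurationError(ValueError):
    """An option or label passed by the caller is not recognised."""


class UnmeasuredBmiError(DataError):
    """BMI is missing or non-finite where a measured value is required."""


class ImplausibleBmiError(DataError):
    """A measured BMI falls outside the plausibility bounds."""


class BmiCategory(str, enum.Enum):
    """WHO BMI band.

    ``UNDERWEIGHT`` < 18.5, ``NORMAL`` [18.5, 25), ``OVERWEIGHT`` [25, 30),
    ``OBESE`` >= 30 kg/m^2.  The merged view used for the trend tables pools
    ``OVERWEIGHT`` and ``OBESE`` into a single "overweight" group.
    """

    UNDERWEIGHT = "underweight"
    NORMAL = "normal"
    OVERWEIGHT = "overweight"
    OBESE = "obese"


def classify_bmi(bmi: float) -> BmiCategory:
    """Classify a measured BMI into its WHO band.

    The bands are half-open: underweight < 18.5 <= normal < 25 <= overweight
    < 30 <= obese.  A missing or non-finite value signals
    :class:`UnmeasuredBmiError` — such records must be excluded upstream,
    never silently categorised.  A finite value outside the plausibility
    bounds ``BMI_PLAUSIBLE`` raises :class:`ImplausibleBmiError`.
    """
    if bmi is None or (isinstance(bmi, float) and math.isnan(bmi)):
        raise UnmeasuredBmiError("BMI is missing (unmeasured)")
    bmi = float(bmi)
    if not math.isfinite(bmi):
        raise UnmeasuredBmiError(f"BMI is non-finite: {bmi!r}")
    lo, hi = BMI_PLAUSIBLE
    if not (lo < bmi < hi):
        raise ImplausibleBmiError(f"BMI {bmi} outside plausible range ({lo}, {hi})")
    if bmi < 18.5:
        return BmiCategory.UNDERWEIGHT
    if bmi < 25.0:
        return BmiCategory.NORMAL
    if bmi < 30.0:
        return BmiCategory.OVERWEIGHT
    return BmiCategory.OBESE


def classify_bmi_array(bmi: np.ndarray) -> np.ndarray:
    """Vectorised :func:`classify_bmi`; returns an object array of categories."""
    bmi = np.asarray(bmi, dtype=float)
    if bmi.size and not np.isfinite(bmi).all():
        raise UnmeasuredBmiError("array contains missing/non-finite BMI values")
    lo, hi = BMI_PLAUSIBLE
    if bmi.size and ((bmi <= lo) | (bmi >= hi)).any():
        bad = bmi[(bmi <= lo) | (bmi >= hi)][:5]
        raise ImplausibleBmiError(f"BMI values outside ({lo}, {hi}): {bad.tolist()}")
    out = np.empty(bmi.shape, dtype=object)
    out[bmi < 18.5] = BmiCategory.UNDERWEIGHT
    out[(bmi >= 18.5) & (bmi < 25.0)] = BmiCategory.NORMAL
    out[(bmi >= 25.0) & (bmi < 30.0)] = BmiCategory.OVERWEIGHT
    out[bmi >= 30.0] = BmiCategory.OBESE
    return out


def dichotomize(category: BmiCategory, outcome: str) -> int:
    """Binary outcome for one of the two analysis views.

    ``outcome="underweight"``: 1 iff underweight (normal and overweight/obese
    pooled as "others").  ``outcome="overweight_merged"``: 1 iff overweight or
    obese (BMI >= 25).
    """
    category = BmiCategory(category)
    if outcome == "underweight":
        return int(category is BmiCategory.UNDERWEIGHT)
    if outcome == "overweight_merged":
        return int(category in (BmiCategory.OVERWEIGHT, BmiCategory.OBESE))
    raise ConfigurationError(
        f"unknown outcome {outcome!r}; expected one of {OUTCOMES}"
    )


def dichotomize_array(bmi: np.ndarray, outcome: str) -> np.ndarray:
    """Vectorised classify-then-dichotomize on measured BMI values."""
    bmi = np.asarray(bmi, dtype=float)
    classify_bmi_array(bmi)  # validation only
    if outcome == "underweight":
        return (bmi < 18.5).astype(float)
    if outcome == "overweight_merged":
        return (bmi >= 25.0).astype(float)
    raise ConfigurationError(
        f"unknown outcome {outcome!r}; expected one of {OUTCOMES}"
    )


@dataclass(frozen=True)
class Covariate:
    """One categorical covariate: ordered category labels plus a reference."""

    name: str
    categories: tuple[str, ...]
    reference: str

    def __post_init__(self) -> None:
        if len(self.categories) < 2:
            raise SchemaError(f"covariate {self.name!r} needs >= 2 categories")
        if len(set(self.categories)) != len(self.categories):
            raise SchemaError(f"covariate {self.name!r} has duplicate categories")
        if self.reference not in self.categories:
            raise SchemaError(
                f"reference {self.reference!r} not among categories of {self.name!r}"
            )


@dataclass(frozen=True)
class CovariateSchema:
    """Ordered declaration of the categorical covariates of a survey wave."""

    covariates: tuple[Covariate, ...]

    def __iter__(self):
        return iter(self.covariates)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.covariates)

    def get(self, name: str) -> Covariate:
        for c in self.covariates:
            if c.name == name:
                return c
        raise SchemaError(f"unknown covariate {name!r}")

    def to_dict(self) -> dict:
        return {
            "covariates": [
                {"name": c.name, "categories": list(c.categories), "reference": c.reference}
                for c in self.covariates
            ]
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CovariateSchema":
        covs = []
        for item in d["covariates"]:
            covs.append(
                Covariate(
                    name=str(item["name"]),
                    categories=tuple(str(c) for c in item["categories"]),
                    reference=str(item["reference"]),
                )
            )
        return cls(covariates=tuple(covs))

    def validate_frame(self, frame: pd.DataFrame) -> None:
        """Raise :class:`SchemaError` listing offending rows on bad labels."""
        for cov in self.covariates:
            if cov.name not in frame.columns:
                raise SchemaError(f"missing covariate column {cov.name!r}")
            col = frame[cov.name].astype(str)
            bad = ~col.isin(cov.categories)
            if bad.any():
                rows = frame.index[bad].tolist()[:10]
                labels = sorted(col[bad].unique().tolist())[:10]
                raise SchemaError(
                    f"covariate {cov.name!r}: unknown labels {labels} "
                    f"in rows {rows}"
                )


@dataclass
class WomanRecord:
    """One survey respondent.

    ``bmi`` is in kg/m^2 and may be ``None`` (unmeasured); ``weight`` is the
    positive individual sampling weight, used as a relative weight throughout;
    ``months_since_last_birth`` is ``None`` for women with no recorded birth.
    """

    id: str
    bmi: float | None
    pregnant: bool
    months_since_last_birth: int | None
    weight: float
    cluster_id: str
    covariates: dict[str, str] = field(default_factory=dict)
    stratum_id: str | None = None

    def __post_init__(self) -> None:
        if not (self.weight > 0):
            raise DataError(f"record {self.id!r}: weight must be > 0, got {self.weight}")
        if self.bmi is not None and not (
            isinstance(self.bmi, float) and math.isnan(self.bmi)
        ):
            lo, hi = BMI_PLAUSIBLE
            if not (lo < float(self.bmi) < hi):
                raise ImplausibleBmiError(
                    f"record {self.id!r}: BMI {self.bmi} outside ({lo}, {hi})"
                )


@dataclass
class SurveyWave:
    """A weighted collection of :class:`WomanRecord` for one survey year.

    Internally backed by a pandas frame (one row per woman; base columns
    followed by one column per schema covariate) so that downstream metrics
    and model fits stay vectorised.
    """

    year: str
    frame: pd.DataFrame
    schema: CovariateSchema

    def __post_init__(self) -> None:
        missing = [c for c in BASE_COLUMNS if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"wave frame missing base columns {missing}")
        self.frame = self.frame.reset_index(drop=True)
        w = pd.to_numeric(self.frame["weight"], errors="coerce")
        bad_w = ~(w > 0)
        if bad_w.any():
            raise DataError(
                f"non-positive/missing sampling weight in rows "
                f"{self.frame.index[bad_w].tolist()[:10]}"
            )
        bmi = pd.to_numeric(self.frame["bmi"], errors="coerce")
        lo, hi = BMI_PLAUSIBLE
        measured = bmi.notna()
        bad_bmi = measured & ~((bmi > lo) & (bmi < hi))
        if bad_bmi.any():
            raise ImplausibleBmiError(
                f"BMI outside ({lo}, {hi}) in rows "
                f"{self.frame.index[bad_bmi].tolist()[:10]}"
            )
        self.schema.validate_frame(self.frame)
        if len(self.frame) and float(w.sum()) <= 0:
            raise DataError("total sampling weight must be positive")

    # -- construction -----------------------------------------------------

    @classmethod
    def from_records(
        cls, year: str, records: Iterable[WomanRecord], schema: CovariateSchema
    ) -> "SurveyWave":
        rows = []
        for r in records:
            row = {
                "id": r.id,
                "bmi": np.nan if r.bmi is None else float(r.bmi),
                "pregnant": bool(r.pregnant),
                "months_since_last_birth": (
                    np.nan
                    if r.months_since_last_birth is None
                    else float(r.months_since_last_birth)
                ),
                "weight": float(r.weight),
                "cluster_id": r.cluster_id,
                "stratum_id": r.stratum_id,
            }
            for name in schema.names:
                if name not in r.covariates:
                    raise SchemaError(
                        f"record {r.id!r} missing covariate {name!r}"
                    )
                row[name] = r.covariates[name]
            rows.append(row)
        frame = pd.DataFrame(rows, columns=list(BASE_COLUMNS) + list(schema.names))
        return cls(year=year, frame=frame, schema=schema)

    # -- basic accessors --------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def total_weight(self) -> float:
        return float(self.frame["weight"].sum())

    @property
    def weights(self) -> np.ndarray:
        return self.frame["weight"].to_numpy(dtype=float)

    def records(self) -> list[WomanRecord]:
        out = []
        for _, row in self.frame.iterrows():
            bmi = row["bmi"]
            months = row["months_since_last_birth"]
            out.append(
                WomanRecord(
                    id=str(row["id"]),
                    bmi=None if pd.isna(bmi) else float(bmi),
                    pregnant=bool(row["pregnant"]),
                    months_since_last_birth=None if pd.isna(months) else int(months),
                    weight=float(row["weight"]),
                    cluster_id=str(row["cluster_id"]),
                    stratum_id=None if pd.isna(row["stratum_id"]) else str(row["stratum_id"]),
                    covariates={n: str(row[n]) for n in self.schema.names},
                )
            )
        return out

    def subset(self, mask: np.ndarray) -> "SurveyWave":
        return SurveyWave(
            year=self.year,
            frame=self.frame.loc[np.asarray(mask, dtype=bool)].reset_index(drop=True),
            schema=self.schema,
        )


@dataclass(frozen=True)
class ExclusionTally:
    """Counts removed per reason; each woman counted once, in the fixed
    precedence pregnant -> puerperal -> unmeasured BMI."""

    pregnant: int
    puerperal: int
    unmeasured_bmi: int
    retained: int

    @property
    def excluded(self) -> int:
        return self.pregnant + self.puerperal + self.unmeasured_bmi

    @property
    def total(self) -> int:
        return self.excluded + self.retained


def apply_exclusions(
    wave: SurveyWave, puerperium_months: int = 2
) -> tuple[SurveyWave, ExclusionTally]:
    """Restrict a wave to the BMI analysis population.

    Removes pregnant women, women within ``puerperium_months`` months of a
    birth (the postpartum window in which BMI is not a meaningful nutritional
    indicator; 2 months by DHS convention), and women with unmeasured BMI.
    The tally counts each excluded woman once, under the first reason that
    applies in the precedence pregnant -> puerperal -> unmeasured BMI.
    Idempotent: applying it to its own output removes nobody.
    """
    frame = wave.frame
    preg = frame["pregnant"].astype(bool).to_numpy()
    months = pd.to_numeric(frame["months_since_last_birth"], errors="coerce").to_numpy(
        dtype=float
    )
    puerp = (~preg) & np.isfinite(months) & (months < puerperium_months)
    bmi = pd.to_numeric(frame["bmi"], errors="coerce").to_numpy(dtype=float)
    unmeasured = (~preg) & (~puerp) & (~np.isfinite(bmi))
    keep = ~(preg | puerp | unmeasured)
    tally = ExclusionTally(
        pregnant=int(preg.sum()),
        puerperal=int(puerp.sum()),
        unmeasured_bmi=int(unmeasured.sum()),
        retained=int(keep.sum()),
    )
    return wave.subset(keep), tally


# ---------------------------------------------------------------------------
# CSV input / output
# ---------------------------------------------------------------------------

#: DHS individual-recode conventions: BMI (v445) stored x100 with sentinel
#: codes >= this value meaning "flagged/missing"; weight (v005) stored x1e6.
_DHS_BMI_SENTINEL = 9990.0


def _default_column_map(schema: CovariateSchema) -> dict[str, str]:
    cm = {c: c for c in BASE_COLUMNS}
    cm.update({n: n for n in schema.names})
    return cm


def read_survey_csv(
    path,
    schema: CovariateSchema,
    column_map: Mapping[str, str] | None = None,
    dialect: str = "plain",
    year: str | None = None,
) -> SurveyWave:
    """Read one survey wave from a CSV file.

    ``column_map`` maps canonical field names (``id``, ``bmi``, ``pregnant``,
    ``months_since_last_birth``, ``weight``, ``cluster_id``, ``stratum_id``
    and each covariate name) to the file's column names; omitted entries
    default to the canonical name.  ``dialect="dhs"`` applies the recode
    conventions: BMI cells are divided by 100 (cells >= 9990, e.g. 9998/9999,
    become missing) and weights are divided by 1,000,000.
    """
    if dialect not in ("plain", "dhs"):
        raise ConfigurationError(f"unknown CSV dialect {dialect!r}")
    df = pd.read_csv(path)
    cm = _default_column_map(schema)
    if column_map:
        cm.update(column_map)
    out = pd.DataFrame(index=df.index)
    for canonical in list(BASE_COLUMNS) + list(schema.names):
        src = cm[canonical]
        if src not in df.columns:
            if canonical == "stratum_id":
                out[canonical] = None
                continue
            if canonical == "months_since_last_birth":
                out[canonical] = np.nan
                continue
            raise SchemaError(f"column {src!r} (for {canonical!r}) not in {path}")
        out[canonical] = df[src]
    out["bmi"] = pd.to_numeric(out["bmi"], errors="coerce")
    out["weight"] = pd.to_numeric(out["weight"], errors="coerce")
    out["months_since_last_birth"] = pd.to_numeric(
        out["months_since_last_birth"], errors="coerce"
    )
    if dialect == "dhs":
        raw = out["bmi"].to_numpy(dtype=float)
        raw = np.where(raw >= _DHS_BMI_SENTINEL, np.nan, raw)
        out["bmi"] = raw / 100.0
        out["weight"] = out["weight"] / 1e6
    preg = out["pregnant"]
    if preg.dtype != bool:
        out["pregnant"] = (
            preg.astype(str).str.strip().str.lower().isin(("1", "true", "yes"))
        )
    out["id"] = out["id"].astype(str)
    out["cluster_id"] = out["cluster_id"].astype(str)
    for name in schema.names:
        out[name] = out[name].astype(str)
    return SurveyWave(year=year or "unknown", frame=out, schema=schema)


def write_survey_csv(wave: SurveyWave, path) -> None:
    """Write a wave back to plain-dialect CSV (round-trips with
    :func:`read_survey_csv`)."""
    wave.frame.to_csv(path, index=False, float_format="%.10g")
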