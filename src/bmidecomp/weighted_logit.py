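"""Weighted maximum-likelihood logistic regression on dummy-coded designs.

Fits the per-wave models that feed the decomposition.  Estimation is by
iteratively reweighted least squares (Newton scoring) with step-halving,
converging on the max-norm of the weighted score.  Sampling weights enter
the likelihood as frequency-style weights, so point estimates coincide with
design-weighted estimates; design-based uncertainty is handled downstream by
the bootstrap.  Separation and rank deficiency raise explicit errors naming
the offending covariate/columns instead of returning divergent coefficients.

``normalize_categorical`` re-expresses each categorical covariate's
coefficients (including the implicit zero of the reference category) as
deviations from their unweighted mean over the categories, folding the means
into the intercept.  The linear predictor of every record is unchanged; the
point is that detailed decomposition contributions become invariant to the
arbitrary choice of reference category.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg
from scipy.special import expit

from .core_records import (
    ConfigurationError,
    Covariate,
    CovariateSchema,
    SchemaError,
    SurveyWave,
    dichotomize_array,
)

__all__ = [
    "DesignSpec",
    "LogitFit",
    "NormalizedFit",
    "build_design",
    "build_full_design",
    "fit_weighted_logit",
    "normalize_categorical",
    "SeparationError",
    "RankDeficiencyError",
    "ConvergenceError",
]

#: |beta| beyond this is treated as complete/quasi-complete separation.
SEPARATION_THRESHOLD = 15.0


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation detected during the fit."""


class RankDeficiencyError(RuntimeError):
    """The weighted design matrix is not of full column rank."""


class ConvergenceError(RuntimeError):
    """IRLS did not reach the score tolerance within the iteration cap."""


@dataclass(frozen=True)
class DesignSpec:
    """Ordered covariates (with ordered categories and a reference each)
    defining a dummy-coded design; an intercept is always included."""

    covariates: tuple[Covariate, ...]

    @classmethod
    def from_schema(
        cls, schema: CovariateSchema, include: Sequence[str] | None = None
    ) -> "DesignSpec":
        if include is None:
            return cls(covariates=tuple(schema.covariates))
        return cls(covariates=tuple(schema.get(n) for n in include))

    @property
    def columns(self) -> tuple[str, ...]:
        """Reference-coded column names: intercept then non-reference dummies."""
        cols = ["intercept"]
        for cov in self.covariates:
            cols.extend(
                f"{cov.name}[{cat}]" for cat in cov.categories if cat != cov.reference
            )
        return tuple(cols)

    @property
    def full_columns(self) -> tuple[str, ...]:
        """Expanded column names: intercept then one dummy per category."""
        cols = ["intercept"]
        for cov in self.covariates:
            cols.extend(f"{cov.name}[{cat}]" for cat in cov.categories)
        return tuple(cols)

    def column_covariate(self, column: str) -> str:
        """Covariate name owning a design column (``intercept`` for the intercept)."""
        if column == "intercept":
            return "intercept"
        return column.split("[", 1)[0]


def _dummy_block(values: np.ndarray, cov: Covariate, drop_reference: bool) -> np.ndarray:
    cats = [c for c in cov.categories if not (drop_reference and c == cov.reference)]
    block = np.empty((values.shape[0], len(cats)), dtype=float)
    for j, cat in enumerate(cats):
        block[:, j] = values == cat
    return block


def build_design(
    wave: SurveyWave, spec: DesignSpec, outcome: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, tuple[str, ...]]:
    """Reference-coded design matrix, binary outcome and weights for a wave.

    Rows follow the record order of the wave; columns are the intercept
    followed by each covariate's non-reference category dummies in declared
    order, so column order is stable across waves sharing a spec.
    """
    frame = wave.frame
    blocks = [np.ones((len(frame), 1))]
    for cov in spec.covariates:
        if cov.name not in frame.columns:
            raise SchemaError(f"wave lacks covariate column {cov.name!r}")
        values = frame[cov.name].astype(str).to_numpy()
        present = set(np.unique(values))
        unknown = present - set(cov.categories)
        if unknown:
            raise SchemaError(
                f"covariate {cov.name!r}: categories {sorted(unknown)} present "
                f"in data but absent from the design spec"
            )
        blocks.append(_dummy_block(values, cov, drop_reference=True))
    X = np.hstack(blocks)
    bmi = frame["bmi"].to_numpy(dtype=float)
    y = dichotomize_array(bmi, outcome)
    w = wave.weights
    return X, y, w, spec.columns


def build_full_design(wave: SurveyWave, spec: DesignSpec) -> np.ndarray:
    """Expanded design: intercept plus one dummy per category of every
    covariate (each record has exactly one 1 per covariate block)."""
    frame = wave.frame
    blocks = [np.ones((len(frame), 1))]
    for cov in spec.covariates:
        values = frame[cov.name].astype(str).to_numpy()
        blocks.append(_dummy_block(values, cov, drop_reference=False))
    return np.hstack(blocks)


@dataclass
class LogitFit:
    """A converged (or not) weighted logit fit on a reference-coded design."""

    params: np.ndarray
    columns: tuple[str, ...]
    vcov: np.ndarray | None
    converged: bool
    n_iter: int
    n: int
    total_weight: float
    loglik: float

    @property
    def coef(self) -> dict[str, float]:
        return dict(zip(self.columns, self.params.tolist()))

    @property
    def bse(self) -> np.ndarray:
        if self.vcov is None:
            raise ValueError("no covariance available")
        return np.sqrt(np.diag(self.vcov))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return expit(np.asarray(X, dtype=float) @ self.params)

    def to_json(self) -> str:
        return json.dumps(
            {
                "columns": list(self.columns),
                "params": self.params.tolist(),
                "converged": self.converged,
                "n_iter": self.n_iter,
                "n": self.n,
                "total_weight": self.total_weight,
                "loglik": self.loglik,
            },
            indent=2,
        )


def _weighted_loglik(X: np.ndarray, y: np.ndarray, w: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    # w * (y*eta - log(1 + exp(eta))), stable for large |eta|
    return float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))


def _check_rank(X: np.ndarray, w: np.ndarray, columns: Sequence[str]) -> None:
    Xw = X * np.sqrt(w)[:, None]
    _, R, piv = scipy.linalg.qr(Xw, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(Xw.shape) * np.finfo(float).eps if diag.size else 0.0
    deficient = diag <= tol
    if deficient.any():
        bad = [columns[piv[i]] for i in np.nonzero(deficient)[0]]
        raise RankDeficiencyError(
            f"design is rank deficient on the weighted sample; collinear "
            f"columns: {bad}"
        )


def fit_weighted_logit(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    columns: Sequence[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
    ridge: float = 0.0,
) -> LogitFit:
    """Maximize the weighted Bernoulli log-likelihood by IRLS.

    Convergence: max-norm of the weighted score below ``tol`` (default 1e-8)
    within ``max_iter`` Newton steps; each step is halved until the penalized
    log-likelihood does not decrease.  ``ridge`` > 0 adds an optional small
    quadratic penalty (off by default) for near-separated designs.  The
    covariance is the inverse weighted observed information at the optimum.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    n, p = X.shape
    cols = tuple(columns) if columns is not None else tuple(f"x{j}" for j in range(p))
    if len(cols) != p:
        raise ConfigurationError("column-name count does not match design width")
    _check_rank(X, w, cols)

    beta = np.zeros(p)
    ll = _weighted_loglik(X, y, w, beta) - 0.5 * ridge * beta @ beta
    H = np.eye(p)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        score = X.T @ (w * (y - mu)) - ridge * beta
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        Wd = np.clip(w * mu * (1.0 - mu), 1e-12, None)
        H = X.T @ (X * Wd[:, None]) + ridge * np.eye(p)
        try:
            delta = np.linalg.solve(H, score)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by rank check
            raise RankDeficiencyError(f"singular information matrix: {exc}") from exc
        # accept steps whose likelihood change is within float noise of the
        # accumulated log-likelihood, or step-halving stalls near the optimum
        noise = 1e-10 * (1.0 + abs(ll))
        step = 1.0
        for _ in range(40):
            cand = beta + step * delta
            ll_cand = _weighted_loglik(X, y, w, cand) - 0.5 * ridge * cand @ cand
            if ll_cand >= ll - noise:
                break
            step *= 0.5
        beta, ll = cand, ll_cand
        if np.max(np.abs(beta)) > SEPARATION_THRESHOLD:
            k = int(np.argmax(np.abs(beta)))
            raise SeparationError(
                f"complete/quasi-complete separation suspected: |beta| > "
                f"{SEPARATION_THRESHOLD} for column {cols[k]!r}"
            )
    if not converged:
        raise ConvergenceError(
            f"IRLS did not converge in {max_iter} iterations (score norm "
            f"{np.max(np.abs(score)):.3e})"
        )
    # polish: up to two further Newton steps drive the score from ~tol down
    # to machine precision, so score-equation identities (fitted weighted
    # mean == weighted outcome mean) hold far below reporting tolerances
    for _ in range(2):
        mu = expit(X @ beta)
        score = X.T @ (w * (y - mu)) - ridge * beta
        if np.max(np.abs(score)) == 0.0:
            break
        Wd = np.clip(w * mu * (1.0 - mu), 1e-12, None)
        Hp = X.T @ (X * Wd[:, None]) + ridge * np.eye(p)
        try:
            cand = beta + np.linalg.solve(Hp, score)
        except np.linalg.LinAlgError:
            break
        ll_cand = _weighted_loglik(X, y, w, cand) - 0.5 * ridge * cand @ cand
        if ll_cand < ll - 1e-10 * (1.0 + abs(ll)) or np.max(np.abs(cand)) > SEPARATION_THRESHOLD:
            break
        beta, ll = cand, ll_cand
    mu = expit(X @ beta)
    Wd = np.clip(w * mu * (1.0 - mu), 1e-12, None)
    H = X.T @ (X * Wd[:, None]) + ridge * np.eye(p)
    vcov = np.linalg.inv(H)
    return LogitFit(
        params=beta,
        columns=cols,
        vcov=vcov,
        converged=True,
        n_iter=it,
        n=n,
        total_weight=float(w.sum()),
        loglik=_weighted_loglik(X, y, w, beta),
    )


@dataclass
class NormalizedFit:
    """Deviation-coded ("normalized") coefficients on the expanded design.

    ``params`` aligns with ``DesignSpec.full_columns``: the adjusted intercept
    followed by one coefficient per category of every covariate, each
    covariate block summing to zero.  The linear predictor on the expanded
    design equals the originating reference-coded fit's for every record.
    """

    params: np.ndarray
    columns: tuple[str, ...]
    converged: bool = True

    @property
    def coef(self) -> dict[str, float]:
        return dict(zip(self.columns, self.params.tolist()))

    def predict_proba(self, X_full: np.ndarray) -> np.ndarray:
        return expit(np.asarray(X_full, dtype=float) @ self.params)


def normalize_categorical(
    fit: LogitFit | NormalizedFit, spec: DesignSpec
) -> NormalizedFit:
    """Center each covariate's coefficients around zero (deviation coding).

    For a covariate with J categories, the J coefficients (the reference's
    implicit 0 included) are replaced by deviations from their unweighted
    mean, and the sum of the means is folded into the intercept.  Applying
    the transform to an already-normalized fit is a no-op (idempotent).
    """
    full_cols = spec.full_columns
    if isinstance(fit, NormalizedFit):
        if tuple(fit.columns) != tuple(full_cols):
            raise ConfigurationError("normalized fit does not match the design spec")
        coef = dict(zip(fit.columns, fit.params))
    else:
        if not fit.converged:
            raise ConvergenceError("refusing to normalize a non-converged fit")
        coef = {c: 0.0 for c in full_cols}
        ref_cols = fit.columns
        lookup = dict(zip(ref_cols, fit.params))
        coef["intercept"] = lookup["intercept"]
        for cov in spec.covariates:
            for cat in cov.categories:
                name = f"{cov.name}[{cat}]"
                coef[name] = lookup.get(name, 0.0)
    params = np.zeros(len(full_cols))
    params[0] = coef["intercept"]
    idx = 1
    for cov in spec.covariates:
        J = len(cov.categories)
        block = np.array([coef[f"{cov.name}[{cat}]"] for cat in cov.categories])
        m = block.mean()
        params[idx : idx + J] = block - m
        params[0] += m
        idx += J
    return NormalizedFit(params=params, columns=tuple(full_cols))
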