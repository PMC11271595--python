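"""Nonlinear (logit) decomposition of change in a binary outcome between
two survey waves.

The observed gap in weighted outcome prevalence, D = p̄_A − p̄_B (A the later
wave, B the earlier), is split additively into a characteristics/endowment
component E — what the gap would close to if the earlier population had the
later wave's composition — and a coefficients/behavioral component C — the
change attributable to shifted covariate effects, intercept included:

    E = meanW_A[F(x'β̂_A)] − meanW_B[F(x'β̂_A)],
    C = meanW_B[F(x'β̂_A)] − meanW_B[F(x'β̂_B)],

with F the logistic function and each mean taken over a wave's records with
its sampling weights.  This is the sample-averaged probability-scale
counterpart of the logit-scale identity

    logit(A) − logit(B) = [β0A − β0B] + Σ β_A (X̄_A − X̄_B) + Σ X̄_B (β_A − β_B).

Because each wave's fit satisfies its intercept score equation (the
weighted mean fitted probability equals the weighted outcome mean, to
machine precision after polishing), the telescope collapses and E + C = D
exactly.  Per-covariate detailed
contributions apportion E and C with Yun's proportional weights built from
the linear-predictor terms β_A_k(X̄_A_k − X̄_B_k) and X̄_B_k(β_A_k − β_B_k);
with categorical normalization on (the default) those shares are invariant
to each covariate's reference-category choice.  Uncertainty comes from a
seeded percentile bootstrap, resampling whole clusters when cluster ids are
present.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .core_records import ConfigurationError, SurveyWave, dichotomize_array
from .weighted_logit import (
    ConvergenceError,
    DesignSpec,
    LogitFit,
    NormalizedFit,
    RankDeficiencyError,
    SeparationError,
    build_design,
    build_full_design,
    fit_weighted_logit,
    normalize_categorical,
)

__all__ = [
    "GroupSummary",
    "DecompositionResult",
    "group_summary",
    "overall_components",
    "yun_detailed",
    "bootstrap_ci",
    "decompose",
    "BootstrapError",
    "UnattributableError",
]

log = logging.getLogger(__name__)

#: |D| below this suppresses percentage attributions (they would explode).
PCT_SUPPRESS_D = 1e-4

#: |sum of linear shares| below this makes Yun weights undefined.
SHARE_EPS = 1e-12


class BootstrapError(RuntimeError):
    """Too many bootstrap resamples failed to converge."""


class UnattributableError(RuntimeError):
    """A component is non-negligible but its linear shares sum to ~zero."""


@dataclass
class GroupSummary:
    """Weighted design summaries plus the raw arrays for one wave."""

    year: str
    X: np.ndarray                 # reference-coded design (n x p)
    X_full: np.ndarray            # expanded design, one dummy per category
    y: np.ndarray
    w: np.ndarray
    cluster_ids: np.ndarray
    columns: tuple[str, ...]
    full_columns: tuple[str, ...]
    xbar: np.ndarray              # weighted means of X
    xbar_full: np.ndarray         # weighted means of X_full
    pbar: float                   # weighted outcome proportion
    total_weight: float
    n: int

    def take(self, idx: np.ndarray) -> "GroupSummary":
        """Row-resampled copy (used by the bootstrap)."""
        X, Xf, y, w = self.X[idx], self.X_full[idx], self.y[idx], self.w[idx]
        sw = float(w.sum())
        return GroupSummary(
            year=self.year,
            X=X,
            X_full=Xf,
            y=y,
            w=w,
            cluster_ids=self.cluster_ids[idx],
            columns=self.columns,
            full_columns=self.full_columns,
            xbar=(w @ X) / sw,
            xbar_full=(w @ Xf) / sw,
            pbar=float((w @ y) / sw),
            total_weight=sw,
            n=len(y),
        )


def group_summary(wave: SurveyWave, spec: DesignSpec, outcome: str) -> GroupSummary:
    """Weighted covariate means (reference-coded and expanded) and the
    weighted outcome proportion of one wave."""
    X, y, w, columns = build_design(wave, spec, outcome)
    X_full = build_full_design(wave, spec)
    sw = float(w.sum())
    if sw <= 0:
        raise ValueError("zero total weight")
    return GroupSummary(
        year=wave.year,
        X=X,
        X_full=X_full,
        y=y,
        w=w,
        cluster_ids=wave.frame["cluster_id"].astype(str).to_numpy(),
        columns=columns,
        full_columns=spec.full_columns,
        xbar=(w @ X) / sw,
        xbar_full=(w @ X_full) / sw,
        pbar=float((w @ y) / sw),
        total_weight=sw,
        n=len(y),
    )


def _require_converged(*fits: LogitFit) -> None:
    for f in fits:
        if not f.converged:
            raise ConvergenceError("refusing to decompose with a non-converged fit")


def overall_components(
    fit_a: LogitFit,
    fit_b: LogitFit,
    sum_a: GroupSummary,
    sum_b: GroupSummary,
    index: str = "late",
) -> tuple[float, float, float]:
    """Overall gap D = p̄_A − p̄_B and its (E, C) split.

    ``index="late"`` (default) evaluates the counterfactual with the later
    wave's coefficients on the earlier wave's records, matching
    Σβ_A[ΔX] + ΣX_B[Δβ]; ``index="early"`` is the mirror-image weighting
    offered for sensitivity, as Oaxaca-type splits are index-dependent.
    E + C = D up to the intercept score-equation residuals of the two fits
    (machine precision for polished IRLS fits); identical coefficient
    vectors give C = 0 exactly.
    """
    _require_converged(fit_a, fit_b)
    if tuple(fit_a.columns) != tuple(fit_b.columns):
        raise ConfigurationError("fits do not share a design spec")
    D = sum_a.pbar - sum_b.pbar

    def wmean(s: GroupSummary, params: np.ndarray) -> float:
        return float((s.w @ expit(s.X @ params)) / s.total_weight)

    if index == "late":
        cf = wmean(sum_b, fit_a.params)
        E = wmean(sum_a, fit_a.params) - cf
        C = cf - wmean(sum_b, fit_b.params)
    elif index == "early":
        cf = wmean(sum_a, fit_b.params)
        E = cf - wmean(sum_b, fit_b.params)
        C = wmean(sum_a, fit_a.params) - cf
    else:
        raise ConfigurationError(f"unknown index convention {index!r}")
    return D, E, C


def _apportion(shares: np.ndarray, total: float, what: str, strict: bool) -> np.ndarray:
    denom = float(shares.sum())
    if abs(denom) < SHARE_EPS:
        if abs(total) < 1e-10:
            return np.zeros_like(shares)
        if strict:
            raise UnattributableError(
                f"{what} component {total:.3g} unattributable: linear shares "
                f"sum to {denom:.3g}"
            )
        return np.full_like(shares, np.nan)
    return shares / denom * total


def yun_detailed(
    fit_a: LogitFit | NormalizedFit,
    fit_b: LogitFit | NormalizedFit,
    sum_a: GroupSummary,
    sum_b: GroupSummary,
    E: float,
    C: float,
    index: str = "late",
    strict: bool = False,
) -> pd.DataFrame:
    """Per-column detailed contributions via Yun's proportional weights.

    The linear shares are s_k^E = β_A_k (X̄_A_k − X̄_B_k) and
    s_k^C = X̄_B_k (β_A_k − β_B_k) (index="late"; the intercept, with
    X̄ ≡ 1 and ΔX̄ = 0, contributes to C only).  Each component is then
    apportioned proportionally: E_k = E · s_k^E / Σ s^E, likewise for C.
    Pass normalized fits for reference-category-invariant contributions.
    """
    normalized = isinstance(fit_a, NormalizedFit)
    if normalized != isinstance(fit_b, NormalizedFit):
        raise ConfigurationError("mix of normalized and reference-coded fits")
    if normalized:
        terms = sum_a.full_columns
        beta_a, beta_b = fit_a.params, fit_b.params
        xbar_a, xbar_b = sum_a.xbar_full, sum_b.xbar_full
    else:
        _require_converged(fit_a, fit_b)
        terms = sum_a.columns
        beta_a, beta_b = fit_a.params, fit_b.params
        xbar_a, xbar_b = sum_a.xbar, sum_b.xbar
    beta_e = beta_a if index == "late" else beta_b
    xbar_c = xbar_b if index == "late" else xbar_a
    s_e = beta_e * (xbar_a - xbar_b)
    s_c = xbar_c * (beta_a - beta_b)
    e_k = _apportion(s_e, E, "characteristics (E)", strict)
    c_k = _apportion(s_c, C, "coefficients (C)", strict)
    return pd.DataFrame(
        {
            "term": list(terms),
            "share_E": s_e,
            "share_C": s_c,
            "E": e_k,
            "C": c_k,
        }
    )


def _estimate_once(
    sum_a: GroupSummary,
    sum_b: GroupSummary,
    spec: DesignSpec,
    normalize: bool,
    index: str,
    tol: float,
    max_iter: int,
):
    fit_a = fit_weighted_logit(sum_a.X, sum_a.y, sum_a.w, columns=sum_a.columns,
                               tol=tol, max_iter=max_iter)
    fit_b = fit_weighted_logit(sum_b.X, sum_b.y, sum_b.w, columns=sum_b.columns,
                               tol=tol, max_iter=max_iter)
    D, E, C = overall_components(fit_a, fit_b, sum_a, sum_b, index=index)
    if normalize:
        na = normalize_categorical(fit_a, spec)
        nb = normalize_categorical(fit_b, spec)
        detail = yun_detailed(na, nb, sum_a, sum_b, E, C, index=index)
    else:
        detail = yun_detailed(fit_a, fit_b, sum_a, sum_b, E, C, index=index)
    return fit_a, fit_b, D, E, C, detail


def _cluster_index_map(cluster_ids: np.ndarray) -> list[np.ndarray]:
    order = pd.unique(cluster_ids)
    return [np.nonzero(cluster_ids == c)[0] for c in order]


def bootstrap_ci(
    wave_a: SurveyWave,
    wave_b: SurveyWave,
    spec: DesignSpec,
    outcome: str,
    reps: int = 500,
    seed: int = 0,
    cluster: bool | None = None,
    normalize: bool = True,
    index: str = "late",
    alpha: float = 0.05,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> dict:
    """Seeded percentile bootstrap intervals for D, E, C and the detailed
    contributions.

    ``cluster=None`` resamples whole clusters (two-stage-design flavour) when
    more than one cluster id is present in both waves, else records.  Any
    resample on which a fit fails (separation, rank loss, non-convergence)
    is redrawn and counted; more than 10% failures aborts.
    """
    if reps < 100:
        raise ConfigurationError("bootstrap needs reps >= 100")
    sum_a = group_summary(wave_a, spec, outcome)
    sum_b = group_summary(wave_b, spec, outcome)
    if cluster is None:
        cluster = (
            len(np.unique(sum_a.cluster_ids)) > 1
            and len(np.unique(sum_b.cluster_ids)) > 1
        )
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(97,)))
    maps = None
    if cluster:
        maps = (_cluster_index_map(sum_a.cluster_ids), _cluster_index_map(sum_b.cluster_ids))

    def draw(summary: GroupSummary, cmap) -> GroupSummary:
        if cluster:
            pick = rng.integers(0, len(cmap), size=len(cmap))
            idx = np.concatenate([cmap[i] for i in pick])
        else:
            idx = rng.integers(0, summary.n, size=summary.n)
        return summary.take(idx)

    stats_D, stats_E, stats_C = [], [], []
    stats_Ek, stats_Ck = [], []
    failures = 0
    max_failures = max(1, int(0.10 * reps))
    while len(stats_D) < reps:
        ra = draw(sum_a, maps[0] if maps else None)
        rb = draw(sum_b, maps[1] if maps else None)
        try:
            _, _, D, E, C, detail = _estimate_once(
                ra, rb, spec, normalize, index, tol, max_iter
            )
        except (SeparationError, RankDeficiencyError, ConvergenceError) as exc:
            failures += 1
            log.info("bootstrap resample redrawn (%s)", exc)
            if failures > max_failures:
                raise BootstrapError(
                    f"{failures} bootstrap resamples failed (> 10% of {reps})"
                ) from exc
            continue
        stats_D.append(D)
        stats_E.append(E)
        stats_C.append(C)
        stats_Ek.append(detail["E"].to_numpy())
        stats_Ck.append(detail["C"].to_numpy())
    qs = [100 * alpha / 2, 100 * (1 - alpha / 2)]
    Ek = np.vstack(stats_Ek)
    Ck = np.vstack(stats_Ck)
    return {
        "D": tuple(np.percentile(stats_D, qs)),
        "E": tuple(np.percentile(stats_E, qs)),
        "C": tuple(np.percentile(stats_C, qs)),
        "E_k": np.percentile(Ek, qs, axis=0).T,   # (n_terms, 2)
        "C_k": np.percentile(Ck, qs, axis=0).T,
        "failures": failures,
        "reps": reps,
        "cluster": bool(cluster),
        "alpha": alpha,
    }


@dataclass
class DecompositionResult:
    """Overall and per-covariate decomposition of a prevalence change.

    Components are on the probability scale (a value of 0.01 is one
    percentage point); percentage attributions are 100·component/D and are
    suppressed (``None``/NaN) when |D| < 1e-4.
    """

    outcome: str
    year_a: str
    year_b: str
    D: float
    E: float
    C: float
    pct_E: float | None
    pct_C: float | None
    detail: pd.DataFrame          # term, covariate, E, C, pct_E, pct_C [+ CI cols]
    ci: dict | None
    meta: dict = field(default_factory=dict)

    def validate(self, atol: float = 1e-10) -> None:
        assert abs(self.E + self.C - self.D) <= atol
        if not self.detail["E"].isna().any():
            assert abs(self.detail["E"].sum() - self.E) <= atol
        if not self.detail["C"].isna().any():
            assert abs(self.detail["C"].sum() - self.C) <= atol

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-term table with an 'overall' row appended."""
        rows = self.detail.copy()
        overall = {
            "term": "overall",
            "covariate": "overall",
            "E": self.E,
            "C": self.C,
            "pct_E": np.nan if self.pct_E is None else self.pct_E,
            "pct_C": np.nan if self.pct_C is None else self.pct_C,
        }
        if self.ci is not None:
            overall.update(
                E_lo=self.ci["E"][0], E_hi=self.ci["E"][1],
                C_lo=self.ci["C"][0], C_hi=self.ci["C"][1],
            )
        return pd.concat([rows, pd.DataFrame([overall])], ignore_index=True)

    def to_text(self) -> str:
        frame = self.to_frame().copy()
        for col in frame.columns:
            if frame[col].dtype.kind == "f":
                frame[col] = frame[col].map(lambda v: f"{v:.5f}" if pd.notna(v) else "—")
        header = (
            f"Decomposition of {self.outcome} change, {self.year_b} -> {self.year_a}\n"
            f"D = {self.D:.5f}  E = {self.E:.5f}  C = {self.C:.5f}"
        )
        if self.pct_E is not None:
            header += f"  (pct E = {self.pct_E:.2f}, pct C = {self.pct_C:.2f})"
        return header + "\n\n" + frame.to_string(index=False)


def decompose(
    wave_a: SurveyWave,
    wave_b: SurveyWave,
    spec: DesignSpec,
    outcome: str,
    reps: int = 500,
    seed: int = 0,
    cluster: bool | None = None,
    normalize: bool = True,
    index: str = "late",
    ci: bool = True,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> DecompositionResult:
    """Full pipeline: summaries -> weighted logits -> (normalized) detailed
    decomposition -> bootstrap intervals.

    ``wave_a`` is the later survey, ``wave_b`` the earlier; both must already
    be restricted to the analysis population (see ``apply_exclusions``).
    """
    sum_a = group_summary(wave_a, spec, outcome)
    sum_b = group_summary(wave_b, spec, outcome)
    _, _, D, E, C, detail = _estimate_once(
        sum_a, sum_b, spec, normalize, index, tol, max_iter
    )
    detail = detail.copy()
    detail.insert(1, "covariate", [spec.column_covariate(t) for t in detail["term"]])
    if abs(D) < PCT_SUPPRESS_D:
        pct_E = pct_C = None
        detail["pct_E"] = np.nan
        detail["pct_C"] = np.nan
    else:
        pct_E = 100.0 * E / D
        pct_C = 100.0 * C / D
        detail["pct_E"] = 100.0 * detail["E"] / D
        detail["pct_C"] = 100.0 * detail["C"] / D
    boot = None
    if ci:
        boot = bootstrap_ci(
            wave_a, wave_b, spec, outcome,
            reps=reps, seed=seed, cluster=cluster,
            normalize=normalize, index=index, tol=tol, max_iter=max_iter,
        )
        detail["E_lo"] = boot["E_k"][:, 0]
        detail["E_hi"] = boot["E_k"][:, 1]
        detail["C_lo"] = boot["C_k"][:, 0]
        detail["C_hi"] = boot["C_k"][:, 1]
    result = DecompositionResult(
        outcome=outcome,
        year_a=wave_a.year,
        year_b=wave_b.year,
        D=D, E=E, C=C, pct_E=pct_E, pct_C=pct_C,
        detail=detail,
        ci=boot,
        meta={
            "index": index,
            "normalize": normalize,
            "reps": reps if ci else 0,
            "seed": seed,
            "n_a": sum_a.n,
            "n_b": sum_b.n,
            "total_weight_a": sum_a.total_weight,
            "total_weight_b": sum_b.total_weight,
        },
    )
    result.validate()
    return result
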