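"""Nested validation models, rare-outcome logistic sequence, and E-values.

The nested sequence on the held-out subsample fits four mixed models on one
common row set (rows complete for the largest model): demographics (M1),
+ non-social screentime (M2), + non-digital adversity (M3), + the digital
risk score (M4), reporting marginal R^2 and its increments.  The rare binary
outcome is modeled with plain logistic regression mirroring the same
sequence.  Confounding sensitivity binarizes the continuous outcome at the
top decile and converts the resulting odds ratio into an E-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mixed_models import (LmmFit, GlmFit, fit_lmm, fit_logistic,
                           ensure_sex_indicator)
from .risk_scoring import ScoreVector

__all__ = [
    "VALIDATION_COVARIATES",
    "ModelSummary",
    "NestedModelReport",
    "EvalueResult",
    "run_nested_validation",
    "run_attempt_models",
    "binarize_top_decile",
    "evalue",
    "run_evalue",
]

VALIDATION_COVARIATES = ("age", "sex_male", "race_black", "race_white",
                         "hispanic", "income_ordinal", "parent_education")

SCORE_COL = "risk_score_z"
SCREENTIME_Z = "nonsocial_screentime_z"


@dataclass
class ModelSummary:
    label: str
    fit: LmmFit
    marginal_r2: float
    delta_r2: float

    def to_dict(self) -> dict:
        return {"label": self.label, "marginal_r2": self.marginal_r2,
                "delta_r2": self.delta_r2, "fit": self.fit.to_dict()}


@dataclass
class NestedModelReport:
    models: dict[str, ModelSummary]
    n_used: int
    converged: bool

    def to_dict(self) -> dict:
        return {"n_used": self.n_used, "converged": self.converged,
                "models": {k: v.to_dict() for k, v in self.models.items()}}

    def table(self) -> pd.DataFrame:
        """Human-readable long table (model, term, estimate, CI, t, p)."""
        rows = []
        for label, summary in self.models.items():
            for term, eff in summary.fit.beta.items():
                rows.append({
                    "model": label, "term": term, "estimate": eff.estimate,
                    "ci_low": eff.ci_low, "ci_high": eff.ci_high,
                    "t": eff.t, "p": eff.p,
                })
            rows.append({"model": label, "term": "<marginal_r2>",
                         "estimate": summary.marginal_r2,
                         "ci_low": np.nan, "ci_high": np.nan,
                         "t": np.nan, "p": np.nan})
        return pd.DataFrame(rows)


@dataclass
class EvalueResult:
    observed_or: float
    ci_limit: float
    evalue_point: float
    evalue_ci: float
    outcome_cutoff: float = float("nan")
    prevalence: float = float("nan")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("observed_or", "ci_limit", "evalue_point", "evalue_ci",
                 "outcome_cutoff", "prevalence")}


def _scores_frame(scores) -> pd.DataFrame:
    if isinstance(scores, ScoreVector):
        return scores.frame()[["participant_id", "z_score"]]
    return scores[["participant_id", "z_score"]]


def _merged_test_table(test: pd.DataFrame, scores) -> pd.DataFrame:
    if "subsample" in test.columns and (test["subsample"] == "train").any():
        test = test[test["subsample"] == "test"]
    test = ensure_sex_indicator(test)
    merged = test.merge(_scores_frame(scores).rename(columns={"z_score": SCORE_COL}),
                        on="participant_id", how="inner")
    st = merged["nonsocial_screentime"]
    sd = st.std(ddof=1)
    if not (sd > 0):
        raise ValueError("non-social screentime is constant; cannot z-score")
    # standardized before any model-specific deletion
    merged[SCREENTIME_Z] = (st - st.mean()) / sd
    return merged


def run_nested_validation(
    test: pd.DataFrame,
    scores,
    outcome: str = "outcome_continuous",
    adversity_col: str = "adversity",
    covariates: tuple[str, ...] = VALIDATION_COVARIATES,
) -> NestedModelReport:
    """Fit the four nested mixed models on one common row set."""
    merged = _merged_test_table(test, scores)
    terms = {
        "M1": list(covariates),
        "M2": list(covariates) + [SCREENTIME_Z],
        "M3": list(covariates) + [SCREENTIME_Z, adversity_col],
        "M4": list(covariates) + [SCREENTIME_Z, adversity_col, SCORE_COL],
    }
    common = merged.dropna(subset=[outcome] + terms["M4"])
    models: dict[str, ModelSummary] = {}
    prev_r2 = 0.0
    converged = True
    for label in ("M1", "M2", "M3", "M4"):
        fit = fit_lmm(common, outcome, terms[label])
        converged = converged and fit.converged
        models[label] = ModelSummary(
            label=label, fit=fit, marginal_r2=fit.marginal_r2,
            delta_r2=fit.marginal_r2 - prev_r2,
        )
        prev_r2 = fit.marginal_r2
    ns = {m.fit.n_used for m in models.values()}
    if len(ns) != 1:
        raise AssertionError("nested models fitted on differing row sets")
    if not converged:
        for m in models.values():
            m.delta_r2 = float("nan")  # Delta R^2 suppressed on flagged fits
    return NestedModelReport(models=models, n_used=ns.pop(), converged=converged)


def run_attempt_models(
    test: pd.DataFrame,
    scores,
    outcome: str = "outcome_binary",
    adversity_col: str = "adversity",
    covariates: tuple[str, ...] = VALIDATION_COVARIATES,
) -> list[GlmFit]:
    """Logistic sequence for the rare binary outcome.

    Two fits on the rows complete for the larger model: score + demographics
    + non-social screentime, then additionally adversity.  Odds ratios for
    the score are per 1 SD because the score enters z-scored.
    """
    merged = _merged_test_table(test, scores)
    base = [SCORE_COL] + list(covariates) + [SCREENTIME_Z]
    full = base + [adversity_col]
    common = merged.dropna(subset=[outcome] + full)
    if (common[outcome] == 1).sum() == 0:
        raise ValueError("binary outcome has no events after deletion")
    return [fit_logistic(common, outcome, base),
            fit_logistic(common, outcome, full)]


def binarize_top_decile(values) -> tuple[np.ndarray, float]:
    """Flag values strictly above the empirical 90th percentile.

    Ties at the cutoff go to the reference class.  Returns the indicator
    vector (NaN preserved for missing inputs) and the realized prevalence.
    """
    v = np.asarray(values, dtype=float)
    obs = v[~np.isnan(v)]
    if len(obs) < 10:
        raise ValueError("need at least 10 non-missing values")
    if obs.max() == obs.min():
        raise ValueError("constant outcome cannot be binarized")
    cutoff = float(np.quantile(obs, 0.9))
    out = np.where(np.isnan(v), np.nan, (v > cutoff).astype(float))
    prevalence = float(np.nanmean(out))
    return out, prevalence


def _evalue_from_rr(rr: float) -> float:
    if rr < 1.0:
        rr = 1.0 / rr
    return rr + np.sqrt(rr * (rr - 1.0))


def evalue(or_point: float, or_ci_limit: float | None = None,
           rare_outcome: bool = True) -> EvalueResult:
    """E-value for an odds ratio on the risk-ratio scale.

    With a rare outcome the OR approximates the RR directly; otherwise the
    square-root correction is applied.  ``or_ci_limit`` is the confidence
    limit closer to the null; the CI E-value is 1 when the interval crosses 1.
    """
    if or_point <= 0 or (or_ci_limit is not None and or_ci_limit <= 0):
        raise ValueError("odds ratios must be positive")
    to_rr = (lambda x: x) if rare_outcome else np.sqrt
    rr = float(to_rr(or_point))
    e_point = float(_evalue_from_rr(rr)) if rr != 1.0 else 1.0
    e_ci = float("nan")
    if or_ci_limit is not None:
        rr_ci = float(to_rr(or_ci_limit))
        crosses = (rr >= 1.0 and rr_ci <= 1.0) or (rr < 1.0 and rr_ci >= 1.0)
        e_ci = 1.0 if crosses else float(_evalue_from_rr(rr_ci))
    return EvalueResult(
        observed_or=float(or_point),
        ci_limit=float(or_ci_limit) if or_ci_limit is not None else float("nan"),
        evalue_point=e_point,
        evalue_ci=e_ci,
    )


def run_evalue(
    test: pd.DataFrame,
    scores,
    outcome: str = "outcome_continuous",
    adversity_col: str = "adversity",
    covariates: tuple[str, ...] = VALIDATION_COVARIATES,
) -> EvalueResult:
    """Top-decile binarization of the continuous outcome, the full-covariate
    logistic model, and the E-value of the score's odds ratio."""
    merged = _merged_test_table(test, scores)
    terms = [SCORE_COL] + list(covariates) + [SCREENTIME_Z, adversity_col]
    common = merged.dropna(subset=[outcome] + terms).copy()
    flags, prevalence = binarize_top_decile(common[outcome].to_numpy())
    cutoff = float(np.quantile(common[outcome], 0.9))
    common["_high_outcome"] = flags
    glm = fit_logistic(common, "_high_outcome", terms)
    est = glm.or_[SCORE_COL]
    limit = est.ci_low if est.odds_ratio >= 1.0 else est.ci_high
    result = evalue(est.odds_ratio, limit, rare_outcome=True)
    result.outcome_cutoff = cutoff
    result.prevalence = prevalence
    return result
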