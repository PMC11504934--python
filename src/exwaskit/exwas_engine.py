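"""Exposure-wide screen: one mixed model per exposure, BH-FDR, classification.

Each exposure is tested in its own linear mixed model on the training
subsample with the screening covariate set (age, sex, Black race, White race,
Hispanic ethnicity) and family-in-site random intercepts.  The
Benjamini-Hochberg adjustment is applied over exactly the set of tested
exposures; significant associations are classified as risk (coefficient > 0)
or protective (coefficient < 0).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .mixed_models import fit_lmm, ensure_sex_indicator

__all__ = ["ExWASRecord", "SCREEN_COVARIATES", "bh_fdr", "run_exwas",
           "records_to_frame", "records_from_frame"]

SCREEN_COVARIATES = ("age", "sex_male", "race_black", "race_white", "hispanic")

_SIG_LEVEL = 0.05


@dataclass
class ExWASRecord:
    exposure: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    t: float
    p: float
    q: float
    direction: str          # "risk" | "protective"
    significant: bool
    domain: str = "other"
    converged: bool = True
    n_used: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p must be a non-empty 1-d vector")
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def run_exwas(
    train: pd.DataFrame,
    exposures: list[str],
    outcome: str = "outcome_continuous",
    covariates: tuple[str, ...] = SCREEN_COVARIATES,
    domains: dict[str, str] | None = None,
    site_col: str = "site_id",
    family_col: str = "family_id",
) -> list[ExWASRecord]:
    """Screen every exposure in a separate mixed model; BH-FDR over the set.

    Non-converged fits stay in the FDR family (their p-value counts toward
    the adjustment) but are flagged and never marked significant, which bars
    them from score construction.
    """
    if "subsample" in train.columns and (train["subsample"] == "test").any():
        train = train[train["subsample"] == "train"]
    train = ensure_sex_indicator(train)
    domains = domains or {}
    fits = []
    for name in exposures:
        fit = fit_lmm(train, outcome, [name, *covariates],
                      site_col=site_col, family_col=family_col)
        fits.append(fit)
    pvals = np.array([f.beta[name].p for f, name in zip(fits, exposures)])
    qvals = bh_fdr(pvals)
    records = []
    for name, fit, q in zip(exposures, fits, qvals):
        eff = fit.beta[name]
        records.append(ExWASRecord(
            exposure=name,
            beta=eff.estimate,
            se=eff.se,
            ci_low=eff.ci_low,
            ci_high=eff.ci_high,
            t=eff.t,
            p=eff.p,
            q=float(q),
            direction="risk" if eff.estimate > 0 else "protective",
            significant=bool(q < _SIG_LEVEL and fit.converged),
            domain=domains.get(name, "other"),
            converged=fit.converged,
            n_used=fit.n_used,
        ))
    return records


def records_to_frame(records: list[ExWASRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in records])


def records_from_frame(frame: pd.DataFrame) -> list[ExWASRecord]:
    return [ExWASRecord(**{k: row[k] for k in ExWASRecord.__dataclass_fields__})
            for _, row in frame.iterrows()]
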