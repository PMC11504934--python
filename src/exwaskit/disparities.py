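"""Subgroup comparisons of risk-score distributions and score-by-group
interaction models with stratified simple slopes.

Differential exposure: Kruskal-Wallis across three race/ethnicity groups with
Dunn-Holm pairwise follow-up, and Mann-Whitney tests with the rank-biserial
effect size for two-group contrasts.  Differential effects: the validation
M4 model augmented with score-by-group product terms, parsed by stratified
refits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .mixed_models import fit_lmm, ensure_sex_indicator
from .validation import (VALIDATION_COVARIATES, SCORE_COL, SCREENTIME_Z,
                         _merged_test_table)

__all__ = [
    "GroupTestResult",
    "InteractionResult",
    "kruskal_wallis",
    "dunn_holm",
    "mann_whitney_rb",
    "fit_interactions",
    "holm_adjust",
    "race3_labels",
]


@dataclass
class GroupTestResult:
    test: str
    groups: list[str]
    statistic: float
    p: float
    df: int | None = None
    adjusted_p: float | None = None
    effect_size: float | None = None
    medians: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "test": self.test, "groups": list(self.groups),
            "statistic": self.statistic, "df": self.df, "p": self.p,
            "adjusted_p": self.adjusted_p, "effect_size": self.effect_size,
            "medians": dict(self.medians),
        }


@dataclass
class InteractionResult:
    term: str
    estimate: float
    se: float
    t: float
    p: float
    stratified_slopes: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"term": self.term, "estimate": self.estimate, "se": self.se,
                "t": self.t, "p": self.p,
                "stratified_slopes": self.stratified_slopes}


def _split_groups(values, labels):
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    keep = ~pd.isna(values) & ~pd.isna(labels)
    values, labels = values[keep], labels[keep]
    order = list(dict.fromkeys(labels))  # first-appearance order
    return order, {g: values[labels == g] for g in order}


def kruskal_wallis(values, labels) -> GroupTestResult:
    """Tie-corrected Kruskal-Wallis H with a chi-square reference (k-1 df)."""
    order, groups = _split_groups(values, labels)
    if len(order) < 3:
        raise ValueError("kruskal_wallis needs >= 3 groups; use mann_whitney_rb")
    if any(len(g) < 2 for g in groups.values()):
        raise ValueError("every group needs at least 2 observations")
    h, p = stats.kruskal(*groups.values())
    return GroupTestResult(
        test="kruskal_wallis", groups=order, statistic=float(h),
        df=len(order) - 1, p=float(p),
        medians={g: float(np.median(v)) for g, v in groups.items()},
    )


def holm_adjust(p) -> np.ndarray:
    """Holm step-down adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.maximum.accumulate(p[order] * (m - np.arange(m)))
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def _tie_term(pooled_ranks_source: np.ndarray) -> float:
    _, counts = np.unique(pooled_ranks_source, return_counts=True)
    n = len(pooled_ranks_source)
    return float(np.sum(counts ** 3 - counts) / (12.0 * (n - 1)))


def dunn_holm(values, labels) -> list[GroupTestResult]:
    """Dunn's pairwise z-tests on the pooled ranking, Holm-adjusted.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) * (1/n_i + 1/n_j)),
    with T the tie correction on the pooled sample.
    """
    order, groups = _split_groups(values, labels)
    if len(order) < 3:
        raise ValueError("dunn_holm needs >= 3 groups")
    pooled = np.concatenate([groups[g] for g in order])
    ranks = stats.rankdata(pooled)
    n_total = len(pooled)
    mean_ranks, sizes = {}, {}
    start = 0
    for g in order:
        k = len(groups[g])
        mean_ranks[g] = ranks[start:start + k].mean()
        sizes[g] = k
        start += k
    var_base = n_total * (n_total + 1) / 12.0 - _tie_term(pooled)
    pairs = [(order[i], order[j]) for i in range(len(order))
             for j in range(i + 1, len(order))]
    zs, ps = [], []
    for a, b in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        zs.append(z)
        ps.append(float(special.erfc(abs(z) / np.sqrt(2.0))))
    adj = holm_adjust(ps)
    return [
        GroupTestResult(
            test="dunn_pairwise", groups=[a, b], statistic=float(z),
            p=float(p), adjusted_p=float(ap),
            medians={a: float(np.median(groups[a])),
                     b: float(np.median(groups[b]))},
        )
        for (a, b), z, p, ap in zip(pairs, zs, ps, adj)
    ]


def mann_whitney_rb(values, labels, order: list[str] | None = None) -> GroupTestResult:
    """Mann-Whitney test with the rank-biserial effect size.

    r_hat = 2*U1/(n1*n2) - 1, where U1 counts wins of the first-listed group
    (positive means that group tends larger).  The p-value uses the
    tie-corrected normal approximation without continuity correction.
    """
    found, groups = _split_groups(values, labels)
    if order is None:
        order = found
    if len(order) != 2:
        raise ValueError("mann_whitney_rb requires exactly 2 groups")
    x, y = groups[order[0]], groups[order[1]]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic", use_continuity=False)
    u1 = float(res.statistic)
    rb = 2.0 * u1 / (len(x) * len(y)) - 1.0
    return GroupTestResult(
        test="mann_whitney", groups=list(order), statistic=u1,
        p=float(res.pvalue), effect_size=float(rb),
        medians={order[0]: float(np.median(x)), order[1]: float(np.median(y))},
    )


def race3_labels(df: pd.DataFrame) -> pd.Series:
    """Three mutually exclusive race/ethnicity labels; others excluded (NaN)."""
    out = pd.Series(np.nan, index=df.index, dtype=object)
    hisp = df["hispanic"] == 1
    out[hisp] = "hispanic"
    out[(~hisp) & (df["race_black"] == 1)] = "nh_black"
    out[(~hisp) & (df["race_black"] != 1) & (df["race_white"] == 1)] = "nh_white"
    return out


_LOW_N = 50


def fit_interactions(
    test: pd.DataFrame,
    scores,
    group_col: str,
    outcome: str = "outcome_continuous",
    adversity_col: str = "adversity",
    covariates: tuple[str, ...] = VALIDATION_COVARIATES,
) -> list[InteractionResult]:
    """Score-by-group interaction terms added to the validation M4 model.

    ``group_col`` may be a binary 0/1 indicator or a categorical column; for
    categoricals the first-appearance level is the reference.  Each non-
    reference level contributes one product term.  Stratified refits per
    level give the simple slopes; levels with n < 50 are flagged.
    """
    merged = _merged_test_table(test, scores)
    if group_col not in merged.columns:
        raise ValueError(f"unknown group column {group_col!r}")
    base_terms = list(covariates) + [SCREENTIME_Z, adversity_col, SCORE_COL]
    merged = merged.dropna(subset=[outcome, group_col] + base_terms).copy()

    values = merged[group_col]
    if set(values.unique()) <= {0, 1, 0.0, 1.0}:
        levels = [0.0, 1.0]
        indicators = {1.0: values.astype(float)}
        label_of = {0.0: f"{group_col}=0", 1.0: f"{group_col}=1"}
    else:
        levels = list(dict.fromkeys(values))
        indicators = {lv: (values == lv).astype(float) for lv in levels[1:]}
        label_of = {lv: str(lv) for lv in levels}

    inter_terms = []
    work = merged
    for lv, ind in indicators.items():
        if group_col in base_terms and len(indicators) == 1:
            ind_col = group_col  # indicator already a model covariate
        else:
            ind_col = f"_g_{label_of[lv]}"
            work[ind_col] = ind.to_numpy(dtype=float)
        prod_col = f"score_x_{label_of[lv]}"
        work[prod_col] = work[ind_col].to_numpy(dtype=float) * work[SCORE_COL]
        inter_terms.append((lv, ind_col, prod_col))

    full_terms = list(dict.fromkeys(base_terms))
    candidates = ([ic for _, ic, _ in inter_terms]
                  + [pc for _, _, pc in inter_terms])
    for cand in dict.fromkeys(candidates):
        if cand in full_terms:
            continue
        X = np.column_stack([np.ones(len(work))]
                            + [work[t].to_numpy(dtype=float)
                               for t in full_terms + [cand]])
        if np.linalg.matrix_rank(X) == X.shape[1]:
            full_terms.append(cand)  # skip exact duplicates of existing terms
    fit = fit_lmm(work, outcome, full_terms)

    slopes: dict[str, dict] = {}
    for lv in levels:
        sub = work[values == lv]
        entry: dict = {"n": int(len(sub))}
        if len(sub) < _LOW_N:
            entry["low_n"] = True
            entry.update(estimate=float("nan"), ci_low=float("nan"),
                         ci_high=float("nan"))
        else:
            strat_terms = [t for t in base_terms
                           if t != group_col and sub[t].nunique() > 1]
            sfit = fit_lmm(sub, outcome, strat_terms)
            eff = sfit.beta[SCORE_COL]
            entry.update(estimate=eff.estimate, ci_low=eff.ci_low,
                         ci_high=eff.ci_high)
        slopes[label_of[lv]] = entry

    results = []
    for lv, _, prod_col in inter_terms:
        if prod_col not in fit.beta:
            continue
        eff = fit.beta[prod_col]
        results.append(InteractionResult(
            term=f"{SCORE_COL}x{label_of[lv]}",
            estimate=eff.estimate, se=eff.se, t=eff.t, p=eff.p,
            stratified_slopes=slopes,
        ))
    return results
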