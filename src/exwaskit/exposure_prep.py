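"""Exposure-variable curation: combining split items, endorsement filtering,
outlier handling, iterative random-forest imputation, and collinearity pruning.

The canonical order, enforced by :func:`run_prep`, is:

    combine hour/minute items -> drop low-endorsement binaries -> upper-tail
    outlier removal -> per-subsample random-forest imputation -> collinearity
    pruning decided on the training subsample and applied to both.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .io import exposure_columns

__all__ = [
    "ExposureSpec",
    "PrepReport",
    "combine_hour_minute",
    "filter_low_endorsement",
    "remove_outliers",
    "prune_collinear",
    "impute_missforest",
    "run_prep",
    "specs_for_cohort",
]

MEASUREMENTS = ("binary", "ordinal", "continuous")
DOMAINS = ("screentime", "parental_monitoring", "apps", "overuse",
           "peer_interaction", "other")


@dataclass
class ExposureSpec:
    """Per-variable metadata driving the cleaning rules."""

    name: str
    measurement: str
    domain: str = "other"
    combine_with: str | None = None   # e.g. a minutes item merged into an hours item
    outlier_rule_applies: bool = False

    def __post_init__(self):
        if self.measurement not in MEASUREMENTS:
            raise ValueError(f"unknown measurement {self.measurement!r}")
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r}")


def specs_to_json(specs: list[ExposureSpec]) -> str:
    return json.dumps([asdict(s) for s in specs], indent=2)


def specs_from_json(text: str) -> list[ExposureSpec]:
    return [ExposureSpec(**d) for d in json.loads(text)]


def specs_for_cohort(truth) -> list[ExposureSpec]:
    """Build specs from generator ground truth (continuous items get the
    outlier rule, mirroring heavy-tailed count-like variables)."""
    return [
        ExposureSpec(name=name, measurement=kind,
                     outlier_rule_applies=(kind == "continuous"))
        for name, kind in truth.exposure_types.items()
    ]


@dataclass
class PrepReport:
    n_input: int = 0
    dropped_low_endorsement: list[str] = field(default_factory=list)
    dropped_collinear: list[str] = field(default_factory=list)
    n_retained: int = 0
    outliers_removed: dict[str, int] = field(default_factory=dict)
    imputation_iterations: int = 0
    imputation_converged: bool = True
    outlier_rule: str = "upper-tail Q3 + k*IQR set to missing (k configurable)"

    def validate(self) -> None:
        expected = (self.n_input - len(self.dropped_low_endorsement)
                    - len(self.dropped_collinear))
        if self.n_retained != expected:
            raise ValueError("PrepReport bookkeeping inconsistent")

    def to_dict(self) -> dict:
        return asdict(self)


def _spec_map(specs: list[ExposureSpec]) -> dict[str, ExposureSpec]:
    m = {s.name: s for s in specs}
    if len(m) != len(specs):
        raise ValueError("duplicate exposure names in specs")
    return m


def combine_hour_minute(cohort: pd.DataFrame,
                        specs: list[ExposureSpec]) -> pd.DataFrame:
    """Merge minute items into their hour counterparts: hours + minutes/60.

    The minutes column is removed; the combined value lives under the hours
    name.  A missing component counts as 0 when its sibling is present; the
    result is missing only when both are.
    """
    out = cohort.copy()
    by_name = _spec_map(specs)
    for spec in specs:
        if spec.combine_with is None:
            continue
        target = spec.combine_with
        if target not in by_name:
            raise ValueError(f"combine_with target {target!r} has no spec")
        minutes = out[spec.name]
        hours = out[target]
        if (minutes.dropna() < 0).any() or (hours.dropna() < 0).any():
            raise ValueError(
                f"negative components in {spec.name!r}/{target!r}")
        both_missing = minutes.isna() & hours.isna()
        combined = hours.fillna(0.0) + minutes.fillna(0.0) / 60.0
        combined[both_missing] = np.nan
        out[target] = combined
        out = out.drop(columns=[spec.name])
    return out


def endorsement(series: pd.Series) -> float:
    """Proportion of non-missing values equal to 1."""
    obs = series.dropna()
    if len(obs) == 0:
        return float("nan")
    return float((obs == 1).mean())


def filter_low_endorsement(
    cohort: pd.DataFrame,
    specs: list[ExposureSpec],
    threshold: float = 0.01,
) -> tuple[pd.DataFrame, list[str]]:
    """Drop binary exposures endorsed by strictly less than ``threshold``."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0,1)")
    dropped = []
    for spec in specs:
        if spec.measurement != "binary" or spec.name not in cohort.columns:
            continue
        if endorsement(cohort[spec.name]) < threshold:
            dropped.append(spec.name)
    return cohort.drop(columns=dropped), dropped


def remove_outliers(
    cohort: pd.DataFrame,
    specs: list[ExposureSpec],
    k: float = 3.0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Set upper-tail outliers (value > Q3 + k*IQR) to missing.

    Applies only to continuous exposures flagged ``outlier_rule_applies``.
    ``k = inf`` is an exact no-op, reproducing the outlier-retention
    sensitivity variant.
    """
    out = cohort.copy()
    counts: dict[str, int] = {}
    if np.isinf(k):
        return out, counts
    for spec in specs:
        if (spec.measurement != "continuous" or not spec.outlier_rule_applies
                or spec.name not in out.columns):
            continue
        values = out[spec.name]
        if values.dropna().empty:
            warnings.warn(f"{spec.name}: all missing, outlier rule skipped",
                          RuntimeWarning, stacklevel=2)
            continue
        # order-statistic quantiles: robust on tiny/heavy-tailed samples
        q1, q3 = np.nanquantile(values.to_numpy(dtype=float), [0.25, 0.75],
                                method="lower")
        cut = q3 + k * (q3 - q1)
        mask = values > cut
        n_out = int(mask.sum())
        if n_out:
            out.loc[mask, spec.name] = np.nan
            counts[spec.name] = n_out
    return out, counts


def _greedy_prune(corr: pd.DataFrame, threshold: float) -> list[str]:
    """Mean-absolute-correlation greedy rule with name-order tie-break."""
    corr = corr.copy()
    dropped: list[str] = []
    while len(corr) > 1:
        a = corr.abs().to_numpy()
        np.fill_diagonal(a, 0.0)
        top = np.nanmax(a)
        if not (top > threshold):
            break
        ii, jj = np.where(a >= top - 1e-15)
        # lexicographically smallest pair among ties
        pairs = sorted(
            {tuple(sorted((corr.index[i], corr.index[j]))) for i, j in zip(ii, jj)}
        )
        x, y = pairs[0]
        mean_abs = corr.abs().where(~np.eye(len(corr), dtype=bool)).mean()
        if mean_abs[x] > mean_abs[y]:
            victim = x
        elif mean_abs[y] > mean_abs[x]:
            victim = y
        else:
            victim = max(x, y)  # name-order tie-break: drop the later name
        dropped.append(victim)
        corr = corr.drop(index=victim, columns=victim)
    return dropped


def prune_collinear(
    cohort: pd.DataFrame,
    exposures: list[str] | None = None,
    r_threshold: float = 0.9,
) -> tuple[pd.DataFrame, list[str]]:
    """Drop collinear exposures (|Pearson r| > threshold), train-decided.

    Pairwise correlations are computed on pairwise-complete observations of
    the training subsample (rows with ``subsample == 'train'`` when that
    column exists, else all rows); the resulting drops are applied to the
    whole table.  While any pair exceeds the threshold, the pair with the
    largest |r| is taken and the member with the larger mean absolute
    correlation against all remaining variables is removed.
    """
    if exposures is None:
        exposures = exposure_columns(cohort)
    if len(exposures) < 2:
        raise ValueError("need at least 2 exposures to prune")
    fit_rows = cohort
    if "subsample" in cohort.columns:
        fit_rows = cohort[cohort["subsample"] == "train"]
    mat = fit_rows[exposures]
    variances = mat.var(skipna=True)
    degenerate = [c for c in exposures if not (variances[c] > 0)]
    if degenerate:
        warnings.warn(
            f"zero-variance exposures excluded from pruning: {degenerate}",
            RuntimeWarning, stacklevel=2)
    usable = [c for c in exposures if c not in degenerate]
    dropped: list[str] = []
    if len(usable) >= 2:
        corr = mat[usable].corr()  # pairwise-complete Pearson
        dropped = _greedy_prune(corr, r_threshold)
    return cohort.drop(columns=dropped), dropped


def _missforest_matrix(
    frame: pd.DataFrame,
    kinds: dict[str, str],
    max_iter: int,
    n_trees: int,
    seed: int,
) -> tuple[pd.DataFrame, int, bool]:
    """Iterative random-forest imputation with the missForest stopping rule."""
    work = frame.copy()
    na_mask = frame.isna()
    targets = [c for c in frame.columns if na_mask[c].any()]
    if not targets:
        return work, 0, True
    for col in targets:
        if na_mask[col].all():
            raise ValueError(f"exposure {col!r} has zero observed values")
        obs = work[col].dropna()
        fill = obs.mode().iloc[0] if kinds.get(col) == "binary" else obs.mean()
        work[col] = work[col].fillna(fill)
    targets = sorted(targets, key=lambda c: na_mask[c].sum())  # least missing first
    cont_cols = [c for c in targets if kinds.get(c) != "binary"]
    cat_cols = [c for c in targets if kinds.get(c) == "binary"]
    n_na_cat = int(na_mask[cat_cols].sum().sum()) if cat_cols else 0

    prev = work.copy()
    prev_dcont, prev_dcat = np.inf, np.inf
    iterations = 0
    converged = False
    for it in range(max_iter):
        new = prev.copy()
        for j, col in enumerate(targets):
            predictors = [c for c in frame.columns if c != col]
            obs_rows = ~na_mask[col]
            Xobs = new.loc[obs_rows, predictors].to_numpy(dtype=float)
            yobs = new.loc[obs_rows, col].to_numpy(dtype=float)
            Xmis = new.loc[na_mask[col], predictors].to_numpy(dtype=float)
            rs = seed + 1000 * it + j
            if kinds.get(col) == "binary" and len(np.unique(yobs)) > 1:
                model = RandomForestClassifier(
                    n_estimators=n_trees, random_state=rs, n_jobs=1)
                model.fit(Xobs, yobs.astype(int))
                pred = model.predict(Xmis).astype(float)
            else:
                model = RandomForestRegressor(
                    n_estimators=n_trees, random_state=rs, n_jobs=1)
                model.fit(Xobs, yobs)
                pred = model.predict(Xmis)
                if kinds.get(col) == "ordinal":
                    pred = np.clip(np.round(pred), yobs.min(), yobs.max())
            new.loc[na_mask[col], col] = pred
        iterations = it + 1
        # normalized change statistics (continuous: SSQ ratio; binary: disagreement)
        if cont_cols:
            num = ((new[cont_cols] - prev[cont_cols]) ** 2).to_numpy().sum()
            den = (new[cont_cols] ** 2).to_numpy().sum()
            dcont = num / den if den > 0 else 0.0
        else:
            dcont = 0.0
        if cat_cols and n_na_cat:
            dcat = float((new[cat_cols] != prev[cat_cols]).to_numpy().sum()) / n_na_cat
        else:
            dcat = 0.0
        worse_cont = (not cont_cols) or dcont >= prev_dcont
        worse_cat = (not cat_cols) or dcat >= prev_dcat
        if it > 0 and worse_cont and worse_cat:
            converged = True
            break  # return the iterate preceding degradation
        prev = new
        prev_dcont, prev_dcat = dcont, dcat
    result = prev
    result[frame.notna()] = frame  # observed cells are never altered
    return result, iterations, converged


def impute_missforest(
    cohort: pd.DataFrame,
    specs: list[ExposureSpec],
    max_iter: int = 10,
    n_trees: int = 100,
    seed: int = 0,
    predictor_columns: list[str] | None = None,
) -> tuple[pd.DataFrame, PrepReport]:
    """Impute missing exposure cells with iterative random forests.

    Outcomes and identifiers are excluded from the imputation matrix; fully
    observed numeric covariates (and, optionally, ``predictor_columns``) are
    included as predictors but never imputed.  Train and test subsamples are
    imputed in separate runs when a ``subsample`` column is present.
    """
    names = [s.name for s in specs if s.name in cohort.columns]
    kinds = {s.name: s.measurement for s in specs}
    if predictor_columns is None:
        predictor_columns = [
            c for c in ("age", "income_ordinal", "parent_education",
                        "adversity", "nonsocial_screentime")
            if c in cohort.columns and not cohort[c].isna().any()
        ]
    cols = names + [c for c in predictor_columns if c not in names]
    out = cohort.copy()
    iterations, converged = 0, True
    if "subsample" in cohort.columns:
        parts = [cohort["subsample"] == lab
                 for lab in ("train", "test")]
    else:
        parts = [pd.Series(True, index=cohort.index)]
    for k, mask in enumerate(parts):
        if not mask.any():
            continue
        block = cohort.loc[mask, cols]
        filled, its, conv = _missforest_matrix(
            block, kinds, max_iter=max_iter, n_trees=n_trees, seed=seed + 7 * k)
        out.loc[mask, names] = filled[names]
        iterations = max(iterations, its)
        converged = converged and conv
    report = PrepReport(
        n_input=len(names),
        n_retained=len(names),
        imputation_iterations=iterations,
        imputation_converged=converged,
    )
    return out, report


def run_prep(
    cohort: pd.DataFrame,
    specs: list[ExposureSpec],
    endorsement_threshold: float = 0.01,
    outlier_k: float = 3.0,
    no_outlier_removal: bool = False,
    listwise: bool = False,
    r_threshold: float = 0.9,
    max_iter: int = 10,
    n_trees: int = 100,
    seed: int = 0,
) -> tuple[pd.DataFrame, PrepReport]:
    """Full curation pipeline in the canonical order.

    ``listwise=True`` skips imputation (the list-wise-deletion sensitivity
    variant); ``no_outlier_removal=True`` retains extreme values.
    """
    df = combine_hour_minute(cohort, specs)
    specs = [s for s in specs if s.combine_with is None]
    n_input = len([s for s in specs if s.name in df.columns])

    df, dropped_low = filter_low_endorsement(df, specs, endorsement_threshold)
    specs = [s for s in specs if s.name not in dropped_low]

    outliers: dict[str, int] = {}
    if not no_outlier_removal:
        df, outliers = remove_outliers(df, specs, k=outlier_k)

    if listwise:
        impute_report = PrepReport(imputation_iterations=0,
                                   imputation_converged=True)
    else:
        df, impute_report = impute_missforest(
            df, specs, max_iter=max_iter, n_trees=n_trees, seed=seed)

    names = [s.name for s in specs if s.name in df.columns]
    df, dropped_collinear = prune_collinear(df, names, r_threshold=r_threshold)

    report = PrepReport(
        n_input=n_input,
        dropped_low_endorsement=dropped_low,
        dropped_collinear=dropped_collinear,
        n_retained=n_input - len(dropped_low) - len(dropped_collinear),
        outliers_removed=outliers,
        imputation_iterations=impute_report.imputation_iterations,
        imputation_converged=impute_report.imputation_converged,
    )
    report.validate()
    return df, report
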