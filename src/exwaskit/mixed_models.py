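"""Two-level random-intercept linear mixed models and logistic regression.

The linear mixed model used throughout the package has random intercepts for
family nested within site:

    y = X beta + u_site + u_family + eps,
    u_site ~ N(0, var_site), u_family ~ N(0, var_family), eps ~ N(0, var_resid).

The marginal covariance ``V = var_resid * (I + g_f Zf Zf' + g_s Zs Zs')`` is
block diagonal by site, and within a site the family part is block diagonal by
family, so ``V^{-1}`` and ``log|V|`` have exact closed forms (two nested
rank-one/Woodbury updates).  REML estimation therefore reduces to a
two-parameter optimisation over the variance ratios ``(g_f, g_s)``, which makes
a single fit run in milliseconds — necessary because the exposure-wide screen
and its calibration simulations perform thousands of fits.

Fixed-effect inference uses the large-sample normal reference: 95% CIs are
``estimate +/- 1.96 * se`` and p-values come from the standard normal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special
import statsmodels.api as sm

__all__ = [
    "FixedEffect",
    "LmmFit",
    "GlmFit",
    "OddsRatio",
    "fit_lmm",
    "fit_logistic",
    "marginal_r2",
    "icc_from_components",
    "ensure_sex_indicator",
]

_Z95 = 1.96  # large-sample 95% normal quantile used for all Wald intervals


@dataclass(frozen=True)
class FixedEffect:
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    t: float
    p: float


@dataclass
class LmmFit:
    """REML fit of the family-in-site random-intercept model."""

    beta: dict[str, FixedEffect]
    var_family_in_site: float
    var_site: float
    var_resid: float
    marginal_r2: float
    icc: float
    n_used: int
    converged: bool
    fixed_predictor_variance: float = 0.0
    reml_criterion: float = float("nan")
    outcome: str = ""
    terms: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "beta": {k: vars(v) for k, v in self.beta.items()},
            "var_family_in_site": self.var_family_in_site,
            "var_site": self.var_site,
            "var_resid": self.var_resid,
            "marginal_r2": self.marginal_r2,
            "icc": self.icc,
            "n_used": self.n_used,
            "converged": self.converged,
            "outcome": self.outcome,
            "terms": list(self.terms),
        }


@dataclass(frozen=True)
class OddsRatio:
    odds_ratio: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    log_or: float
    se: float


@dataclass
class GlmFit:
    """Maximum-likelihood logistic fit with Wald odds-ratio intervals."""

    or_: dict[str, OddsRatio]
    n_used: int
    converged: bool
    outcome: str = ""
    terms: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "or": {k: vars(v) for k, v in self.or_.items()},
            "n_used": self.n_used,
            "converged": self.converged,
            "outcome": self.outcome,
            "terms": list(self.terms),
        }


def ensure_sex_indicator(df: pd.DataFrame) -> pd.DataFrame:
    """Return ``df`` with a numeric ``sex_male`` column derived from ``sex``."""
    if "sex_male" in df.columns or "sex" not in df.columns:
        return df
    out = df.copy()
    out["sex_male"] = (out["sex"].astype(str) == "male").astype(float)
    out.loc[df["sex"].isna(), "sex_male"] = np.nan
    return out


# ---------------------------------------------------------------------------
# REML machinery
# ---------------------------------------------------------------------------


class _NestedDesign:
    """Pre-sorted design for the family-in-site covariance structure.

    Rows are sorted so that families are contiguous within contiguous sites;
    all W^{-1} products are then computed with segment sums.
    """

    def __init__(self, y, X, site, family):
        site = np.asarray(site)
        family = np.asarray(family)
        # nested coding: a family key is unique within its site
        fam_key = pd.MultiIndex.from_arrays([site, family])
        fam_codes, _ = pd.factorize(fam_key, sort=True)
        site_codes, _ = pd.factorize(site, sort=True)
        order = np.lexsort((fam_codes, site_codes))
        self.y = np.asarray(y, dtype=float)[order]
        self.X = np.asarray(X, dtype=float)[order]
        fam_codes = fam_codes[order]
        site_codes = site_codes[order]
        # re-factorize so codes are contiguous 0..F-1 in sorted order
        self.fam = pd.factorize(fam_codes)[0]
        self.site = pd.factorize(site_codes)[0]
        self.n, self.p = self.X.shape
        self.n_fam = int(self.fam.max()) + 1
        self.n_site = int(self.site.max()) + 1
        self.m_f = np.bincount(self.fam).astype(float)
        self.site_of_fam = np.zeros(self.n_fam, dtype=int)
        self.site_of_fam[self.fam] = self.site
        self.Z = np.column_stack([self.X, self.y])

    def _winv_gram(self, g_f: float, g_s: float):
        """Return (Z' W^{-1} Z, log|W|) for Z = [X, y]."""
        Z = self.Z
        m_f = self.m_f
        # family-level Woodbury: A = I + g_f * blockdiag(J_f)
        fam_sum = np.zeros((self.n_fam, Z.shape[1]))
        np.add.at(fam_sum, self.fam, Z)
        shrink_f = g_f / (1.0 + g_f * m_f)  # per family
        AinvZ = Z - shrink_f[self.fam, None] * fam_sum[self.fam]
        # site-level rank-one update: W = A + g_s * 1 1' per site
        u = 1.0 / (1.0 + g_f * m_f[self.fam])  # rows of A^{-1} 1
        c_s = np.bincount(self.site_of_fam, weights=m_f / (1.0 + g_f * m_f),
                          minlength=self.n_site)
        sZ = np.zeros((self.n_site, Z.shape[1]))
        np.add.at(sZ, self.site, u[:, None] * Z)
        shrink_s = g_s / (1.0 + g_s * c_s)
        WinvZ = AinvZ - shrink_s[self.site, None] * u[:, None] * sZ[self.site]
        gram = Z.T @ WinvZ
        logdet = (np.sum(np.log1p(g_f * m_f))
                  + np.sum(np.log1p(g_s * c_s)))
        return gram, logdet

    def reml_criterion(self, g_f: float, g_s: float) -> float:
        """-2 * profiled REML log-likelihood up to an additive constant."""
        gram, logdetW = self._winv_gram(g_f, g_s)
        p = self.p
        XtWiX = gram[:p, :p]
        XtWiy = gram[:p, p]
        ytWiy = gram[p, p]
        try:
            beta = np.linalg.solve(XtWiX, XtWiy)
        except np.linalg.LinAlgError:
            return np.inf
        rwr = max(ytWiy - beta @ XtWiy, 1e-300)
        sign, logdetG = np.linalg.slogdet(XtWiX)
        if sign <= 0:
            return np.inf
        return (self.n - p) * np.log(rwr) + logdetW + logdetG

    def solve(self, g_f: float, g_s: float):
        gram, _ = self._winv_gram(g_f, g_s)
        p = self.p
        XtWiX = gram[:p, :p]
        beta = np.linalg.solve(XtWiX, gram[:p, p])
        rwr = max(gram[p, p] - beta @ gram[:p, p], 0.0)
        sigma2 = rwr / (self.n - p)
        cov_beta = sigma2 * np.linalg.inv(XtWiX)
        return beta, cov_beta, sigma2


def _optimize_ratios(design: _NestedDesign):
    """Minimise the REML criterion over non-negative variance ratios."""
    starts = [(0.2, 0.05), (0.01, 0.01), (1.0, 0.5)]
    best = None
    for x0 in starts:
        res = optimize.minimize(
            lambda x: design.reml_criterion(x[0], x[1]),
            x0=np.asarray(x0),
            method="L-BFGS-B",
            bounds=[(0.0, 1e6), (0.0, 1e6)],
        )
        if best is None or res.fun < best.fun:
            best = res
        if res.success and np.isfinite(res.fun):
            break  # fall through to the next start only on failure
    return best


def fit_lmm(
    data: pd.DataFrame,
    outcome: str,
    fixed_terms: list[str],
    site_col: str = "site_id",
    family_col: str = "family_id",
) -> LmmFit:
    """Fit the nested random-intercept LMM by REML.

    Rows missing the outcome or any fixed term are list-wise deleted.  Fixed
    effects get Wald normal-reference inference; variance components are
    bounded at zero (a component estimated on the boundary is reported as 0).

    Raises
    ------
    ValueError
        If fewer than two sites remain after deletion, or the design is empty.
    """
    data = ensure_sex_indicator(data)
    cols = [outcome] + list(fixed_terms)
    missing_cols = [c for c in cols + [site_col, family_col]
                    if c not in data.columns]
    if missing_cols:
        raise ValueError(f"columns not in table: {missing_cols}")
    sub = data[cols + [site_col, family_col]].dropna(subset=cols)
    if len(sub) == 0:
        raise ValueError("no complete rows after list-wise deletion")
    if sub[site_col].nunique() < 2:
        raise ValueError("need at least 2 sites to fit the nested model")

    y = sub[outcome].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(sub))] + [sub[t].to_numpy(dtype=float) for t in fixed_terms]
    )
    names = ["Intercept"] + list(fixed_terms)
    design = _NestedDesign(y, X, sub[site_col].to_numpy(), sub[family_col].to_numpy())

    res = _optimize_ratios(design)
    converged = bool(res is not None and res.success and np.isfinite(res.fun))
    g_f, g_s = (res.x if res is not None else (0.0, 0.0))
    g_f = float(max(g_f, 0.0))
    g_s = float(max(g_s, 0.0))

    beta, cov_beta, sigma2 = design.solve(g_f, g_s)
    var_family = g_f * sigma2
    var_site = g_s * sigma2
    if g_f < 1e-10 or g_s < 1e-10:
        warnings.warn(
            "variance component estimated on the zero boundary; reported as 0",
            RuntimeWarning,
            stacklevel=2,
        )
        if g_f < 1e-10:
            var_family = 0.0
        if g_s < 1e-10:
            var_site = 0.0

    se = np.sqrt(np.diag(cov_beta))
    tvals = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pvals = special.erfc(np.abs(tvals) / np.sqrt(2.0))
    effects = {
        name: FixedEffect(
            estimate=float(b),
            se=float(s),
            ci_low=float(b - _Z95 * s),
            ci_high=float(b + _Z95 * s),
            t=float(t),
            p=float(pv),
        )
        for name, b, s, t, pv in zip(names, beta, se, tvals, pvals)
    }

    lp = design.X @ beta
    fixed_var = float(np.var(lp, ddof=1)) if len(lp) > 1 else 0.0
    total = fixed_var + var_family + var_site + sigma2
    r2 = fixed_var / total if total > 0 else 0.0
    denom = var_family + var_site + sigma2
    icc = (var_family + var_site) / denom if denom > 0 else 0.0

    return LmmFit(
        beta=effects,
        var_family_in_site=float(var_family),
        var_site=float(var_site),
        var_resid=float(sigma2),
        marginal_r2=float(r2),
        icc=float(icc),
        n_used=int(len(sub)),
        converged=converged,
        fixed_predictor_variance=fixed_var,
        reml_criterion=float(res.fun) if res is not None else float("nan"),
        outcome=outcome,
        terms=tuple(fixed_terms),
    )


def marginal_r2(fit: LmmFit, fixed_predictor_variance: float) -> float:
    """Fixed-effects share of total variance (Nakagawa-style marginal R^2)."""
    total = (fixed_predictor_variance + fit.var_family_in_site
             + fit.var_site + fit.var_resid)
    if total <= 0:
        raise ValueError("all variance components are zero; R^2 undefined")
    return fixed_predictor_variance / total


def icc_from_components(var_family_in_site: float, var_site: float,
                        var_resid: float) -> float:
    """Intra-class correlation: clustering share of total variance."""
    total = var_family_in_site + var_site + var_resid
    if total <= 0:
        raise ValueError("all variance components are zero; ICC undefined")
    return (var_family_in_site + var_site) / total


def _separating_terms(y: np.ndarray, X: np.ndarray, names: list[str]) -> list[str]:
    out = []
    for j, name in enumerate(names):
        if name == "Intercept":
            continue
        x = X[:, j]
        x1, x0 = x[y == 1], x[y == 0]
        if len(x1) and len(x0) and (x1.min() > x0.max() or x1.max() < x0.min()):
            out.append(name)
    return out


def fit_logistic(
    data: pd.DataFrame,
    outcome: str,
    fixed_terms: list[str],
) -> GlmFit:
    """Maximum-likelihood logistic regression with Wald odds-ratio CIs.

    Fitted without random effects (plain logistic regression).  Rows missing
    the outcome or any term are list-wise deleted; the outcome must retain
    both classes afterwards.
    """
    data = ensure_sex_indicator(data)
    cols = [outcome] + list(fixed_terms)
    sub = data[cols].dropna()
    if len(sub) == 0:
        raise ValueError("no complete rows after list-wise deletion")
    y = sub[outcome].to_numpy(dtype=float)
    classes = np.unique(y)
    if not np.all(np.isin(classes, [0.0, 1.0])) or len(classes) < 2:
        raise ValueError("binary outcome must contain both classes 0 and 1")
    X = np.column_stack(
        [np.ones(len(sub))] + [sub[t].to_numpy(dtype=float) for t in fixed_terms]
    )
    names = ["Intercept"] + list(fixed_terms)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception as exc:  # includes PerfectSeparationError
            sep = _separating_terms(y, X, names)
            raise ValueError(
                f"logistic fit failed ({exc}); separating terms: {sep or 'unknown'}"
            ) from exc
    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    if not np.all(np.isfinite(bse)) or np.any(bse > 1e3):
        sep = _separating_terms(y, X, names)
        if sep:
            raise ValueError(f"complete separation by terms: {sep}")
    z = np.divide(params, bse, out=np.zeros_like(params), where=bse > 0)
    p = special.erfc(np.abs(z) / np.sqrt(2.0))
    ors = {
        name: OddsRatio(
            odds_ratio=float(np.exp(b)),
            ci_low=float(np.exp(b - _Z95 * s)),
            ci_high=float(np.exp(b + _Z95 * s)),
            z=float(zz),
            p=float(pp),
            log_or=float(b),
            se=float(s),
        )
        for name, b, s, zz, pp in zip(names, params, bse, z, p)
    }
    return GlmFit(
        or_=ors,
        n_used=int(len(sub)),
        converged=bool(res.mle_retvals.get("converged", True)),
        outcome=outcome,
        terms=tuple(fixed_terms),
    )
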