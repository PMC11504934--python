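"""Seeded synthetic cohort generator with nested family/site structure.

Produces participant-level tables that mirror the structure the screening
pipeline assumes: families nested within sites, demographic covariates, a
mixed-type exposure battery (binary endorsements, ordinal frequencies,
continuous hours) with planted collinear pairs and rare items, configurable
signed exposure effects on a continuous T-score outcome, a rare binary
outcome driven by the same exposure burden, subgroup shifts in exposure
level, and MCAR/MAR missingness restricted to the exposures.  The generator
also returns the ground truth needed for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = ["SimConfig", "SimTruth", "simulate_cohort", "split_train_test"]

# MAR missingness coefficients on standardized income and age
_MAR_INCOME_COEF = -0.7
_MAR_AGE_COEF = 0.4


@dataclass
class SimConfig:
    """Generator configuration.  Defaults give an ABCD-like cohort shape."""

    n_sites: int = 21
    n_families: int = 3000
    mean_children_per_family: float = 1.2
    n_exposures: int = 41
    n_true_risk: int = 8
    n_true_protective: int = 2
    exposure_type_mix: tuple[float, float, float] = (0.4, 0.3, 0.3)
    endorsement_range: tuple[float, float] = (0.05, 0.6)
    n_rare_binary: int = 3
    rare_endorsement_range: tuple[float, float] = (0.002, 0.008)
    n_collinear_pairs: int = 2
    collinear_r: float = 0.95
    effect_size_range: tuple[float, float] = (0.5, 2.0)
    var_family: float = 4.0
    var_site: float = 0.5
    var_resid: float = 20.0
    outcome_mean: float = 50.0
    outcome_sd: float = 10.0
    binary_outcome_prevalence: float = 0.02
    binary_effect_scale: float = 0.5
    missing_rate: float = 0.10
    missing_mechanism: str = "MAR"  # "MCAR" or "MAR"
    exposure_correlation: float = 0.45  # loading on the shared burden factor
    covariate_effects: dict[str, float] = field(default_factory=dict)
    subgroup_exposure_shift: dict[str, float] = field(
        default_factory=lambda: {"race_black": 0.6, "hispanic": 0.25, "sgm": 0.5}
    )
    train_ratio: float = 0.5
    seed: int = 0

    def n_eligible_for_effects(self) -> int:
        return self.n_exposures - self.n_rare_binary - 2 * self.n_collinear_pairs

    def validate(self) -> None:
        if abs(sum(self.exposure_type_mix) - 1.0) > 1e-9:
            raise ValueError("exposure_type_mix must sum to 1")
        if self.n_true_risk + self.n_true_protective > self.n_exposures:
            raise ValueError("more true effects than exposures")
        if self.n_true_risk + self.n_true_protective > self.n_eligible_for_effects():
            raise ValueError(
                "infeasible config: n_true_risk + n_true_protective exceeds the "
                "number of non-rare, non-collinear exposures "
                f"({self.n_eligible_for_effects()})"
            )
        if not (0.9 < self.collinear_r < 1.0):
            raise ValueError("collinear_r must lie in (0.9, 1)")
        if self.n_collinear_pairs and self.n_exposures < 2 * self.n_collinear_pairs:
            raise ValueError("not enough exposures for the requested collinear pairs")
        if not (0.0 < self.binary_outcome_prevalence < 1.0):
            raise ValueError("binary_outcome_prevalence must be in (0,1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0,1)")
        if self.missing_mechanism not in ("MCAR", "MAR"):
            raise ValueError("missing_mechanism must be 'MCAR' or 'MAR'")
        if self.var_resid <= 0:
            raise ValueError("var_resid must be positive")
        if self.mean_children_per_family < 1:
            raise ValueError("mean_children_per_family must be >= 1")
        if not (0.0 < self.train_ratio < 1.0):
            raise ValueError("train_ratio must be in (0,1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key in ("exposure_type_mix", "endorsement_range",
                    "rare_endorsement_range", "effect_size_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated cohort."""

    true_beta: dict[str, float]            # outcome points per raw exposure unit
    null_set: list[str]
    collinear_pairs: list[tuple[str, str]]
    variance_components: tuple[float, float, float]  # family, site, resid
    subgroup_shifts: dict[str, float]
    exposure_types: dict[str, str] = field(default_factory=dict)
    rare_exposures: list[str] = field(default_factory=list)
    binary_outcome_intercept: float = float("nan")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["collinear_pairs"] = [list(p) for p in self.collinear_pairs]
        d["variance_components"] = list(self.variance_components)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimTruth":
        d = dict(d)
        d["collinear_pairs"] = [tuple(p) for p in d["collinear_pairs"]]
        d["variance_components"] = tuple(d["variance_components"])
        return cls(**d)

    def latent_burden(self, cohort: pd.DataFrame) -> pd.Series:
        """True weighted exposure burden sum_j beta_j x_ij per participant."""
        burden = pd.Series(0.0, index=cohort.index)
        for name, beta in self.true_beta.items():
            burden = burden + beta * cohort[name]
        return burden


def _exposure_names(n: int) -> list[str]:
    return [f"exp_{i + 1:02d}" for i in range(n)]


def _calibrate_intercept(eta: np.ndarray, target: float) -> float:
    """Bisection on the logistic intercept so mean probability hits target."""
    f = lambda a: special.expit(a + eta).mean() - target
    return float(optimize.brentq(f, -40.0, 40.0, xtol=1e-10))


def simulate_cohort(config: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Generate a cohort table and its ground truth.  Seed-deterministic."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    # --- nesting structure -------------------------------------------------
    site_of_family = np.arange(config.n_families) % config.n_sites
    rng.shuffle(site_of_family)
    children = 1 + rng.poisson(config.mean_children_per_family - 1.0,
                               config.n_families)
    fam_idx = np.repeat(np.arange(config.n_families), children)
    n = len(fam_idx)
    site_idx = site_of_family[fam_idx]

    df = pd.DataFrame({
        "participant_id": [f"p{i + 1:06d}" for i in range(n)],
        "family_id": [f"f{j + 1:05d}" for j in fam_idx],
        "site_id": [f"site{s + 1:02d}" for s in site_idx],
    })

    # --- demographics ------------------------------------------------------
    df["age"] = rng.normal(12.0, 0.66, n)
    df["sex"] = np.where(rng.random(n) < 0.52, "male", "female")
    race = rng.choice(3, n, p=[0.6, 0.2, 0.2])  # white / black / other
    df["race_white"] = (race == 0).astype(int)
    df["race_black"] = (race == 1).astype(int)
    df["hispanic"] = (rng.random(n) < 0.20).astype(int)
    df["sgm"] = (rng.random(n) < 0.08).astype(int)
    df["income_ordinal"] = rng.integers(1, 11, n)
    df["parent_education"] = rng.normal(16.0, 2.0, n)
    z_income = (df["income_ordinal"] - df["income_ordinal"].mean()) / df["income_ordinal"].std()
    df["adversity"] = -0.3 * z_income.to_numpy() + rng.normal(0, np.sqrt(1 - 0.09), n)
    df["nonsocial_screentime"] = np.maximum(rng.normal(25.0, 14.0, n), 0.0)

    # --- exposures ---------------------------------------------------------
    names = _exposure_names(config.n_exposures)
    shift_vec = np.zeros(n)
    for col, shift in config.subgroup_exposure_shift.items():
        if col not in df.columns:
            raise ValueError(f"subgroup_exposure_shift references unknown column {col!r}")
        shift_vec += shift * df[col].to_numpy(dtype=float)
    latent = rng.normal(0.0, 1.0, n)

    rho = config.exposure_correlation
    if not (0.0 <= rho < 1.0):
        raise ValueError("exposure_correlation must be in [0,1)")
    n_rare = config.n_rare_binary
    n_dup = 2 * config.n_collinear_pairs
    regular = names[n_rare:config.n_exposures - n_dup]
    dup_block = names[config.n_exposures - n_dup:]

    # split regular exposures by type mix (binary first, then ordinal, rest cont.)
    n_reg = len(regular)
    n_bin = int(round(config.exposure_type_mix[0] * n_reg))
    n_ord = int(round(config.exposure_type_mix[1] * n_reg))
    n_bin = min(n_bin, n_reg)
    n_ord = min(n_ord, n_reg - n_bin)
    types: dict[str, str] = {}
    z_cols: dict[str, np.ndarray] = {}

    def _latent_column() -> np.ndarray:
        # unit variance around a per-participant mean shifted for subgroups
        return (shift_vec + rho * latent
                + np.sqrt(1 - rho ** 2) * rng.normal(0.0, 1.0, n))

    for name in names[:n_rare]:
        p = rng.uniform(*config.rare_endorsement_range)
        z = _latent_column()
        # per participant z_i ~ N(rho*shift_i, 1); solve the exact threshold
        # so realized endorsement is Binomial(n, p), not forced to round(n*p)
        tail = lambda c: stats.norm.sf(c - shift_vec).mean() - p
        cut = optimize.brentq(tail, -10.0, 10.0, xtol=1e-12)
        df[name] = (z > cut).astype(float)
        types[name] = "binary"
    for i, name in enumerate(regular):
        z = _latent_column()
        z_cols[name] = z
        if i < n_bin:
            p = rng.uniform(*config.endorsement_range)
            df[name] = (z > np.quantile(z, 1 - p)).astype(float)
            types[name] = "binary"
        elif i < n_bin + n_ord:
            cuts = np.quantile(z, [0.4, 0.65, 0.85, 0.95])
            df[name] = np.searchsorted(cuts, z).astype(float)
            types[name] = "ordinal"
        else:
            df[name] = 2.0 + z
            types[name] = "continuous"

    collinear_pairs: list[tuple[str, str]] = []
    r = config.collinear_r
    for k in range(config.n_collinear_pairs):
        a, b = dup_block[2 * k], dup_block[2 * k + 1]
        z = _latent_column()
        df[a] = 2.0 + z
        df[b] = 2.0 + r * z + np.sqrt(1 - r ** 2) * rng.normal(0.0, 1.0, n)
        types[a] = types[b] = "continuous"
        collinear_pairs.append((a, b))
        sample_r = np.corrcoef(df[a], df[b])[0, 1]
        if abs(sample_r) <= 0.9:
            raise ValueError(
                f"infeasible config: planted collinear pair ({a},{b}) achieved "
                f"sample r={sample_r:.3f} <= 0.9; increase n or collinear_r"
            )

    # --- true effects ------------------------------------------------------
    eligible = list(regular)
    effect_names = list(rng.choice(eligible,
                                   config.n_true_risk + config.n_true_protective,
                                   replace=False))
    true_beta: dict[str, float] = {}
    for i, name in enumerate(effect_names):
        mag = rng.uniform(*config.effect_size_range)  # points per 1 SD of exposure
        sign = 1.0 if i < config.n_true_risk else -1.0
        sd = float(df[name].std())
        true_beta[name] = sign * mag / sd if sd > 0 else 0.0
    null_set = [name for name in names if name not in true_beta]

    # --- continuous outcome ------------------------------------------------
    burden = np.zeros(n)
    for name, beta in true_beta.items():
        burden += beta * df[name].to_numpy()
    fixed = burden.copy()
    for col, eff in config.covariate_effects.items():
        fixed += eff * df[col].to_numpy(dtype=float)
    u_fam = rng.normal(0.0, np.sqrt(config.var_family), config.n_families)
    u_site = rng.normal(0.0, np.sqrt(config.var_site), config.n_sites)
    eps = rng.normal(0.0, np.sqrt(config.var_resid), n)
    df["outcome_continuous"] = (config.outcome_mean + fixed
                                + u_fam[fam_idx] + u_site[site_idx] + eps)

    # --- binary outcome (shares the exposure-burden predictor) -------------
    b_sd = burden.std()
    eta = (config.binary_effect_scale * (burden - burden.mean()) / b_sd
           if b_sd > 0 else np.zeros(n))
    alpha = _calibrate_intercept(eta, config.binary_outcome_prevalence)
    df["outcome_binary"] = (rng.random(n) < special.expit(alpha + eta)).astype(float)

    # --- missingness (exposures only) --------------------------------------
    if config.missing_rate > 0:
        if config.missing_mechanism == "MCAR":
            p_miss = np.full(n, config.missing_rate)
        else:
            zi = ((df["income_ordinal"] - df["income_ordinal"].mean())
                  / df["income_ordinal"].std()).to_numpy()
            za = ((df["age"] - df["age"].mean()) / df["age"].std()).to_numpy()
            lin = _MAR_INCOME_COEF * zi + _MAR_AGE_COEF * za
            a0 = _calibrate_intercept(lin, config.missing_rate)
            p_miss = special.expit(a0 + lin)
        for name in names:
            mask = rng.random(n) < p_miss
            df.loc[mask, name] = np.nan

    df = split_train_test(df, config.train_ratio, seed=config.seed + 1)

    truth = SimTruth(
        true_beta=true_beta,
        null_set=null_set,
        collinear_pairs=collinear_pairs,
        variance_components=(config.var_family, config.var_site, config.var_resid),
        subgroup_shifts=dict(config.subgroup_exposure_shift),
        exposure_types=types,
        rare_exposures=names[:n_rare],
        binary_outcome_intercept=alpha,
    )
    return df, truth


def split_train_test(cohort: pd.DataFrame, ratio: float, seed: int) -> pd.DataFrame:
    """Assign a family-integral, site-stratified train/test split.

    All children of a family land in the same subsample; within every site the
    training fraction deviates from ``ratio`` by at most one family.
    """
    if not (0.0 < ratio < 1.0):
        raise ValueError("ratio must be in (0,1)")
    if cohort["family_id"].nunique() < 2:
        raise ValueError("cannot split a cohort with a single family")
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    out["subsample"] = ""
    for site, site_rows in cohort.groupby("site_id", sort=True):
        fams = site_rows.groupby("family_id", sort=True).size()
        fam_names = np.array(fams.index)
        rng.shuffle(fam_names)
        target = ratio * len(site_rows)
        cum = 0
        train_fams = []
        for fam in fam_names:
            if cum < target:
                train_fams.append(fam)
                cum += int(fams[fam])
        is_train = out["family_id"].isin(train_fams) & (out["site_id"] == site)
        out.loc[is_train, "subsample"] = "train"
        out.loc[(~out["family_id"].isin(train_fams)) & (out["site_id"] == site),
                "subsample"] = "test"
    return out
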