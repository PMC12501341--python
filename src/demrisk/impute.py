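"""Sensitivity analyses for missing data.

Joint multivariate-normal multiple imputation of the harmonized factor
variables (numeric level codes modelled jointly with the always-complete
predictors age, sex, education and dementia status), Rubin's-rules
pooling with relative variance increase (RVI) and fraction of missing
information (FMI) diagnostics, and index-specific available-case refits.

The posterior-predictive draws come from a data-augmentation Gibbs
sampler (statsmodels' Bayesian Gaussian MI) with 200 burn-in sweeps and
a thinning interval of 10 between retained datasets; imputed cells are
rounded back to the nearest legal category code.  Observed cells are
never altered, and draws are deterministic for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.imputation.bayes_mi import BayesGaussMI

from ._util import FACTOR_LEVELS
from .evaluate import EDUCATION_CODE, FitResult, fit_logistic, zstandardize
from .score import score_cohort

log = logging.getLogger(__name__)

#: default factor variables eligible for imputation
DEFAULT_IMPUTE_FACTORS = [
    f for f in FACTOR_LEVELS if f not in ("sex", "education_level")
]


@dataclasses.dataclass
class ImputationSpec:
    m: int = 100
    seed: int = 0
    variables_to_impute: list[str] = dataclasses.field(
        default_factory=lambda: list(DEFAULT_IMPUTE_FACTORS)
    )
    burn_in: int = 200
    thin: int = 10

    def __post_init__(self):
        if self.m < 2:
            raise ValueError("need at least 2 imputed datasets")


def _encode(profiles: pd.DataFrame, outcome: pd.Series, variables: list[str]):
    """Numeric matrix [age, sex, education, dementia, factor codes...]."""
    cols = {}
    cols["age"] = pd.to_numeric(profiles["baseline_age"], errors="coerce")
    cols["sex"] = profiles["sex"].map({"female": 1.0, "male": 0.0})
    cols["education"] = profiles["education_level"].map(EDUCATION_CODE)
    cols["dementia"] = (outcome == "dementia").astype(float).where(outcome.notna())
    for f in variables:
        code = {lvl: float(i) for i, lvl in enumerate(FACTOR_LEVELS[f])}
        cols[f] = profiles[f].map(code)
    df = pd.DataFrame(cols, index=profiles.index)
    predictors = ["age", "sex", "education", "dementia"]
    if df[predictors].isna().any().any():
        raise ValueError("imputation predictors must be complete")
    return df, predictors


def _decode(imputed: pd.DataFrame, profiles: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    out = profiles.copy()
    for f in variables:
        levels = FACTOR_LEVELS[f]
        codes = imputed[f].to_numpy(dtype=float)
        codes = np.clip(np.rint(codes), 0, len(levels) - 1).astype(int)
        filled = np.array(levels, dtype=object)[codes]
        observed = profiles[f].notna().to_numpy()
        out[f] = np.where(observed, profiles[f].to_numpy(dtype=object), filled)
    return out


def mvn_impute(
    profiles: pd.DataFrame,
    outcome: pd.Series,
    spec: ImputationSpec,
) -> list[pd.DataFrame]:
    """Draw ``spec.m`` completed factor tables from the joint-normal
    posterior predictive.  Factors with no observed values are excluded
    with a warning; with no missing cells at all, the input is returned
    m times unchanged."""
    variables = [v for v in spec.variables_to_impute if v in profiles.columns]
    usable = []
    for v in variables:
        if profiles[v].notna().sum() == 0:
            log.warning("factor %s has zero observed cases; excluded", v)
        else:
            usable.append(v)
    data, predictors = _encode(profiles, outcome, usable)
    if not data[usable].isna().any().any():
        return [profiles.copy() for _ in range(spec.m)]

    # drop constant observed columns: they carry no covariance information
    model_cols = predictors + usable
    mat = data[model_cols].to_numpy(dtype=float)
    np.random.seed(spec.seed % (2**31 - 1))
    mi = BayesGaussMI(mat.copy())
    completed = []
    for _ in range(spec.burn_in):
        mi.update()
    for k in range(spec.m):
        for _ in range(spec.thin):
            mi.update()
        snap = pd.DataFrame(mi.data.copy(), columns=model_cols, index=profiles.index)
        completed.append(_decode(snap, profiles, usable))
    return completed


# ---------------------------------------------------------------------------
# Rubin's rules


@dataclasses.dataclass
class PooledEstimate:
    qbar: float
    ubar: float
    b: float
    total_variance: float
    rvi: float
    fmi: float
    df: float
    ci: tuple[float, float]
    p: float
    ftest: float
    m: int


def pool_rubin(estimates, variances, n_complete_df: float = np.inf) -> PooledEstimate:
    """Rubin's rules for one scalar parameter.

    qbar is the mean estimate; b the between-imputation variance (ddof
    1); total variance ubar + (1 + 1/m) b; RVI = (1 + 1/m) b / ubar; the
    degrees of freedom use the Barnard-Rubin small-sample formula with
    complete-data df ``n_complete_df``; FMI = (rvi + 2/(df+3)) / (1 + rvi).
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    m = len(q)
    if m < 2 or len(u) != m:
        raise ValueError("need at least 2 estimate/variance pairs")
    qbar = float(q.mean())
    ubar = float(u.mean())
    b = float(q.var(ddof=1))
    # identical estimates must give exactly b = 0; snap pure roundoff
    if b < np.finfo(float).eps * max(1.0, qbar**2):
        b = 0.0
    t = ubar + (1 + 1 / m) * b
    rvi = (1 + 1 / m) * b / ubar if ubar > 0 else 0.0
    if b > 0:
        nu_large = (m - 1) * (1 + 1 / rvi) ** 2
    else:
        nu_large = np.inf
    lam = (1 + 1 / m) * b / t if t > 0 else 0.0
    if np.isfinite(n_complete_df):
        nu_obs = (n_complete_df + 1) / (n_complete_df + 3) * n_complete_df * (1 - lam)
        df = 1.0 / (1.0 / nu_large + 1.0 / nu_obs) if np.isfinite(nu_large) else nu_obs
    else:
        df = nu_large
    fmi = (rvi + 2.0 / (df + 3.0)) / (1.0 + rvi) if np.isfinite(df) else lam
    se = np.sqrt(t)
    if np.isfinite(df):
        tq = stats.t.ppf(0.975, df)
        p = float(2 * stats.t.sf(abs(qbar / se), df)) if se > 0 else 0.0
        ftest = (qbar / se) ** 2 if se > 0 else np.inf
    else:
        tq = stats.norm.ppf(0.975)
        p = float(2 * stats.norm.sf(abs(qbar / se))) if se > 0 else 0.0
        ftest = (qbar / se) ** 2 if se > 0 else np.inf
    return PooledEstimate(
        qbar=qbar,
        ubar=ubar,
        b=b,
        total_variance=t,
        rvi=rvi,
        fmi=fmi,
        df=float(df),
        ci=(qbar - tq * se, qbar + tq * se),
        p=p,
        ftest=float(ftest),
        m=m,
    )


# ---------------------------------------------------------------------------
# pipeline-facing sensitivity analyses


def impute_and_pool(
    profiles: pd.DataFrame,
    outcome: pd.Series,
    tables: dict,
    spec: ImputationSpec,
    include_demographics: bool = True,
) -> pd.DataFrame:
    """MI sensitivity analysis: impute factors, rescore each completed
    dataset, fit the per-index logistic models within each, and pool by
    Rubin's rules.  Returns one row per index with the pooled per-SD
    log-odds coefficient, CI, model F, average RVI, largest FMI,
    observations and imputed-case counts."""
    completed = mvn_impute(profiles, outcome, spec)
    y_obs = (outcome == "dementia").astype(float)
    rows = []
    per_index_missing = {}
    for idx, table in tables.items():
        factors = set(table.covered_factors(include_demographics)) - {"age"}
        factor_cols = [f for f in factors if f in profiles.columns]
        per_index_missing[idx] = int(
            profiles[factor_cols].isna().any(axis=1).sum()
        )
    for idx in tables:
        ests, vars_, r2s = [], [], []
        for comp in completed:
            cs = score_cohort(comp, {idx: tables[idx]}, include_demographics)
            s = cs.scores[idx]
            mask = s.notna() & outcome.notna()
            z, _, _ = zstandardize(s[mask].to_numpy())
            fit = fit_logistic(
                y_obs[mask],
                pd.DataFrame({idx: z}, index=s[mask].index),
                model_id=idx,
                index_col=idx,
            )
            beta = np.log(fit.or_per_sd)
            se = (np.log(fit.or_ci[1]) - np.log(fit.or_ci[0])) / (2 * 1.959963984540054)
            ests.append(beta)
            vars_.append(se**2)
            r2s.append(fit.pseudo_r2)
        n_obs = int(outcome.notna().sum())
        pooled = pool_rubin(ests, vars_, n_complete_df=n_obs - 2)
        rows.append(
            {
                "index": idx,
                "coefficient": pooled.qbar,
                "ci_low": pooled.ci[0],
                "ci_high": pooled.ci[1],
                "f_test": pooled.ftest,
                "p": pooled.p,
                "avg_rvi": pooled.rvi,
                "largest_fmi": pooled.fmi,
                "mean_pseudo_r2": float(np.mean(r2s)),
                "observations": n_obs,
                "imputed_cases": per_index_missing[idx],
                "m": spec.m,
            }
        )
    return pd.DataFrame(rows).set_index("index")


def index_specific_complete_case(
    scores: pd.DataFrame,
    profiles: pd.DataFrame,
    outcome: pd.Series,
) -> pd.DataFrame:
    """Available-case refits: each index on all participants with
    complete data for that index, regardless of other indices; the
    demographics model on the union sample."""
    from .delong import delong_covariance
    from .evaluate import _demographics_design

    y_all = (outcome == "dementia").astype(float)
    rows = []
    for idx in scores.columns:
        mask = scores[idx].notna() & outcome.notna()
        z, _, _ = zstandardize(scores.loc[mask, idx].to_numpy())
        fit = fit_logistic(
            y_all[mask],
            pd.DataFrame({idx: z}, index=scores.index[mask]),
            model_id=idx,
            index_col=idx,
        )
        aucs, _ = delong_covariance(z.reshape(-1, 1), y_all[mask].astype(bool))
        rows.append(
            {
                "model": idx,
                "odds_ratio": fit.or_per_sd,
                "ci_low": fit.or_ci[0],
                "ci_high": fit.or_ci[1],
                "pseudo_r2": fit.pseudo_r2,
                "chi2": fit.lr_chi2,
                "aic": fit.aic,
                "auc": float(aucs[0]),
                "observations": int(mask.sum()),
            }
        )
    demo = _demographics_design(profiles)
    mask = demo.notna().all(axis=1) & outcome.notna()
    fit = fit_logistic(y_all[mask], demo[mask], model_id="demographics")
    aucs, _ = delong_covariance(
        fit.linear_predictor.reshape(-1, 1), y_all[mask].astype(bool)
    )
    rows.append(
        {
            "model": "demographics",
            "odds_ratio": np.nan,
            "ci_low": np.nan,
            "ci_high": np.nan,
            "pseudo_r2": fit.pseudo_r2,
            "chi2": fit.lr_chi2,
            "aic": fit.aic,
            "auc": float(aucs[0]),
            "observations": int(mask.sum()),
        }
    )
    return pd.DataFrame(rows).set_index("model")
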