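"""Statistical evaluation of the risk indices.

Each index score is z-standardized and entered as the single covariate
of a logistic model for dementia (or AD) status, reported as an odds
ratio per standard deviation with a Wald 95% CI and McFadden pseudo-R².
Discrimination is compared through rank AUCs with DeLong covariance: a
global chi-square test across all curves gates the pairwise z-tests
(pairwise comparisons are run only when the global test is significant
at 0.05), while each index's contrast against the demographics-only
reference model (age + ordered education) is reported regardless.
Stratified analyses refit models within sex, baseline-age and APOE4
strata.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import delong
from ._util import stars

#: AUC interpretation bands (lower-inclusive)
AUC_BANDS = [
    (0.9, "excellent"),
    (0.8, "good"),
    (0.7, "moderate"),
    (0.6, "poor"),
    (0.5, "fail"),
    (-np.inf, "worse than chance"),
]


def interpretation_band(auc: float) -> str:
    for lo, name in AUC_BANDS:
        if auc >= lo:
            return name
    raise AssertionError


def zstandardize(values) -> tuple[np.ndarray, float, float]:
    """Z-scores (mean 0, SD 1 with the n-1 denominator) plus the
    transform parameters, for reuse on strata."""
    v = np.asarray(values, dtype=float)
    finite = v[~np.isnan(v)]
    if np.unique(finite).size < 2:
        raise ValueError("cannot z-standardize a constant input")
    mean = float(finite.mean())
    sd = float(finite.std(ddof=1))
    return (v - mean) / sd, mean, sd


@dataclasses.dataclass
class FitResult:
    model_id: str
    n: int
    params: dict
    or_per_sd: float | None
    or_ci: tuple[float, float] | None
    pseudo_r2: float
    outcome_kind: str
    converged: bool
    llf: float
    llnull: float
    separation_flag: bool = False
    p_value: float | None = None
    linear_predictor: np.ndarray | None = None

    @property
    def aic(self) -> float:
        return 2 * (len(self.params)) - 2 * self.llf

    @property
    def lr_chi2(self) -> float:
        return 2 * (self.llf - self.llnull)


def fit_logistic(
    outcome,
    covariates: pd.DataFrame,
    model_id: str = "model",
    index_col: str | None = None,
    outcome_kind: str = "dementia",
) -> FitResult:
    """Maximum-likelihood logistic fit with Wald 95% CIs.

    ``index_col`` names the (already standardized) index covariate whose
    exponentiated coefficient is the odds ratio per SD.  Quasi-complete
    separation is flagged and refit with a light L2 penalty.
    """
    y = np.asarray(outcome, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class")
    X = sm.add_constant(covariates.astype(float), has_constant="add")
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            if not res.mle_retvals.get("converged", True) or np.any(
                np.abs(res.params) > 50
            ):
                raise RuntimeError("suspect separation")
        except Exception:
            separation = True
            res = sm.Logit(y, X).fit_regularized(
                disp=0, alpha=1e-4, L1_wt=0.0, maxiter=500
            )
    params = dict(res.params)
    llf = float(res.llf)
    llnull = float(sm.Logit(y, X[["const"]]).fit(disp=0).llf)
    pseudo_r2 = 1.0 - llf / llnull if llnull != 0 else 0.0
    or_per_sd = or_ci = p_value = None
    if index_col is not None:
        beta = float(res.params[index_col])
        se = float(res.bse[index_col])
        or_per_sd = float(np.exp(beta))
        or_ci = (float(np.exp(beta - 1.959963984540054 * se)),
                 float(np.exp(beta + 1.959963984540054 * se)))
        p_value = float(res.pvalues[index_col])
    return FitResult(
        model_id=model_id,
        n=len(y),
        params={k: float(v) for k, v in params.items()},
        or_per_sd=or_per_sd,
        or_ci=or_ci,
        pseudo_r2=float(pseudo_r2),
        outcome_kind=outcome_kind,
        converged=not separation,
        llf=llf,
        llnull=llnull,
        separation_flag=separation,
        p_value=p_value,
        linear_predictor=np.asarray(X @ res.params, dtype=float),
    )


def auc(predicted_risk, outcome) -> tuple[float, tuple[float, float]]:
    """Rank-based AUC with a DeLong-variance Wald CI."""
    y = np.asarray(outcome, dtype=bool)
    aucs, cov = delong.delong_covariance(
        np.asarray(predicted_risk, dtype=float).reshape(-1, 1), y
    )
    return float(aucs[0]), delong.auc_confint(float(aucs[0]), float(cov[0, 0]))


@dataclasses.dataclass
class RocComparison:
    model_ids: list
    auc: dict
    auc_ci: dict
    delong_cov: np.ndarray
    global_stat: float
    global_p: float
    global_df: int
    pairwise_p: pd.DataFrame | None
    reference_contrasts: dict
    bands: dict
    n: int

    def to_jsonable(self) -> dict:
        return {
            "model_ids": list(self.model_ids),
            "auc": self.auc,
            "auc_ci": {k: list(v) for k, v in self.auc_ci.items()},
            "delong_cov": self.delong_cov.tolist(),
            "global_stat": self.global_stat,
            "global_p": self.global_p,
            "global_df": self.global_df,
            "pairwise_p": None
            if self.pairwise_p is None
            else self.pairwise_p.to_dict(),
            "reference_contrasts": self.reference_contrasts,
            "bands": self.bands,
            "n": self.n,
        }


def delong_compare(
    predictions: dict,
    outcome,
    reference: str | None = None,
    include_reference_in_global: bool = True,
    gate_alpha: float = 0.05,
) -> RocComparison:
    """Gated global-then-pairwise DeLong comparison of correlated AUCs.

    All predictions must be scored on the identical participant set
    (same length, no missing values) — mismatched sets raise rather
    than silently intersecting.  Pairwise p-values are populated only
    when the global test passes the gate; contrasts against the
    reference model are always reported with significance flags.
    """
    ids = list(predictions)
    n = {len(np.asarray(v)) for v in predictions.values()}
    if len(n) != 1:
        raise ValueError("predictions are not on the identical participant set")
    for k, v in predictions.items():
        if np.isnan(np.asarray(v, dtype=float)).any():
            raise ValueError(f"prediction {k!r} has missing values")
    y = np.asarray(outcome, dtype=bool)
    X = np.column_stack([np.asarray(predictions[k], dtype=float) for k in ids])
    aucs, cov = delong.delong_covariance(X, y)

    global_ids = ids
    if reference is not None and not include_reference_in_global:
        keep = [i for i, k in enumerate(ids) if k != reference]
        stat, p, df = delong.global_auc_test(aucs[keep], cov[np.ix_(keep, keep)])
    else:
        stat, p, df = delong.global_auc_test(aucs, cov)

    pairwise = None
    if p <= gate_alpha:
        mat = pd.DataFrame(np.ones((len(ids), len(ids))), index=ids, columns=ids)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                _, pij = delong.pairwise_z_test(aucs, cov, i, j)
                mat.iloc[i, j] = mat.iloc[j, i] = pij
        pairwise = mat

    contrasts = {}
    if reference is not None:
        r = ids.index(reference)
        for i, k in enumerate(ids):
            if k == reference:
                continue
            z, pik = delong.pairwise_z_test(aucs, cov, i, r)
            contrasts[k] = {"z": z, "p": pik, "stars": stars(pik)}

    return RocComparison(
        model_ids=global_ids,
        auc={k: float(a) for k, a in zip(ids, aucs)},
        auc_ci={
            k: delong.auc_confint(float(aucs[i]), float(cov[i, i]))
            for i, k in enumerate(ids)
        },
        delong_cov=cov,
        global_stat=stat,
        global_p=p,
        global_df=df,
        pairwise_p=pairwise,
        reference_contrasts=contrasts,
        bands={k: interpretation_band(float(a)) for k, a in zip(ids, aucs)},
        n=len(y),
    )


# ---------------------------------------------------------------------------
# analysis blocks


EDUCATION_CODE = {"low": 0.0, "medium": 1.0, "high": 2.0}


def _demographics_design(profiles: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "age": pd.to_numeric(profiles["baseline_age"], errors="coerce"),
            "education": profiles["education_level"].map(EDUCATION_CODE),
        },
        index=profiles.index,
    )


@dataclasses.dataclass
class EvaluationBlock:
    """One Table-2/Table-3-shaped analysis: per-index fits + gated ROC
    comparison against the demographics reference."""

    label: str
    n: int
    fits: dict
    demographics_fit: FitResult
    roc: RocComparison


def evaluate_block(
    scores: pd.DataFrame,
    profiles: pd.DataFrame,
    outcome: pd.Series,
    label: str,
    outcome_kind: str = "dementia",
    z_params: dict | None = None,
    include_reference_in_global: bool = True,
) -> EvaluationBlock:
    """Fit index models and the demographics reference on one sample.

    ``z_params`` optionally carries {index: (mean, sd)} estimated on a
    parent sample, so per-SD ORs stay comparable across strata; by
    default the standardization is estimated on this sample.
    """
    mask = outcome.notna()
    for c in scores.columns:
        mask &= scores[c].notna()
    demo = _demographics_design(profiles)
    mask &= demo.notna().all(axis=1)
    y = _binary_outcome(outcome[mask], outcome_kind)
    sc = scores.loc[mask]
    demo = demo.loc[mask]

    fits = {}
    preds = {}
    for idx in sc.columns:
        if z_params and idx in z_params:
            mean, sd = z_params[idx]
            z = (sc[idx].to_numpy(dtype=float) - mean) / sd
        else:
            z, _, _ = zstandardize(sc[idx].to_numpy(dtype=float))
        fit = fit_logistic(
            y,
            pd.DataFrame({idx: z}, index=sc.index),
            model_id=idx,
            index_col=idx,
            outcome_kind=outcome_kind,
        )
        fits[idx] = fit
        preds[idx] = z  # rank AUC is invariant to the monotone logistic link
    demo_fit = fit_logistic(
        y, demo, model_id="demographics", outcome_kind=outcome_kind
    )
    preds = {"demographics": demo_fit.linear_predictor, **preds}
    roc = delong_compare(
        preds,
        y,
        reference="demographics",
        include_reference_in_global=include_reference_in_global,
    )
    return EvaluationBlock(
        label=label, n=int(mask.sum()), fits=fits, demographics_fit=demo_fit, roc=roc
    )


def _binary_outcome(outcome: pd.Series, outcome_kind: str) -> np.ndarray:
    positive = {"dementia": "dementia", "ad": "ad"}[outcome_kind]
    return (outcome == positive).to_numpy(dtype=float)


def run_outcome_variants(
    scores_with: pd.DataFrame,
    scores_without: pd.DataFrame,
    profiles: pd.DataFrame,
    outcomes: pd.DataFrame,
) -> dict[str, EvaluationBlock]:
    """The four main analysis blocks: {dementia, ad} x {with, without
    demographic weights}.  AD analyses drop non-AD dementia (missing
    ``ad_binary``) before fitting."""
    blocks = {}
    for kind, col in (("dementia", "dementia_binary"), ("ad", "ad_binary")):
        for demo_label, sc in (("with_demographics", scores_with),
                               ("without_demographics", scores_without)):
            label = f"{kind}_{demo_label}"
            blocks[label] = evaluate_block(
                sc, profiles, outcomes[col], label, outcome_kind=kind
            )
    return blocks


@dataclasses.dataclass
class StratumSpec:
    axis: str  # sex | baseline_age_group | apoe4
    age_cut: float = 65.0

    def assign(self, profiles: pd.DataFrame) -> pd.Series:
        if self.axis == "sex":
            return profiles["sex"]
        if self.axis == "baseline_age_group":
            age = pd.to_numeric(profiles["baseline_age"], errors="coerce")
            lab = np.where(age < self.age_cut, f"<={self.age_cut - 1:.0f}y",
                           f">={self.age_cut:.0f}y")
            return pd.Series(lab, index=profiles.index).where(age.notna(), None)
        if self.axis == "apoe4":
            return profiles["apoe_carrier"]
        raise ValueError(f"unknown stratification axis {self.axis!r}")


def run_stratified(
    scores: pd.DataFrame,
    profiles: pd.DataFrame,
    outcomes: pd.DataFrame,
    strata: list[StratumSpec],
    z_on_full_sample: bool = True,
) -> dict[str, dict[str, EvaluationBlock]]:
    """Per-stratum refits (all-cause dementia only).

    Standardization parameters are estimated on the full analytic sample
    and reused within strata by default, keeping per-SD odds ratios
    comparable across strata; the demographics reference is refit within
    each stratum.  Strata with a single outcome class are skipped with a
    warning.
    """
    z_params = None
    if z_on_full_sample:
        z_params = {}
        for idx in scores.columns:
            _, mean, sd = zstandardize(scores[idx].dropna().to_numpy())
            z_params[idx] = (mean, sd)
    out: dict[str, dict[str, EvaluationBlock]] = {}
    for spec in strata:
        groups = spec.assign(profiles)
        axis_result: dict[str, EvaluationBlock] = {}
        for level in pd.unique(groups.dropna()):
            m = groups == level
            y = outcomes.loc[m, "dementia_binary"]
            if y.dropna().nunique() < 2:
                warnings.warn(
                    f"stratum {spec.axis}={level!r} has a single outcome "
                    "class; skipped"
                )
                continue
            axis_result[str(level)] = evaluate_block(
                scores.loc[m],
                profiles.loc[m],
                y,
                label=f"{spec.axis}={level}",
                z_params=z_params,
            )
        out[spec.axis] = axis_result
    return out
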