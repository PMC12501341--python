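"""Synthetic cohort generator.

Generates participant-level cohorts with the statistical structure the
downstream analysis assumes, without any access to restricted cohort
data: correlated categorical risk factors (Gaussian copula with a
latent-normal dependence structure, matching the latent-normal family
used by the imputation stage), a logistic outcome model on baseline
covariates, raw continuous measurements back-filled consistently with
each assigned category (so harmonization recovers the generated levels
exactly), and configurable MAR missingness driven by age, sex and
education.

Default marginal prevalences, demographic moments and outcome
calibration are transcribed from the analytic sample of the source
cohort's descriptive table and ship in ``data/cohort_defaults.yaml``.
"""

from __future__ import annotations

import dataclasses
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.stats import norm

from ._util import FACTOR_LEVELS, expit, rank_cut
from .harmonize import COGNITIVE_ITEMS, HEART_FLAGS, SLEEP_ITEMS, SOCIAL_ITEMS

#: factors drawn through the latent copula, in a fixed order
COPULA_FACTORS = [
    "education_level",
    "alcohol",
    "apoe_carrier",
    "bmi",
    "cognitive_activity",
    "heart_disease",
    "depression",
    "diabetes",
    "fish_intake",
    "mediterranean_diet",
    "hearing_impairment",
    "hypercholesterolemia",
    "hypertension",
    "physical_activity",
    "tbi",
    "sleep_disturbance",
    "smoking",
    "social_activity",
    "lonely",
    "stroke",
]

#: cohort-relative factors assigned by within-sample rank, not prevalence
QUANTILE_FACTORS = {"cognitive_activity": 3, "social_activity": 4}

#: ICD-10 codes the generator emits for condition-positive participants
_REGISTRY_EMIT = {
    "depression": "F32",
    "diabetes": "E11",
    "hypertension": "I10",
    "heart_disease": "I25",
    "stroke": "I63",
    "tbi": "S06",
}

#: raw-variable groups that go missing together under the MAR model
MISSINGNESS_GROUPS = {
    "blood_pressure": ["systolic_bp_2nd", "systolic_bp_3rd"],
    "cholesterol": ["total_cholesterol"],
    "glucose": ["non_fasting_glucose"],
    "hads": ["hads_depression"],
    "mvpa": ["mvpa_minutes_per_week", "mvpa_sessions_per_week"],
    "diet": ["fruit_points", "vegetable_points", "fish_points"],
    "alcohol": ["alcohol_units_per_week"],
    "smoking": ["smoking"],
    "fish": ["fish_frequency"],
    "height_weight": ["height_m", "weight_kg"],
    "cognitive": COGNITIVE_ITEMS,
    "social": SOCIAL_ITEMS,
    "sleep": SLEEP_ITEMS,
    "hearing": ["hearing_loss"],
    "diabetes_report": ["diabetes_self_report"],
    "heart": HEART_FLAGS,
    "stroke": ["stroke_self_report"],
    "tbi": ["tbi_hospitalized"],
    "apoe": ["apoe_e4_count"],
    "lonely": ["lonely_report"],
    "education": ["education_years"],
}


class CorrelationError(ValueError):
    """Latent correlation matrix is not a valid correlation matrix."""


@dataclasses.dataclass
class OutcomeModel:
    """Logistic outcome model on baseline covariates.

    Either ``intercept`` is given, or it is calibrated per cohort so the
    marginal dementia probability equals ``target_prevalence``.
    """

    target_prevalence: float | None = 0.108
    intercept: float | None = None
    age_per_year: float = 0.148
    education_per_level: float = -0.478
    factor_effects: dict = dataclasses.field(default_factory=dict)
    ad_fraction_of_dementia: float = 0.583
    amci_fraction_of_nondementia: float = 0.12
    namci_fraction_of_nondementia: float = 0.08


@dataclasses.dataclass
class MissingnessRule:
    """Per-variable-group MAR logistic model (predictors: age, sex,
    education only, matching the imputation stage's predictor set)."""

    intercept: float
    age_per_year: float = 0.0
    female: float = 0.0
    education_per_level: float = 0.0
    age_center: float = 67.0


@dataclasses.dataclass
class CohortSpec:
    n_participants: int
    seed: int
    age_mean: float = 66.6
    age_sd: float = 5.8
    age_range: tuple[float, float] = (45.0, 100.0)
    female_fraction: float = 0.528
    followup_gap_years: tuple[float, float] = (9.5, 11.5)
    factor_prevalences: dict = dataclasses.field(default_factory=dict)
    latent_loadings: dict | None = None
    latent_correlation: np.ndarray | None = None  # overrides loadings
    outcome_model: OutcomeModel = dataclasses.field(default_factory=OutcomeModel)
    missingness_model: dict = dataclasses.field(default_factory=dict)
    registry_report_rate: float = 0.25

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if not 0 <= self.female_fraction <= 1:
            raise ValueError("female_fraction must be in [0, 1]")
        for factor, prev in self.factor_prevalences.items():
            levels = FACTOR_LEVELS.get(factor)
            if levels is None:
                raise ValueError(f"unknown factor {factor!r}")
            if factor in QUANTILE_FACTORS:
                continue
            p = np.array([prev.get(lvl, 0.0) for lvl in levels], dtype=float)
            if (p < 0).any() or (p > 1).any() or abs(p.sum() - 1.0) > 1e-6:
                raise ValueError(
                    f"prevalences for {factor!r} must lie in [0,1] and sum to 1"
                )


def default_spec(n_participants: int, seed: int, **overrides) -> CohortSpec:
    """Build a :class:`CohortSpec` from the packaged default conditions."""
    raw = yaml.safe_load(
        (resources.files("demrisk") / "data" / "cohort_defaults.yaml").read_text()
    )
    demo = raw["demographics"]
    om = raw["outcome_model"]
    spec = CohortSpec(
        n_participants=n_participants,
        seed=seed,
        age_mean=demo["age_mean"],
        age_sd=demo["age_sd"],
        age_range=tuple(demo["age_range"]),
        female_fraction=demo["female_fraction"],
        followup_gap_years=tuple(demo["followup_gap_years"]),
        factor_prevalences=raw["factor_prevalences"],
        latent_loadings=raw["latent_loadings"],
        outcome_model=OutcomeModel(
            target_prevalence=om["target_prevalence"],
            age_per_year=om["age_per_year"],
            education_per_level=om["education_per_level"],
            factor_effects=om["factor_effects"],
            ad_fraction_of_dementia=om["ad_fraction_of_dementia"],
            amci_fraction_of_nondementia=om["amci_fraction_of_nondementia"],
            namci_fraction_of_nondementia=om["namci_fraction_of_nondementia"],
        ),
        missingness_model={
            k: MissingnessRule(**v) for k, v in raw["missingness_model"].items()
        },
        registry_report_rate=raw["registry_report_rate"],
    )
    for key, value in overrides.items():
        setattr(spec, key, value)
    spec.validate()
    return spec


def _latent_correlation(spec: CohortSpec) -> np.ndarray:
    dims = ["age"] + COPULA_FACTORS
    k = len(dims)
    if spec.latent_correlation is not None:
        corr = np.asarray(spec.latent_correlation, dtype=float)
        if corr.shape != (k, k):
            raise CorrelationError(
                f"latent correlation must be {k}x{k} (age + copula factors)"
            )
        if not np.allclose(corr, corr.T, atol=1e-10):
            raise CorrelationError("latent correlation must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
            raise CorrelationError("latent correlation must have unit diagonal")
        eig = np.linalg.eigvalsh(corr)
        if eig.min() < -1e-10:
            raise CorrelationError(
                "latent correlation is not positive semidefinite: "
                f"smallest eigenvalue {eig.min():.6g}"
            )
        return corr
    lam = np.array(
        [(spec.latent_loadings or {}).get(d, 0.0) for d in dims], dtype=float
    )
    corr = np.outer(lam, lam)
    np.fill_diagonal(corr, 1.0)
    return corr


def _draw_latents(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    dims = ["age"] + COPULA_FACTORS
    corr = _latent_correlation(spec)
    w, v = np.linalg.eigh(corr)
    w = np.clip(w, 0.0, None)
    root = v @ np.diag(np.sqrt(w))
    z = rng.standard_normal((spec.n_participants, len(dims))) @ root.T
    return pd.DataFrame(z, columns=dims)


def _threshold_levels(z: np.ndarray, prev: dict, levels: list[str]) -> np.ndarray:
    p = np.array([prev.get(lvl, 0.0) for lvl in levels], dtype=float)
    cuts = norm.ppf(np.clip(np.cumsum(p)[:-1], 0.0, 1.0))
    idx = np.searchsorted(cuts, z, side="left")
    return np.array(levels, dtype=object)[idx]


@dataclasses.dataclass
class CohortData:
    """A generated cohort: raw records, generation-truth factor levels,
    registry code table and a machine-readable data dictionary."""

    records: pd.DataFrame
    truth: pd.DataFrame
    registry: pd.DataFrame
    dictionary: dict

    def write(self, cohort_csv, dictionary_yaml=None, registry_csv=None) -> None:
        self.records.to_csv(cohort_csv, index=False)
        if dictionary_yaml is not None:
            with open(dictionary_yaml, "w") as fh:
                yaml.safe_dump(self.dictionary, fh, sort_keys=True)
        if registry_csv is not None:
            self.registry.to_csv(registry_csv, index=False)


def _calibrate_intercept(lp: np.ndarray, target: float) -> float:
    def gap(c):
        return expit(c + lp).mean() - target

    return brentq(gap, -40.0, 40.0, xtol=1e-12)


def generate_cohort(spec: CohortSpec) -> CohortData:
    """Generate a cohort of raw records per the spec.

    Categorical factors are drawn by thresholding a latent multivariate
    normal at the quantiles implied by the configured prevalences
    (cohort-relative composites by within-sample rank); the outcome is
    Bernoulli from the logistic outcome model; raw continuous fields are
    back-filled inside their category's numeric interval.  Deterministic
    for a fixed seed.
    """
    spec.validate()
    n = spec.n_participants
    rng = np.random.default_rng(spec.seed)

    z = _draw_latents(spec, rng)
    sex = np.where(rng.random(n) < spec.female_fraction, "female", "male")
    age = spec.age_mean + spec.age_sd * z["age"].to_numpy()
    age = np.clip(age, *spec.age_range)

    truth = pd.DataFrame({"sex": sex, "baseline_age": age})
    for factor in COPULA_FACTORS:
        levels = FACTOR_LEVELS[factor]
        zf = z[factor].to_numpy()
        if factor in QUANTILE_FACTORS:
            k = QUANTILE_FACTORS[factor]
            truth[factor] = np.array(levels, dtype=object)[rank_cut(zf, k)]
        else:
            prev = spec.factor_prevalences.get(factor)
            if prev is None:
                raise ValueError(f"no prevalences configured for {factor!r}")
            truth[factor] = _threshold_levels(zf, prev, levels)

    # ---- outcome ----
    om = spec.outcome_model
    edu_idx = truth["education_level"].map(
        {l: i for i, l in enumerate(FACTOR_LEVELS["education_level"])}
    ).to_numpy(dtype=float)
    lp = om.age_per_year * age + om.education_per_level * edu_idx
    for factor, effects in om.factor_effects.items():
        lp = lp + truth[factor].map(lambda l: effects.get(l, 0.0)).to_numpy(dtype=float)
    if om.intercept is not None:
        c = om.intercept
    else:
        c = _calibrate_intercept(lp, om.target_prevalence)
    dementia = rng.random(n) < expit(c + lp)
    sub = rng.random(n)
    outcome = np.where(
        dementia,
        np.where(sub < om.ad_fraction_of_dementia, "dementia_AD", "dementia_other"),
        np.where(
            sub < om.amci_fraction_of_nondementia,
            "aMCI",
            np.where(
                sub < om.amci_fraction_of_nondementia + om.namci_fraction_of_nondementia,
                "naMCI",
                "no_cognitive_impairment",
            ),
        ),
    )

    # ---- back-fill raw records consistently with assigned categories ----
    rec = pd.DataFrame({"id": np.arange(1, n + 1)})
    rec["baseline_age"] = np.round(age, 1)
    truth["baseline_age"] = rec["baseline_age"].to_numpy()
    rec["follow_up_age"] = np.round(age + rng.uniform(*spec.followup_gap_years, n), 1)
    rec["sex"] = sex

    def uniform_int(lo, hi, mask=None):
        out = rng.integers(lo, hi + 1, n).astype(float)
        return out if mask is None else np.where(mask, out, np.nan)

    lvl = {f: truth[f].to_numpy() for f in COPULA_FACTORS}

    edu_years = np.select(
        [lvl["education_level"] == "low", lvl["education_level"] == "medium"],
        [uniform_int(3, 7), uniform_int(8, 11)],
        uniform_int(12, 20),
    )
    rec["education_years"] = edu_years

    # BMI: sample target inside the band (0.1 margin), then derive weight
    # from the already-rounded height so rounding cannot cross a cut point
    bmi_target = np.select(
        [lvl["bmi"] == "underweight", lvl["bmi"] == "normal", lvl["bmi"] == "overweight"],
        [rng.uniform(16.0, 18.4, n), rng.uniform(18.6, 24.9, n), rng.uniform(25.1, 29.9, n)],
        rng.uniform(30.1, 44.0, n),
    )
    height = np.round(np.clip(rng.normal(1.72, 0.08, n), 1.50, 1.95), 2)
    rec["height_m"] = height
    rec["weight_kg"] = np.round(bmi_target * height**2, 1)

    hyper = lvl["hypertension"] == "yes"
    sbp = np.where(
        hyper, 2 * rng.integers(70, 111, n), 2 * rng.integers(46, 70, n)
    ).astype(float)  # hypertensive 140-220, normotensive 92-138
    delta = 2.0 * rng.integers(0, 2, n)
    rec["systolic_bp_2nd"] = sbp + delta
    rec["systolic_bp_3rd"] = sbp - delta

    chol = lvl["hypercholesterolemia"] == "yes"
    rec["total_cholesterol"] = np.round(
        np.where(chol, rng.uniform(6.6, 11.0, n), rng.uniform(3.6, 6.3, n)), 1
    )

    diab = lvl["diabetes"] == "yes"
    rec["non_fasting_glucose"] = np.round(
        np.where(diab, rng.uniform(5.0, 15.0, n), rng.uniform(4.0, 8.4, n)), 1
    )
    rec["diabetes_self_report"] = diab.astype(float)

    dep = lvl["depression"] == "yes"
    rec["hads_depression"] = np.where(dep, uniform_int(8, 21), uniform_int(0, 7))

    alc = lvl["alcohol"]
    rec["alcohol_units_per_week"] = np.select(
        [alc == "none", alc == "low_moderate"],
        [0.0, uniform_int(1, 13)],
        uniform_int(14, 40),
    )

    rec["smoking"] = lvl["smoking"]

    pa = lvl["physical_activity"]
    minutes = np.select(
        [pa == "inactive", pa == "medium"],
        [uniform_int(0, 29), uniform_int(30, 149)],
        uniform_int(150, 600),
    )
    sessions = np.select(
        [pa == "inactive", pa == "medium"],
        [uniform_int(0, 2), uniform_int(1, 4)],
        uniform_int(1, 7),
    )
    rec["mvpa_minutes_per_week"] = minutes
    rec["mvpa_sessions_per_week"] = sessions
    truth["physical_activity_caide"] = np.where(
        (sessions >= 2) & (minutes >= 60), "active", "inactive"
    )

    fish_levels = FACTOR_LEVELS["fish_intake"]
    rec["fish_frequency"] = (
        truth["fish_intake"].map({l: i + 1 for i, l in enumerate(fish_levels)}).astype(float)
    )

    triples = np.array(
        [(f, v, w) for f in range(1, 5) for v in range(1, 5) for w in range(1, 5)]
    )
    sums = triples.sum(axis=1)
    healthy_triples = triples[sums >= 10]
    unhealthy_triples = triples[sums < 10]
    healthy = lvl["mediterranean_diet"] == "healthy"
    pick_h = rng.integers(0, len(healthy_triples), n)
    pick_u = rng.integers(0, len(unhealthy_triples), n)
    diet = np.where(
        healthy[:, None], healthy_triples[pick_h], unhealthy_triples[pick_u]
    ).astype(float)
    rec["fruit_points"], rec["vegetable_points"], rec["fish_points"] = diet.T

    # composites: deterministic monotone transforms of the factor latent,
    # with at least one strictly increasing continuous item, so the
    # harmonizer's z-sum composite preserves the latent ranking exactly
    zc = z["cognitive_activity"].to_numpy()
    rec["cognitive_work_computer_hours"] = 40.0 * norm.cdf(zc)
    rec["cognitive_leisure_computer"] = (
        np.digitize(zc, [-1.2, -0.4, 0.4, 1.2]) + 1.0
    )
    rec["cognitive_culture_frequency"] = (
        np.digitize(zc, [-1.5, -0.5, 0.5, 1.5]) + 1.0
    )

    zs = z["social_activity"].to_numpy()
    rec["cohabiting"] = (zs > norm.ppf(0.40)).astype(float)
    rec["friends_help"] = (zs > norm.ppf(0.15)).astype(float)
    rec["friends_confide"] = (zs > norm.ppf(0.20)).astype(float)
    rec["neighborhood_community"] = 1.0 + 4.0 * norm.cdf(zs)
    rec["neighborhood_trust"] = np.digitize(zs, [-1.2, -0.4, 0.4, 1.2]) + 1.0
    rec["neighborhood_liking"] = np.digitize(zs, [-1.5, -0.5, 0.5, 1.5]) + 1.0
    rec["social_participation"] = 1.0 + 4.0 * norm.cdf(0.8 * zs)

    lonely = lvl["lonely"] == "yes"
    rec["lonely_report"] = np.where(
        lonely, np.where(rng.random(n) < 0.25, "strong", "some"), "none"
    )

    sleep_yes = lvl["sleep_disturbance"] == "yes"
    patt = rng.integers(1, 8, n)  # nonzero 3-bit pattern
    for bit, col in enumerate(SLEEP_ITEMS):
        rec[col] = np.where(sleep_yes, (patt >> bit) & 1, 0).astype(float)

    heart_yes = lvl["heart_disease"] == "yes"
    hpatt = rng.integers(1, 8, n)
    for bit, col in enumerate(HEART_FLAGS):
        rec[col] = np.where(heart_yes, (hpatt >> bit) & 1, 0).astype(float)

    hear_yes = lvl["hearing_impairment"] == "yes"
    u_hear = rng.random(n)
    survey_hear = hear_yes & (u_hear < 0.85)
    earlier_hear = hear_yes & ((u_hear >= 0.85) | (rng.random(n) < 0.6))
    rec["hearing_loss"] = np.where(hear_yes, survey_hear, 0.0).astype(float)
    rec["hearing_loss_earlier_wave"] = earlier_hear.astype(float)

    stroke_yes = lvl["stroke"] == "yes"
    rec["stroke_self_report"] = stroke_yes.astype(float)
    rec["stroke_earlier_wave"] = (stroke_yes & (rng.random(n) < 0.3)).astype(float)

    rec["tbi_hospitalized"] = (lvl["tbi"] == "yes").astype(float)

    carrier = lvl["apoe_carrier"] == "carrier"
    homo = rng.random(n) < (138.0 / 1399.0)
    rec["apoe_e4_count"] = np.where(carrier, np.where(homo, 2.0, 1.0), 0.0)

    rec["outcome"] = outcome
    truth["outcome"] = outcome
    truth.insert(0, "id", rec["id"].to_numpy())

    # ---- registry code emissions for condition-positive participants ----
    reg_rows = []
    for condition, code in _REGISTRY_EMIT.items():
        pos = (
            truth[condition] == "yes"
            if condition != "tbi"
            else truth["tbi"] == "yes"
        )
        emit = pos.to_numpy() & (rng.random(n) < spec.registry_report_rate)
        years = rng.integers(2007, 2010, n)
        for pid, yr in zip(rec.loc[emit, "id"], years[emit]):
            reg_rows.append((pid, code, int(yr)))
    registry = pd.DataFrame(reg_rows, columns=["id", "icd10_3digit", "year"])
    registry = registry.sort_values(["id", "icd10_3digit"]).reset_index(drop=True)

    return CohortData(
        records=rec,
        truth=truth,
        registry=registry,
        dictionary=_data_dictionary(),
    )


def inject_missingness(
    records: pd.DataFrame,
    missingness_model: dict,
    seed: int,
) -> pd.DataFrame:
    """Blank raw fields per the MAR model (never ``id`` or ``outcome``).

    ``missingness_model`` maps a variable-group name (see
    :data:`MISSINGNESS_GROUPS`) to a :class:`MissingnessRule`; the rule's
    predictors are restricted by construction to age, sex and education.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    out = records.copy()
    age = pd.to_numeric(records["baseline_age"], errors="coerce").to_numpy()
    female = (records["sex"] == "female").to_numpy(dtype=float)
    years = pd.to_numeric(records["education_years"], errors="coerce").to_numpy()
    edu_idx = np.select([years < 8, years <= 11], [0.0, 1.0], 2.0)
    for group in sorted(missingness_model):
        rule = missingness_model[group]
        cols = MISSINGNESS_GROUPS.get(group)
        if cols is None:
            raise ValueError(f"unknown missingness variable group {group!r}")
        p = expit(
            rule.intercept
            + rule.age_per_year * (age - rule.age_center)
            + rule.female * female
            + rule.education_per_level * edu_idx
        )
        mask = rng.random(len(records)) < p
        if mask.all():
            import logging

            logging.getLogger(__name__).warning(
                "missingness model blanks every value of group %s", group
            )
        for col in cols:
            if col in ("id", "outcome"):
                continue
            out.loc[mask, col] = np.nan
    return out


def _data_dictionary() -> dict:
    b = {"type": "boolean", "coding": "1=yes, 0=no, empty=missing"}
    return {
        "id": {"type": "integer", "coding": "participant identifier"},
        "baseline_age": {"type": "float", "units": "years"},
        "follow_up_age": {"type": "float", "units": "years"},
        "sex": {"type": "categorical", "coding": "female/male"},
        "education_years": {"type": "integer", "units": "years of formal education"},
        "height_m": {"type": "float", "units": "m", "coding": "rounded to 2 decimals"},
        "weight_kg": {"type": "float", "units": "kg", "coding": "rounded to 1 decimal"},
        "systolic_bp_2nd": {"type": "float", "units": "mmHg", "coding": "2nd reading, nearest 2 mmHg"},
        "systolic_bp_3rd": {"type": "float", "units": "mmHg", "coding": "3rd reading, nearest 2 mmHg"},
        "total_cholesterol": {"type": "float", "units": "mmol/L", "coding": "non-fasting serum"},
        "non_fasting_glucose": {"type": "float", "units": "mmol/L"},
        "hads_depression": {"type": "integer", "coding": "HADS depression subscale 0-21"},
        "alcohol_units_per_week": {"type": "float", "units": "units/week"},
        "smoking": {"type": "categorical", "coding": "never/former/current"},
        "mvpa_minutes_per_week": {"type": "float", "units": "min/week"},
        "mvpa_sessions_per_week": {"type": "float", "units": "sessions/week"},
        "fish_frequency": {"type": "integer", "coding": "1=0-0.25, 2=0.26-2, 3=2.1-4, 4=>4.1 servings/week"},
        "fruit_points": {"type": "integer", "coding": "diet frequency points 1-4"},
        "vegetable_points": {"type": "integer", "coding": "diet frequency points 1-4"},
        "fish_points": {"type": "integer", "coding": "diet frequency points 1-4"},
        "cognitive_work_computer_hours": {"type": "float", "units": "hours/week"},
        "cognitive_leisure_computer": {"type": "integer", "coding": "frequency 1-5"},
        "cognitive_culture_frequency": {"type": "integer", "coding": "frequency 1-5"},
        "cohabiting": b,
        "friends_help": b,
        "friends_confide": b,
        "neighborhood_community": {"type": "float", "coding": "agreement 1-5"},
        "neighborhood_trust": {"type": "integer", "coding": "agreement 1-5"},
        "neighborhood_liking": {"type": "integer", "coding": "agreement 1-5"},
        "social_participation": {"type": "float", "coding": "frequency 1-5"},
        "lonely_report": {"type": "categorical", "coding": "none/some/strong"},
        "sleep_falling_asleep": b,
        "sleep_staying_asleep": b,
        "sleep_early_waking": b,
        "hearing_loss": b,
        "hearing_loss_earlier_wave": b,
        "tbi_hospitalized": b,
        "stroke_self_report": b,
        "stroke_earlier_wave": b,
        "angina": b,
        "heart_failure": b,
        "myocardial_infarction": b,
        "diabetes_self_report": b,
        "apoe_e4_count": {"type": "integer", "coding": "APOE epsilon-4 allele count 0/1/2"},
        "outcome": {
            "type": "categorical",
            "coding": "no_cognitive_impairment/aMCI/naMCI/dementia_AD/dementia_other",
        },
    }
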