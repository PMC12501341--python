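"""Map raw survey/registry measurements to the categorical factor levels
used by the risk indices.

The harmonizer applies, per factor: the published threshold rules
(BMI, blood pressure, cholesterol, glucose, HADS depression, activity
minutes, diet points), composite construction with cohort-relative
tertiles/quartiles (cognitive and social activity), carry-forward of
positive earlier-wave reports (hearing, stroke), and a registry
(3-digit ICD-10) fallback used only when the survey value is missing.
Survey always wins a survey/registry conflict; conflicts and boundary
cases are logged.

Every factor column in the output is accompanied by a ``<factor>_prov``
provenance column taking values survey / earlier_wave / registry /
derived / missing.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from ._util import FACTOR_LEVELS, rank_cut

log = logging.getLogger(__name__)

# registry fallback code sets (3-digit ICD-10 prefixes)
REGISTRY_CODES = {
    "depression": ["F32", "F33"],
    "diabetes": ["E10", "E11", "E12", "E13", "E14"],
    "hypertension": ["I10", "I15"],
    "heart_disease": ["I11", "I20", "I21", "I22", "I23", "I24", "I25", "I50", "I51"],
    "stroke": ["I60", "I61", "I62", "I63", "I64", "I65", "I66", "I67", "I68", "I69"],
    "tbi": ["S06", "S07", "S09"],
}

COGNITIVE_ITEMS = [
    "cognitive_work_computer_hours",
    "cognitive_leisure_computer",
    "cognitive_culture_frequency",
]
SOCIAL_ITEMS = [
    "cohabiting",
    "friends_help",
    "friends_confide",
    "neighborhood_community",
    "neighborhood_trust",
    "neighborhood_liking",
    "social_participation",
]
SLEEP_ITEMS = ["sleep_falling_asleep", "sleep_staying_asleep", "sleep_early_waking"]
HEART_FLAGS = ["angina", "heart_failure", "myocardial_infarction"]

DEMENTIA_LABELS = {"dementia_AD", "dementia_other"}
NON_DEMENTIA_LABELS = {"no_cognitive_impairment", "aMCI", "naMCI"}


@dataclasses.dataclass
class HarmonizeConfig:
    """Tunable harmonization choices (defaults follow the index rules)."""

    alcohol_high_from: float = 14.0  # >=14 units/week scores as high
    education_banding: str = "table"  # "table": <8 / 8-11 / >11 years
    registry_years: tuple[int, int] = (2007, 2009)
    hads_cutoff: float = 8.0
    sbp_cutoff: float = 140.0
    cholesterol_cutoff: float = 6.5
    glucose_cutoff: float = 9.0
    diet_healthy_cutoff: float = 10.0
    mvpa_high_minutes: float = 150.0
    mvpa_medium_minutes: float = 30.0
    caide_min_sessions: int = 2
    caide_min_minutes: float = 60.0  # 30 min at least twice per week


# ---------------------------------------------------------------------------
# scalar categorizers


def categorize_bmi(height_m: float, weight_kg: float) -> str | None:
    """BMI = weight / height**2, banded at the published cut points
    (<18.5 / 18.5-24.99 / 25-29.99 / >=30); boundary values go to the
    upper band as printed (25.0 -> overweight, 30.0 -> obese)."""
    if pd.isna(height_m) or pd.isna(weight_kg):
        return None
    if height_m <= 0 or weight_kg <= 0:
        log.warning("nonpositive height/weight (%s, %s) -> BMI missing", height_m, weight_kg)
        return None
    bmi = weight_kg / height_m**2
    if bmi < 18.5:
        return "underweight"
    if bmi < 25.0:
        return "normal"
    if bmi < 30.0:
        return "overweight"
    return "obese"


def categorize_alcohol(units_per_week: float, cfg: HarmonizeConfig | None = None) -> str | None:
    """Weekly alcohol units -> none / low_moderate / high.

    The published bands (none = 0, low/moderate = 1-14, high = >=14)
    overlap at exactly 14; 14 is assigned to high (the more specific
    risk condition) and logged as a boundary case.
    """
    cfg = cfg or HarmonizeConfig()
    if pd.isna(units_per_week):
        return None
    if units_per_week < 0:
        log.warning("negative alcohol units %s -> missing", units_per_week)
        return None
    if units_per_week == 0:
        return "none"
    if units_per_week == cfg.alcohol_high_from:
        log.info("alcohol units exactly %s assigned to high band", units_per_week)
    if units_per_week >= cfg.alcohol_high_from:
        return "high"
    return "low_moderate"


def categorize_education(years: float, cfg: HarmonizeConfig | None = None) -> str | None:
    cfg = cfg or HarmonizeConfig()
    if pd.isna(years):
        return None
    hi = 12 if cfg.education_banding == "alt" else 11
    if years < 8:
        return "low"
    if years <= hi:
        return "medium"
    return "high"


# ---------------------------------------------------------------------------
# cohort-level harmonization


def _registry_positive(registry: pd.DataFrame | None, condition: str,
                       cfg: HarmonizeConfig) -> set:
    """ids with a qualifying registry code inside the accepted window."""
    if registry is None or len(registry) == 0:
        return set()
    codes = tuple(REGISTRY_CODES[condition])
    y0, y1 = cfg.registry_years
    m = (
        registry["icd10_3digit"].astype(str).str.upper().str.startswith(codes)
        & (registry["year"] >= y0)
        & (registry["year"] <= y1)
    )
    return set(registry.loc[m, "id"])


def _bool_col(records: pd.DataFrame, col: str) -> pd.Series:
    if col not in records:
        return pd.Series(np.nan, index=records.index)
    return pd.to_numeric(records[col], errors="coerce")


def _flag_with_fallback(
    records: pd.DataFrame,
    survey: pd.Series,
    condition: str | None,
    registry: pd.DataFrame | None,
    cfg: HarmonizeConfig,
    earlier: pd.Series | None = None,
) -> tuple[pd.Series, pd.Series]:
    """yes/no flag from survey, then positive earlier-wave carry-forward,
    then registry codes; absence of a registry code is not evidence of
    absence, so survey-missing/registry-negative stays missing."""
    level = pd.Series(None, index=records.index, dtype=object)
    prov = pd.Series("missing", index=records.index, dtype=object)
    has_survey = survey.notna()
    level[has_survey] = np.where(survey[has_survey] > 0, "yes", "no")
    prov[has_survey] = "survey"
    if earlier is not None:
        carry = ~has_survey & (earlier > 0)
        level[carry] = "yes"
        prov[carry] = "earlier_wave"
    if condition is not None:
        pos_ids = _registry_positive(registry, condition, cfg)
        if pos_ids:
            reg = records["id"].isin(pos_ids)
            conflict = has_survey & (survey == 0) & reg
            if conflict.any():
                log.info(
                    "%s: %d survey/registry conflicts; survey wins",
                    condition, int(conflict.sum()),
                )
            use = level.isna() & reg
            level[use] = "yes"
            prov[use] = "registry"
    return level, prov


def _zsum_composite(records: pd.DataFrame, items: list[str]) -> pd.Series:
    """Sum of per-item cohort z-scores (equal weights); missing if any
    component is missing."""
    cols = []
    for c in items:
        v = pd.to_numeric(records[c], errors="coerce")
        sd = v.std(ddof=1)
        if pd.isna(sd) or sd == 0:
            log.warning("composite item %s is constant; contributes 0", c)
            cols.append(pd.Series(np.where(v.notna(), 0.0, np.nan), index=records.index))
        else:
            cols.append((v - v.mean()) / sd)
    comp = cols[0]
    for c in cols[1:]:
        comp = comp + c
    return comp


def composite_tertiles_quartiles(
    records: pd.DataFrame,
) -> pd.DataFrame:
    """Cohort-relative composite factors: cognitive-activity tertiles,
    social-activity quartiles, and the direct loneliness recode."""
    out = pd.DataFrame(index=records.index)
    cog = _zsum_composite(records, COGNITIVE_ITEMS)
    tert = rank_cut(cog.to_numpy(), 3)
    out["cognitive_activity"] = [
        FACTOR_LEVELS["cognitive_activity"][t] if t >= 0 else None for t in tert
    ]
    soc = _zsum_composite(records, SOCIAL_ITEMS)
    quart = rank_cut(soc.to_numpy(), 4)
    out["social_activity"] = [
        FACTOR_LEVELS["social_activity"][q] if q >= 0 else None for q in quart
    ]
    lonely_raw = records["lonely_report"]
    out["lonely"] = lonely_raw.map(
        {"none": "no", "some": "yes", "strong": "yes"}
    ).where(lonely_raw.notna(), None)
    return out


def harmonize_cohort(
    records: pd.DataFrame,
    registry: pd.DataFrame | None = None,
    cfg: HarmonizeConfig | None = None,
) -> pd.DataFrame:
    """Harmonize a raw cohort table into factor levels + provenance.

    Returns one row per participant with ``id``, ``baseline_age``,
    ``follow_up_age``, one column per factor and one ``<factor>_prov``
    column.  Cohort-relative quantities (composite tertiles/quartiles)
    use this cohort as the reference, so harmonization is a cohort-level
    operation.
    """
    cfg = cfg or HarmonizeConfig()
    n = len(records)
    prof = pd.DataFrame(index=records.index)
    prof["id"] = records["id"]
    prof["baseline_age"] = pd.to_numeric(records["baseline_age"], errors="coerce")
    if "follow_up_age" in records:
        prof["follow_up_age"] = pd.to_numeric(records["follow_up_age"], errors="coerce")

    def put(factor: str, level: pd.Series, prov) -> None:
        level = level.where(level.notna(), None)
        prof[factor] = level
        if isinstance(prov, str):
            p = pd.Series(prov, index=records.index, dtype=object)
            p[level.isna()] = "missing"
            prof[f"{factor}_prov"] = p
        else:
            prov = prov.copy()
            prov[level.isna()] = "missing"
            prof[f"{factor}_prov"] = prov

    put("sex", records["sex"], "survey")

    edu_years = pd.to_numeric(records.get("education_years"), errors="coerce")
    put(
        "education_level",
        pd.Series([categorize_education(y, cfg) for y in edu_years], index=records.index),
        "survey",
    )

    put(
        "alcohol",
        pd.Series(
            [categorize_alcohol(u, cfg) for u in pd.to_numeric(records["alcohol_units_per_week"], errors="coerce")],
            index=records.index,
        ),
        "survey",
    )

    e4 = pd.to_numeric(records["apoe_e4_count"], errors="coerce")
    put(
        "apoe_carrier",
        pd.Series(np.where(e4.notna(), np.where(e4 >= 1, "carrier", "non_carrier"), None), index=records.index),
        "survey",
    )

    put(
        "bmi",
        pd.Series(
            [categorize_bmi(h, w) for h, w in zip(
                pd.to_numeric(records["height_m"], errors="coerce"),
                pd.to_numeric(records["weight_kg"], errors="coerce"))],
            index=records.index,
        ),
        "derived",
    )

    # --- clinical flags with registry fallback ---
    hads = pd.to_numeric(records["hads_depression"], errors="coerce")
    dep_survey = pd.Series(np.where(hads.notna(), (hads >= cfg.hads_cutoff).astype(float), np.nan), index=records.index)
    put("depression", *_flag_with_fallback(records, dep_survey, "depression", registry, cfg))

    glucose = pd.to_numeric(records["non_fasting_glucose"], errors="coerce")
    diab_report = _bool_col(records, "diabetes_self_report")
    diab_survey = pd.Series(np.nan, index=records.index)
    any_info = diab_report.notna() | glucose.notna()
    positive = (diab_report > 0) | (glucose >= cfg.glucose_cutoff)
    diab_survey[any_info] = positive[any_info].astype(float)
    put("diabetes", *_flag_with_fallback(records, diab_survey, "diabetes", registry, cfg))

    sbp2 = pd.to_numeric(records["systolic_bp_2nd"], errors="coerce")
    sbp3 = pd.to_numeric(records["systolic_bp_3rd"], errors="coerce")
    sbp_mean = pd.concat([sbp2, sbp3], axis=1).mean(axis=1)  # mean of available
    if (sbp2.isna() ^ sbp3.isna()).any():
        log.info(
            "hypertension: %d participants with fewer than 2 usable readings; "
            "mean of available used", int((sbp2.isna() ^ sbp3.isna()).sum()),
        )
    hyp_survey = pd.Series(np.where(sbp_mean.notna(), (sbp_mean >= cfg.sbp_cutoff).astype(float), np.nan), index=records.index)
    put("hypertension", *_flag_with_fallback(records, hyp_survey, "hypertension", registry, cfg))

    chol = pd.to_numeric(records["total_cholesterol"], errors="coerce")
    put(
        "hypercholesterolemia",
        pd.Series(np.where(chol.notna(), np.where(chol >= cfg.cholesterol_cutoff, "yes", "no"), None), index=records.index),
        "survey",
    )

    flags = [_bool_col(records, c) for c in HEART_FLAGS]
    flag_df = pd.concat(flags, axis=1)
    heart_survey = pd.Series(np.nan, index=records.index)
    has_any = flag_df.notna().any(axis=1)
    heart_survey[has_any] = (flag_df[has_any] > 0).any(axis=1).astype(float)
    put("heart_disease", *_flag_with_fallback(records, heart_survey, "heart_disease", registry, cfg))

    put(
        "stroke",
        *_flag_with_fallback(
            records,
            _bool_col(records, "stroke_self_report"),
            "stroke",
            registry,
            cfg,
            earlier=_bool_col(records, "stroke_earlier_wave"),
        ),
    )

    put(
        "tbi",
        *_flag_with_fallback(records, _bool_col(records, "tbi_hospitalized"), "tbi", registry, cfg),
    )

    # hearing: a positive report in any earlier wave is carried forward even
    # when the baseline survey reports no hearing loss
    hear_now = _bool_col(records, "hearing_loss")
    hear_then = _bool_col(records, "hearing_loss_earlier_wave")
    level = pd.Series(None, index=records.index, dtype=object)
    prov = pd.Series("missing", index=records.index, dtype=object)
    level[hear_now.notna()] = np.where(hear_now[hear_now.notna()] > 0, "yes", "no")
    prov[hear_now.notna()] = "survey"
    carried = (hear_then > 0) & (level != "yes")
    level[carried] = "yes"
    prov[carried] = "earlier_wave"
    put("hearing_impairment", level, prov)

    # sleep disturbance: any of the three items "several times a week"
    sleep_df = pd.concat([_bool_col(records, c) for c in SLEEP_ITEMS], axis=1)
    any_yes = (sleep_df > 0).any(axis=1)
    all_no = sleep_df.notna().all(axis=1) & ~any_yes
    sleep_level = pd.Series(None, index=records.index, dtype=object)
    sleep_level[any_yes] = "yes"
    sleep_level[all_no] = "no"
    put("sleep_disturbance", sleep_level, "survey")

    put("smoking", records["smoking"], "survey")

    minutes = pd.to_numeric(records["mvpa_minutes_per_week"], errors="coerce")
    pa = pd.Series(None, index=records.index, dtype=object)
    pa[minutes.notna() & (minutes < cfg.mvpa_medium_minutes)] = "inactive"
    pa[minutes.notna() & (minutes >= cfg.mvpa_medium_minutes) & (minutes < cfg.mvpa_high_minutes)] = "medium"
    pa[minutes.notna() & (minutes >= cfg.mvpa_high_minutes)] = "high"
    put("physical_activity", pa, "survey")

    sessions = pd.to_numeric(records["mvpa_sessions_per_week"], errors="coerce")
    caide = pd.Series(None, index=records.index, dtype=object)
    known = minutes.notna() & sessions.notna()
    active = known & (sessions >= cfg.caide_min_sessions) & (minutes >= cfg.caide_min_minutes)
    caide[known] = "inactive"
    caide[active] = "active"
    put("physical_activity_caide", caide, "derived")

    fish = pd.to_numeric(records["fish_frequency"], errors="coerce")
    put(
        "fish_intake",
        fish.map({1: "0-0.25", 2: "0.26-2", 3: "2.1-4", 4: ">4.1"}),
        "survey",
    )

    diet = (
        pd.to_numeric(records["fruit_points"], errors="coerce")
        + pd.to_numeric(records["vegetable_points"], errors="coerce")
        + pd.to_numeric(records["fish_points"], errors="coerce")
    )
    put(
        "mediterranean_diet",
        pd.Series(np.where(diet.notna(), np.where(diet >= cfg.diet_healthy_cutoff, "healthy", "unhealthy"), None), index=records.index),
        "derived",
    )

    composites = composite_tertiles_quartiles(records)
    put("cognitive_activity", composites["cognitive_activity"], "derived")
    put("social_activity", composites["social_activity"], "derived")
    put("lonely", composites["lonely"], "survey")

    assert len(prof) == n
    return prof


def outcome_labels(records: pd.DataFrame) -> pd.DataFrame:
    """Binary outcome codings from the adjudicated five-way label.

    ``dementia_binary``: dementia (any type) vs no dementia (MCI counts
    as no dementia).  ``ad_binary``: AD vs no dementia, with non-AD
    dementia set missing.
    """
    raw = records["outcome"]
    out = pd.DataFrame(index=records.index)
    dem = pd.Series(None, index=records.index, dtype=object)
    dem[raw.isin(DEMENTIA_LABELS)] = "dementia"
    dem[raw.isin(NON_DEMENTIA_LABELS)] = "no_dementia"
    out["dementia_binary"] = dem
    ad = pd.Series(None, index=records.index, dtype=object)
    ad[raw == "dementia_AD"] = "ad"
    ad[raw.isin(NON_DEMENTIA_LABELS)] = "no_dementia"
    out["ad_binary"] = ad  # non-AD dementia stays missing
    return out
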