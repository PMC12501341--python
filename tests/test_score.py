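"""Scoring: published worked examples, completeness semantics, and the
additive-separability properties of the point scores."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import random_complete_profile
from demrisk.score import score_cohort, score_index, theoretical_range
from demrisk.weights import WeightTable

ZERO_PROFILE = {
    # every factor at a zero-weight level for every index
    "baseline_age": 60.0,  # <65 band: 0 everywhere (CAIDE: >53 = 5, handled below)
    "sex": "female",
    "education_level": "high",
    "alcohol": "none",
    "apoe_carrier": "non_carrier",
    "bmi": "normal",
    "cognitive_activity": "low",
    "heart_disease": "no",
    "depression": "no",
    "diabetes": "no",
    "fish_intake": "0-0.25",
    "mediterranean_diet": "unhealthy",
    "hearing_impairment": "no",
    "hypercholesterolemia": "no",
    "hypertension": "no",
    "physical_activity": "inactive",
    "physical_activity_caide": "active",
    "tbi": "no",
    "sleep_disturbance": "no",
    "smoking": "never",
    "social_activity": "q1",
    "lonely": "no",
    "stroke": "no",
}

# ANU-ADRI zero level for physical activity is "inactive" but LIBRA gives
# inactive 1.1; there is no level set that zeroes every index at once for
# physical activity and Mediterranean diet, so zero-profile checks go
# index by index below.
ZERO_BY_INDEX = {
    "ANU-ADRI": dict(ZERO_PROFILE, physical_activity="inactive", mediterranean_diet="healthy"),
    "CAIDE": ZERO_PROFILE,
    "CogDrisk": dict(ZERO_PROFILE, physical_activity="inactive", cognitive_activity="low"),
    "LIBRA": dict(ZERO_PROFILE, physical_activity="high", mediterranean_diet="unhealthy",
                  cognitive_activity="low"),
    "LIBRA2": dict(ZERO_PROFILE, physical_activity="high", mediterranean_diet="healthy",
                   cognitive_activity="high"),
}


def test_zero_weight_profile_scores_zero_without_demographics(tables):
    for idx, prof in ZERO_BY_INDEX.items():
        s = score_index(pd.Series(prof), tables[idx], include_demographics=False)
        assert s.value == 0.0, idx


def test_libra_manual_sum_obese_hypertensive_smoker(tables):
    prof = dict(ZERO_BY_INDEX["LIBRA"], bmi="obese", hypertension="yes", smoking="current")
    s = score_index(pd.Series(prof), tables["LIBRA"], include_demographics=False)
    assert s.value == pytest.approx(1.6 + 1.6 + 1.5)


def test_obese_only_profile_across_indices(tables):
    expected = {"ANU-ADRI": 5.0, "CAIDE": 2.0, "CogDrisk": 3.0, "LIBRA": 1.6, "LIBRA2": 7.0}
    for idx, want in expected.items():
        prof = dict(ZERO_BY_INDEX[idx], bmi="obese")
        s = score_index(pd.Series(prof), tables[idx], include_demographics=False)
        assert s.value == pytest.approx(want), idx


def test_former_smoker_scored_only_by_anu_adri(tables):
    for idx in tables:
        base = dict(ZERO_BY_INDEX[idx], smoking="never")
        former = dict(ZERO_BY_INDEX[idx], smoking="former")
        d = (
            score_index(pd.Series(former), tables[idx], include_demographics=False).value
            - score_index(pd.Series(base), tables[idx], include_demographics=False).value
        )
        assert d == pytest.approx(1.0 if idx == "ANU-ADRI" else 0.0), idx


def test_cogdrisk_diabetes_weight_is_sex_specific(tables):
    for sex, want in (("male", 2.0), ("female", 3.0)):
        prof = dict(ZERO_BY_INDEX["CogDrisk"], sex=sex, diabetes="yes")
        s = score_index(pd.Series(prof), tables["CogDrisk"], include_demographics=False)
        assert s.value == pytest.approx(want)


def test_demographics_difference_equals_demographic_entry_sum(tables, rng):
    for _ in range(50):
        prof = random_complete_profile(rng)
        for idx, table in tables.items():
            with_d = score_index(prof, table, include_demographics=True).value
            without = score_index(prof, table, include_demographics=False).value
            demo_sum = 0.0
            for factor in table.covered_factors():
                entries = [e for e in table.entries if e.factor == factor and e.demographic]
                if not entries:
                    continue
                if factor == "age":
                    demo_sum += table.lookup("age", sex=prof["sex"], age=prof["baseline_age"]).points
                else:
                    level = prof["sex"] if factor == "sex" else prof[factor]
                    demo_sum += table.lookup(factor, level=level, sex=prof["sex"]).points
            assert with_d - without == pytest.approx(demo_sum), idx


def test_single_factor_upgrade_never_decreases_score(tables, rng):
    """Monotonicity: moving one factor to a higher-point level."""
    for _ in range(30):
        prof = random_complete_profile(rng)
        for idx, table in tables.items():
            base = score_index(prof, table).value
            for factor in table.covered_factors():
                if factor in ("age", "sex"):
                    continue
                entries = [
                    e for e in table.entries
                    if e.factor == factor and (e.sex in (None, prof["sex"]))
                ]
                cur = [e for e in entries if e.level == prof[factor] or (
                    factor == "smoking" and prof[factor] == "former"
                    and e.level == "never" and
                    "former" not in [x.level for x in entries])]
                if not cur:
                    continue
                best = max(entries, key=lambda e: e.centi_points)
                if best.centi_points >= cur[0].centi_points:
                    up = prof.copy()
                    up[factor] = best.level
                    assert score_index(up, table).value >= base


def test_scores_lie_within_theoretical_range(tables, rng):
    for _ in range(100):
        prof = random_complete_profile(rng)
        for idx, table in tables.items():
            for demo in (True, False):
                lo, hi = theoretical_range(table, demo)
                v = score_index(prof, table, include_demographics=demo).value
                assert lo - 1e-9 <= v <= hi + 1e-9


def test_caide_range_with_demographics_dominates_without(tables):
    lo_w, hi_w = theoretical_range(tables["CAIDE"], True)
    lo_wo, hi_wo = theoretical_range(tables["CAIDE"], False)
    assert hi_w >= hi_wo and lo_w <= lo_wo


def test_all_zero_table_has_zero_range():
    entries = [
        {"factor": "hypertension", "level": "no", "points": 0},
        {"factor": "hypertension", "level": "yes", "points": 0},
    ]
    from demrisk.weights import _parse

    t = _parse({"index": "CAIDE", "entries": entries})
    assert theoretical_range(t) == (0.0, 0.0)


def test_theoretical_range_matches_enumeration_on_subtables(tables):
    """Per-factor extreme selection equals brute-force enumeration over
    all level combinations of reduced 3-factor tables."""
    for idx, table in tables.items():
        factors = [f for f in table.covered_factors(False) if f not in ("age", "sex")][:3]
        sub = WeightTable(
            index=table.index,
            entries=[e for e in table.entries if e.factor in factors],
        )
        lo, hi = theoretical_range(sub, include_demographics=False)
        level_sets = [sub.factor_levels(f) for f in factors]
        best = {}
        for sex in ("female", "male"):
            sums = []
            for combo in itertools.product(*level_sets):
                total = 0
                for f, lvl in zip(factors, combo):
                    total += sub.lookup(f, level=lvl, sex=sex).centi_points
                sums.append(total)
            best[sex] = (min(sums), max(sums))
        assert lo == min(b[0] for b in best.values()) / 100.0
        assert hi == max(b[1] for b in best.values()) / 100.0


def test_complete_case_vs_permissive_mode(tables):
    prof = pd.Series(dict(ZERO_BY_INDEX["LIBRA2"], hearing_impairment=None, bmi="obese"))
    strict = score_index(prof, tables["LIBRA2"], include_demographics=False)
    assert strict.value is None
    assert strict.missing_factors == ["hearing_impairment"]
    loose = score_index(prof, tables["LIBRA2"], include_demographics=False, mode="permissive")
    assert loose.value == pytest.approx(7.0)
    assert loose.missing_factors == ["hearing_impairment"]


def test_missing_hearing_excludes_only_libra2(tables):
    """Hearing is covered only by LIBRA2, so a profile missing hearing
    stays scoreable for the other four indices."""
    prof = pd.Series(dict(ZERO_PROFILE, hearing_impairment=None))
    profiles = pd.DataFrame([prof])
    cs = score_cohort(profiles, tables, include_demographics=False)
    assert not cs.available["LIBRA2"].iloc[0]
    for idx in ("ANU-ADRI", "CAIDE", "CogDrisk", "LIBRA"):
        assert cs.available[idx].iloc[0], idx


def test_complete_case_subset_count(tables, rng):
    profs = pd.DataFrame([random_complete_profile(rng) for _ in range(10)])
    profs.loc[:2, "bmi"] = None  # bmi is covered by every index
    cs = score_cohort(profs, tables)
    assert int(cs.complete_all.sum()) == 7
    assert cs.missing_factor_counts["bmi"] == 3 * len(tables)


def test_vectorized_cohort_scoring_matches_per_profile(tables, rng):
    profs = pd.DataFrame([random_complete_profile(rng) for _ in range(60)])
    # punch some holes
    for col, frac in (("hypertension", 0.2), ("alcohol", 0.1), ("sex", 0.05)):
        mask = rng.random(len(profs)) < frac
        profs.loc[mask, col] = None
    for demo in (True, False):
        cs = score_cohort(profs, tables, include_demographics=demo)
        for idx, table in tables.items():
            for i in range(len(profs)):
                s = score_index(profs.iloc[i], table, include_demographics=demo)
                v = cs.scores[idx].iloc[i]
                if s.value is None:
                    assert np.isnan(v)
                else:
                    assert v == s.value


def test_empty_cohort_rejected(tables):
    with pytest.raises(ValueError, match="empty"):
        score_cohort(pd.DataFrame(), tables)
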