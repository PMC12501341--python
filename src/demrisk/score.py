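"""Scoring harmonized profiles against the index weight tables.

A profile is a mapping (pandas Series or dict) with a numeric
``baseline_age`` plus one categorical level per factor column (see
:data:`demrisk._util.FACTOR_LEVELS`); missing factors are None/NaN.

Complete-case scoring (the default) returns a missing value whenever any
factor the index covers is missing; the permissive mode scores the
available factors and lists what was skipped.  Sums are computed in
exact integer centi-points, so they are independent of summation order.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from ._util import FACTOR_LEVELS
from .weights import WeightTable, WeightTableError


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and np.isnan(value):
        return True
    return pd.isna(value)


@dataclasses.dataclass
class IndexScore:
    index: str
    value: float | None
    include_demographics: bool
    n_factors_scored: int
    n_factors_missing: int
    missing_factors: list[str]
    mode: str = "complete"


def _entry_for(table: WeightTable, factor: str, level, sex, age):
    if factor == "age":
        return table.lookup("age", sex=sex, age=age)
    if (
        factor == "smoking"
        and level == "former"
        and "former" not in table.factor_levels("smoking")
    ):
        # every index except ANU-ADRI groups ex-smokers with never-smokers
        level = "never"
    if level not in FACTOR_LEVELS[factor]:
        raise WeightTableError(
            f"{table.index}: unknown level {level!r} for factor {factor!r}"
        )
    return table.lookup(factor, level=level, sex=sex)


def score_index(
    profile,
    table: WeightTable,
    include_demographics: bool = True,
    mode: str = "complete",
) -> IndexScore:
    """Score one harmonized profile against one index weight table."""
    if mode not in ("complete", "permissive"):
        raise ValueError(f"unknown scoring mode {mode!r}")
    sex = profile.get("sex") if hasattr(profile, "get") else profile["sex"]
    sex = None if _is_missing(sex) else sex
    age = profile.get("baseline_age")
    age = None if _is_missing(age) else float(age)

    centi = 0
    missing: list[str] = []
    scored = 0
    for factor in table.covered_factors(include_demographics):
        if factor == "age":
            if age is None or (sex is None and _age_is_sex_specific(table)):
                missing.append("age")
                continue
            entry = table.lookup("age", sex=sex, age=age)
        else:
            level = profile.get(factor)
            if _is_missing(level) or (factor != "sex" and sex is None and _factor_is_sex_specific(table, factor)):
                missing.append(factor)
                continue
            entry = _entry_for(table, factor, level, sex, age)
        centi += entry.centi_points
        scored += 1

    value: float | None = centi / 100.0
    if mode == "complete" and missing:
        value = None
    return IndexScore(
        index=table.index,
        value=value,
        include_demographics=include_demographics,
        n_factors_scored=scored,
        n_factors_missing=len(missing),
        missing_factors=missing,
        mode=mode,
    )


def _age_is_sex_specific(table: WeightTable) -> bool:
    return any(e.factor == "age" and e.sex is not None for e in table.entries)


def _factor_is_sex_specific(table: WeightTable, factor: str) -> bool:
    return any(e.factor == factor and e.sex is not None for e in table.entries)


def theoretical_range(
    table: WeightTable, include_demographics: bool = True
) -> tuple[float, float]:
    """Attainable (min, max) score by per-factor extreme selection.

    Valid because the score is additively separable across factors: for a
    fixed sex, the extremes are the sums of per-factor extreme entries;
    sex (which conditions the age bands and a few factor cells) is then
    scanned exhaustively.
    """
    lo_best: int | None = None
    hi_best: int | None = None
    for sex in ("female", "male"):
        lo = hi = 0
        for factor in table.covered_factors(include_demographics):
            pts = [
                e.centi_points
                for e in table.entries
                if e.factor == factor
                and (e.sex is None or e.sex == sex)
                and (include_demographics or not e.demographic)
                and (factor != "sex" or e.level == sex)
            ]
            lo += min(pts)
            hi += max(pts)
        lo_best = lo if lo_best is None else min(lo_best, lo)
        hi_best = hi if hi_best is None else max(hi_best, hi)
    return lo_best / 100.0, hi_best / 100.0


@dataclasses.dataclass
class CohortScores:
    """Per-index score columns plus completeness bookkeeping."""

    scores: pd.DataFrame  # one column per index, NaN = incomplete
    available: pd.DataFrame  # boolean per-index availability flags
    complete_all: pd.Series  # complete for every index (main analysis set)
    missing_factor_counts: pd.Series  # per-factor missing counts


def _factor_centi_column(
    table: WeightTable, factor: str, profiles: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (centi-points, missing-mask) for one factor of one index."""
    n = len(profiles)
    sex = profiles["sex"] if "sex" in profiles else pd.Series([None] * n)
    entries = [e for e in table.entries if e.factor == factor]
    if factor == "age":
        age = pd.to_numeric(profiles["baseline_age"], errors="coerce")
        sex_specific = any(e.sex is not None for e in entries)
        missing = age.isna().to_numpy()
        if sex_specific:
            missing |= sex.isna().to_numpy()
        centi = np.zeros(n, dtype=np.int64)
        assigned = np.zeros(n, dtype=bool)
        for e in entries:
            m = ~missing
            if e.sex is not None:
                m &= (sex == e.sex).to_numpy()
            if e.age_min is not None:
                m &= (age >= e.age_min).to_numpy()
            if e.age_max is not None:
                m &= (age < e.age_max).to_numpy()
            centi[m] = e.centi_points
            assigned |= m
        missing |= ~assigned
        return centi, missing
    level = sex if factor == "sex" else profiles[factor]
    sex_specific = any(e.sex is not None for e in entries)
    table_levels = {e.level for e in entries}
    alias: dict[str, str] = {}
    if factor == "smoking" and "former" not in table_levels:
        alias["former"] = "never"
    if sex_specific:
        mapping = {(e.level, e.sex): e.centi_points for e in entries}
        keys = list(zip(level.map(lambda x: alias.get(x, x)), sex))
        centi = np.array(
            [mapping.get(k, 0) for k in keys], dtype=np.int64
        )
        missing = np.array(
            [k not in mapping for k in keys], dtype=bool
        )
        bad = missing & level.notna().to_numpy() & sex.notna().to_numpy()
    else:
        mapping = {e.level: float(e.centi_points) for e in entries}
        mapped = level.map(lambda x: alias.get(x, x)).map(mapping)
        missing = mapped.isna().to_numpy()
        centi = np.nan_to_num(mapped.to_numpy(dtype=float)).astype(np.int64)
        bad = missing & level.notna().to_numpy()
    if bad.any():
        value = level[bad].iloc[0]
        raise WeightTableError(
            f"{table.index}: unknown level {value!r} for factor {factor!r}"
        )
    return centi, missing


def score_cohort(
    profiles: pd.DataFrame,
    tables: dict[str, WeightTable],
    include_demographics: bool = True,
    mode: str = "complete",
) -> CohortScores:
    """Score a harmonized cohort for every index (vectorized).

    Emits per-index scores, per-index availability (the index-specific
    available-case sets used in sensitivity analyses) and the
    all-indices complete-case flag that defines the main analysis
    sample.  Agrees exactly with per-profile :func:`score_index`.
    """
    if len(profiles) == 0:
        raise ValueError("empty cohort")
    if mode not in ("complete", "permissive"):
        raise ValueError(f"unknown scoring mode {mode!r}")
    n = len(profiles)
    cols = {}
    avail = {}
    miss_counts: dict[str, int] = {}
    for idx, table in tables.items():
        total = np.zeros(n, dtype=np.int64)
        any_missing = np.zeros(n, dtype=bool)
        for factor in table.covered_factors(include_demographics):
            centi, missing = _factor_centi_column(table, factor, profiles)
            total += np.where(missing, 0, centi)
            any_missing |= missing
            if missing.any():
                miss_counts[factor] = miss_counts.get(factor, 0) + int(
                    missing.sum()
                )
        values = total / 100.0
        if mode == "complete":
            values = np.where(any_missing, np.nan, values)
        cols[idx] = values
        avail[idx] = ~any_missing
    scores = pd.DataFrame(cols, index=profiles.index)
    available = pd.DataFrame(avail, index=profiles.index)
    return CohortScores(
        scores=scores,
        available=available,
        complete_all=available.all(axis=1),
        missing_factor_counts=pd.Series(miss_counts, dtype=int).sort_index(),
    )
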