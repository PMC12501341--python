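"""Shared helpers: canonical factor levels, rank-based grouping, rounding."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np
from scipy.stats import rankdata

# Canonical factor level sets, in canonical (ordinal where meaningful) order.
# Level codes used for numeric round-trips (imputation) are list positions.
FACTOR_LEVELS: dict[str, list[str]] = {
    "sex": ["female", "male"],
    "education_level": ["low", "medium", "high"],
    "alcohol": ["none", "low_moderate", "high"],
    "apoe_carrier": ["non_carrier", "carrier"],
    "bmi": ["underweight", "normal", "overweight", "obese"],
    "cognitive_activity": ["low", "medium", "high"],
    "heart_disease": ["no", "yes"],
    "depression": ["no", "yes"],
    "diabetes": ["no", "yes"],
    "fish_intake": ["0-0.25", "0.26-2", "2.1-4", ">4.1"],
    "mediterranean_diet": ["unhealthy", "healthy"],
    "hearing_impairment": ["no", "yes"],
    "hypercholesterolemia": ["no", "yes"],
    "hypertension": ["no", "yes"],
    "physical_activity": ["inactive", "medium", "high"],
    "physical_activity_caide": ["inactive", "active"],
    "tbi": ["no", "yes"],
    "sleep_disturbance": ["no", "yes"],
    "smoking": ["never", "former", "current"],
    "social_activity": ["q1", "q2", "q3", "q4"],
    "lonely": ["no", "yes"],
    "stroke": ["no", "yes"],
}

# All harmonized profile columns that hold factor levels (age is numeric).
PROFILE_FACTORS = list(FACTOR_LEVELS)


def rank_cut(values, k: int) -> np.ndarray:
    """Assign each value to one of ``k`` rank-based groups (0 .. k-1).

    Groups are cut at the empirical positions j*n/k.  Ties share the
    lowest rank of their tie group and therefore fall into the lower
    group together.  NaNs propagate as -1.
    """
    v = np.asarray(values, dtype=float)
    out = np.full(v.shape, -1, dtype=int)
    ok = ~np.isnan(v)
    n = int(ok.sum())
    if n == 0:
        return out
    r = rankdata(v[ok], method="min")
    cuts = np.array([j * n / k for j in range(1, k)])
    out[ok] = (r[:, None] > cuts[None, :]).sum(axis=1)
    return out


def percent_1dp(numerator: float, denominator: float) -> float:
    """100*numerator/denominator rounded half-up to one decimal place."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    numerator = int(numerator) if float(numerator).is_integer() else float(numerator)
    denominator = int(denominator) if float(denominator).is_integer() else float(denominator)
    q = 100 * Decimal(numerator) / Decimal(denominator)
    return float(q.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def expit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def logit(p):
    p = np.asarray(p, dtype=float)
    return np.log(p / (1.0 - p))


def stars(p: float) -> str:
    """Significance flags at the conventional 0.05 / 0.005 / 0.001 levels."""
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.005:
        return "**"
    if p < 0.05:
        return "*"
    return ""
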