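"""Evaluation stage: standardization, logistic fits, rank AUC, the gated
DeLong comparison and stratified/outcome-variant analyses."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from demrisk import delong
from demrisk.evaluate import (
    StratumSpec,
    delong_compare,
    evaluate_block,
    fit_logistic,
    interpretation_band,
    run_stratified,
    zstandardize,
)


# ---------------------------------------------------------------------------
# z-standardization


def test_zstandardize_simple_triplet():
    z, mean, sd = zstandardize([1, 2, 3])
    assert np.allclose(z, [-1, 0, 1])
    assert (mean, sd) == (2.0, 1.0)


def test_zstandardize_mean_zero_sd_one(rng):
    v = rng.normal(5, 3, 500)
    z, _, _ = zstandardize(v)
    assert abs(z.mean()) < 1e-12
    assert np.std(z, ddof=1) == pytest.approx(1.0)


def test_zstandardize_uses_n_minus_one_denominator():
    v = np.array([2, 4, 4, 4, 5, 5, 7, 9], dtype=float)
    z, mean, sd = zstandardize(v)
    assert mean == pytest.approx(5.0)
    assert sd == pytest.approx(np.sqrt(32 / 7))  # ddof=1
    assert z[-1] == pytest.approx((9 - 5) / np.sqrt(32 / 7))


def test_zstandardize_rejects_constant():
    with pytest.raises(ValueError, match="constant"):
        zstandardize([3.0, 3.0, 3.0])


# ---------------------------------------------------------------------------
# AUC


def _pair_count_auc(scores, y):
    """Exhaustive pair-count oracle with half credit for ties."""
    cases = scores[y.astype(bool)]
    controls = scores[~y.astype(bool)]
    total = 0.0
    for c in cases:
        for d in controls:
            total += 1.0 if c > d else (0.5 if c == d else 0.0)
    return total / (len(cases) * len(controls))


def test_auc_perfect_separation_is_one():
    y = np.array([0, 0, 1, 1])
    assert delong.auc_mann_whitney([1, 2, 5, 6], y) == 1.0


def test_auc_identical_scores_is_half():
    y = np.array([0, 1, 0, 1])
    assert delong.auc_mann_whitney([3, 3, 3, 3], y) == 0.5


def test_auc_small_example_matches_pair_count():
    scores = np.array([1.0, 4.0, 3.0, 5.0])
    y = np.array([0, 0, 1, 1])
    want = _pair_count_auc(scores, y)
    assert want == 0.75  # pairs: 3>1, 3<4, 5>1, 5>4
    assert delong.auc_mann_whitney(scores, y) == pytest.approx(want)


def test_auc_single_class_rejected():
    with pytest.raises(ValueError, match="class"):
        delong.auc_mann_whitney([1.0, 2.0], np.array([1, 1]))


def test_auc_invariant_to_monotone_logistic_link(rng):
    x = rng.normal(0, 1, 300)
    y = (rng.random(300) < 1 / (1 + np.exp(-x))).astype(float)
    fit = fit_logistic(y, pd.DataFrame({"x": x}), index_col="x")
    a1 = delong.auc_mann_whitney(x, y)
    a2 = delong.auc_mann_whitney(fit.linear_predictor, y)
    assert a1 == pytest.approx(a2, abs=1e-12)


# ---------------------------------------------------------------------------
# logistic models


def test_two_by_two_or_equals_cross_product_ratio():
    # counts: exposed cases 30, exposed controls 70, unexposed cases 10,
    # unexposed controls 90 -> OR = (30*90)/(70*10)
    x = np.r_[np.ones(100), np.zeros(100)]
    y = np.r_[np.ones(30), np.zeros(70), np.ones(10), np.zeros(90)]
    fit = fit_logistic(y, pd.DataFrame({"x": x}), index_col="x")
    assert fit.or_per_sd == pytest.approx((30 * 90) / (70 * 10), rel=1e-6)


def test_null_covariate_gives_or_one_and_tiny_r2(rng):
    x = rng.normal(0, 1, 20_000)
    y = (rng.random(20_000) < 0.2).astype(float)
    fit = fit_logistic(y, pd.DataFrame({"x": x}), index_col="x")
    assert fit.or_per_sd == pytest.approx(1.0, abs=0.05)
    assert fit.pseudo_r2 < 0.001
    assert fit.or_ci[0] < fit.or_per_sd < fit.or_ci[1]


def test_or_per_sd_invariant_to_affine_rescaling(rng):
    x = rng.normal(10, 4, 2000)
    y = (rng.random(2000) < 1 / (1 + np.exp(-(x - 10) / 4))).astype(float)
    z1, _, _ = zstandardize(x)
    z2, _, _ = zstandardize(100 + 7 * x)
    f1 = fit_logistic(y, pd.DataFrame({"x": z1}), index_col="x")
    f2 = fit_logistic(y, pd.DataFrame({"x": z2}), index_col="x")
    assert f1.or_per_sd == pytest.approx(f2.or_per_sd, rel=1e-8)


def test_single_class_outcome_rejected():
    with pytest.raises(ValueError, match="single class"):
        fit_logistic(np.ones(10), pd.DataFrame({"x": np.arange(10.0)}))


def test_separation_flagged_and_refit():
    x = np.r_[np.zeros(20), np.ones(20)]
    y = x.copy()  # perfectly separated
    fit = fit_logistic(y, pd.DataFrame({"x": x}), index_col="x")
    assert fit.separation_flag


# ---------------------------------------------------------------------------
# DeLong comparison


def test_model_compared_to_itself_gives_p_one(rng):
    x = rng.normal(0, 1, 200)
    y = (rng.random(200) < 0.3).astype(bool)
    rc = delong_compare({"a": x, "b": x.copy()}, y)
    assert rc.auc["a"] == rc.auc["b"]
    assert rc.global_p == 1.0


def test_global_chi2_equals_squared_pairwise_z_for_two_models(rng):
    n = 300
    y = (rng.random(n) < 0.4).astype(bool)
    x1 = rng.normal(0, 1, n) + y
    x2 = rng.normal(0, 1, n) + 0.5 * y
    aucs, cov = delong.delong_covariance(np.column_stack([x1, x2]), y)
    stat, p, df = delong.global_auc_test(aucs, cov)
    z, _ = delong.pairwise_z_test(aucs, cov, 0, 1)
    assert df == 1
    assert stat == pytest.approx(z**2, rel=1e-9)


def test_mismatched_participant_sets_rejected(rng):
    y = (rng.random(50) < 0.5).astype(bool)
    with pytest.raises(ValueError, match="identical participant set"):
        delong_compare({"a": rng.normal(size=50), "b": rng.normal(size=49)}, y)


def test_missing_predictions_rejected(rng):
    y = (rng.random(50) < 0.5).astype(bool)
    bad = rng.normal(size=50)
    bad[3] = np.nan
    with pytest.raises(ValueError, match="missing"):
        delong_compare({"a": rng.normal(size=50), "b": bad}, y)


def test_pairwise_gated_on_global_significance(rng):
    n = 400
    y = (rng.random(n) < 0.3).astype(bool)
    # null: independent noise -> gate usually closed
    rc_null = delong_compare({"a": rng.normal(size=n), "b": rng.normal(size=n)}, y)
    if rc_null.global_p > 0.05:
        assert rc_null.pairwise_p is None
    # strong signal vs noise -> gate open
    rc_alt = delong_compare({"a": rng.normal(size=n) + 2 * y, "b": rng.normal(size=n)}, y)
    assert rc_alt.global_p <= 0.05
    assert rc_alt.pairwise_p is not None
    assert rc_alt.pairwise_p.loc["a", "b"] <= 0.05


def test_interpretation_bands():
    assert interpretation_band(0.55) == "fail"
    assert interpretation_band(0.65) == "poor"
    assert interpretation_band(0.75) == "moderate"
    assert interpretation_band(0.85) == "good"


def test_binormal_auc_limit(rng):
    # N(0,1) controls vs N(delta,1) cases -> AUC -> Phi(delta/sqrt(2))
    n = 20_000
    delta = 0.8
    scores = np.r_[rng.normal(0, 1, n), rng.normal(delta, 1, n)]
    y = np.r_[np.zeros(n), np.ones(n)].astype(bool)
    assert delong.auc_mann_whitney(scores, y) == pytest.approx(
        norm.cdf(delta / np.sqrt(2)), abs=0.01
    )


# ---------------------------------------------------------------------------
# analysis blocks


def _toy_analysis(rng, n=600):
    profiles = pd.DataFrame(
        {
            "baseline_age": rng.normal(67, 5, n),
            "sex": rng.choice(["female", "male"], n),
            "education_level": rng.choice(["low", "medium", "high"], n),
            "apoe_carrier": rng.choice(["non_carrier", "carrier"], n),
        }
    )
    scores = pd.DataFrame(
        {
            "A": rng.normal(0, 1, n) + 0.05 * profiles["baseline_age"],
            "B": rng.normal(0, 1, n),
        }
    )
    lp = -9.0 + 0.12 * profiles["baseline_age"] + 0.5 * scores["A"]
    y = rng.random(n) < 1 / (1 + np.exp(-lp))
    outcome = pd.Series(np.where(y, "dementia", "no_dementia"))
    return profiles, scores, outcome


def test_degenerate_single_stratum_equals_unstratified(rng):
    profiles, scores, outcome = _toy_analysis(rng)
    outcomes = pd.DataFrame({"dementia_binary": outcome})
    whole = evaluate_block(scores, profiles, outcome, "all")
    strat = run_stratified(
        scores, profiles, outcomes, [StratumSpec(axis="baseline_age_group", age_cut=0.0)]
    )
    (only,) = strat["baseline_age_group"].values()
    assert only.n == whole.n
    for k in whole.roc.auc:
        assert only.roc.auc[k] == pytest.approx(whole.roc.auc[k])
        assert only.fits.get(k).or_per_sd == pytest.approx(
            whole.fits[k].or_per_sd
        ) if k in whole.fits else True


def test_stratum_sizes_partition_analytic_sample(rng):
    profiles, scores, outcome = _toy_analysis(rng)
    outcomes = pd.DataFrame({"dementia_binary": outcome})
    strat = run_stratified(scores, profiles, outcomes, [StratumSpec(axis="apoe4")])
    sizes = [b.n for b in strat["apoe4"].values()]
    assert sum(sizes) == len(profiles)


def test_single_class_stratum_skipped_with_warning(rng):
    profiles, scores, outcome = _toy_analysis(rng)
    outcome = outcome.copy()
    outcome[profiles["sex"] == "male"] = "no_dementia"  # degenerate stratum
    outcomes = pd.DataFrame({"dementia_binary": outcome})
    with pytest.warns(UserWarning, match="single outcome class"):
        strat = run_stratified(scores, profiles, outcomes, [StratumSpec(axis="sex")])
    assert set(strat["sex"]) == {"female"}


def test_ad_analysis_drops_non_ad_dementia(rng):
    """With 238 of 5247 participants labelled non-AD dementia, the AD
    analysis sample is 5009 (row-dropping rule)."""
    from demrisk.harmonize import outcome_labels

    n = 5247
    labels = np.array(["no_cognitive_impairment"] * n, dtype=object)
    labels[:238] = "dementia_other"
    labels[238:566] = "dementia_AD"
    records = pd.DataFrame({"outcome": labels})
    out = outcome_labels(records)
    assert int(out["dementia_binary"].notna().sum()) == 5247
    assert int(out["ad_binary"].notna().sum()) == 5009
    assert (out.loc[out["ad_binary"].isna(), "dementia_binary"] == "dementia").all()


def test_run_outcome_variants_produces_four_blocks(rng):
    from demrisk.evaluate import run_outcome_variants
    from demrisk.harmonize import outcome_labels

    profiles, scores, outcome = _toy_analysis(rng)
    raw_outcome = np.where(outcome == "dementia", "dementia_AD", "no_cognitive_impairment")
    outcomes = outcome_labels(pd.DataFrame({"outcome": raw_outcome}))
    blocks = run_outcome_variants(scores, scores * 0.5, profiles, outcomes)
    assert set(blocks) == {
        "dementia_with_demographics",
        "dementia_without_demographics",
        "ad_with_demographics",
        "ad_without_demographics",
    }
    # zero non-AD dementia: AD and dementia analytic n equal
    assert blocks["ad_with_demographics"].n == blocks["dementia_with_demographics"].n
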