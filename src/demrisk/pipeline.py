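"""End-to-end orchestration: simulate -> harmonize -> score -> evaluate
-> impute, with a serialized config, structured logging and
deterministic report tables.

Reports follow the shapes of the study tables this pipeline emulates:
a descriptive included-vs-missing contrast table (level counts,
one-decimal percentages, chi-square stars), per-outcome model tables
(OR per SD, CI, pseudo-R², significance flags), AUC tables with
reference contrasts, and the imputation/available-case sensitivity
tables.  Every percentage in a report is re-derivable from counts in
the same report; an internal consistency check enforces this.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import chi2_contingency

from . import evaluate as ev
from ._util import FACTOR_LEVELS, percent_1dp, stars
from .harmonize import harmonize_cohort, outcome_labels
from .impute import ImputationSpec, impute_and_pool, index_specific_complete_case
from .score import score_cohort
from .synthetic import default_spec, generate_cohort, inject_missingness
from .weights import load_all_weight_tables


@dataclasses.dataclass
class RunConfig:
    n_participants: int = 5247
    seed: int = 1
    missingness: bool = True
    imputation: bool = True
    m_imputations: int = 100
    strata: tuple[str, ...] = ("sex", "baseline_age_group", "apoe4")
    include_reference_in_global: bool = True
    weights_dir: str | None = None
    cohort_csv: str | None = None  # load instead of simulating
    registry_csv: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "strata" in raw:
            raw["strata"] = tuple(raw["strata"])
        return cls(**raw)


def describe_sample(
    included: pd.DataFrame, excluded: pd.DataFrame
) -> pd.DataFrame:
    """Included-vs-excluded descriptive contrasts per factor.

    Level counts and one-decimal percentages for each group, plus a
    Pearson chi-square p-value per factor (suppressed with a note when
    an expected cell count is zero) and significance stars.
    """
    rows = []
    for factor, levels in FACTOR_LEVELS.items():
        if factor not in included.columns:
            continue
        inc = included[factor].value_counts()
        exc = excluded[factor].value_counts()
        n_inc = int(inc.sum())
        n_exc = int(exc.sum())
        counts = np.array(
            [[int(inc.get(l, 0)) for l in levels], [int(exc.get(l, 0)) for l in levels]]
        )
        keep = counts.sum(axis=0) > 0
        p = np.nan
        note = ""
        if keep.sum() >= 2 and n_inc > 0 and n_exc > 0:
            sub = counts[:, keep]
            expected = np.outer(sub.sum(axis=1), sub.sum(axis=0)) / sub.sum()
            if (expected == 0).any():
                note = "chi-square suppressed: zero expected cell count"
            else:
                stat, p, _, _ = chi2_contingency(sub, correction=False)
        else:
            note = "chi-square suppressed: degenerate table"
        for i, level in enumerate(levels):
            rows.append(
                {
                    "factor": factor,
                    "level": level,
                    "n_included": counts[0, i],
                    "pct_included": percent_1dp(counts[0, i], n_inc) if n_inc else np.nan,
                    "n_excluded": counts[1, i],
                    "pct_excluded": percent_1dp(counts[1, i], n_exc) if n_exc else np.nan,
                    "chi2_p": p,
                    "stars": stars(p) if not np.isnan(p) else "",
                    "note": note,
                }
            )
    return pd.DataFrame(rows)


def _check_percentages(table: pd.DataFrame) -> None:
    """Internal consistency: every percentage re-derives from the counts
    printed beside it."""
    for _, r in table.iterrows():
        for side in ("included", "excluded"):
            n = table.loc[table["factor"] == r["factor"], f"n_{side}"].sum()
            if n > 0 and not np.isnan(r[f"pct_{side}"]):
                assert r[f"pct_{side}"] == percent_1dp(r[f"n_{side}"], n)


def _fit_table(block: ev.EvaluationBlock) -> pd.DataFrame:
    rows = []
    for idx, fit in block.fits.items():
        rows.append(
            {
                "model": idx,
                "n": fit.n,
                "odds_ratio_per_sd": fit.or_per_sd,
                "ci_low": fit.or_ci[0],
                "ci_high": fit.or_ci[1],
                "pseudo_r2": fit.pseudo_r2,
                "p": fit.p_value,
                "stars": stars(fit.p_value),
            }
        )
    demo = block.demographics_fit
    rows.append(
        {
            "model": "demographics",
            "n": demo.n,
            "odds_ratio_per_sd": np.nan,
            "ci_low": np.nan,
            "ci_high": np.nan,
            "pseudo_r2": demo.pseudo_r2,
            "p": np.nan,
            "stars": "",
        }
    )
    return pd.DataFrame(rows).set_index("model")


def _auc_table(block: ev.EvaluationBlock) -> pd.DataFrame:
    roc = block.roc
    rows = []
    for model in roc.auc:
        contrast = roc.reference_contrasts.get(model, {})
        rows.append(
            {
                "model": model,
                "n": roc.n,
                "auc": roc.auc[model],
                "ci_low": roc.auc_ci[model][0],
                "ci_high": roc.auc_ci[model][1],
                "band": roc.bands[model],
                "p_vs_reference": contrast.get("p", np.nan),
                "stars": contrast.get("stars", ""),
                "global_p": roc.global_p,
            }
        )
    return pd.DataFrame(rows).set_index("model")


@dataclasses.dataclass
class RunReport:
    config: RunConfig
    flow: dict
    descriptive: pd.DataFrame
    fit_tables: dict
    auc_tables: dict
    stratified: dict
    sensitivity_mi: pd.DataFrame | None
    sensitivity_available_case: pd.DataFrame | None
    log: list


def run_all(config: RunConfig, out_dir=None) -> RunReport:
    """Execute the full analysis per config; optionally persist all
    intermediate artifacts and report tables under ``out_dir``.
    Identical config (and inputs) produce byte-identical outputs."""
    logbook: list[dict] = []

    def note(stage: str, **kw) -> None:
        logbook.append({"stage": stage, **kw})

    tables = load_all_weight_tables(config.weights_dir)
    note("weights", indices=sorted(tables))

    if config.cohort_csv:
        records = pd.read_csv(config.cohort_csv)
        registry = (
            pd.read_csv(config.registry_csv) if config.registry_csv else None
        )
        note("load", n=len(records))
    else:
        spec = default_spec(config.n_participants, seed=config.seed)
        cohort = generate_cohort(spec)
        records = cohort.records
        registry = cohort.registry
        if config.missingness:
            records = inject_missingness(
                records, spec.missingness_model, seed=spec.seed + 1
            )
        note("simulate", n=len(records), seed=config.seed,
             missingness=config.missingness)

    profiles = harmonize_cohort(records, registry)
    outcomes = outcome_labels(records)
    note("harmonize", n=len(profiles))

    scored_with = score_cohort(profiles, tables, include_demographics=True)
    scored_without = score_cohort(profiles, tables, include_demographics=False)
    eligible = outcomes["dementia_binary"].notna()
    complete = scored_with.complete_all & eligible
    note(
        "score",
        eligible=int(eligible.sum()),
        complete_all=int(complete.sum()),
        per_index_available={
            k: int((scored_with.available[k] & eligible).sum())
            for k in scored_with.available
        },
    )

    flow = {
        "n_total": len(records),
        "n_outcome_eligible": int(eligible.sum()),
        "n_complete_all_indices": int(complete.sum()),
        "n_excluded_incomplete": int((eligible & ~complete).sum()),
        "pct_complete_of_eligible": percent_1dp(
            int(complete.sum()), int(eligible.sum())
        ),
    }

    descriptive = describe_sample(
        profiles[complete], profiles[eligible & ~complete]
    )
    _check_percentages(descriptive)

    analytic = complete
    blocks = ev.run_outcome_variants(
        scored_with.scores[analytic],
        scored_without.scores[analytic],
        profiles[analytic],
        outcomes[analytic],
    )
    fit_tables = {label: _fit_table(b) for label, b in blocks.items()}
    auc_tables = {label: _auc_table(b) for label, b in blocks.items()}
    note("evaluate", blocks=sorted(blocks))

    strata = [ev.StratumSpec(axis=a) for a in config.strata]
    strat = ev.run_stratified(
        scored_with.scores[analytic],
        profiles[analytic],
        outcomes[analytic],
        strata,
    )
    stratified = {
        axis: {
            level: {"fits": _fit_table(b), "auc": _auc_table(b)}
            for level, b in groups.items()
        }
        for axis, groups in strat.items()
    }
    note("stratify", axes=list(config.strata))

    sens_mi = None
    sens_ac = None
    if config.imputation:
        ispec = ImputationSpec(m=config.m_imputations, seed=config.seed + 2)
        sens_mi = impute_and_pool(
            profiles[eligible],
            outcomes.loc[eligible, "dementia_binary"],
            tables,
            ispec,
        )
        sens_ac = index_specific_complete_case(
            scored_with.scores[eligible],
            profiles[eligible],
            outcomes.loc[eligible, "dementia_binary"],
        )
        note("impute", m=config.m_imputations)

    report = RunReport(
        config=config,
        flow=flow,
        descriptive=descriptive,
        fit_tables=fit_tables,
        auc_tables=auc_tables,
        stratified=stratified,
        sensitivity_mi=sens_mi,
        sensitivity_available_case=sens_ac,
        log=logbook,
    )
    if out_dir is not None:
        write_report(report, out_dir, records=records, profiles=profiles,
                     scores=scored_with.scores)
    return report


_FLOAT_FMT = "%.6g"


def write_report(report: RunReport, out_dir, records=None, profiles=None,
                 scores=None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(report.config), fh, sort_keys=True)
    if records is not None:
        records.to_csv(out / "cohort.csv", index=False, float_format=_FLOAT_FMT)
    if profiles is not None:
        profiles.to_csv(out / "harmonized.csv", index=False, float_format=_FLOAT_FMT)
    if scores is not None:
        scores.to_csv(out / "scores.csv", float_format=_FLOAT_FMT)
    with open(out / "flow.json", "w") as fh:
        json.dump(report.flow, fh, indent=2, sort_keys=True)
    report.descriptive.to_csv(
        out / "table1_descriptive.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    for label, tab in sorted(report.fit_tables.items()):
        tab.to_csv(out / f"table2_{label}.tsv", sep="\t", float_format=_FLOAT_FMT)
    for label, tab in sorted(report.auc_tables.items()):
        tab.to_csv(out / f"table3_{label}.tsv", sep="\t", float_format=_FLOAT_FMT)
    strat_rows = []
    for axis, groups in sorted(report.stratified.items()):
        for level, tabs in sorted(groups.items()):
            for kind in ("fits", "auc"):
                t = tabs[kind].copy()
                t.insert(0, "axis", axis)
                t.insert(1, "stratum", level)
                t.insert(2, "table", kind)
                strat_rows.append(t.reset_index())
    if strat_rows:
        pd.concat(strat_rows, ignore_index=True).to_csv(
            out / "stratified.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
        )
    if report.sensitivity_mi is not None:
        report.sensitivity_mi.to_csv(
            out / "table4_mi.tsv", sep="\t", float_format=_FLOAT_FMT
        )
    if report.sensitivity_available_case is not None:
        report.sensitivity_available_case.to_csv(
            out / "table4_available_case.tsv", sep="\t", float_format=_FLOAT_FMT
        )
    with open(out / "log.jsonl", "w") as fh:
        for entry in report.log:
            fh.write(json.dumps(entry, sort_keys=True) + "\n")
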