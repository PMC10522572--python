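"""Primary, subgroup, leave-one-out and sensitivity analyses.

Orchestrates the full nested case-control pipeline — screening, matching,
exposure, confounders, conditional-logistic fits — and emits result tables
shaped like a pharmacoepidemiology report: a descriptive table of the
matched sample, exposure-category prevalences, and odds-ratio tables for

* analysis one: cumulative flupentixol exposure (0-365 days reference),
  adjusted for cumulative other-antipsychotic exposure and 21 confounders;
* analysis two: cumulative any-antipsychotic exposure (1-365 days
  reference), adjusted for the 21 confounders;

each also stratified by sex, refit under a leave-one-out exclusion of each
lung-cancer subtype, and under two sensitivity configurations (excluding
users of ten specific antipsychotic agents; unlimited control reuse).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import clogit, cohort, covariates as cov_mod, exposure, matching
from .config import COVARIATE_NAMES, LUNG_CANCER_SUBTYPES, StudyConfig

AGE_BANDS = ((18, 24), (25, 44), (45, 64), (65, 84), (85, 200))


@dataclass
class StudyData:
    """Everything the analyses consume, computed once from the raw tables."""

    config: StudyConfig
    patients: pd.DataFrame
    prescriptions: pd.DataFrame
    diagnoses: pd.DataFrame
    eligible: pd.DataFrame
    attrition: pd.DataFrame
    cases: pd.DataFrame
    matched: pd.DataFrame
    matching_log: dict
    exposures: pd.DataFrame
    covariates: pd.DataFrame
    logs: dict = field(default_factory=dict)


def prepare_study(
    patients: pd.DataFrame,
    prescriptions: pd.DataFrame,
    diagnoses: pd.DataFrame,
    config: StudyConfig,
    reuse_cap="config",
) -> StudyData:
    """Run screening, case finding, matching, exposure and confounders."""
    eligible, attrition = cohort.screen(patients, prescriptions, diagnoses, config)
    cases = cohort.identify_cases(eligible, diagnoses, config)
    first_ca = cohort.first_lung_cancer_date(diagnoses, config)
    cap = config.control_reuse_cap if reuse_cap == "config" else reuse_cap
    matched, mlog = matching.match_all(
        cases,
        eligible,
        first_ca,
        ratio=config.matching_ratio,
        policy=matching.ReusePolicy(max_uses_per_patient=cap),
        seed=config.seed,
    )
    imputer = exposure.DurationImputer.fit(
        prescriptions[prescriptions["drug_code"].isin(set(config.antipsychotic_codes))]
    )
    exposures = exposure.compute_exposures(matched, prescriptions, imputer, config)
    covs = cov_mod.compute_covariates(matched, prescriptions, diagnoses, config)
    return StudyData(
        config=config,
        patients=patients,
        prescriptions=prescriptions,
        diagnoses=diagnoses,
        eligible=eligible,
        attrition=attrition,
        cases=cases,
        matched=matched,
        matching_log=mlog,
        exposures=exposures,
        covariates=covs,
    )


# ---------------------------------------------------------------------------
# fitting helpers

def _or_rows(result: clogit.FitResult, analysis: str, stratum: str) -> pd.DataFrame:
    tab = clogit.wald_summary(result)
    tab.insert(0, "analysis", analysis)
    tab.insert(1, "stratum", stratum)
    tab["n_sets"] = result.n_sets
    tab["n_informative"] = result.n_informative
    return tab


def _empty_rows(analysis: str, stratum: str, reason: str, n_sets: int = 0) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "analysis": analysis,
                "stratum": stratum,
                "term": f"<empty: {reason}>",
                "OR": np.nan,
                "ci_low": np.nan,
                "ci_high": np.nan,
                "p": np.nan,
                "significant": False,
                "n_sets": n_sets,
                "n_informative": 0,
            }
        ]
    )


def _inestimable_rows(analysis: str, stratum: str, terms, n_sets: int) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "analysis": analysis,
                "stratum": stratum,
                "term": t,
                "OR": np.nan,
                "ci_low": np.nan,
                "ci_high": np.nan,
                "p": np.nan,
                "significant": False,
                "n_sets": n_sets,
                "n_informative": 0,
            }
            for t in terms
        ]
    )


def _fit_subset(data: StudyData, matched: pd.DataFrame, analysis: str, stratum: str) -> pd.DataFrame:
    if matched.empty:
        return _empty_rows(analysis, stratum, "no matched sets")
    design = clogit.build_design(matched, data.exposures, data.covariates, analysis)
    design, dropped = clogit.drop_inestimable_columns(design)
    n_sets = design.n_sets
    try:
        result = clogit.fit(design)
    except ValueError as err:
        return _empty_rows(analysis, stratum, str(err), n_sets=n_sets)
    rows = _or_rows(result, analysis, stratum)
    if dropped:
        rows = pd.concat(
            [rows, _inestimable_rows(analysis, stratum, dropped, n_sets)], ignore_index=True
        )
    return rows


def _strata_frames(matched: pd.DataFrame, stratum: str) -> pd.DataFrame:
    if stratum == "all":
        return matched
    sex = {"male": "M", "female": "F"}[stratum]
    return matched[matched["sex"] == sex]


def run_primary(data: StudyData) -> pd.DataFrame:
    """Both adjusted conditional-logistic analyses on the full sample."""
    if data.matched.empty:
        raise ValueError("no matched sets available for the primary analysis")
    return pd.concat(
        [
            _fit_subset(data, data.matched, "analysis_one", "all"),
            _fit_subset(data, data.matched, "analysis_two", "all"),
        ],
        ignore_index=True,
    )


def run_sex_strata(data: StudyData) -> pd.DataFrame:
    """Independent refits on the male-case and female-case set subsets."""
    frames = []
    for stratum in ("male", "female"):
        sub = _strata_frames(data.matched, stratum)
        for analysis in ("analysis_one", "analysis_two"):
            frames.append(_fit_subset(data, sub, analysis, stratum))
    return pd.concat(frames, ignore_index=True)


def run_leave_one_out(data: StudyData, strata: bool = True) -> pd.DataFrame:
    """Refit after removing each lung-cancer subtype's matched sets in turn.

    Dropping a case's subtype drops the whole matched set: controls exist
    only relative to their case.
    """
    frames = []
    strata_list = ("all", "male", "female") if strata else ("all",)
    for subtype in LUNG_CANCER_SUBTYPES:
        keep = data.matched[data.matched["subtype_code"] != subtype]
        for stratum in strata_list:
            sub = _strata_frames(keep, stratum)
            for analysis in ("analysis_one", "analysis_two"):
                tab = _fit_subset(data, sub, analysis, stratum)
                tab.insert(2, "excluded_subtype", subtype)
                frames.append(tab)
    return pd.concat(frames, ignore_index=True)


def run_sensitivity_exclude_drugs(data: StudyData, drug_codes=None) -> pd.DataFrame:
    """Refit after removing members with prior use of the listed agents.

    Removal operates on individual members: a set that keeps its case and at
    least one control stays in; sets losing the case or every control are
    dropped.
    """
    config = data.config
    codes = set(drug_codes if drug_codes is not None else config.sensitivity_exclude_drugs)
    rx = data.prescriptions[data.prescriptions["drug_code"].isin(codes)]
    anchor = cohort.rx_anchor_dates(rx)
    first_use = anchor.dropna().groupby(rx.loc[anchor.dropna().index, "patient_id"]).min()

    matched = data.matched
    used = pd.DatetimeIndex(matched["patient_id"].map(first_use))
    prior_use = used.notna() & (used < pd.DatetimeIndex(matched["index_date"]))
    kept = matched.loc[~prior_use]
    case_sets = set(kept.loc[kept["role"] == "case", "set_id"])
    ctrl_sets = set(kept.loc[kept["role"] == "control", "set_id"])
    valid = case_sets & ctrl_sets
    kept = kept[kept["set_id"].isin(valid)]

    frames = []
    for analysis in ("analysis_one", "analysis_two"):
        tab = _fit_subset(data, kept, analysis, "all")
        tab.insert(2, "sensitivity", "exclude_prior_drug_users")
        frames.append(tab)
    out = pd.concat(frames, ignore_index=True)
    data.logs["sensitivity_exclude_drugs"] = {
        "n_members_removed": int(prior_use.sum()),
        "n_sets_dropped": int(data.matched["set_id"].nunique() - len(valid)),
    }
    return out


def run_sensitivity_unlimited_reuse(
    patients: pd.DataFrame,
    prescriptions: pd.DataFrame,
    diagnoses: pd.DataFrame,
    config: StudyConfig,
) -> tuple[pd.DataFrame, StudyData]:
    """Re-run matching (and everything downstream) with no reuse cap."""
    data = prepare_study(patients, prescriptions, diagnoses, config, reuse_cap=None)
    tab = run_primary(data)
    tab.insert(2, "sensitivity", "unlimited_reuse")
    return tab, data


# ---------------------------------------------------------------------------
# descriptive outputs

def pct(count: float, total: float) -> float:
    """Percentage on the printed scale, rounded to 2 decimals."""
    if total == 0:
        return float("nan")
    return round(100.0 * count / total, 2)


def prevalence_percentages(counts: dict[str, int], total: int) -> dict[str, float]:
    """Category percentages (2 dp) from category counts and a denominator."""
    return {label: pct(c, total) for label, c in counts.items()}


def descriptive_table(data: StudyData) -> pd.DataFrame:
    """Case/control descriptive statistics of the matched sample.

    Counts and percentages for sex and age bands, mean (SD) age, and each
    co-medication/comorbidity flag, by role.
    """
    members = data.matched.merge(
        data.covariates.drop(columns=["index_date"]), on=["set_id", "patient_id"], how="left"
    )
    rows = []
    for role in ("case", "control"):
        sub = members[members["role"] == role]
        n = len(sub)
        rows.append({"variable": "patients_n", "role": role, "count": n, "pct": np.nan})
        for sex, label in (("F", "female"), ("M", "male")):
            c = int((sub["sex"] == sex).sum())
            rows.append({"variable": f"sex_{label}", "role": role, "count": c, "pct": pct(c, n)})
        for lo, hi in AGE_BANDS:
            c = int(((sub["age"] >= lo) & (sub["age"] <= hi)).sum())
            label = f"age_{lo}_{hi}" if hi < 200 else f"age_{lo}_plus"
            rows.append({"variable": label, "role": role, "count": c, "pct": pct(c, n)})
        rows.append(
            {
                "variable": "age_mean",
                "role": role,
                "count": round(float(sub["age"].mean()), 2) if n else np.nan,
                "pct": round(float(sub["age"].std(ddof=1)), 2) if n > 1 else np.nan,
            }
        )
        for flag in COVARIATE_NAMES:
            c = int(sub[flag].sum())
            rows.append({"variable": flag, "role": role, "count": c, "pct": pct(c, n)})
    return pd.DataFrame(rows)


def exposure_prevalence_table(data: StudyData) -> pd.DataFrame:
    """Exposure-category counts and percentages by role, per exposure kind."""
    df = data.exposures
    rows = []
    for kind, col in (("any_antipsychotics", "cat_any"), ("flupentixol", "cat_flupentixol")):
        for role in ("case", "control"):
            sub = df[df["role"] == role]
            n = len(sub)
            counts = sub[col].value_counts().to_dict()
            for label in sorted(counts):
                rows.append(
                    {
                        "exposure": kind,
                        "role": role,
                        "category": label,
                        "count": int(counts[label]),
                        "pct": pct(counts[label], n),
                    }
                )
    return pd.DataFrame(rows)


def run_all(
    patients: pd.DataFrame,
    prescriptions: pd.DataFrame,
    diagnoses: pd.DataFrame,
    config: StudyConfig,
    loo_strata: bool = True,
) -> dict:
    """Full report: primary, strata, leave-one-out, both sensitivities."""
    data = prepare_study(patients, prescriptions, diagnoses, config)
    out = {
        "data": data,
        "descriptive": descriptive_table(data),
        "exposure_prevalence": exposure_prevalence_table(data),
        "primary": run_primary(data),
        "sex_strata": run_sex_strata(data),
        "leave_one_out": run_leave_one_out(data, strata=loo_strata),
        "sensitivity_exclude_drugs": run_sensitivity_exclude_drugs(data),
    }
    unlimited_tab, unlimited_data = run_sensitivity_unlimited_reuse(
        patients, prescriptions, diagnoses, config
    )
    out["sensitivity_unlimited_reuse"] = unlimited_tab
    out["unlimited_data"] = unlimited_data
    return out
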