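"""Cohort screening and incident case identification.

Implements the study-entry cascade for a cohort of antipsychotic initiators:
patients enter on their first antipsychotic prescription inside the enrolment
window, four exclusion rules are applied in a fixed order, and incident
lung-cancer cases are the screened patients whose first lung-cancer diagnosis
falls inside the outcome window at adult age.

The four exclusions, applied sequentially for attrition reporting (final
membership is order-invariant):

1. structurally invalid demographics (missing sex or birth date);
2. incorrect records: death date before the first antipsychotic prescription;
3. lung-cancer diagnosis before or at the date of the first antipsychotic
   prescription;
4. lung-cancer diagnosis before the start of the outcome window (the two
   preceding years serve as a screening period for prevalent cancer).

An empty death date means alive at database end and is not an exclusion;
rule 1 is a data-quality rule, not a vital-status filter.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import StudyConfig

logger = logging.getLogger(__name__)

ATTRITION_RULES = (
    "no_antipsychotic_in_enrolment_window",
    "rule1_missing_demographics",
    "rule2_death_before_first_rx",
    "rule3_lung_cancer_on_or_before_first_rx",
    "rule4_lung_cancer_before_outcome_window",
)


def coerce_dates(df: pd.DataFrame, columns) -> pd.DataFrame:
    """Parse date columns, turning malformed values into NaT with a warning."""
    out = df.copy()
    for col in columns:
        raw = out[col]
        parsed = pd.to_datetime(raw, errors="coerce", format="mixed")
        bad = parsed.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        if bad.any():
            logger.warning("%d malformed values in %r coerced to missing", int(bad.sum()), col)
        out[col] = parsed
    return out


def rx_anchor_dates(prescriptions: pd.DataFrame) -> pd.Series:
    """Anchor date per prescription row: start date, else end date."""
    return prescriptions["start_date"].fillna(prescriptions["end_date"])


def first_antipsychotic_date(prescriptions: pd.DataFrame, codelist) -> pd.Series:
    """Earliest antipsychotic prescription date per patient.

    Rows whose drug code is not in ``codelist`` are ignored; patients with no
    antipsychotic record are absent from the result.  A row missing its start
    date is anchored at its end date; rows with neither date cannot anchor a
    first prescription and are skipped.
    """
    mask = prescriptions["drug_code"].isin(set(codelist))
    sub = prescriptions.loc[mask]
    anchor = rx_anchor_dates(sub).dropna()
    if anchor.empty:
        return pd.Series(dtype="datetime64[ns]", name="first_rx")
    out = anchor.groupby(sub.loc[anchor.index, "patient_id"]).min()
    out.name = "first_rx"
    return out


def first_lung_cancer_date(diagnoses: pd.DataFrame, config: StudyConfig) -> pd.Series:
    """Earliest lung-cancer diagnosis date per patient (any 162.x code)."""
    codes = diagnoses["icd9_code"].astype(str)
    mask = codes.str.startswith(config.lung_cancer_prefix)
    sub = diagnoses.loc[mask]
    out = sub.groupby("patient_id")["diagnosis_date"].min()
    out.name = "first_lung_cancer"
    return out


def screen(
    patients: pd.DataFrame,
    prescriptions: pd.DataFrame,
    diagnoses: pd.DataFrame,
    config: StudyConfig,
):
    """Apply the exclusion cascade; return (eligible patients, attrition log).

    The eligible frame carries ``first_rx`` alongside the patient columns.
    The attrition log records, in application order, how many patients were
    removed at each rule (each patient counted once, at the first rule that
    removes it).
    """
    first_rx = first_antipsychotic_date(prescriptions, config.antipsychotic_codes)
    in_window = first_rx[(first_rx >= config.enrolment_start) & (first_rx <= config.enrolment_end)]
    df = patients.merge(in_window.rename("first_rx"), left_on="patient_id", right_index=True, how="left")

    first_ca = first_lung_cancer_date(diagnoses, config)
    df = df.merge(first_ca.rename("first_ca"), left_on="patient_id", right_index=True, how="left")

    fails = {
        "no_antipsychotic_in_enrolment_window": df["first_rx"].isna(),
        "rule1_missing_demographics": df["sex"].isna() | df["birth_date"].isna(),
        "rule2_death_before_first_rx": df["death_date"].notna() & (df["death_date"] < df["first_rx"]),
        "rule3_lung_cancer_on_or_before_first_rx": df["first_ca"].notna() & (df["first_ca"] <= df["first_rx"]),
        "rule4_lung_cancer_before_outcome_window": df["first_ca"].notna() & (df["first_ca"] < config.outcome_start),
    }
    removed = np.zeros(len(df), dtype=bool)
    rows = []
    for rule in ATTRITION_RULES:
        hit = fails[rule].to_numpy() & ~removed
        rows.append({"rule": rule, "n_removed": int(hit.sum())})
        removed |= hit
    eligible = df.loc[~removed].drop(columns=["first_ca"]).reset_index(drop=True)
    attrition = pd.DataFrame(rows)
    attrition.loc[len(attrition)] = {"rule": "eligible", "n_removed": int(len(eligible))}
    return eligible, attrition


def completed_age(index_date, birth_date) -> np.ndarray:
    """Age in completed years at ``index_date`` (vectorized)."""
    idx = pd.DatetimeIndex(np.atleast_1d(np.asarray(index_date, dtype="datetime64[ns]")))
    brt = pd.DatetimeIndex(np.atleast_1d(np.asarray(birth_date, dtype="datetime64[ns]")))
    before_birthday = (idx.month * 100 + idx.day) < (brt.month * 100 + brt.day)
    return (idx.year - brt.year - before_birthday).to_numpy()


def identify_cases(
    eligible: pd.DataFrame, diagnoses: pd.DataFrame, config: StudyConfig
) -> pd.DataFrame:
    """Incident lung-cancer cases among the screened patients.

    One row per eligible patient whose first lung-cancer diagnosis falls in
    the outcome window at completed age >= the adult threshold.  Columns:
    patient_id, index_date, age_at_index, sex, subtype_code.  Same-day
    diagnosis ties resolve to the lowest code.
    """
    codes = diagnoses["icd9_code"].astype(str)
    ca = diagnoses.loc[codes.str.startswith(config.lung_cancer_prefix)].copy()
    ca["icd9_code"] = ca["icd9_code"].astype(str)
    ca = ca.sort_values(["patient_id", "diagnosis_date", "icd9_code"], kind="stable")
    first = ca.drop_duplicates("patient_id", keep="first")

    cases = eligible.merge(
        first.rename(columns={"diagnosis_date": "index_date", "icd9_code": "subtype_code"}),
        on="patient_id",
        how="inner",
    )
    cases = cases[
        (cases["index_date"] >= config.outcome_start) & (cases["index_date"] <= config.outcome_end)
    ].copy()
    if cases.empty:
        return pd.DataFrame(columns=["patient_id", "index_date", "age_at_index", "sex", "subtype_code"])
    cases["age_at_index"] = completed_age(cases["index_date"].values, cases["birth_date"].values)
    cases = cases[cases["age_at_index"] >= config.adult_age]
    return (
        cases[["patient_id", "index_date", "age_at_index", "sex", "subtype_code"]]
        .sort_values(["index_date", "patient_id"], kind="stable")
        .reset_index(drop=True)
    )
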