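"""Confounder ascertainment over the fixed lookback window.

Each of the 21 binary flags (4 co-medications, 17 diagnoses) is set when at
least one matching record falls between the covariate window start
(2001-01-01, the earliest date with usable clinical information) and the
member's index date, both ends inclusive by default.  Drug flags match
prescription drug codes exactly; diagnosis flags match normalized ICD-9
codes by prefix.  Codelists are configuration, not hard-coded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import COVARIATE_NAMES, StudyConfig


def _normalize_codes(codes: pd.Series) -> pd.Series:
    return codes.astype(str).str.strip()


def _flag_record_dates(flag: str, spec: dict, prescriptions: pd.DataFrame, diagnoses: pd.DataFrame):
    """(patient_id, date) pairs of records matching one flag's codelist."""
    if "drug_codes" in spec:
        sub = prescriptions[prescriptions["drug_code"].isin(set(spec["drug_codes"]))]
        from .cohort import rx_anchor_dates

        return sub["patient_id"], rx_anchor_dates(sub)
    if "icd9_prefixes" in spec:
        codes = _normalize_codes(diagnoses["icd9_code"])
        mask = np.zeros(len(diagnoses), dtype=bool)
        for prefix in spec["icd9_prefixes"]:
            mask |= codes.str.startswith(prefix).to_numpy()
        sub = diagnoses.loc[mask]
        return sub["patient_id"], sub["diagnosis_date"]
    raise ValueError(f"codelist for {flag!r} must define drug_codes or icd9_prefixes")


def ascertain(
    patient_id,
    index_date,
    prescriptions: pd.DataFrame,
    diagnoses: pd.DataFrame,
    config: StudyConfig,
) -> dict[str, int]:
    """Covariate vector for one (patient, index date), as an ordered dict."""
    members = pd.DataFrame({"set_id": [0], "patient_id": [patient_id], "index_date": [pd.Timestamp(index_date)]})
    out = compute_covariates(members, prescriptions, diagnoses, config)
    return {name: int(out.iloc[0][name]) for name in COVARIATE_NAMES}


def compute_covariates(
    members: pd.DataFrame,
    prescriptions: pd.DataFrame,
    diagnoses: pd.DataFrame,
    config: StudyConfig,
) -> pd.DataFrame:
    """Covariate flags for every matched-set member.

    ``members`` needs set_id, patient_id, index_date.  Returns those keys
    plus the 21 flag columns in the documented order.
    """
    lists = config.covariate_codelists
    unknown = set(lists) - set(COVARIATE_NAMES)
    if unknown:
        raise ValueError(f"unknown covariate flags: {sorted(unknown)}")
    out = members[["set_id", "patient_id", "index_date"]].copy()
    idx_dates = pd.DatetimeIndex(out["index_date"])
    start = config.covariate_start
    for flag in COVARIATE_NAMES:
        pids, dates = _flag_record_dates(flag, lists[flag], prescriptions, diagnoses)
        ok = dates.notna() & (dates >= start)
        earliest = dates[ok].groupby(pids[ok]).min()
        mapped = pd.DatetimeIndex(out["patient_id"].map(earliest))
        if config.covariate_window_inclusive:
            hit = mapped <= idx_dates
        else:
            hit = mapped < idx_dates
        out[flag] = np.where(mapped.isna(), 0, hit.astype(int))
    return out
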