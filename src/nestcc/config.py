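"""Study configuration: windows, cut-points, codelists, matching policy.

All analysis choices that the study design fixes (ascertainment windows,
exposure category cut-points, matching ratio, control reuse cap) live here,
together with the drug and diagnosis codelists that drive cohort entry,
exposure and confounder ascertainment.  The shipped codelists are editable
placeholders that match the synthetic generator's vocabulary; they are not
an authoritative transcription of any clinical coding dictionary.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd
import yaml

# Fixed, documented ordering of the 21 confounder flags:
# 4 co-medications followed by 17 diagnoses.
COVARIATE_NAMES: tuple[str, ...] = (
    "nsaids",
    "statins",
    "aspirin",
    "metformin",
    "tobacco_use",
    "diabetes",
    "copd",
    "hypertension",
    "hyperlipidemia",
    "cirrhosis",
    "ckd",
    "peptic_ulcer",
    "pneumonia",
    "schizophrenia",
    "depressive_disorders",
    "anxiety_disorders",
    "bipolar_disorders",
    "personality_disorders",
    "delusional_disorders",
    "other_nonorganic_psychoses",
    "dementia",
)

# Lung-cancer outcome: ICD-9-CM 162.x, with the seven subtype codes used for
# the leave-one-out secondary analysis (162.1 is not a valid ICD-9-CM code).
LUNG_CANCER_PREFIX = "162"
LUNG_CANCER_SUBTYPES: tuple[str, ...] = (
    "162.0",
    "162.2",
    "162.3",
    "162.4",
    "162.5",
    "162.8",
    "162.9",
)

ANTIPSYCHOTIC_CODES: tuple[str, ...] = (
    "FLUPENTIXOL",
    "HALOPERIDOL",
    "RISPERIDONE",
    "OLANZAPINE",
    "QUETIAPINE",
    "CHLORPROMAZINE",
    "ARIPIPRAZOLE",
    "AMISULPRIDE",
    "SULPIRIDE",
    "CLOZAPINE",
    "TRIFLUOPERAZINE",
    "PIMOZIDE",
    "LURASIDONE",
    "BREXPIPRAZOLE",
)

# Ten agents with previously reported lung-cancer risk reduction, removed in
# the first sensitivity analysis.
SENSITIVITY_EXCLUDE_DRUGS: tuple[str, ...] = (
    "RISPERIDONE",
    "PIMOZIDE",
    "ARIPIPRAZOLE",
    "OLANZAPINE",
    "LURASIDONE",
    "BREXPIPRAZOLE",
    "TRIFLUOPERAZINE",
    "CLOZAPINE",
    "CHLORPROMAZINE",
    "HALOPERIDOL",
)

NSAID_CODES = (
    "IBUPROFEN",
    "DICLOFENAC",
    "INDOMETHACIN",
    "KETOPROFEN",
    "KETOROLAC",
    "MEFENAMIC ACID",
    "NAPROXEN",
    "PIROXICAM",
    "CELECOXIB",
    "ETORICOXIB",
)
STATIN_CODES = (
    "ATORVASTATIN",
    "FLUVASTATIN",
    "LOVASTATIN",
    "ROSUVASTATIN",
    "PRAVASTATIN",
    "SIMVASTATIN",
)


def default_covariate_codelists() -> dict[str, dict[str, list[str]]]:
    """Editable placeholder codelists keyed by confounder flag.

    Each entry maps to ``drug_codes`` (exact match on prescription drug code)
    or ``icd9_prefixes`` (prefix match on the normalized diagnosis code).
    """
    return {
        "nsaids": {"drug_codes": list(NSAID_CODES)},
        "statins": {"drug_codes": list(STATIN_CODES)},
        "aspirin": {"drug_codes": ["ASPIRIN"]},
        "metformin": {"drug_codes": ["METFORMIN"]},
        "tobacco_use": {"icd9_prefixes": ["305.1"]},
        "diabetes": {"icd9_prefixes": ["250"]},
        "copd": {"icd9_prefixes": ["490", "491", "492", "494", "496"]},
        "hypertension": {"icd9_prefixes": ["401", "402", "403", "404", "405"]},
        "hyperlipidemia": {"icd9_prefixes": ["272"]},
        "cirrhosis": {"icd9_prefixes": ["571"]},
        "ckd": {"icd9_prefixes": ["585"]},
        "peptic_ulcer": {"icd9_prefixes": ["531", "532", "533", "534"]},
        "pneumonia": {"icd9_prefixes": ["480", "481", "482", "483", "485", "486"]},
        "schizophrenia": {"icd9_prefixes": ["295"]},
        "depressive_disorders": {"icd9_prefixes": ["296.2", "296.3", "300.4", "311"]},
        "anxiety_disorders": {"icd9_prefixes": ["300.0"]},
        "bipolar_disorders": {"icd9_prefixes": ["296.0", "296.1", "296.4", "296.5", "296.6", "296.7", "296.8"]},
        "personality_disorders": {"icd9_prefixes": ["301"]},
        "delusional_disorders": {"icd9_prefixes": ["297"]},
        "other_nonorganic_psychoses": {"icd9_prefixes": ["298"]},
        "dementia": {"icd9_prefixes": ["290"]},
    }


@dataclass
class StudyConfig:
    """Design parameters of the nested case-control analysis.

    Dates are ISO-8601 strings for YAML friendliness; accessors return
    ``pandas.Timestamp``.
    """

    outcome_window: tuple[str, str] = ("2003-01-01", "2022-08-31")
    screening_period: tuple[str, str] = ("2001-01-01", "2002-12-31")
    enrolment_window: tuple[str, str] = ("2001-01-01", "2022-08-31")
    covariate_window_start: str = "2001-01-01"
    lung_cancer_prefix: str = LUNG_CANCER_PREFIX
    antipsychotic_codes: tuple[str, ...] = ANTIPSYCHOTIC_CODES
    flupentixol_codes: tuple[str, ...] = ("FLUPENTIXOL",)
    adult_age: int = 18
    exposure_cutpoints: tuple[int, int] = (365, 1825)
    matching_ratio: int = 10
    control_reuse_cap: Optional[int] = 4  # None => unlimited reuse
    flupentixol_sum_mode: str = "union"  # or "raw_sum"
    covariate_window_inclusive: bool = True
    sensitivity_exclude_drugs: tuple[str, ...] = SENSITIVITY_EXCLUDE_DRUGS
    covariate_codelists: dict = field(default_factory=default_covariate_codelists)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.exposure_cutpoints
        if not lo < hi:
            raise ValueError("exposure cut-points must be strictly increasing")
        for name, win in (
            ("outcome_window", self.outcome_window),
            ("screening_period", self.screening_period),
            ("enrolment_window", self.enrolment_window),
        ):
            if pd.Timestamp(win[0]) > pd.Timestamp(win[1]):
                raise ValueError(f"{name} is not well-ordered: {win}")
        if self.control_reuse_cap is not None and self.control_reuse_cap < 1:
            raise ValueError("control_reuse_cap must be >= 1 or None")
        if self.flupentixol_sum_mode not in ("union", "raw_sum"):
            raise ValueError("flupentixol_sum_mode must be 'union' or 'raw_sum'")
        unknown = set(self.covariate_codelists) - set(COVARIATE_NAMES)
        if unknown:
            raise ValueError(f"unknown covariate flags in codelists: {sorted(unknown)}")
        missing = set(COVARIATE_NAMES) - set(self.covariate_codelists)
        if missing:
            raise ValueError(f"codelists missing covariate flags: {sorted(missing)}")

    # -- window accessors -------------------------------------------------
    @property
    def outcome_start(self) -> pd.Timestamp:
        return pd.Timestamp(self.outcome_window[0])

    @property
    def outcome_end(self) -> pd.Timestamp:
        return pd.Timestamp(self.outcome_window[1])

    @property
    def enrolment_start(self) -> pd.Timestamp:
        return pd.Timestamp(self.enrolment_window[0])

    @property
    def enrolment_end(self) -> pd.Timestamp:
        return pd.Timestamp(self.enrolment_window[1])

    @property
    def covariate_start(self) -> pd.Timestamp:
        return pd.Timestamp(self.covariate_window_start)

    # -- serialization ----------------------------------------------------
    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["antipsychotic_codes"] = list(self.antipsychotic_codes)
        d["flupentixol_codes"] = list(self.flupentixol_codes)
        d["sensitivity_exclude_drugs"] = list(self.sensitivity_exclude_drugs)
        d["outcome_window"] = list(self.outcome_window)
        d["screening_period"] = list(self.screening_period)
        d["enrolment_window"] = list(self.enrolment_window)
        d["exposure_cutpoints"] = list(self.exposure_cutpoints)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("outcome_window", "screening_period", "enrolment_window", "exposure_cutpoints"):
            if key in d:
                d[key] = tuple(d[key])
        for key in ("antipsychotic_codes", "flupentixol_codes", "sensitivity_exclude_drugs"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)
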