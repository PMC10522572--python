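"""Synthetic electronic-health-record generator with known ground truth.

Emulates a territory-wide hospital database of antipsychotic initiators:
longitudinal prescription episodes (overlapping, gapped, with a small
completely-at-random fraction of missing end dates), binary comorbidity and
co-medication events, competing death, and an incident lung-cancer outcome
whose hazard depends on the *current* cumulative antipsychotic exposure
category through configurable log-odds effects.

The outcome is simulated as a discrete-time logistic hazard on a 30-day grid
starting at each patient's first antipsychotic prescription.  At every step
the cumulative distinct-day exposure to any antipsychotic is computed from
the generated episodes (interval union), categorized at the 365/1825-day
cut-points, and a lung-cancer event occurs with probability
``expit(baseline + b2*I[366-1825] + b3*I[1826+] + gamma'z)``; death is a
competing event with a constant per-step hazard.  Because incidence-density
sampling plus conditional logistic regression estimates a rate ratio, the
exponentiated effects are the quantities the downstream pipeline should
recover, which makes ``exp(b2)``/``exp(b3)`` the generator's ground truth.

All randomness flows from a single seeded ``numpy`` generator, and every
random array has a size that does not depend on the effect parameters, so two
runs that differ only in the effect sizes share their uniform draws (common
random numbers).  Same config + same seed => byte-identical output tables.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import COVARIATE_NAMES, LUNG_CANCER_SUBTYPES, default_covariate_codelists

STEP_DAYS = 30
_EPOCH = np.datetime64("1970-01-01")
# per-patient offset used to turn per-patient searchsorted into one global call
_PID_STRIDE = 10**6

# representative diagnosis code emitted for each flagged diagnosis covariate
_DIAGNOSIS_CODE = {
    "tobacco_use": "305.1",
    "diabetes": "250.0",
    "copd": "496",
    "hypertension": "401.9",
    "hyperlipidemia": "272.4",
    "cirrhosis": "571.5",
    "ckd": "585.9",
    "peptic_ulcer": "533.9",
    "pneumonia": "486",
    "schizophrenia": "295.9",
    "depressive_disorders": "311",
    "anxiety_disorders": "300.0",
    "bipolar_disorders": "296.4",
    "personality_disorders": "301.9",
    "delusional_disorders": "297.1",
    "other_nonorganic_psychoses": "298.9",
    "dementia": "290.0",
}
_DRUG_COVARIATE_CODES = {
    "nsaids": ("IBUPROFEN", "DICLOFENAC", "NAPROXEN", "CELECOXIB"),
    "statins": ("SIMVASTATIN", "ATORVASTATIN", "ROSUVASTATIN"),
    "aspirin": ("ASPIRIN",),
    "metformin": ("METFORMIN",),
}
_OTHER_ANTIPSYCHOTICS = (
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
)


def _default_covariate_prevalences() -> dict[str, float]:
    # plausible prevalences for an elderly antipsychotic-user cohort
    return {
        "nsaids": 0.49,
        "statins": 0.28,
        "aspirin": 0.39,
        "metformin": 0.19,
        "tobacco_use": 0.008,
        "diabetes": 0.20,
        "copd": 0.095,
        "hypertension": 0.36,
        "hyperlipidemia": 0.10,
        "cirrhosis": 0.017,
        "ckd": 0.028,
        "peptic_ulcer": 0.007,
        "pneumonia": 0.19,
        "schizophrenia": 0.20,
        "depressive_disorders": 0.13,
        "anxiety_disorders": 0.034,
        "bipolar_disorders": 0.031,
        "personality_disorders": 0.012,
        "delusional_disorders": 0.048,
        "other_nonorganic_psychoses": 0.083,
        "dementia": 0.28,
    }


def _default_covariate_log_ors() -> dict[str, float]:
    return {
        "tobacco_use": 0.4,
        "copd": 0.7,
        "pneumonia": 0.7,
        "schizophrenia": -0.6,
        "dementia": -0.5,
    }


def _default_subtype_weights() -> dict[str, float]:
    return {
        "162.0": 0.01,
        "162.2": 0.05,
        "162.3": 0.30,
        "162.4": 0.05,
        "162.5": 0.15,
        "162.8": 0.08,
        "162.9": 0.36,
    }


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    Marginal rates (episodes per patient, episode lengths, gaps) have no
    published counterpart and are free parameters chosen to produce a chronic
    antipsychotic-user cohort whose exposure distribution straddles both
    cut-points; the baseline hazard is set so that roughly 1.5% of patients
    become incident cases, matching the case fraction of the cohort the
    generator emulates (6435 cases among 445,015 antipsychotic users).
    """

    n_patients: int = 20_000
    prob_male: float = 0.48
    birth_year_range: tuple[int, int] = (1920, 1980)
    first_rx_window: tuple[str, str] = ("2001-01-01", "2022-08-31")
    episodes_per_patient_mean: float = 24.0
    episodes_per_patient_dispersion: float = 1.0
    episode_length_log_mean: float = math.log(28.0)
    episode_length_log_sd: float = 0.9
    gap_mean_days: float = 30.0
    overlap_prob: float = 0.15
    prob_flupentixol_user: float = 0.12
    prob_flupentixol_episode: float = 0.8
    missing_end_date_rate: float = 0.02
    missing_keep_dispense_fields: float = 0.5
    covariate_prevalences: dict[str, float] = field(default_factory=_default_covariate_prevalences)
    baseline_hazard_logit: float = -8.8
    true_log_or_cat2: float = math.log(0.5)
    true_log_or_cat3: float = math.log(0.6)
    covariate_log_ors: dict[str, float] = field(default_factory=_default_covariate_log_ors)
    death_hazard_per_step: float = 0.003
    prob_prevalent_lung_cancer: float = 0.004
    prob_bad_death_record: float = 0.0005
    prob_missing_demographics: float = 0.001
    subtype_weights: dict[str, float] = field(default_factory=_default_subtype_weights)
    simulation_end: str = "2022-08-31"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        probs = {
            "prob_male": self.prob_male,
            "prob_flupentixol_user": self.prob_flupentixol_user,
            "prob_flupentixol_episode": self.prob_flupentixol_episode,
            "missing_end_date_rate": self.missing_end_date_rate,
            "missing_keep_dispense_fields": self.missing_keep_dispense_fields,
            "overlap_prob": self.overlap_prob,
            "death_hazard_per_step": self.death_hazard_per_step,
            "prob_prevalent_lung_cancer": self.prob_prevalent_lung_cancer,
            "prob_bad_death_record": self.prob_bad_death_record,
            "prob_missing_demographics": self.prob_missing_demographics,
            **{f"prevalence[{k}]": v for k, v in self.covariate_prevalences.items()},
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        unknown = set(self.covariate_prevalences) - set(COVARIATE_NAMES)
        if unknown:
            raise ValueError(f"unknown covariates: {sorted(unknown)}")


@dataclass
class SyntheticTruth:
    """Ground-truth effects and realized counts of one generated cohort."""

    true_or_cat2: float
    true_or_cat3: float
    covariate_true_ors: dict[str, float]
    n_patients: int
    n_cases: int
    n_prescriptions: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def _day(date_str: str) -> int:
    return int((np.datetime64(date_str) - _EPOCH).astype(int))


def _dates_from_days(days: np.ndarray, missing: np.ndarray | None = None) -> pd.Series:
    """Epoch-day ints -> datetime64[ns] Series, with optional NaT mask."""
    out = pd.Series(days.astype("datetime64[D]").astype("datetime64[ns]"))
    if missing is not None and missing.any():
        out[missing] = pd.NaT
    return out


def _merge_intervals(pidx: np.ndarray, starts: np.ndarray, ends: np.ndarray):
    """Union adjacent/overlapping closed day intervals within each patient.

    Inputs must be sorted by (pidx, start).  Returns merged (pidx, start,
    end) plus, for each merged run, the exclusive prefix of covered days
    within its patient.
    """
    off = pidx.astype(np.int64) * _PID_STRIDE
    s = starts + off
    e = ends + off
    cummax_e = np.maximum.accumulate(e)
    prev_cummax = np.concatenate(([np.iinfo(np.int64).min], cummax_e[:-1]))
    new_run = s > prev_cummax + 1
    new_run[0] = True
    run_id = np.cumsum(new_run) - 1
    run_starts_idx = np.flatnonzero(new_run)
    m_start = s[run_starts_idx]
    m_end = np.maximum.reduceat(e, run_starts_idx)
    m_pidx = pidx[run_starts_idx]
    m_len = m_end - m_start + 1
    first_of_patient = np.empty(m_pidx.size, dtype=bool)
    first_of_patient[0] = True
    first_of_patient[1:] = m_pidx[1:] != m_pidx[:-1]
    cum = np.cumsum(m_len)
    shifted = np.concatenate(([0], cum[:-1]))
    base_idx = np.where(first_of_patient, np.arange(m_pidx.size), 0)
    base_idx = np.maximum.accumulate(base_idx)
    prefix = shifted - shifted[base_idx]
    return m_pidx, m_start - m_pidx * _PID_STRIDE, m_end - m_pidx * _PID_STRIDE, prefix


def covered_days_at(
    m_pidx: np.ndarray,
    m_start: np.ndarray,
    m_len: np.ndarray,
    m_prefix: np.ndarray,
    q_pidx: np.ndarray,
    q_day: np.ndarray,
) -> np.ndarray:
    """Distinct covered days up to and including ``q_day`` per query.

    Merged runs must be sorted by (patient, start); queries may not precede a
    patient's first run start.
    """
    key = m_start + m_pidx.astype(np.int64) * _PID_STRIDE
    q = q_day + q_pidx.astype(np.int64) * _PID_STRIDE
    j = np.searchsorted(key, q, side="right") - 1
    return m_prefix[j] + np.clip(q_day - m_start[j] + 1, 0, m_len[j])


def generate_population(config: GeneratorConfig):
    """Generate (patients, prescriptions, diagnoses, SyntheticTruth).

    Tables come back as pandas DataFrames in the on-disk schema (see
    ``write_tables``), with datetime64 date columns and NaN/NaT for missing
    values.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients

    # --- demographics ----------------------------------------------------
    male = rng.random(n) < cfg.prob_male
    y0, y1 = cfg.birth_year_range
    birth_year = rng.integers(y0, y1 + 1, n)
    birth_doy = rng.integers(0, 365, n)
    jan1 = (birth_year.astype("datetime64[Y]") - 1970).astype("datetime64[D]")
    birth_day = jan1.astype(np.int64) + birth_doy

    rx_lo, rx_hi = _day(cfg.first_rx_window[0]), _day(cfg.first_rx_window[1])
    first_rx = rng.integers(rx_lo, rx_hi + 1, n)

    # --- prescription episodes -------------------------------------------
    m = cfg.episodes_per_patient_mean
    k = cfg.episodes_per_patient_dispersion
    extra_mean = max(m - 1.0, 1e-9)
    n_eps = 1 + rng.negative_binomial(k, k / (k + extra_mean), n)
    tot = int(n_eps.sum())
    pidx = np.repeat(np.arange(n), n_eps)
    group_starts = np.concatenate(([0], np.cumsum(n_eps)[:-1]))
    first_mask = np.zeros(tot, dtype=bool)
    first_mask[group_starts] = True

    lengths = np.maximum(
        1, np.ceil(rng.lognormal(cfg.episode_length_log_mean, cfg.episode_length_log_sd, tot)).astype(np.int64)
    )
    gaps = np.floor(rng.exponential(cfg.gap_mean_days, tot)).astype(np.int64)
    overlap = rng.random(tot) < cfg.overlap_prob
    overlap_frac = rng.random(tot)

    len_prev = np.empty(tot, dtype=np.int64)
    len_prev[1:] = lengths[:-1]
    len_prev[0] = 0
    # distance from previous episode start: inside it when overlapping,
    # otherwise past its end plus an exponential gap (gap 0 => contiguous)
    delta = np.where(overlap, (overlap_frac * len_prev).astype(np.int64), len_prev + gaps)
    delta[first_mask] = 0
    cum = np.cumsum(delta)
    rel = cum - np.repeat(cum[group_starts], n_eps)
    ep_start = first_rx[pidx] + rel
    ep_end = ep_start + lengths - 1

    flup_user = rng.random(n) < cfg.prob_flupentixol_user
    is_flup = flup_user[pidx] & (rng.random(tot) < cfg.prob_flupentixol_episode)
    other_idx = rng.integers(0, len(_OTHER_ANTIPSYCHOTICS), tot)
    drug_code = np.where(is_flup, "FLUPENTIXOL", np.asarray(_OTHER_ANTIPSYCHOTICS)[other_idx])

    dosage = rng.integers(1, 4, tot).astype(float)
    freq = rng.integers(1, 4, tot).astype(float)
    quantity = dosage * freq * lengths  # consistent, so dispense-based imputation is exact

    miss_end = rng.random(tot) < cfg.missing_end_date_rate
    keep_dfq = rng.random(tot) < cfg.missing_keep_dispense_fields
    drop_dfq = miss_end & ~keep_dfq

    # --- latent covariates ------------------------------------------------
    p_cov = len(COVARIATE_NAMES)
    prev = np.array([cfg.covariate_prevalences.get(c, 0.0) for c in COVARIATE_NAMES])
    Z = rng.random((n, p_cov)) < prev
    gamma = np.array([cfg.covariate_log_ors.get(c, 0.0) for c in COVARIATE_NAMES])
    zlp = Z @ gamma

    # --- outcome simulation on the 30-day grid ----------------------------
    order = np.lexsort((ep_start, pidx))
    m_pidx, m_start, m_end, m_prefix = _merge_intervals(pidx[order], ep_start[order], ep_end[order])
    m_len = m_end - m_start + 1

    sim_end = _day(cfg.simulation_end)
    n_steps = np.maximum((sim_end - first_rx) // STEP_DAYS, 0)
    tot_steps = int(n_steps.sum())
    step_pidx = np.repeat(np.arange(n), n_steps)
    sg_starts = np.concatenate(([0], np.cumsum(n_steps)[:-1]))
    step_k = np.arange(tot_steps) - np.repeat(sg_starts, n_steps) + 1
    t = first_rx[step_pidx] + STEP_DAYS * step_k

    covered = covered_days_at(m_pidx, m_start, m_len, m_prefix, step_pidx, t)
    lo_cut, hi_cut = 365, 1825
    c2 = (covered > lo_cut) & (covered <= hi_cut)
    c3 = covered > hi_cut
    lp = (
        cfg.baseline_hazard_logit
        + cfg.true_log_or_cat2 * c2
        + cfg.true_log_or_cat3 * c3
        + zlp[step_pidx]
    )
    p_event = 1.0 / (1.0 + np.exp(-lp))
    u_cancer = rng.random(tot_steps)
    u_death = rng.random(tot_steps)
    cancer_hit = u_cancer < p_event
    death_hit = u_death < cfg.death_hazard_per_step

    big = np.iinfo(np.int64).max
    cancer_k = np.full(n, big)
    np.minimum.at(cancer_k, step_pidx[cancer_hit], step_k[cancer_hit])
    death_k = np.full(n, big)
    np.minimum.at(death_k, step_pidx[death_hit], step_k[death_hit])

    # within a step the cancer draw is evaluated before the death draw
    is_case = (cancer_k < big) & (cancer_k <= death_k)
    cancer_day = np.where(is_case, first_rx + STEP_DAYS * np.minimum(cancer_k, big // STEP_DAYS), -1)
    has_death = death_k < big
    death_day = np.where(has_death, first_rx + STEP_DAYS * np.minimum(death_k, big // STEP_DAYS), -1)

    # --- remaining draws (fixed sizes, independent of effect parameters) --
    subtypes = np.asarray(LUNG_CANCER_SUBTYPES)
    w = np.array([cfg.subtype_weights[s] for s in LUNG_CANCER_SUBTYPES], dtype=float)
    w = w / w.sum()
    subtype_all = subtypes[rng.choice(len(subtypes), size=n, p=w)]

    prev_ca = rng.random(n) < cfg.prob_prevalent_lung_cancer
    prev_hi = np.maximum(first_rx, _day("2002-12-31"))
    prev_day = _day("2001-01-01") + (rng.random(n) * (prev_hi - _day("2001-01-01") + 1)).astype(np.int64)
    prev_code = subtypes[rng.choice(len(subtypes), size=n, p=w)]

    cov_day = _day("2001-01-01") + (
        rng.random((n, p_cov)) * (_day("2022-08-31") - _day("2001-01-01") + 1)
    ).astype(np.int64)
    cov_code_pick = rng.integers(0, 1 << 30, (n, p_cov))

    bad_death = rng.random(n) < cfg.prob_bad_death_record
    bad_death_back = rng.integers(1, 365, n)
    miss_demo = rng.random(n) < cfg.prob_missing_demographics

    # --- assemble patients table ------------------------------------------
    patient_id = np.arange(1, n + 1)
    sex = np.where(male, "M", "F").astype(object)
    sex[miss_demo] = None
    death_day_final = np.where(bad_death, first_rx - bad_death_back, death_day)
    death_missing = ~(has_death | bad_death)

    patients = pd.DataFrame(
        {
            "patient_id": patient_id,
            "sex": sex,
            "birth_date": _dates_from_days(birth_day),
            "death_date": _dates_from_days(death_day_final, missing=death_missing),
        }
    )

    # --- prescriptions table ----------------------------------------------
    ap = pd.DataFrame(
        {
            "patient_id": pidx + 1,
            "drug_code": drug_code,
            "drug_class": "antipsychotic",
            "start_date": _dates_from_days(ep_start),
            "end_date": _dates_from_days(ep_end, missing=miss_end),
            "dosage": np.where(drop_dfq, np.nan, dosage),
            "frequency_per_day": np.where(drop_dfq, np.nan, freq),
            "quantity": np.where(drop_dfq, np.nan, quantity),
        }
    )

    comed_frames = []
    for ci, name in enumerate(COVARIATE_NAMES):
        codes = _DRUG_COVARIATE_CODES.get(name)
        if codes is None:
            continue
        hit = Z[:, ci]
        ids = patient_id[hit]
        days = cov_day[hit, ci]
        code = np.asarray(codes)[cov_code_pick[hit, ci] % len(codes)]
        comed_frames.append(
            pd.DataFrame(
                {
                    "patient_id": ids,
                    "drug_code": code,
                    "drug_class": name if name != "nsaids" else "nsaid",
                    "start_date": _dates_from_days(days),
                    "end_date": _dates_from_days(days + 27),
                    "dosage": 1.0,
                    "frequency_per_day": 1.0,
                    "quantity": 28.0,
                }
            )
        )
    prescriptions = pd.concat([ap] + comed_frames, ignore_index=True)
    prescriptions = prescriptions.sort_values(["patient_id", "start_date"], kind="stable").reset_index(
        drop=True
    )

    # --- diagnoses table ---------------------------------------------------
    diag_frames = []
    case_ids = patient_id[is_case]
    diag_frames.append(
        pd.DataFrame(
            {
                "patient_id": case_ids,
                "icd9_code": subtype_all[is_case],
                "diagnosis_date": _dates_from_days(cancer_day[is_case]),
            }
        )
    )
    diag_frames.append(
        pd.DataFrame(
            {
                "patient_id": patient_id[prev_ca],
                "icd9_code": prev_code[prev_ca],
                "diagnosis_date": _dates_from_days(prev_day[prev_ca]),
            }
        )
    )
    for ci, name in enumerate(COVARIATE_NAMES):
        if name in _DRUG_COVARIATE_CODES:
            continue
        hit = Z[:, ci]
        diag_frames.append(
            pd.DataFrame(
                {
                    "patient_id": patient_id[hit],
                    "icd9_code": _DIAGNOSIS_CODE[name],
                    "diagnosis_date": _dates_from_days(cov_day[hit, ci]),
                }
            )
        )
    diagnoses = pd.concat(diag_frames, ignore_index=True)
    diagnoses = diagnoses.sort_values(["patient_id", "diagnosis_date"], kind="stable").reset_index(
        drop=True
    )

    truth = SyntheticTruth(
        true_or_cat2=math.exp(cfg.true_log_or_cat2),
        true_or_cat3=math.exp(cfg.true_log_or_cat3),
        covariate_true_ors={c: math.exp(cfg.covariate_log_ors.get(c, 0.0)) for c in COVARIATE_NAMES},
        n_patients=n,
        n_cases=int(is_case.sum()),
        n_prescriptions=int(len(prescriptions)),
    )
    return patients, prescriptions, diagnoses, truth


# ---------------------------------------------------------------------------
# on-disk round trip

_DATE_COLS = {
    "patients": ["birth_date", "death_date"],
    "prescriptions": ["start_date", "end_date"],
    "diagnoses": ["diagnosis_date"],
}


def write_tables(tables, directory) -> dict[str, str]:
    """Write (patients, prescriptions, diagnoses, truth) as delimited text.

    Dates are ISO-8601; missing values are empty fields.  Returns the mapping
    table-name -> file path.
    """
    patients, prescriptions, diagnoses, truth = tables
    os.makedirs(directory, exist_ok=True)
    paths = {}
    for name, df in (("patients", patients), ("prescriptions", prescriptions), ("diagnoses", diagnoses)):
        out = df.copy()
        for col in _DATE_COLS[name]:
            out[col] = out[col].dt.strftime("%Y-%m-%d")
        path = os.path.join(directory, f"{name}.csv")
        out.to_csv(path, index=False, float_format="%.10g")
        paths[name] = path
    tpath = os.path.join(directory, "truth.json")
    truth.to_json(tpath)
    paths["truth"] = tpath
    return paths


def read_tables(directory):
    """Read tables written by :func:`write_tables` back into DataFrames."""
    frames = {}
    for name in ("patients", "prescriptions", "diagnoses"):
        df = pd.read_csv(
            os.path.join(directory, f"{name}.csv"), dtype={"icd9_code": str, "drug_code": str}
        )
        for col in _DATE_COLS[name]:
            df[col] = pd.to_datetime(df[col], format="%Y-%m-%d")
        frames[name] = df
    with open(os.path.join(directory, "truth.json")) as fh:
        truth = SyntheticTruth(**json.load(fh))
    return frames["patients"], frames["prescriptions"], frames["diagnoses"], truth
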