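"""Incidence-density (risk-set) sampling of matched controls.

For each case, up to ``ratio`` controls are sampled uniformly without
replacement from the screened patients who, at the case's index date, share
its sex and completed age in years, have at least one antipsychotic
prescription strictly before the index date, have no lung-cancer diagnosis on
or before the index date, and are alive on the index date.  A future case is
eligible as a control before its own diagnosis — the defining feature of
risk-set sampling, which lets the conditional-logistic odds ratio estimate a
rate ratio.

A reuse policy caps how many different cases one patient may serve as a
control for (default 4; ``None`` removes the cap, the configuration used by
the unlimited-reuse sensitivity analysis).  Cases are processed in ascending
index-date order (ties by patient id) because sampling under a reuse cap is
order-sensitive; the sampling primitive is a partial Fisher-Yates shuffle of
the candidate list sorted by patient id under a seeded generator, so the
output is a deterministic function of (inputs, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import completed_age
from .config import StudyConfig

_NO_DEATH = np.iinfo(np.int64).max
_NO_CA = np.iinfo(np.int64).max


@dataclass
class ReusePolicy:
    """Cap on the number of distinct cases one control may serve."""

    max_uses_per_patient: Optional[int] = 4  # None => unlimited

    def __post_init__(self) -> None:
        if self.max_uses_per_patient is not None and self.max_uses_per_patient < 1:
            raise ValueError("max_uses_per_patient must be >= 1 or None")


class _Pool:
    """Columnar view of the screened patients for fast per-case predicates."""

    def __init__(self, pool: pd.DataFrame, first_ca: pd.Series):
        pool = pool.sort_values("patient_id", kind="stable")
        self.ids = pool["patient_id"].to_numpy()
        self.sex = pool["sex"].to_numpy()
        birth = pd.DatetimeIndex(pool["birth_date"])
        self.birth_year = birth.year.to_numpy()
        self.birth_md = (birth.month * 100 + birth.day).to_numpy()
        death = pd.DatetimeIndex(pool["death_date"])
        self.death_day = death.asi8 // 86_400_000_000_000
        self.death_day[death.isna()] = _NO_DEATH
        rx = pd.DatetimeIndex(pool["first_rx"])
        self.first_rx_day = rx.asi8 // 86_400_000_000_000
        ca = first_ca.reindex(pool["patient_id"])
        ca_idx = pd.DatetimeIndex(ca)
        self.first_ca_day = ca_idx.asi8 // 86_400_000_000_000
        self.first_ca_day[ca_idx.isna()] = _NO_CA
        self.by_sex = {s: np.flatnonzero(self.sex == s) for s in ("M", "F")}

    def candidates(self, case_id, case_sex, case_age, index_date) -> np.ndarray:
        """Positions (into the sorted pool) of eligible control candidates."""
        sub = self.by_sex.get(case_sex, np.empty(0, dtype=int))
        ts = pd.Timestamp(index_date)
        day = ts.value // 86_400_000_000_000
        md = ts.month * 100 + ts.day
        age = ts.year - self.birth_year[sub] - (self.birth_md[sub] > md)
        ok = (
            (age == case_age)
            & (self.first_rx_day[sub] < day)
            & (self.first_ca_day[sub] > day)
            & (self.death_day[sub] > day)
            & (self.ids[sub] != case_id)
        )
        return sub[ok]


def eligible_controls(
    case, pool: pd.DataFrame, first_ca: pd.Series
) -> np.ndarray:
    """Patient ids eligible as controls for one case (no reuse accounting).

    ``case`` is a mapping/row with patient_id, sex, age_at_index, index_date;
    ``pool`` is the screened patient frame (with ``first_rx``); ``first_ca``
    maps patient id to first lung-cancer diagnosis date.
    """
    p = _Pool(pool, first_ca)
    pos = p.candidates(case["patient_id"], case["sex"], case["age_at_index"], case["index_date"])
    return p.ids[pos]


def _partial_fisher_yates(items: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    arr = items.copy()
    n = arr.size
    for i in range(min(k, n)):
        j = i + int(rng.integers(0, n - i))
        arr[i], arr[j] = arr[j], arr[i]
    return arr[:k]


def match_all(
    cases: pd.DataFrame,
    pool: pd.DataFrame,
    first_ca: pd.Series,
    ratio: int = 10,
    policy: ReusePolicy = ReusePolicy(),
    seed: int = 0,
):
    """Sample matched sets for every case; return (long frame, log).

    The long frame has one row per set member: set_id, role {case, control},
    patient_id, index_date, sex, age, subtype_code (case's subtype, repeated
    on controls for convenient set-level filtering).  Sets with zero eligible
    controls are dropped and logged; the conditional likelihood is undefined
    for a singleton set.
    """
    if cases["patient_id"].duplicated().any():
        raise ValueError("duplicate case patient ids")
    cases = cases.sort_values(["index_date", "patient_id"], kind="stable").reset_index(drop=True)
    p = _Pool(pool, first_ca)
    cap = policy.max_uses_per_patient
    use_count = np.zeros(p.ids.size, dtype=np.int64)
    rng = np.random.default_rng(seed)

    rows = []
    dropped = []
    candidate_counts = []
    set_id = 0
    for case in cases.itertuples(index=False):
        pos = p.candidates(case.patient_id, case.sex, case.age_at_index, case.index_date)
        if cap is not None:
            pos = pos[use_count[pos] < cap]
        candidate_counts.append(pos.size)
        if pos.size == 0:
            dropped.append(case.patient_id)
            continue
        k = min(ratio, pos.size)
        chosen = _partial_fisher_yates(pos, k, rng)
        use_count[chosen] += 1
        set_id += 1
        rows.append(
            (set_id, "case", case.patient_id, case.index_date, case.sex, case.age_at_index, case.subtype_code)
        )
        for c in np.sort(p.ids[chosen]):
            rows.append((set_id, "control", c, case.index_date, case.sex, case.age_at_index, case.subtype_code))

    matched = pd.DataFrame(
        rows,
        columns=["set_id", "role", "patient_id", "index_date", "sex", "age", "subtype_code"],
    )
    log = {
        "n_cases_in": int(len(cases)),
        "n_sets": int(set_id),
        "n_cases_dropped_no_controls": int(len(dropped)),
        "dropped_case_ids": [int(x) for x in dropped],
        "n_controls_total": int((matched["role"] == "control").sum()) if len(matched) else 0,
        "mean_candidates_per_case": float(np.mean(candidate_counts)) if candidate_counts else 0.0,
        "n_reuse_saturated": int((use_count >= cap).sum()) if cap is not None else 0,
    }
    return matched, log


def matching_policy_from_config(config: StudyConfig) -> ReusePolicy:
    return ReusePolicy(max_uses_per_patient=config.control_reuse_cap)
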