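"""Cumulative drug-exposure computation before an index date.

Exposure is counted in distinct calendar days covered by at least one
qualifying prescription interval strictly before the index date (closed
intervals; a same-day prescription contributes one day).  Days covered by
several overlapping prescriptions — across drugs or within one drug — are
counted once; the raw-sum alternative for the per-drug totals is available
behind a configuration switch.

Prescription durations are resolved through a three-level hierarchy:

1. both start and end dates present — use them as-is;
2. one date missing but dosage, frequency and quantity all present —
   duration = ceil(quantity / (dosage * frequency_per_day)) days, anchored
   at the known date;
3. otherwise — the median duration of the drug's complete records (global
   median as fallback), anchored at the known date.

Records with neither date carry no anchor and are dropped with a warning.
Cumulative totals are categorized at the 365 / 1825-day cut-points:
1-365 (reference) / 366-1825 / 1826+ days for any antipsychotic, and
0-365 (reference) / 366-1825 / 1826+ for per-drug-group totals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import StudyConfig

logger = logging.getLogger(__name__)

_NS_PER_DAY = 86_400_000_000_000


@dataclass
class ExposureSummary:
    patient_id: int
    index_date: pd.Timestamp
    days_any: int
    days_flupentixol: int
    days_other_antipsychotics: int
    cat_any: str
    cat_flupentixol: str
    cat_other: str


class DurationImputer:
    """Median prescription duration per drug, from complete records only."""

    def __init__(self, per_drug: dict[str, float], global_median: float):
        self.per_drug = per_drug
        self.global_median = global_median

    @classmethod
    def fit(cls, prescriptions: pd.DataFrame) -> "DurationImputer":
        both = prescriptions.dropna(subset=["start_date", "end_date"])
        if both.empty:
            raise ValueError("no complete prescription records to fit duration medians")
        dur = (both["end_date"] - both["start_date"]).dt.days + 1
        per_drug = dur.groupby(both["drug_code"]).median().to_dict()
        return cls(per_drug, float(dur.median()))

    def duration_for(self, drug_code: str) -> int:
        return int(math.ceil(self.per_drug.get(drug_code, self.global_median)))


def resolve_duration(record, imputer: DurationImputer) -> tuple[int, int]:
    """Resolve one prescription to a closed day interval (ints, epoch days).

    ``record`` is a mapping with start_date/end_date (Timestamp or NaT),
    dosage, frequency_per_day, quantity and drug_code.  Raises ValueError if
    neither date is present.
    """
    start, end = record["start_date"], record["end_date"]
    has_start, has_end = pd.notna(start), pd.notna(end)
    if not has_start and not has_end:
        raise ValueError("prescription has neither start nor end date")
    if has_start and has_end:
        return pd.Timestamp(start).value // _NS_PER_DAY, pd.Timestamp(end).value // _NS_PER_DAY

    dos, frq, qty = record.get("dosage"), record.get("frequency_per_day"), record.get("quantity")
    duration = None
    if pd.notna(dos) and pd.notna(frq) and pd.notna(qty):
        daily = float(dos) * float(frq)
        if daily > 0:
            duration = int(math.ceil(float(qty) / daily))
    if duration is None or duration < 1:
        duration = imputer.duration_for(record["drug_code"])
    if has_start:
        s = pd.Timestamp(start).value // _NS_PER_DAY
        return s, s + duration - 1
    e = pd.Timestamp(end).value // _NS_PER_DAY
    return e - duration + 1, e


def resolve_table(prescriptions: pd.DataFrame, imputer: DurationImputer) -> pd.DataFrame:
    """Vectorized duration resolution for a prescription table.

    Returns a frame with patient_id, drug_code, start_day, end_day (epoch
    days, closed interval).  Rows with neither date are dropped and counted
    in the log.
    """
    df = prescriptions
    start = pd.DatetimeIndex(df["start_date"]).asi8 // _NS_PER_DAY
    end = pd.DatetimeIndex(df["end_date"]).asi8 // _NS_PER_DAY
    has_start = df["start_date"].notna().to_numpy()
    has_end = df["end_date"].notna().to_numpy()
    anchored = has_start | has_end
    n_dropped = int((~anchored).sum())
    if n_dropped:
        logger.warning("%d prescriptions with neither date dropped", n_dropped)

    dos = pd.to_numeric(df["dosage"], errors="coerce").to_numpy(dtype=float)
    frq = pd.to_numeric(df["frequency_per_day"], errors="coerce").to_numpy(dtype=float)
    qty = pd.to_numeric(df["quantity"], errors="coerce").to_numpy(dtype=float)
    daily = dos * frq
    with np.errstate(invalid="ignore", divide="ignore"):
        disp_dur = np.ceil(qty / daily)
    disp_ok = np.isfinite(disp_dur) & (disp_dur >= 1)

    med = df["drug_code"].map(imputer.per_drug).fillna(imputer.global_median)
    med_dur = np.ceil(med.to_numpy(dtype=float))
    duration = np.where(disp_ok, disp_dur, med_dur).astype(np.int64)

    s = np.where(has_start, start, end - duration + 1)
    e = np.where(has_end, end, start + duration - 1)
    complete = has_start & has_end
    s = np.where(complete, start, s)
    e = np.where(complete, end, e)

    out = pd.DataFrame(
        {
            "patient_id": df["patient_id"].to_numpy(),
            "drug_code": df["drug_code"].to_numpy(),
            "start_day": s,
            "end_day": e,
        }
    )
    return out.loc[anchored].reset_index(drop=True)


def _truncate(starts: np.ndarray, ends: np.ndarray, cutoff_day: int):
    """Clip closed intervals to end strictly before the index date."""
    keep = starts <= cutoff_day
    return starts[keep], np.minimum(ends[keep], cutoff_day)


def union_days(starts: np.ndarray, ends: np.ndarray) -> int:
    """Distinct days covered by >=1 closed interval (sort-and-sweep).

    Sorts by start, tracks the running maximum end, and sums the lengths of
    the maximal disjoint runs.
    """
    if starts.size == 0:
        return 0
    order = np.argsort(starts, kind="stable")
    s = starts[order]
    cummax_e = np.maximum.accumulate(ends[order])
    # a new run begins where the next interval starts past everything seen
    run_first = np.empty(s.size, dtype=bool)
    run_first[0] = True
    run_first[1:] = s[1:] > cummax_e[:-1]
    run_starts = np.flatnonzero(run_first)
    run_last = np.append(run_starts[1:] - 1, s.size - 1)
    return int(np.sum(cummax_e[run_last] - s[run_starts] + 1))


def cumulative_union_days(intervals, index_date) -> int:
    """Distinct covered days before ``index_date`` (exclusive).

    ``intervals`` is an iterable of (start, end) pairs, as Timestamps/strings
    or epoch-day ints; every interval is truncated at index_date - 1 day.
    """
    cutoff = _as_day(index_date) - 1
    arr = np.array([(_as_day(s), _as_day(e)) for s, e in intervals], dtype=np.int64).reshape(-1, 2)
    s, e = _truncate(arr[:, 0], arr[:, 1], cutoff)
    return union_days(s, e)


def cumulative_drug_days(intervals, index_date, mode: str = "union") -> int:
    """Per-drug-group cumulative days before the index date.

    ``mode='union'`` counts overlapping same-group prescriptions once;
    ``mode='raw_sum'`` adds up the truncated interval lengths (a literal
    sum-of-periods reading, which can double-count overlap days).
    """
    if mode == "union":
        return cumulative_union_days(intervals, index_date)
    if mode != "raw_sum":
        raise ValueError("mode must be 'union' or 'raw_sum'")
    cutoff = _as_day(index_date) - 1
    arr = np.array([(_as_day(s), _as_day(e)) for s, e in intervals], dtype=np.int64).reshape(-1, 2)
    s, e = _truncate(arr[:, 0], arr[:, 1], cutoff)
    return int(np.sum(e - s + 1)) if s.size else 0


def _as_day(x) -> int:
    if isinstance(x, (int, np.integer)):
        return int(x)
    return pd.Timestamp(x).value // _NS_PER_DAY


def categorize(days: int, cutpoints: tuple[int, int], zero_based_ref: bool) -> str:
    lo, hi = cutpoints
    if days <= lo:
        return f"0-{lo}" if zero_based_ref else f"1-{lo}"
    if days <= hi:
        return f"{lo + 1}-{hi}"
    return f"{hi + 1}+"


def summarize_exposure(
    patient_id,
    index_date,
    prescriptions: pd.DataFrame,
    imputer: DurationImputer,
    config: StudyConfig,
) -> ExposureSummary:
    """Exposure days and categories for one (patient, index date)."""
    sub = prescriptions[
        (prescriptions["patient_id"] == patient_id)
        & prescriptions["drug_code"].isin(set(config.antipsychotic_codes))
    ]
    resolved = resolve_table(sub, imputer)
    is_flup = resolved["drug_code"].isin(set(config.flupentixol_codes)).to_numpy()
    s = resolved["start_day"].to_numpy()
    e = resolved["end_day"].to_numpy()
    return _summarize_arrays(patient_id, pd.Timestamp(index_date), s, e, is_flup, config)


def _summarize_arrays(patient_id, index_date, s, e, is_flup, config: StudyConfig) -> ExposureSummary:
    cutoff = _as_day(index_date) - 1
    ts, te = _truncate(s, e, cutoff)
    tf = _truncate(s[is_flup], e[is_flup], cutoff)
    to = _truncate(s[~is_flup], e[~is_flup], cutoff)
    days_any = union_days(ts, te)
    if days_any == 0:
        raise ValueError(
            f"patient {patient_id} has zero antipsychotic exposure days before {index_date!s}; "
            "set members must have at least one day of exposure"
        )
    if config.flupentixol_sum_mode == "union":
        days_f = union_days(*tf)
        days_o = union_days(*to)
    else:
        days_f = int(np.sum(tf[1] - tf[0] + 1)) if tf[0].size else 0
        days_o = int(np.sum(to[1] - to[0] + 1)) if to[0].size else 0
    cut = config.exposure_cutpoints
    return ExposureSummary(
        patient_id=patient_id,
        index_date=index_date,
        days_any=days_any,
        days_flupentixol=days_f,
        days_other_antipsychotics=days_o,
        cat_any=categorize(days_any, cut, zero_based_ref=False),
        cat_flupentixol=categorize(days_f, cut, zero_based_ref=True),
        cat_other=categorize(days_o, cut, zero_based_ref=True),
    )


def compute_exposures(
    members: pd.DataFrame,
    prescriptions: pd.DataFrame,
    imputer: DurationImputer,
    config: StudyConfig,
) -> pd.DataFrame:
    """ExposureSummary rows for every matched-set member.

    ``members`` is the long matched-set frame (set_id, role, patient_id,
    index_date).  Returns one row per member with days and categories.
    """
    ap = prescriptions[prescriptions["drug_code"].isin(set(config.antipsychotic_codes))]
    resolved = resolve_table(ap, imputer)
    resolved = resolved.sort_values("patient_id", kind="stable")
    pids = resolved["patient_id"].to_numpy()
    s_all = resolved["start_day"].to_numpy()
    e_all = resolved["end_day"].to_numpy()
    flup_all = resolved["drug_code"].isin(set(config.flupentixol_codes)).to_numpy()

    rows = []
    for member in members.itertuples(index=False):
        lo = np.searchsorted(pids, member.patient_id, side="left")
        hi = np.searchsorted(pids, member.patient_id, side="right")
        summ = _summarize_arrays(
            member.patient_id,
            pd.Timestamp(member.index_date),
            s_all[lo:hi],
            e_all[lo:hi],
            flup_all[lo:hi],
            config,
        )
        rows.append(
            (
                member.set_id,
                member.patient_id,
                member.role,
                summ.days_any,
                summ.days_flupentixol,
                summ.days_other_antipsychotics,
                summ.cat_any,
                summ.cat_flupentixol,
                summ.cat_other,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "set_id",
            "patient_id",
            "role",
            "days_any",
            "days_flupentixol",
            "days_other",
            "cat_any",
            "cat_flupentixol",
            "cat_other",
        ],
    )
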