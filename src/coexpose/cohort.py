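"""New-user cohort assembly, censoring, stage attribution and summary tables.

The cohort design is a new-user design: a patient enters at the index date,
their first qualifying redemption inside the enrollment window preceded by a
washout window free of study-drug redemptions. Follow-up runs a fixed number
of days from the index date and is split into an early stage (internal days
``0 .. early_end-1``, printed as days 1-180) and a late stage
(``early_end .. followup-1``, printed as days 181-730). A combination is
*incident* in the stage containing its first co-exposed day; its per-stage
duration is the day count clipped to the stage window. All published counts
honour small-cell suppression: counts below ``min_cell_size`` are masked.
"""
from __future__ import annotations

import dataclasses
import logging
from datetime import date
from typing import Iterable, Mapping, Sequence, TypeVar

import numpy as np
import pandas as pd

from .model import CensoringRecord, CoExposurePeriod, PrescriptionRecord, StudyConfig

log = logging.getLogger(__name__)

_I = TypeVar("_I")  # any frozen dataclass with start_day / end_day fields


def add_years(when: date, years: int) -> date:
    """Calendar-year shift, clamping Feb 29 to Feb 28."""
    try:
        return when.replace(year=when.year + years)
    except ValueError:
        return when.replace(year=when.year + years, day=28)


def identify_new_users(
    records: Sequence[PrescriptionRecord],
    config: StudyConfig,
    birthdates: Mapping[str, date] | None = None,
) -> dict[str, date]:
    """Per-patient index dates under the washout-based new-user definition.

    A patient's index date is their first redemption inside the enrollment
    window whose ATC matches a study-drug prefix and whose nearest preceding
    redemption (of any register drug) is at least ``washout_days`` earlier.
    Patients with no such redemption are excluded. When birthdates are given,
    patients must reach the age threshold for at least one day during the
    study window.
    """
    enroll_lo, enroll_hi = config.enrollment_window
    if (enroll_lo - config.study_window[0]).days < config.washout_days:
        raise ValueError(
            "register window too short: need at least washout_days of data "
            "before the enrollment window start"
        )
    by_patient: dict[str, list[PrescriptionRecord]] = {}
    for rec in sorted(records):
        by_patient.setdefault(rec.patient_id, []).append(rec)

    index_dates: dict[str, date] = {}
    for patient, recs in by_patient.items():
        if birthdates is not None and patient in birthdates:
            # age threshold reached for >= 1 day inside the study window
            if add_years(birthdates[patient], config.age_threshold_years) > config.study_window[1]:
                continue
        prev_date: date | None = None
        for rec in recs:
            eligible = (
                enroll_lo <= rec.redemption_date <= enroll_hi
                and any(rec.atc_code.startswith(p) for p in config.index_atc_prefixes)
                and (
                    prev_date is None
                    or (rec.redemption_date - prev_date).days >= config.washout_days
                )
            )
            if eligible:
                index_dates[patient] = rec.redemption_date
                break
            prev_date = rec.redemption_date
    log.info("new-user cohort: %d of %d patients indexed", len(index_dates), len(by_patient))
    return index_dates


def truncate_interval(obj: _I, last_day: int) -> _I | None:
    """Clip a start_day/end_day interval at ``last_day``; None if nothing remains."""
    if obj.start_day > last_day:
        return None
    if obj.end_day <= last_day:
        return obj
    return dataclasses.replace(obj, end_day=last_day)


def apply_censoring(
    intervals: Iterable[_I],
    censoring: Mapping[str, int] | Iterable[CensoringRecord],
    followup_days: int = 730,
) -> list[_I]:
    """Truncate intervals at ``min(censor_day - 1, followup_days - 1)`` per patient.

    Accepts any interval objects carrying ``patient_id``, ``start_day`` and
    ``end_day``. Intervals emptied by truncation are removed; a censor day of
    0 removes everything for that patient.
    """
    if not isinstance(censoring, Mapping):
        censoring = {rec.patient_id: rec.censor_day for rec in censoring}
    out: list[_I] = []
    for obj in intervals:
        censor_day = censoring.get(obj.patient_id, followup_days)
        last = min(censor_day - 1, followup_days - 1)
        if last < 0:
            continue
        clipped = truncate_interval(obj, last)
        if clipped is not None:
            out.append(clipped)
    return out


def _clip_len(start: int, end: int, lo: int, hi: int) -> int:
    return max(0, min(end, hi) - max(start, lo) + 1)


def stage_split(
    periods: Iterable[CoExposurePeriod],
    early_end: int = 180,
    followup_days: int = 730,
) -> pd.DataFrame:
    """Per-period early/late day counts on the internal 0-based grid.

    Columns: patient_id, agent_set, start_day, end_day, early_days,
    late_days. Stage additivity holds per period:
    ``early_days + late_days == n_days`` for periods inside follow-up.
    """
    rows = [
        (
            p.patient_id,
            p.agent_set,
            p.start_day,
            p.end_day,
            _clip_len(p.start_day, p.end_day, 0, early_end - 1),
            _clip_len(p.start_day, p.end_day, early_end, followup_days - 1),
        )
        for p in periods
    ]
    return pd.DataFrame(
        rows,
        columns=["patient_id", "agent_set", "start_day", "end_day", "early_days", "late_days"],
    )


def _per_patient_set(
    periods: Iterable[CoExposurePeriod], early_end: int, followup_days: int
) -> pd.DataFrame:
    """First co-exposed day and per-stage durations for each (patient, agent set)."""
    staged = stage_split(periods, early_end, followup_days)
    if staged.empty:
        return pd.DataFrame(
            columns=["patient_id", "agent_set", "first_day", "early_days", "late_days"]
        )
    grouped = (
        staged.groupby(["patient_id", "agent_set"], sort=False)
        .agg(first_day=("start_day", "min"), early_days=("early_days", "sum"),
             late_days=("late_days", "sum"))
        .reset_index()
    )
    return grouped


def _stage_columns(stage: str) -> tuple[str, str]:
    if stage not in ("early", "late"):
        raise ValueError("stage must be 'early' or 'late'")
    return ("early_days", "late_days") if stage == "early" else ("late_days", "early_days")


def summarize_combinations(
    periods: Iterable[CoExposurePeriod],
    *,
    stage: str,
    early_end: int = 180,
    followup_days: int = 730,
    min_cell_size: int = 5,
    top_n: int | None = None,
) -> pd.DataFrame:
    """Ranked combination table for one treatment stage.

    For every agent set: the number of patients with incident co-exposure in
    the stage (first co-exposed day of that set falls in the stage window),
    their percentage among all patients co-exposed at any point of the
    stage, and the median (Q1-Q3) of the per-patient total days of that
    combination clipped to the stage (quartiles by linear interpolation).
    Rows with fewer than ``min_cell_size`` patients are suppressed: counts
    and durations masked, ``n_display`` rendered as ``"<k"``. Ranking is by
    descending count with lexicographic agent-set tie-break.
    """
    per_set = _per_patient_set(periods, early_end, followup_days)
    cols = ["agent_set", "label", "n_patients", "pct_patients",
            "median_days", "q1_days", "q3_days", "n_display"]
    if per_set.empty:
        return pd.DataFrame(columns=cols)
    stage_col, _ = _stage_columns(stage)
    if stage == "early":
        incident = per_set["first_day"] < early_end
    else:
        incident = (per_set["first_day"] >= early_end) & (per_set["first_day"] < followup_days)
    denominator = per_set.loc[per_set[stage_col] >= 1, "patient_id"].nunique()

    rows = []
    for agent_set, grp in per_set[incident].groupby("agent_set", sort=False):
        durations = grp[stage_col].to_numpy(dtype=float)
        n = int(grp["patient_id"].nunique())
        q1, med, q3 = np.percentile(durations, [25, 50, 75])  # linear interpolation
        rows.append((agent_set, " + ".join(agent_set), n,
                     100.0 * n / denominator if denominator else float("nan"),
                     med, q1, q3))
    table = pd.DataFrame(rows, columns=cols[:-1])
    table = table.sort_values(
        ["n_patients", "label"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    suppressed = table["n_patients"] < min_cell_size
    table["n_display"] = table["n_patients"].astype(str)
    table.loc[suppressed, "n_display"] = f"<{min_cell_size}"
    table["n_patients"] = table["n_patients"].astype("Int64")
    table.loc[suppressed, ["n_patients", "pct_patients", "median_days", "q1_days", "q3_days"]] = pd.NA
    if top_n is not None:
        table = table.head(top_n).reset_index(drop=True)
    return table


def multiplicity_counts(
    periods: Iterable[CoExposurePeriod],
    *,
    stage: str,
    early_end: int = 180,
    followup_days: int = 730,
    min_cell_size: int | None = None,
    bucket_top: int | None = None,
) -> pd.DataFrame:
    """Patients by the largest number of agents concurrently covered in a stage.

    Per patient, multiplicity is the size of the largest agent set with at
    least one co-exposed day inside the stage window. ``bucket_top=k``
    collapses multiplicities >= k into one ``"k+"`` row. With
    ``min_cell_size`` set, counts below it are masked.
    """
    per_set = _per_patient_set(periods, early_end, followup_days)
    stage_col, _ = _stage_columns(stage)
    cols = ["multiplicity", "n_patients", "pct_patients", "n_display"]
    if per_set.empty:
        return pd.DataFrame(columns=cols)
    active = per_set[per_set[stage_col] >= 1].copy()
    if active.empty:
        return pd.DataFrame(columns=cols)
    active["k"] = active["agent_set"].map(len)
    mult = active.groupby("patient_id")["k"].max()
    if bucket_top is not None:
        mult = mult.clip(upper=bucket_top)
    counts = mult.value_counts().sort_index()
    total = int(counts.sum())
    table = pd.DataFrame({
        "multiplicity": [
            f"{k}+" if bucket_top is not None and k == bucket_top else str(k)
            for k in counts.index
        ],
        "n_patients": counts.to_numpy(),
        "pct_patients": 100.0 * counts.to_numpy() / total,
    })
    table["n_display"] = table["n_patients"].astype(str)
    if min_cell_size is not None:
        suppressed = table["n_patients"] < min_cell_size
        table.loc[suppressed, "n_display"] = f"<{min_cell_size}"
        table["n_patients"] = table["n_patients"].astype("Int64")
        table.loc[suppressed, ["n_patients", "pct_patients"]] = pd.NA
    return table


def timeline_top_combinations(
    periods: Iterable[CoExposurePeriod],
    index_dates: Mapping[str, date],
    *,
    bins: Sequence[tuple[int, int]] = ((1996, 2000), (2001, 2005), (2006, 2010),
                                       (2011, 2015), (2016, 2018)),
    early_end: int = 180,
    followup_days: int = 730,
    min_cell_size: int = 5,
    top_n: int = 5,
) -> pd.DataFrame:
    """Top combinations per calendar bin and stage (long format).

    Patients are binned by index year into the configured year groups; per
    bin and stage the ``top_n`` agent sets by incident patient count are
    ranked. Combinations below ``min_cell_size`` are excluded from ranking.
    Bin ranges must be non-overlapping and cover every index year.
    """
    bins = sorted(bins)
    for (a_lo, a_hi), (b_lo, b_hi) in zip(bins, bins[1:]):
        if a_hi >= b_lo:
            raise ValueError(f"overlapping calendar bins {(a_lo, a_hi)} and {(b_lo, b_hi)}")
    for lo, hi in bins:
        if lo > hi:
            raise ValueError(f"invalid calendar bin ({lo}, {hi})")

    def bin_of(year: int) -> str:
        for lo, hi in bins:
            if lo <= year <= hi:
                return f"{lo}-{hi}"
        raise ValueError(f"index year {year} not covered by the calendar bins")

    per_set = _per_patient_set(periods, early_end, followup_days)
    cols = ["bin", "stage", "rank", "agent_set", "label", "n_patients"]
    if per_set.empty:
        return pd.DataFrame(columns=cols)
    per_set = per_set[per_set["patient_id"].isin(index_dates.keys())].copy()
    per_set["bin"] = per_set["patient_id"].map(lambda p: bin_of(index_dates[p].year))

    rows = []
    for stage in ("early", "late"):
        stage_col, _ = _stage_columns(stage)
        if stage == "early":
            incident = per_set["first_day"] < early_end
        else:
            incident = (per_set["first_day"] >= early_end) & (per_set["first_day"] < followup_days)
        sub = per_set[incident]
        for bin_label, grp in sub.groupby("bin", sort=True):
            counts = (
                grp.groupby("agent_set")["patient_id"].nunique().reset_index(name="n")
            )
            counts = counts[counts["n"] >= min_cell_size]
            counts["label"] = counts["agent_set"].map(" + ".join)
            counts = counts.sort_values(["n", "label"], ascending=[False, True],
                                        kind="mergesort").head(top_n)
            for rank, rec in enumerate(counts.itertuples(index=False), start=1):
                rows.append((bin_label, stage, rank, rec.agent_set, rec.label, int(rec.n)))
    return pd.DataFrame(rows, columns=cols)
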