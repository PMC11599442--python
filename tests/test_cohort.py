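"""New-user identification, censoring, stage attribution and summary tables."""
from __future__ import annotations

from datetime import date

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coexpose import (
    CoExposurePeriod,
    PrescriptionRecord,
    StudyConfig,
    TreatmentEpisode,
    apply_censoring,
    identify_new_users,
    multiplicity_counts,
    stage_split,
    summarize_combinations,
    timeline_top_combinations,
)

CONFIG = StudyConfig()


def _rec(pid, when, atc="C09AA02"):
    return PrescriptionRecord(pid, when, atc)


def _period(pid, agents, s, e):
    return CoExposurePeriod(pid, tuple(agents), s, e)


# ---------------------------------------------------------------- new users

def test_redemption_within_washout_disqualifies():
    records = [_rec("P1", date(1995, 6, 1)), _rec("P1", date(1996, 3, 1))]  # 274 d apart
    assert identify_new_users(records, CONFIG) == {}


def test_first_redemption_with_no_history_is_the_index():
    records = [_rec("P1", date(1996, 7, 1))]
    assert identify_new_users(records, CONFIG) == {"P1": date(1996, 7, 1)}


def test_prior_redemption_exactly_washout_days_before_is_allowed():
    records = [_rec("P1", date(1995, 7, 2)), _rec("P1", date(1996, 7, 1))]  # 365 d apart
    assert identify_new_users(records, CONFIG) == {"P1": date(1996, 7, 1)}


def test_non_study_drug_cannot_be_the_index():
    records = [_rec("P1", date(1996, 7, 1), atc="N02BE01")]
    assert identify_new_users(records, CONFIG) == {}


def test_age_threshold_must_be_reached_during_study_window():
    records = [_rec("P1", date(1996, 7, 1)), _rec("P2", date(1996, 7, 1))]
    birthdates = {"P1": date(1950, 1, 1), "P2": date(1954, 6, 1)}  # P2 turns 65 in 2019
    assert set(identify_new_users(records, CONFIG, birthdates)) == {"P1"}


def test_register_must_cover_washout_before_enrollment():
    config = StudyConfig(study_window=(date(1995, 7, 1), date(2018, 12, 31)))
    with pytest.raises(ValueError):
        identify_new_users([_rec("P1", date(1996, 7, 1))], config)


# ---------------------------------------------------------------- censoring

def _episode(pid, s, e):
    return TreatmentEpisode(pid, "C09AA02", 1, s, e, 1)


def test_death_truncates_coverage_the_day_before():
    out = apply_censoring([_episode("P1", 0, 500)], {"P1": 400}, 730)
    assert [(ep.start_day, ep.end_day) for ep in out] == [(0, 399)]


def test_uncensored_patients_capped_at_followup_end():
    out = apply_censoring([_episode("P1", 0, 745)], {}, 730)
    assert [(ep.start_day, ep.end_day) for ep in out] == [(0, 729)]


def test_censor_day_zero_removes_everything():
    assert apply_censoring([_episode("P1", 0, 100)], {"P1": 0}, 730) == []


def test_interval_fully_after_censoring_is_removed():
    assert apply_censoring([_episode("P1", 500, 600)], {"P1": 300}, 730) == []


# ---------------------------------------------------------------- stages

def test_stage_clip_arithmetic():
    # printed days 170..200 are internal days 169..199: 11 early + 20 late
    staged = stage_split([_period("P1", "AB", 169, 199)], 180, 730)
    row = staged.iloc[0]
    assert (row.early_days, row.late_days) == (11, 20)


def test_period_inside_early_stage_only():
    staged = stage_split([_period("P1", "AB", 0, 100)], 180, 730)
    assert (staged.iloc[0].early_days, staged.iloc[0].late_days) == (101, 0)


def test_period_starting_at_stage_boundary_is_late_incident():
    table = summarize_combinations(
        [_period("P1", "AB", 180, 200)], stage="late", min_cell_size=1
    )
    assert table.iloc[0].n_patients == 1
    assert summarize_combinations(
        [_period("P1", "AB", 180, 200)], stage="early", min_cell_size=1
    ).empty


@settings(deadline=None, derandomize=True, max_examples=100)
@given(start=st.integers(0, 729), length=st.integers(1, 400))
def test_stage_additivity(start, length):
    end = min(729, start + length - 1)
    staged = stage_split([_period("P1", "AB", start, end)], 180, 730)
    row = staged.iloc[0]
    assert row.early_days + row.late_days == end - start + 1


# ---------------------------------------------------------------- tables

def test_quartiles_by_linear_interpolation_and_suppression():
    periods = [
        _period("P1", "AB", 0, 9),    # 10 days
        _period("P2", "AB", 0, 19),   # 20 days
        _period("P3", "AB", 0, 29),   # 30 days
    ]
    table = summarize_combinations(periods, stage="early", min_cell_size=1)
    row = table.iloc[0]
    assert (row.median_days, row.q1_days, row.q3_days) == (20, 15, 25)
    assert row.n_patients == 3 and row.pct_patients == 100.0
    suppressed = summarize_combinations(periods, stage="early", min_cell_size=5)
    assert suppressed.iloc[0].n_display == "<5"
    assert pd.isna(suppressed.iloc[0].n_patients)


def test_equal_counts_break_ties_lexicographically():
    periods = [
        _period("P1", ("B", "C"), 0, 9), _period("P2", ("B", "C"), 0, 9),
        _period("P1", ("A", "B"), 20, 29), _period("P2", ("A", "B"), 20, 29),
    ]
    table = summarize_combinations(periods, stage="early", min_cell_size=1)
    assert list(table.label) == ["A + B", "B + C"]


def test_no_coexposed_patients_gives_empty_table():
    assert summarize_combinations([], stage="early").empty


def test_multiplicity_is_largest_concurrent_agent_set():
    periods = [
        _period("P1", "AB", 0, 9),
        _period("P2", "AB", 0, 9), _period("P2", "ABC", 5, 9),
        _period("P3", "AB", 200, 300),  # late only
    ]
    table = multiplicity_counts(periods, stage="early")
    assert dict(zip(table.multiplicity, table.n_patients)) == {"2": 1, "3": 1}
    late = multiplicity_counts(periods, stage="late")
    assert dict(zip(late.multiplicity, late.n_patients)) == {"2": 1}


def test_multiplicity_histogram_matches_hand_count():
    # ten patients: six pair-only, three with a triple, one with a quadruple
    periods = []
    for i in range(6):
        periods.append(_period(f"P{i}", "AB", 0, 50))
    for i in range(6, 9):
        periods += [_period(f"P{i}", "AB", 0, 50), _period(f"P{i}", "ABC", 10, 20)]
    periods += [_period("P9", "ABCD", 0, 10)]
    table = multiplicity_counts(periods, stage="early", bucket_top=4)
    assert dict(zip(table.multiplicity, table.n_patients)) == {"2": 6, "3": 3, "4+": 1}
    assert float(table.pct_patients.sum()) == pytest.approx(100.0)


def test_timeline_single_bin_and_suppression():
    periods = [_period(f"P{i}", "AB", 0, 50) for i in range(6)]
    periods += [_period("P9", "AC", 0, 50)]  # below the cell threshold
    index_dates = {f"P{i}": date(1998, 1, 1) for i in range(6)}
    index_dates["P9"] = date(1998, 5, 1)
    table = timeline_top_combinations(
        periods, index_dates, bins=[(1996, 2000)], min_cell_size=5
    )
    assert list(table["bin"].unique()) == ["1996-2000"]
    assert list(table.label) == ["A + B"]  # only early has data; A + C suppressed


def test_timeline_rank_flip_between_bins():
    periods, index_dates = [], {}
    for i in range(4):  # early era: AB dominates
        periods += [_period(f"E{i}", "AB", 0, 50)]
        index_dates[f"E{i}"] = date(1997, 1, 1)
    periods += [_period("E9", "AC", 0, 50)]
    index_dates["E9"] = date(1997, 1, 1)
    for i in range(4):  # late era: AC dominates
        periods += [_period(f"L{i}", "AC", 0, 50)]
        index_dates[f"L{i}"] = date(2003, 1, 1)
    periods += [_period("L9", "AB", 0, 50)]
    index_dates["L9"] = date(2003, 1, 1)
    table = timeline_top_combinations(
        periods, index_dates, bins=[(1996, 2000), (2001, 2005)], min_cell_size=1
    )
    early_stage = table[table.stage == "early"]
    top = {row.bin: row.label for row in early_stage[early_stage["rank"] == 1].itertuples()}
    assert top == {"1996-2000": "A + B", "2001-2005": "A + C"}


def test_timeline_bin_validation():
    periods = [_period("P1", "AB", 0, 10)]
    with pytest.raises(ValueError):
        timeline_top_combinations(periods, {"P1": date(1998, 1, 1)},
                                  bins=[(1996, 2000), (2000, 2005)])
    with pytest.raises(ValueError):
        timeline_top_combinations(periods, {"P1": date(1998, 1, 1)}, bins=[(2001, 2005)])
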