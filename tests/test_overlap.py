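"""Co-exposure interval algebra against brute-force day-set computation."""
from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coexpose import (
    CoExposurePeriod,
    TreatmentEpisode,
    build_final_episode,
    check_overlap,
    combine_pairs,
    day_level_oracle,
    expand_fixed_dose,
    find_overlaps,
    pairwise_co_exposure,
    patient_co_exposure,
)
from coexpose.simulate import coverage_from_episodes

FDC_MAP = {"C09BB04": frozenset({"C09AA04", "C08CA01"})}


def _episodes(atc, *intervals):
    return [
        TreatmentEpisode("P1", atc, i + 1, s, e, 1) for i, (s, e) in enumerate(intervals)
    ]


# ---------------------------------------------------------------- check_overlap

@pytest.mark.parametrize(
    ("a", "b", "expected"),
    [
        ((0, 10), (5, 15), True),
        ((0, 4), (5, 9), False),   # adjacent closed intervals share no day
        ((0, 10), (10, 20), True),  # single shared boundary day
    ],
)
def test_closed_interval_overlap(a, b, expected):
    assert check_overlap(a, b) is expected
    assert check_overlap(b, a) is expected


def test_invalid_interval_rejected():
    with pytest.raises(ValueError):
        check_overlap((10, 0), (0, 5))


# ---------------------------------------------------------------- pairwise

def test_pairwise_overlap_periods_and_total():
    periods, total = pairwise_co_exposure(
        _episodes("A", (0, 100)), _episodes("B", (50, 150), (200, 300))
    )
    assert [(p.start_day, p.end_day) for p in periods] == [(50, 100)]
    assert total == 51  # |{50..100}|


def test_full_window_identity():
    periods, total = pairwise_co_exposure(
        _episodes("A", (0, 729)), _episodes("B", (0, 729))
    )
    assert total == 730 and periods[0].agent_set == ("A", "B")


def test_multiple_episode_pairs_sum():
    periods, total = pairwise_co_exposure(
        _episodes("A", (0, 10), (20, 30)), _episodes("B", (5, 25))
    )
    assert [(p.start_day, p.end_day) for p in periods] == [(5, 10), (20, 25)]
    assert total == 12


def test_pairwise_is_symmetric():
    a, b = _episodes("A", (0, 10), (40, 90)), _episodes("B", (5, 60))
    pa, ta = pairwise_co_exposure(a, b)
    pb, tb = pairwise_co_exposure(b, a)
    assert ta == tb
    assert {(p.agent_set, p.start_day, p.end_day) for p in pa} == {
        (p.agent_set, p.start_day, p.end_day) for p in pb
    }


def test_empty_episode_lists_yield_nothing():
    assert pairwise_co_exposure([], _episodes("B", (0, 10))) == ([], 0)


# ---------------------------------------------------------------- fixed-dose

def test_fdc_episode_passes_through_with_component_agents():
    periods = expand_fixed_dose(_episodes("C09BB04", (0, 90)), FDC_MAP)
    assert [(p.agent_set, p.start_day, p.end_day) for p in periods] == [
        (("C08CA01", "C09AA04"), 0, 90)
    ]


def test_empty_fdc_map_yields_no_periods():
    assert expand_fixed_dose(_episodes("C09BB04", (0, 90)), {}) == []


def test_fdc_overlapping_free_agent_yields_three_agent_period():
    per_product = {
        "C09BB04": _episodes("C09BB04", (0, 90)),
        "C09CA01": _episodes("C09CA01", (50, 120)),
    }
    periods, _ = patient_co_exposure(per_product, FDC_MAP)
    triples = [p for p in periods if len(p.agent_set) == 3]
    assert [(p.agent_set, p.start_day, p.end_day) for p in triples] == [
        (("C08CA01", "C09AA04", "C09CA01"), 50, 90)
    ]


# ---------------------------------------------------------------- find_overlaps

def _pair(agents, s, e):
    return CoExposurePeriod("P1", tuple(agents), s, e)


def test_three_pairs_intersect_into_a_triple():
    pairs = [_pair("AB", 10, 60), _pair("BC", 40, 90), _pair("AC", 40, 60)]
    higher = find_overlaps(pairs)
    assert [(p.agent_set, p.start_day, p.end_day) for p in higher] == [
        (("A", "B", "C"), 40, 60)
    ]


def test_disjoint_pairs_yield_no_higher_order():
    assert find_overlaps([_pair("AB", 0, 10), _pair("CD", 50, 60)]) == []


def test_four_agents_full_window_yield_all_subsets():
    per_product = {code: _episodes(code, (0, 729)) for code in "ABCD"}
    periods, finals = patient_co_exposure(per_product)
    by_size: dict[int, set] = {}
    for p in periods:
        assert (p.start_day, p.end_day) == (0, 729)
        by_size.setdefault(len(p.agent_set), set()).add(p.agent_set)
    assert len(by_size[2]) == 6 and len(by_size[3]) == 4 and len(by_size[4]) == 1
    assert [(f.start_day, f.end_day) for f in finals] == [(0, 729)]


# ---------------------------------------------------------------- combine_pairs

def test_combine_pairs_union_sort_idempotence():
    assert combine_pairs([{"A", "B"}, {"B", "C"}]) == ("A", "B", "C")
    assert combine_pairs([{"A", "B"}, {"A", "B"}]) == ("A", "B")
    assert combine_pairs([("C", "B"), ("A",)]) == combine_pairs([("A", "B"), ("C",)])
    with pytest.raises(ValueError):
        combine_pairs([])


# ---------------------------------------------------------------- final episode

def test_overlapping_periods_merge_into_final_episodes():
    finals = build_final_episode([_pair("AB", 10, 50), _pair("AC", 40, 80), _pair("AB", 100, 120)])
    assert [(f.start_day, f.end_day, f.total_days) for f in finals] == [
        (10, 80, 71), (100, 120, 21)
    ]
    assert sum(f.total_days for f in finals) == 92


def test_single_period_is_its_own_final_episode():
    finals = build_final_episode([_pair("AB", 5, 9)])
    assert [(f.start_day, f.end_day) for f in finals] == [(5, 9)]


def test_one_uncovered_day_separates_final_episodes():
    finals = build_final_episode([_pair("AB", 0, 10), _pair("AB", 12, 20)])
    assert [(f.start_day, f.end_day) for f in finals] == [(0, 10), (12, 20)]
    # exactly adjacent periods merge (contiguous coverage has no gap)
    finals = build_final_episode([_pair("AB", 0, 10), _pair("AB", 11, 20)])
    assert [(f.start_day, f.end_day) for f in finals] == [(0, 20)]


# ---------------------------------------------------------------- properties

PRODUCTS = ("C03AB01", "C08CA01", "C09CA01", "C09BB04")


@st.composite
def patient_episodes(draw):
    n_products = draw(st.integers(2, 4))
    per_product = {}
    for code in PRODUCTS[:n_products]:
        eps = []
        cursor = 0
        for _ in range(draw(st.integers(0, 3))):
            start = cursor + draw(st.integers(0, 180))
            if start > 729:
                break
            end = min(729, start + draw(st.integers(0, 250)))
            eps.append(TreatmentEpisode("P1", code, len(eps) + 1, start, end, 1))
            cursor = end + 2
        if eps:
            per_product[code] = eps
    return per_product


@settings(deadline=None, derandomize=True, max_examples=200)
@given(per_product=patient_episodes(), include_fdc_alone=st.booleans())
def test_interval_algebra_matches_day_enumeration(per_product, include_fdc_alone):
    """Final episodes, totals and per-day agent labels equal brute force."""
    periods, finals = patient_co_exposure(
        per_product, FDC_MAP, include_fdc_alone=include_fdc_alone
    )
    coverage = coverage_from_episodes(ep for eps in per_product.values() for ep in eps)
    oracle = day_level_oracle(coverage, FDC_MAP, include_fdc_alone=include_fdc_alone)
    assert tuple((f.start_day, f.end_day) for f in finals) == oracle.episodes
    assert sum(f.total_days for f in finals) == oracle.total_days
    method_agents: dict[int, set[str]] = {}
    for p in periods:
        for d in range(p.start_day, p.end_day + 1):
            method_agents.setdefault(d, set()).update(p.agent_set)
    assert {d: frozenset(a) for d, a in method_agents.items()} == dict(oracle.agents_by_day)


@settings(deadline=None, derandomize=True, max_examples=100)
@given(per_product=patient_episodes())
def test_containment_and_pair_total_bounds(per_product):
    periods, _ = patient_co_exposure(per_product, FDC_MAP)
    agent_days: dict[str, set[int]] = {}
    for code, eps in per_product.items():
        for agent in FDC_MAP.get(code, frozenset({code})):
            agent_days.setdefault(agent, set()).update(
                d for ep in eps for d in range(ep.start_day, ep.end_day + 1)
            )
    for p in periods:
        days = set(range(p.start_day, p.end_day + 1))
        for agent in p.agent_set:
            assert days <= agent_days[agent]  # k-set period inside every member's coverage


@settings(deadline=None, derandomize=True, max_examples=100)
@given(per_product=patient_episodes(), extra_start=st.integers(0, 700),
       extra_len=st.integers(0, 200))
def test_adding_an_episode_never_decreases_coexposure(per_product, extra_start, extra_len):
    _, finals_before = patient_co_exposure(per_product, FDC_MAP)
    code = PRODUCTS[0]
    eps = list(per_product.get(code, []))
    extra_end = min(729, extra_start + extra_len)
    # rebuild that product's coverage with one extra disjoint-or-merged interval
    days = set(range(extra_start, extra_end + 1))
    for ep in eps:
        days.update(range(ep.start_day, ep.end_day + 1))
    merged, idx = [], 1
    for d in sorted(days):
        if merged and d == merged[-1].end_day + 1:
            merged[-1] = TreatmentEpisode("P1", code, merged[-1].episode_index,
                                          merged[-1].start_day, d, 1)
        elif not merged or d > merged[-1].end_day + 1:
            merged.append(TreatmentEpisode("P1", code, idx, d, d, 1))
            idx += 1
    augmented = dict(per_product)
    augmented[code] = merged
    _, finals_after = patient_co_exposure(augmented, FDC_MAP)
    assert sum(f.total_days for f in finals_after) >= sum(f.total_days for f in finals_before)
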