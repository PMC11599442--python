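"""Co-exposure interval algebra.

Given per-product treatment episodes, co-exposure to free-dose combinations
is the day-level overlap of episodes of distinct products; a fixed-dose
combination (FDC) product is co-exposure in itself, its episodes passing
straight through with the product's component agents as the agent set.
Higher-order (>= 3 agent) combinations are exact k-way interval
intersections obtained as the fixed point of pairwise intersection of
overlapping periods with differing agent sets — order-independent, and
equivalent to iterating over pairs until no new combination appears.
The final co-exposure episode of a patient is the union of all their
co-exposure periods merged over day-adjacent intervals: it allows no
carry-over and no gap of even a single day.

All intervals are closed ``[start_day, end_day]`` on the integer day grid;
two intervals overlap iff ``max(starts) <= min(ends)`` and the overlap
length is ``min(ends) - max(starts) + 1``.
"""
from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

from .model import CoExposurePeriod, FinalCoExposureEpisode, TreatmentEpisode

log = logging.getLogger(__name__)

Interval = tuple[int, int]


def _validate(interval: Interval) -> None:
    if interval[0] > interval[1]:
        raise ValueError(f"invalid interval {interval}: start > end")


def check_overlap(a: Interval, b: Interval) -> bool:
    """True iff two closed day intervals share at least one day."""
    _validate(a)
    _validate(b)
    return max(a[0], b[0]) <= min(a[1], b[1])


def overlap_interval(a: Interval, b: Interval) -> Interval | None:
    """The shared closed interval of two intervals, or None if disjoint."""
    if not check_overlap(a, b):
        return None
    return (max(a[0], b[0]), min(a[1], b[1]))


def combine_pairs(sets: Iterable[Iterable[str]]) -> tuple[str, ...]:
    """Merge agent sets into one canonical sorted tuple (idempotent)."""
    merged: set[str] = set()
    empty = True
    for s in sets:
        empty = False
        merged.update(s)
    if empty:
        raise ValueError("combine_pairs needs at least one agent set")
    return tuple(sorted(merged))


def pairwise_co_exposure(
    episodes_a: Sequence[TreatmentEpisode],
    episodes_b: Sequence[TreatmentEpisode],
    *,
    agents_a: Iterable[str] | None = None,
    agents_b: Iterable[str] | None = None,
) -> tuple[list[CoExposurePeriod], int]:
    """Co-exposure periods between the episodes of two distinct products.

    One period is emitted per overlapping episode pair, with interval
    ``[max(starts), min(ends)]``; the total co-exposure duration is the sum
    of the period lengths. Agent sets default to the product codes; pass
    ``agents_a``/``agents_b`` to expand fixed-dose products into components.
    Product pairs whose combined agent set has fewer than two distinct
    agents yield nothing.
    """
    if not episodes_a or not episodes_b:
        return [], 0
    set_a = tuple(agents_a) if agents_a is not None else (episodes_a[0].atc_code,)
    set_b = tuple(agents_b) if agents_b is not None else (episodes_b[0].atc_code,)
    union = combine_pairs([set_a, set_b])
    if len(union) < 2:
        return [], 0
    periods: list[CoExposurePeriod] = []
    for ea in episodes_a:
        for eb in episodes_b:
            shared = overlap_interval((ea.start_day, ea.end_day), (eb.start_day, eb.end_day))
            if shared is not None:
                periods.append(CoExposurePeriod(ea.patient_id, union, shared[0], shared[1]))
    return periods, sum(p.n_days for p in periods)


def expand_fixed_dose(
    episodes: Iterable[TreatmentEpisode],
    fdc_map: Mapping[str, frozenset[str]],
) -> list[CoExposurePeriod]:
    """Emit FDC treatment episodes directly as co-exposure periods.

    The estimated supply duration of a fixed-dose product already is the
    number of co-exposed days for its components, so no overlap computation
    applies; each episode becomes one period carrying the component agent
    set. Episodes of products absent from the map are ignored here (they
    behave as single agents elsewhere).
    """
    periods: list[CoExposurePeriod] = []
    for ep in episodes:
        components = fdc_map.get(ep.atc_code)
        if components is None:
            continue
        if len(components) < 2:
            raise ValueError(f"FDC {ep.atc_code} maps to fewer than 2 components")
        periods.append(
            CoExposurePeriod(ep.patient_id, tuple(components), ep.start_day, ep.end_day)
        )
    return periods


def find_overlaps(periods: Sequence[CoExposurePeriod]) -> list[CoExposurePeriod]:
    """Higher-order (>= 3 agent) combinations from one patient's periods.

    Iteratively intersects overlapping periods whose agent sets differ,
    accumulating each distinct union set, until a fixed point; every emitted
    k-agent interval is therefore the exact intersection of the coverage of
    all k member agents. Maximal intervals per agent set are returned
    (overlapping same-set fragments merged, nested ones absorbed).
    """
    if not periods:
        return []
    patient_id = periods[0].patient_id
    found: set[tuple[frozenset[str], Interval]] = {
        (frozenset(p.agent_set), (p.start_day, p.end_day)) for p in periods
    }
    frontier = set(found)
    while frontier:
        new: set[tuple[frozenset[str], Interval]] = set()
        for agents_a, iv_a in frontier:
            for agents_b, iv_b in found:
                if agents_a == agents_b:
                    continue
                shared = overlap_interval(iv_a, iv_b)
                if shared is None:
                    continue
                cand = (agents_a | agents_b, shared)
                if cand not in found:
                    new.add(cand)
        found |= new
        frontier = new

    by_set: dict[frozenset[str], list[Interval]] = {}
    for agents, iv in found:
        if len(agents) >= 3:
            by_set.setdefault(agents, []).append(iv)
    out: list[CoExposurePeriod] = []
    for agents in sorted(by_set, key=sorted):
        for start, end in _merge_overlapping(by_set[agents]):
            out.append(CoExposurePeriod(patient_id, tuple(agents), start, end))
    return out


def _merge_overlapping(intervals: list[Interval]) -> list[Interval]:
    """Merge intervals that share days (adjacency is NOT merged)."""
    merged: list[Interval] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def _canonicalize(periods: Iterable[CoExposurePeriod]) -> list[CoExposurePeriod]:
    """One disjoint interval list per agent set (overlapping fragments merged).

    Same-set periods can overlap when a free-dose product co-occurs with a
    fixed-dose product sharing a component; merging keeps per-set day counts
    free of double counting.
    """
    by_set: dict[tuple[str, ...], list[Interval]] = {}
    patient_id = ""
    for p in periods:
        patient_id = p.patient_id
        by_set.setdefault(p.agent_set, []).append((p.start_day, p.end_day))
    out: list[CoExposurePeriod] = []
    for agent_set in sorted(by_set):
        for start, end in _merge_overlapping(by_set[agent_set]):
            out.append(CoExposurePeriod(patient_id, agent_set, start, end))
    return out


def build_final_episode(
    periods: Sequence[CoExposurePeriod],
) -> list[FinalCoExposureEpisode]:
    """Merge all of a patient's co-exposure periods into final episodes.

    Projects every period (any agent set) onto the day grid and merges
    intervals that overlap or are exactly day-adjacent; a gap of one or more
    uncovered days always separates episodes. No carry-over is applied.
    """
    if not periods:
        return []
    patient_id = periods[0].patient_id
    merged: list[list[int]] = []
    for start, end in sorted((p.start_day, p.end_day) for p in periods):
        if merged and start <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [FinalCoExposureEpisode(patient_id, s, e) for s, e in merged]


def patient_co_exposure(
    episodes_by_product: Mapping[str, Sequence[TreatmentEpisode]],
    fdc_map: Mapping[str, frozenset[str]] | None = None,
    *,
    include_fdc_alone: bool = True,
) -> tuple[list[CoExposurePeriod], list[FinalCoExposureEpisode]]:
    """Full co-exposure assessment for one patient.

    Combines pairwise overlap of all product pairs (fixed-dose products
    contributing their component agent sets), direct pass-through of FDC
    episodes, and higher-order combination discovery. Returns all
    co-exposure periods (any agent-set size) and the final gap-free
    episodes. ``include_fdc_alone`` controls whether days covered only by a
    single fixed-dose product count as co-exposure.
    """
    fdc_map = fdc_map or {}
    products = sorted(code for code, eps in episodes_by_product.items() if eps)
    agents = {code: tuple(sorted(fdc_map.get(code, frozenset({code})))) for code in products}

    base: list[CoExposurePeriod] = []
    for i, code_a in enumerate(products):
        for code_b in products[i + 1:]:
            pair_periods, _ = pairwise_co_exposure(
                list(episodes_by_product[code_a]),
                list(episodes_by_product[code_b]),
                agents_a=agents[code_a],
                agents_b=agents[code_b],
            )
            base.extend(pair_periods)

    fdc_periods: list[CoExposurePeriod] = []
    for code in products:
        fdc_periods.extend(expand_fixed_dose(episodes_by_product[code], fdc_map))

    countable = base + (fdc_periods if include_fdc_alone else [])
    higher = find_overlaps(countable)
    all_periods = _canonicalize(countable + [p for p in higher if len(p.agent_set) >= 3])
    finals = build_final_episode(countable)
    return all_periods, finals
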