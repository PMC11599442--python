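"""Treatment-episode construction with same-product carry-over and a permissible gap.

A treatment episode is a maximal interval of presumed continuous use of one
product. Events are processed in redemption order while maintaining a running
coverage end ``C``. A refill redeemed before the current supply is exhausted
carries the unused supply forward (``C <- max(C, t - 1) + d``); a refill
within the permissible gap of the coverage end joins the same episode; a
longer supply-free interval closes the episode. Gap arithmetic on the closed
day grid: a redemption the day after coverage ends is a 0-day gap, so an
event joins iff ``t - C - 1 <= permissible_gap``. Episode coverage (not the
accumulated supply) is truncated at the end of follow-up.
"""
from __future__ import annotations

from typing import Sequence

from .model import MedicationEvent, TreatmentEpisode


def build_episodes(
    events: Sequence[MedicationEvent],
    permissible_gap: float = 30,
    followup_days: int = 730,
) -> list[TreatmentEpisode]:
    """Merge one patient-product's medication events into treatment episodes.

    ``events`` must be sorted by ``start_day`` with all starts inside
    ``[0, followup_days)``. ``permissible_gap`` may be ``math.inf``, which
    collapses every event into a single episode.
    """
    if not events:
        return []
    patient_id, atc = events[0].patient_id, events[0].atc_code
    for prev, cur in zip(events, events[1:]):
        if cur.start_day < prev.start_day:
            raise ValueError("events must be sorted by start_day")
    for ev in events:
        if ev.patient_id != patient_id or ev.atc_code != atc:
            raise ValueError("build_episodes expects events of a single patient-product")
        if not (0 <= ev.start_day < followup_days):
            raise ValueError(
                f"event start {ev.start_day} outside follow-up [0, {followup_days})"
            )

    episodes: list[TreatmentEpisode] = []

    def close(start: int, coverage_end: int, n: int) -> None:
        episodes.append(
            TreatmentEpisode(
                patient_id, atc,
                episode_index=len(episodes) + 1,
                start_day=start,
                end_day=min(coverage_end, followup_days - 1),
                n_events=n,
            )
        )

    start = events[0].start_day
    coverage_end = events[0].end_day
    n_events = 1
    for ev in events[1:]:
        t = ev.start_day
        if t <= coverage_end + permissible_gap + 1:
            # joins: carry unused supply forward past the redemption day
            coverage_end = max(coverage_end, t - 1) + ev.duration_days
            n_events += 1
        else:
            close(start, coverage_end, n_events)
            start, coverage_end, n_events = t, ev.end_day, 1
    close(start, coverage_end, n_events)
    return episodes


__all__ = ["build_episodes"]
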