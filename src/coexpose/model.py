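"""Core domain types for register-based co-exposure assessment.

All exposure intervals are expressed on an integer day grid relative to each
patient's index date (day 0 = index date, the first qualifying redemption).
Intervals are closed on both ends: an event ``[start_day, end_day]`` covers
``end_day - start_day + 1`` days, and two intervals overlap iff
``max(starts) <= min(ends)``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

CENSOR_CAUSES = ("end_of_followup", "emigration", "death")


@dataclass(frozen=True, order=True)
class PrescriptionRecord:
    """One redeemed prescription: the register's observable event.

    Ordering and equality use ``(patient_id, redemption_date, atc_code)`` so
    that sorting gives the register order the estimators expect and exact
    same-day duplicates of the same product collapse under deduplication.
    """

    patient_id: str
    redemption_date: date
    atc_code: str
    quantity: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.atc_code:
            raise ValueError("atc_code must be non-empty")
        if self.quantity is not None and self.quantity <= 0:
            raise ValueError(f"quantity must be positive, got {self.quantity}")


@dataclass(frozen=True)
class MedicationEvent:
    """A redemption paired with an estimated supply duration (days)."""

    patient_id: str
    atc_code: str
    start_day: int
    duration_days: int

    def __post_init__(self) -> None:
        if self.duration_days < 1:
            raise ValueError("duration_days must be >= 1")
        if self.start_day < 0:
            raise ValueError("start_day must be >= 0 (relative to index date)")

    @property
    def end_day(self) -> int:
        return self.start_day + self.duration_days - 1


@dataclass(frozen=True)
class TreatmentEpisode:
    """A maximal interval of presumed continuous use of one product.

    Built from medication events with same-product carry-over and a
    permissible gap; ``episode_index`` is the 1-based ordinal within
    one (patient, product).
    """

    patient_id: str
    atc_code: str
    episode_index: int
    start_day: int
    end_day: int
    n_events: int

    def __post_init__(self) -> None:
        if self.end_day < self.start_day:
            raise ValueError("end_day must be >= start_day")
        if self.n_events < 1:
            raise ValueError("an episode needs at least one contributing event")

    @property
    def n_days(self) -> int:
        return self.end_day - self.start_day + 1


@dataclass(frozen=True)
class CoExposurePeriod:
    """An interval during which a specific set of >= 2 agents is concurrently covered.

    ``agent_set`` holds active-agent identifiers (components of fixed-dose
    products already expanded), stored as a sorted tuple so periods are
    hashable and combination labels deterministic.
    """

    patient_id: str
    agent_set: tuple[str, ...]
    start_day: int
    end_day: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "agent_set", tuple(sorted(set(self.agent_set))))
        if len(self.agent_set) < 2:
            raise ValueError("agent_set must contain >= 2 distinct agents")
        if self.end_day < self.start_day:
            raise ValueError("end_day must be >= start_day")

    @property
    def n_days(self) -> int:
        return self.end_day - self.start_day + 1


@dataclass(frozen=True)
class FinalCoExposureEpisode:
    """A maximal gap-free run of days on which a patient is co-exposed to >= 2 agents."""

    patient_id: str
    start_day: int
    end_day: int

    def __post_init__(self) -> None:
        if self.end_day < self.start_day:
            raise ValueError("end_day must be >= start_day")

    @property
    def total_days(self) -> int:
        return self.end_day - self.start_day + 1


@dataclass(frozen=True)
class CensoringRecord:
    """End of observation before the administrative follow-up cap.

    ``censor_day`` is the first day the patient is no longer observed;
    coverage on days >= censor_day is removed.
    """

    patient_id: str
    censor_day: int
    cause: str = "end_of_followup"

    def __post_init__(self) -> None:
        if self.censor_day < 0:
            raise ValueError("censor_day must be >= 0")
        if self.cause not in CENSOR_CAUSES:
            raise ValueError(f"cause must be one of {CENSOR_CAUSES}, got {self.cause!r}")


@dataclass(frozen=True)
class StudyConfig:
    """Study-level parameters of the new-user cohort design.

    Defaults mirror a two-year new-user design over a national register:
    365-day washout, 730-day follow-up split at day 180 into an early and a
    late treatment stage, a 30-day permissible gap within treatment episodes,
    and small-cell suppression below five observations.
    """

    washout_days: int = 365
    followup_days: int = 730
    early_stage_end_day: int = 180
    permissible_gap_days: int = 30
    min_cell_size: int = 5
    age_threshold_years: int = 65
    study_window: tuple[date, date] = (date(1995, 1, 1), date(2018, 12, 31))
    enrollment_window: tuple[date, date] = (date(1996, 1, 1), date(2016, 12, 31))
    index_atc_prefixes: tuple[str, ...] = ("C03AA", "C03AB", "C08CA", "C09AA", "C09CA")
    calendar_bins: tuple[tuple[int, int], ...] = (
        (1996, 2000), (2001, 2005), (2006, 2010), (2011, 2015), (2016, 2018),
    )
    # Sessa Empirical Estimator knobs
    trim_percentile: float = 0.8
    k_min: int = 2
    k_max: int = 10
    duration_statistic: str = "median"
    default_duration_days: int = 30
    see_assignment: str = "per_event"  # or "per_drug"
    # whether a fixed-dose product alone (>=2 components) counts as co-exposure
    count_fdc_alone: bool = True
    seed: int = 20240101

    def __post_init__(self) -> None:
        if not (0 < self.early_stage_end_day < self.followup_days):
            raise ValueError("need 0 < early_stage_end_day < followup_days")
        if self.permissible_gap_days < 0:
            raise ValueError("permissible_gap_days must be >= 0")
        if self.min_cell_size < 1:
            raise ValueError("min_cell_size must be >= 1")
        if not (0 < self.trim_percentile <= 1):
            raise ValueError("trim_percentile must be in (0, 1]")
        if self.k_min < 1 or self.k_max < self.k_min:
            raise ValueError("need 1 <= k_min <= k_max")
        if self.duration_statistic not in ("median", "mean"):
            raise ValueError("duration_statistic must be 'median' or 'mean'")
        if self.see_assignment not in ("per_event", "per_drug"):
            raise ValueError("see_assignment must be 'per_event' or 'per_drug'")
        for name in ("study_window", "enrollment_window"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be ordered (first <= last)")
        if self.default_duration_days < 1:
            raise ValueError("default_duration_days must be >= 1")
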