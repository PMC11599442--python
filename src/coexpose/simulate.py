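"""Synthetic redemption registers with ground truth, and the validation harness.

The generator emulates the structure of a prescription-redemption register:
per-patient refill sequences per product with product-specific supply
durations (pack sizes) and refill-interval jitter, staggered regimen starts,
discontinuations, injected adherence gaps long enough to break treatment
episodes, fixed-dose combination products, censoring, and decoy patients
that must be caught by the cohort filters (washout violators and
redemptions beyond follow-up). Every patient carries day-resolution ground
truth of which products truly supplied which days.

The validation harness mirrors the method's accuracy audit: draw a random
sample of patients who redeemed more than one agent, and score a patient as
correctly classified iff every final co-exposure episode start and end date
produced by the interval method matches a brute-force day-enumeration
oracle exactly. The oracle can run in two modes: *episode mode* enumerates
days from the method's own treatment episodes (auditing the overlap algebra
in isolation, as the published audit did), while *truth mode* enumerates the
generator's true supply days (auditing the whole chain including duration
estimation).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Iterable, Mapping, Sequence

import numpy as np

from .model import CensoringRecord, PrescriptionRecord, StudyConfig, TreatmentEpisode

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AgentPlan:
    """Refill behaviour of one product within a regimen.

    ``durations`` are the true supply durations (days) a redemption may
    carry, drawn with ``duration_weights``; refills are scheduled at the
    drawn duration plus uniform integer jitter in ``[-refill_jitter,
    refill_jitter]``. With probability ``gap_prob`` a refill is further
    delayed by a uniform draw from ``gap_range`` (long enough, by default,
    to exceed a 30-day permissible gap and split the treatment episode).
    """

    atc: str
    durations: tuple[int, ...] = (30,)
    duration_weights: tuple[float, ...] | None = None
    refill_jitter: int = 2
    start_offset: int = 0
    stop_day: int | None = None
    gap_prob: float = 0.0
    gap_range: tuple[int, int] = (45, 120)

    def __post_init__(self) -> None:
        if any(d < 1 for d in self.durations):
            raise ValueError("true supply durations must be >= 1 day")
        if self.refill_jitter < 0:
            raise ValueError("refill_jitter must be >= 0")
        if self.start_offset < 0:
            raise ValueError("start_offset must be >= 0")


@dataclass(frozen=True)
class RegimenSpec:
    """A multi-product treatment pattern assigned to simulated patients."""

    name: str
    agents: tuple[AgentPlan, ...]

    def __post_init__(self) -> None:
        if not self.agents:
            raise ValueError("a regimen needs at least one agent")


@dataclass
class SyntheticRegister:
    """A generated register plus everything needed to audit the method."""

    records: list[PrescriptionRecord]
    index_dates: dict[str, date]
    coverage: dict[str, dict[str, set[int]]]  # patient -> product -> true supply days
    censoring: list[CensoringRecord]
    fdc_map: dict[str, frozenset[str]]
    eligible: set[str]  # patients intended to survive the cohort filters
    regimen_by_patient: dict[str, str]

    @property
    def censor_days(self) -> dict[str, int]:
        return {c.patient_id: c.censor_day for c in self.censoring}


DEFAULT_FDC_MAP: dict[str, frozenset[str]] = {
    # perindopril/amlodipine fixed-dose product
    "C09BB04": frozenset({"C09AA04", "C08CA01"}),
}


def default_regimen_mix() -> list[tuple[RegimenSpec, float]]:
    """The study conditions the generator emulates by default.

    A mix of mono to quadruple antihypertensive regimens built from the
    drugs that dominate first-line use in the emulated setting
    (thiazide+potassium C03AB01, amlodipine C08CA01, enalapril C09AA02,
    ramipril C09AA05, losartan C09CA01) plus one fixed-dose product
    (C09BB04 = perindopril/amlodipine). Pack sizes of roughly one and three
    months, a few days of refill jitter, staggered add-on starts, some
    discontinuation, and adherence gaps of 45-120 days that exceed the
    30-day permissible gap.
    """
    thz = AgentPlan("C03AB01", (30, 100), (0.7, 0.3), refill_jitter=4, gap_prob=0.15)
    aml = AgentPlan("C08CA01", (30, 100), (0.7, 0.3), refill_jitter=4, gap_prob=0.10)
    ena = AgentPlan("C09AA02", (30, 100), (0.6, 0.4), refill_jitter=5,
                    start_offset=45, stop_day=500, gap_prob=0.15)
    ram = AgentPlan("C09AA05", (30,), refill_jitter=3, start_offset=150,
                    stop_day=600, gap_prob=0.20)
    los = AgentPlan("C09CA01", (28, 98), (0.7, 0.3), refill_jitter=3,
                    start_offset=90, gap_prob=0.10)
    fdc = AgentPlan("C09BB04", (30, 100), (0.8, 0.2), refill_jitter=3,
                    start_offset=60, gap_prob=0.10)
    aml30 = AgentPlan("C08CA01", (30, 100), (0.7, 0.3), refill_jitter=4,
                      start_offset=30, gap_prob=0.10)
    ena60 = AgentPlan("C09AA02", (30, 100), (0.6, 0.4), refill_jitter=5,
                      start_offset=60, gap_prob=0.15)
    los200 = AgentPlan("C09CA01", (28, 98), (0.7, 0.3), refill_jitter=3,
                       start_offset=200, stop_day=650, gap_prob=0.10)
    return [
        (RegimenSpec("mono", (thz,)), 0.12),
        (RegimenSpec("dual-thz-aml", (thz, aml)), 0.22),
        (RegimenSpec("dual-thz-ena", (thz, ena)), 0.18),
        (RegimenSpec("dual-aml-los", (aml, los)), 0.12),
        (RegimenSpec("triple", (thz, aml30, ram)), 0.14),
        (RegimenSpec("dual-thz-fdc", (thz, fdc)), 0.12),
        (RegimenSpec("quad", (thz, aml, ena60, los200)), 0.10),
    ]


def generate_register(
    n_patients: int,
    regimen_mix: Sequence[tuple[RegimenSpec, float]] | None = None,
    *,
    config: StudyConfig | None = None,
    seed: int = 0,
    fdc_map: Mapping[str, frozenset[str]] | None = None,
    decoy_washout_frac: float = 0.05,
    decoy_post_followup_frac: float = 0.05,
    censor_frac: float = 0.05,
) -> SyntheticRegister:
    """Generate a reproducible synthetic redemption register with ground truth.

    Decoy washout violators receive an extra study-drug redemption inside
    their washout window (placed before the enrollment window so it cannot
    itself become an index date); decoy late redemptions fall beyond the
    follow-up window and must be dropped by the day-index transform.
    Censored patients redeem nothing on or after their censor day and their
    true coverage is truncated accordingly.
    """
    if regimen_mix is None:
        regimen_mix = default_regimen_mix()
    if not regimen_mix:
        raise ValueError("regimen mix must not be empty")
    config = config or StudyConfig()
    fdc_map = dict(fdc_map) if fdc_map is not None else dict(DEFAULT_FDC_MAP)
    rng = np.random.default_rng(seed)

    specs = [spec for spec, _ in regimen_mix]
    weights = np.array([w for _, w in regimen_mix], dtype=float)
    if np.any(weights <= 0):
        raise ValueError("regimen weights must be positive")
    weights /= weights.sum()

    enroll_lo, enroll_hi = config.enrollment_window
    span = (enroll_hi - enroll_lo).days
    followup = config.followup_days

    records: list[PrescriptionRecord] = []
    index_dates: dict[str, date] = {}
    coverage: dict[str, dict[str, set[int]]] = {}
    censoring: list[CensoringRecord] = []
    eligible: set[str] = set()
    regimen_by_patient: dict[str, str] = {}

    for i in range(n_patients):
        pid = f"P{i:05d}"
        is_washout_decoy = rng.random() < decoy_washout_frac
        if is_washout_decoy:
            # early-1996 index so the decoy redemption lands in the pre-window year
            index = enroll_lo + timedelta(days=int(rng.integers(0, 180)))
        else:
            index = enroll_lo + timedelta(days=int(rng.integers(0, span + 1)))
        spec = specs[int(rng.choice(len(specs), p=weights))]
        regimen_by_patient[pid] = spec.name
        index_dates[pid] = index

        censor_day: int | None = None
        if rng.random() < censor_frac:
            censor_day = int(rng.integers(30, followup))
            cause = "death" if rng.random() < 0.5 else "emigration"
            censoring.append(CensoringRecord(pid, censor_day, cause))
        last_day = followup - 1 if censor_day is None else censor_day - 1

        patient_cov: dict[str, set[int]] = {}
        for plan in spec.agents:
            days_covered = patient_cov.setdefault(plan.atc, set())
            stop = followup if plan.stop_day is None else min(plan.stop_day, followup)
            t = plan.start_offset
            while t <= last_day and t < stop:
                duration = int(
                    rng.choice(plan.durations, p=plan.duration_weights)
                    if len(plan.durations) > 1
                    else plan.durations[0]
                )
                records.append(PrescriptionRecord(pid, index + timedelta(days=t), plan.atc))
                days_covered.update(range(t, min(t + duration - 1, last_day) + 1))
                step = duration
                if plan.refill_jitter:
                    step += int(rng.integers(-plan.refill_jitter, plan.refill_jitter + 1))
                if plan.gap_prob and rng.random() < plan.gap_prob:
                    step += int(rng.integers(plan.gap_range[0], plan.gap_range[1] + 1))
                t += max(1, step)
        coverage[pid] = patient_cov

        if is_washout_decoy:
            # a study-drug redemption inside the washout window, pre-enrollment
            min_back = (index - enroll_lo).days + 1
            back = int(rng.integers(min_back, config.washout_days))
            records.append(
                PrescriptionRecord(pid, index - timedelta(days=back), spec.agents[0].atc)
            )
        else:
            eligible.add(pid)

        # post-follow-up decoys only for non-washout-decoys: a late redemption
        # >= washout_days after a censored decoy's last one would legitimately
        # re-qualify the patient as a new user at that date
        if not is_washout_decoy and rng.random() < decoy_post_followup_frac:
            extra = followup + int(rng.integers(1, 90))
            records.append(
                PrescriptionRecord(pid, index + timedelta(days=extra), spec.agents[0].atc)
            )

    records = sorted(set(records))
    log.info(
        "synthetic register: %d patients (%d eligible), %d records",
        n_patients, len(eligible), len(records),
    )
    return SyntheticRegister(
        records=records,
        index_dates=index_dates,
        coverage=coverage,
        censoring=censoring,
        fdc_map=fdc_map,
        eligible=eligible,
        regimen_by_patient=regimen_by_patient,
    )


# ---------------------------------------------------------------------------
# Brute-force day-resolution oracle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OracleResult:
    """Day-enumeration truth for one patient."""

    day_set: frozenset[int]
    episodes: tuple[tuple[int, int], ...]
    agents_by_day: Mapping[int, frozenset[str]] = field(default_factory=dict, compare=False)

    @property
    def total_days(self) -> int:
        return len(self.day_set)


def coverage_from_episodes(
    episodes: Iterable[TreatmentEpisode],
) -> dict[str, set[int]]:
    """Expand treatment episodes into per-product covered-day sets."""
    cov: dict[str, set[int]] = {}
    for ep in episodes:
        cov.setdefault(ep.atc_code, set()).update(range(ep.start_day, ep.end_day + 1))
    return cov


def day_level_oracle(
    coverage_by_product: Mapping[str, set[int]],
    fdc_map: Mapping[str, frozenset[str]] | None = None,
    *,
    include_fdc_alone: bool = True,
) -> OracleResult:
    """Brute-force co-exposure by literal day enumeration.

    A day is co-exposed iff at least two distinct agents (fixed-dose
    components expanded) cover it; when ``include_fdc_alone`` is false a day
    covered by a single product only is never co-exposed, even if that
    product is a multi-component FDC. Contiguous runs of co-exposed days
    form the oracle episodes.
    """
    fdc_map = fdc_map or {}
    agents_by_day: dict[int, set[str]] = {}
    products_by_day: dict[int, int] = {}
    for product, days in coverage_by_product.items():
        agents = fdc_map.get(product, frozenset({product}))
        for day in days:
            agents_by_day.setdefault(day, set()).update(agents)
            products_by_day[day] = products_by_day.get(day, 0) + 1

    qualifying: list[int] = []
    kept_agents: dict[int, frozenset[str]] = {}
    for day, agents in agents_by_day.items():
        if len(agents) < 2:
            continue
        if products_by_day[day] < 2 and not include_fdc_alone:
            continue
        qualifying.append(day)
        kept_agents[day] = frozenset(agents)

    qualifying.sort()
    episodes: list[tuple[int, int]] = []
    for day in qualifying:
        if episodes and day == episodes[-1][1] + 1:
            episodes[-1] = (episodes[-1][0], day)
        else:
            episodes.append((day, day))
    return OracleResult(frozenset(qualifying), tuple(episodes), kept_agents)


# ---------------------------------------------------------------------------
# Accuracy evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AccuracyResult:
    percent_correct: float
    n_sampled: int
    n_correct: int
    discrepancies: tuple[tuple[str, tuple, tuple], ...]  # (patient, method, oracle)


def evaluate_accuracy(
    method_episodes: Mapping[str, Sequence],
    oracle_episodes: Mapping[str, Sequence[tuple[int, int]]],
    eligible_patients: Iterable[str],
    *,
    sample_size: int = 400,
    seed: int = 0,
) -> AccuracyResult:
    """Percentage of sampled patients with exactly correct start AND end dates.

    Draws ``sample_size`` patients uniformly without replacement (seeded)
    from the eligible population; a patient is correct iff the method's
    final-episode boundary list equals the oracle's exactly (including both
    being empty). When fewer eligible patients exist than requested, all are
    evaluated with a warning.
    """
    pool = sorted(eligible_patients)
    if not pool:
        raise ValueError("no eligible patients to evaluate")
    rng = np.random.default_rng(seed)
    if len(pool) < sample_size:
        log.warning(
            "only %d eligible patients (< sample size %d): evaluating all",
            len(pool), sample_size,
        )
        sample = pool
    else:
        sample = [pool[j] for j in rng.choice(len(pool), size=sample_size, replace=False)]

    discrepancies: list[tuple[str, tuple, tuple]] = []
    for pid in sample:
        method = tuple(
            (ep.start_day, ep.end_day) for ep in method_episodes.get(pid, ())
        )
        truth = tuple(oracle_episodes.get(pid, ()))
        if method != truth:
            discrepancies.append((pid, method, truth))
    n_correct = len(sample) - len(discrepancies)
    return AccuracyResult(
        percent_correct=100.0 * n_correct / len(sample),
        n_sampled=len(sample),
        n_correct=n_correct,
        discrepancies=tuple(discrepancies),
    )
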