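"""End-to-end orchestration: register -> cohort -> durations -> episodes -> co-exposure."""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .cohort import apply_censoring, identify_new_users
from .episodes import build_episodes
from .io import normalize_records, to_relative_days
from .model import (
    CensoringRecord,
    CoExposurePeriod,
    FinalCoExposureEpisode,
    MedicationEvent,
    PrescriptionRecord,
    StudyConfig,
    TreatmentEpisode,
)
from .overlap import patient_co_exposure
from .see import SEEModel, assign_durations, compute_waiting_times, fit_see
from .simulate import (
    AccuracyResult,
    coverage_from_episodes,
    day_level_oracle,
    evaluate_accuracy,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """All per-stage artifacts of one pipeline run."""

    config: StudyConfig
    index_dates: dict[str, date]
    models: dict[str, SEEModel]
    events: dict[tuple[str, str], list[MedicationEvent]]
    episodes: dict[tuple[str, str], list[TreatmentEpisode]]
    periods: dict[str, list[CoExposurePeriod]]
    final_episodes: dict[str, list[FinalCoExposureEpisode]]
    fdc_map: dict[str, frozenset[str]] = field(default_factory=dict)
    n_records_in: int = 0
    n_dropped_pre_index: int = 0
    n_dropped_post_followup: int = 0

    def episodes_by_patient(self) -> dict[str, dict[str, list[TreatmentEpisode]]]:
        out: dict[str, dict[str, list[TreatmentEpisode]]] = {}
        for (pid, atc), eps in self.episodes.items():
            if eps:
                out.setdefault(pid, {})[atc] = eps
        return out

    def all_periods(self) -> list[CoExposurePeriod]:
        return [p for periods in self.periods.values() for p in periods]

    # -- tabular views -------------------------------------------------
    def events_frame(self) -> pd.DataFrame:
        rows = [
            (e.patient_id, e.atc_code, e.start_day, e.duration_days, e.end_day)
            for evs in self.events.values() for e in evs
        ]
        return pd.DataFrame(
            rows, columns=["patient_id", "atc", "start_day", "duration_days", "end_day"]
        )

    def episodes_frame(self) -> pd.DataFrame:
        rows = [
            (ep.patient_id, ep.atc_code, ep.episode_index, ep.start_day, ep.end_day, ep.n_events)
            for eps in self.episodes.values() for ep in eps
        ]
        return pd.DataFrame(
            rows,
            columns=["patient_id", "atc", "episode_index", "start_day", "end_day", "n_events"],
        )

    def periods_frame(self) -> pd.DataFrame:
        rows = [
            (p.patient_id, ";".join(p.agent_set), p.start_day, p.end_day, p.n_days)
            for p in self.all_periods()
        ]
        return pd.DataFrame(
            rows, columns=["patient_id", "agent_set", "start_day", "end_day", "n_days"]
        )

    def final_frame(self) -> pd.DataFrame:
        rows = [
            (f.patient_id, f.start_day, f.end_day, f.total_days)
            for finals in self.final_episodes.values() for f in finals
        ]
        return pd.DataFrame(rows, columns=["patient_id", "start_day", "end_day", "total_days"])

    def write_csvs(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.events_frame().to_csv(out / "events.csv", index=False)
        self.episodes_frame().to_csv(out / "episodes.csv", index=False)
        self.periods_frame().to_csv(out / "periods.csv", index=False)
        self.final_frame().to_csv(out / "final_episodes.csv", index=False)
        pd.DataFrame(
            sorted(self.index_dates.items()), columns=["patient_id", "index_date"]
        ).to_csv(out / "cohort.csv", index=False)


def fit_models(
    relative_records: Iterable[tuple[str, str, int]],
    config: StudyConfig,
) -> dict[str, SEEModel]:
    """Fit one SEE model per product from pooled waiting times."""
    by_atc: dict[str, list[tuple[str, int]]] = {}
    for pid, atc, day in relative_records:
        by_atc.setdefault(atc, []).append((pid, day))
    models: dict[str, SEEModel] = {}
    for atc, rows in sorted(by_atc.items()):
        waits = compute_waiting_times(sorted(rows))
        models[atc] = fit_see(
            waits,
            trim_percentile=config.trim_percentile,
            k_range=(config.k_min, config.k_max),
            duration_statistic=config.duration_statistic,
            default_duration_days=config.default_duration_days,
            atc_code=atc,
        )
    return models


def run_pipeline(
    records: Sequence[PrescriptionRecord],
    config: StudyConfig | None = None,
    *,
    fdc_map: Mapping[str, frozenset[str]] | None = None,
    censoring: Mapping[str, int] | Iterable[CensoringRecord] | None = None,
    birthdates: Mapping[str, date] | None = None,
    index_dates: Mapping[str, date] | None = None,
) -> PipelineResult:
    """Run the full co-exposure assessment on a redemption register.

    Cohort construction (new-user washout + optional age filter) can be
    bypassed by passing precomputed ``index_dates``. Censoring may be given
    as records or as a ``patient -> censor_day`` mapping.
    """
    config = config or StudyConfig()
    fdc_map = dict(fdc_map or {})
    records = normalize_records(records)

    if index_dates is None:
        index_dates = identify_new_users(records, config, birthdates)
    index_dates = dict(index_dates)

    in_cohort = [r for r in records if r.patient_id in index_dates]
    pre_index = [r for r in in_cohort if r.redemption_date < index_dates[r.patient_id]]
    retained = [r for r in in_cohort if r.redemption_date >= index_dates[r.patient_id]]
    if pre_index:
        log.info("dropped %d pre-index redemptions during cohort construction", len(pre_index))
    relative, n_late = to_relative_days(retained, index_dates, config.followup_days)

    models = fit_models(relative, config)

    by_patient_drug: dict[tuple[str, str], list[int]] = {}
    for pid, atc, day in sorted(relative):
        by_patient_drug.setdefault((pid, atc), []).append(day)

    events: dict[tuple[str, str], list[MedicationEvent]] = {}
    episodes: dict[tuple[str, str], list[TreatmentEpisode]] = {}
    if censoring is None:
        censor_days: Mapping[str, int] = {}
    elif isinstance(censoring, Mapping):
        censor_days = censoring
    else:
        censor_days = {c.patient_id: c.censor_day for c in censoring}

    for (pid, atc), days in by_patient_drug.items():
        if atc not in models:
            raise KeyError(f"no fitted duration model for ATC {atc}")
        evs = assign_durations(pid, atc, days, models[atc], assignment=config.see_assignment)
        events[(pid, atc)] = evs
        eps = build_episodes(evs, config.permissible_gap_days, config.followup_days)
        episodes[(pid, atc)] = apply_censoring(eps, censor_days, config.followup_days)

    periods: dict[str, list[CoExposurePeriod]] = {}
    finals: dict[str, list[FinalCoExposureEpisode]] = {}
    by_patient: dict[str, dict[str, list[TreatmentEpisode]]] = {}
    for (pid, atc), eps in episodes.items():
        if eps:
            by_patient.setdefault(pid, {})[atc] = eps
    for pid in index_dates:
        per_product = by_patient.get(pid, {})
        patient_periods, patient_finals = patient_co_exposure(
            per_product, fdc_map, include_fdc_alone=config.count_fdc_alone
        )
        periods[pid] = patient_periods
        finals[pid] = patient_finals

    log.info(
        "pipeline: %d records in, %d patients indexed, %d products modelled, "
        "%d patients with co-exposure",
        len(records), len(index_dates), len(models),
        sum(1 for f in finals.values() if f),
    )
    return PipelineResult(
        config=config,
        index_dates=index_dates,
        models=models,
        events=events,
        episodes=episodes,
        periods=periods,
        final_episodes=finals,
        fdc_map=fdc_map,
        n_records_in=len(records),
        n_dropped_pre_index=len(pre_index),
        n_dropped_post_followup=n_late,
    )


def multi_agent_patients(result: PipelineResult) -> set[str]:
    """Patients who redeemed more than one distinct agent during follow-up.

    Fixed-dose products count with their component multiplicity, so a
    patient on a single two-component FDC qualifies when FDC-alone
    co-exposure is being counted.
    """
    out: set[str] = set()
    agents_by_patient: dict[str, set[str]] = {}
    for (pid, atc), evs in result.events.items():
        if not evs:
            continue
        agents = result.fdc_map.get(atc, frozenset({atc}))
        agents_by_patient.setdefault(pid, set()).update(agents)
        if len(agents) >= 2 and result.config.count_fdc_alone:
            out.add(pid)
    out.update(pid for pid, agents in agents_by_patient.items() if len(agents) >= 2)
    return out


def validate_against_oracle(
    result: PipelineResult,
    *,
    mode: str = "episode",
    truth_coverage: Mapping[str, Mapping[str, set[int]]] | None = None,
    censor_days: Mapping[str, int] | None = None,
    sample_size: int = 400,
    seed: int = 0,
) -> AccuracyResult:
    """Audit the interval method against the brute-force day oracle.

    ``episode`` mode enumerates days from the method's own treatment
    episodes, isolating the overlap algebra; ``truth`` mode enumerates the
    generator's true supply days (requires ``truth_coverage``), auditing the
    whole chain including duration estimation. Patients eligible for
    sampling are those who redeemed more than one agent.
    """
    if mode not in ("episode", "truth"):
        raise ValueError("mode must be 'episode' or 'truth'")
    eligible = multi_agent_patients(result)
    oracle_eps: dict[str, tuple[tuple[int, int], ...]] = {}
    if mode == "episode":
        for pid, per_product in result.episodes_by_patient().items():
            cov = coverage_from_episodes(ep for eps in per_product.values() for ep in eps)
            oracle_eps[pid] = day_level_oracle(
                cov, result.fdc_map, include_fdc_alone=result.config.count_fdc_alone
            ).episodes
    else:
        if truth_coverage is None:
            raise ValueError("truth mode requires truth_coverage")
        followup = result.config.followup_days
        censor_days = censor_days or {}
        for pid in eligible:
            last = min(censor_days.get(pid, followup), followup) - 1
            cov = {
                atc: {d for d in days if 0 <= d <= last}
                for atc, days in truth_coverage.get(pid, {}).items()
            }
            oracle_eps[pid] = day_level_oracle(
                cov, result.fdc_map, include_fdc_alone=result.config.count_fdc_alone
            ).episodes
    return evaluate_accuracy(
        result.final_episodes, oracle_eps, eligible, sample_size=sample_size, seed=seed
    )
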