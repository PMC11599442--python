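"""Sessa Empirical Estimator (SEE): data-driven prescription-duration assignment.

The SEE assigns each redemption a supply duration estimated from the
empirical distribution of refill waiting times of the same product, pooled
across patients:

1. compute waiting times between consecutive redemptions of one product
   within one patient;
2. discard waiting times above a trim percentile (default 80th) to remove
   gaps that reflect discontinuation rather than supply;
3. cluster the retained waiting times (1-D k-means, k selected by maximum
   mean silhouette over a configured range) so that products dispensed in
   several pack sizes resolve into one cluster per typical supply;
4. assign each medication event the configured statistic (default median) of
   the cluster containing its waiting time; events without a usable waiting
   time (the last redemption, or a waiting time above the trim bound)
   receive the fallback duration, the same statistic over all retained
   waiting times.

Clustering is fully deterministic: centers are initialized from evenly
spaced quantiles of the retained waiting times, a single k-means run with a
fixed iteration cap is used (no random restarts), and the silhouette
subsample (used only for very large registers) has a fixed random state.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Hashable, Iterable, Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .model import MedicationEvent

log = logging.getLogger(__name__)

_SILHOUETTE_SAMPLE = 2000


@dataclass(frozen=True)
class SEECluster:
    """One waiting-time cluster; bounds are half-open ``(lower, upper]`` days."""

    cluster_id: int
    lower_bound_days: float
    upper_bound_days: float
    assigned_duration_days: int
    n_members: int


@dataclass(frozen=True)
class SEEModel:
    """Fitted per-product duration-assignment rule.

    ``clusters`` partition ``(0, trim_bound_days]``; any waiting time above
    the trim bound, and any event without a waiting time, maps to
    ``fallback_duration_days``.
    """

    atc_code: str
    trim_bound_days: float
    clusters: tuple[SEECluster, ...]
    fallback_duration_days: int
    n_waiting_times: int = 0

    def duration_for(self, waiting_time: float | None) -> int:
        """Duration assigned to an event whose next refill is ``waiting_time`` days away."""
        if waiting_time is None or waiting_time > self.trim_bound_days or not self.clusters:
            return self.fallback_duration_days
        for cluster in self.clusters:
            if cluster.lower_bound_days < waiting_time <= cluster.upper_bound_days:
                return cluster.assigned_duration_days
        return self.fallback_duration_days  # pragma: no cover - partition covers (0, bound]


def compute_waiting_times(
    redemptions: Iterable[tuple[Hashable, int]],
) -> list[int]:
    """Waiting times between consecutive same-patient redemptions of one product.

    ``redemptions`` is a sequence of ``(patient_id, day)`` sorted by patient
    then day, with same-day duplicates already collapsed. Patients with a
    single redemption contribute nothing; every returned gap is >= 1.
    """
    waits: list[int] = []
    prev_patient: Hashable = object()
    prev_day = 0
    for patient, day in redemptions:
        if patient == prev_patient:
            gap = day - prev_day
            if gap <= 0:
                raise ValueError(
                    f"redemptions for patient {patient!r} are unsorted or duplicated "
                    f"(days {prev_day}, {day})"
                )
            waits.append(gap)
        prev_patient, prev_day = patient, day
    return waits


def _statistic(values: np.ndarray, kind: str) -> float:
    if kind == "median":
        return float(np.median(values))
    if kind == "mean":
        return float(np.mean(values))
    raise ValueError(f"unknown duration statistic {kind!r}")


def _round_duration(x: float) -> int:
    return max(1, int(math.floor(x + 0.5)))


def fit_see(
    waiting_times: Sequence[int] | np.ndarray,
    *,
    trim_percentile: float = 0.8,
    k_range: tuple[int, int] = (2, 10),
    duration_statistic: str = "median",
    default_duration_days: int = 30,
    atc_code: str = "",
) -> SEEModel:
    """Fit a SEE duration model from pooled waiting times of one product.

    Waiting times strictly above the empirical ``trim_percentile`` quantile
    are discarded; the rest are clustered with 1-D k-means, choosing k within
    ``k_range`` by maximum mean silhouette (k = 1 when fewer than two
    distinct values remain). Cluster boundaries are midpoints between
    adjacent cluster extremes, so the model maps any waiting time in
    ``(0, trim bound]`` to exactly one cluster.
    """
    if not (0 < trim_percentile <= 1):
        raise ValueError("trim_percentile must be in (0, 1]")
    wts = np.asarray(list(waiting_times), dtype=float)
    if wts.size == 0:
        log.warning(
            "no waiting times for %s: falling back to default duration %d d",
            atc_code or "<product>", default_duration_days,
        )
        return SEEModel(atc_code, 0.0, (), default_duration_days, 0)
    bound = float(np.quantile(wts, trim_percentile))
    kept = wts[wts <= bound]
    fallback = _round_duration(_statistic(kept, duration_statistic))
    distinct = np.unique(kept)

    if distinct.size < 2:
        clusters = (
            SEECluster(0, 0.0, bound, _round_duration(float(distinct[0])), int(kept.size)),
        )
        return SEEModel(atc_code, bound, clusters, fallback, int(kept.size))

    labels = _cluster_1d(kept, k_range)
    order = np.argsort([kept[labels == lab].mean() for lab in np.unique(labels)])
    groups = [kept[labels == lab] for lab in np.unique(labels)[order]]

    clusters: list[SEECluster] = []
    lower = 0.0
    for i, members in enumerate(groups):
        upper = bound if i == len(groups) - 1 else (members.max() + groups[i + 1].min()) / 2.0
        clusters.append(
            SEECluster(
                cluster_id=i,
                lower_bound_days=lower,
                upper_bound_days=float(upper),
                assigned_duration_days=_round_duration(_statistic(members, duration_statistic)),
                n_members=int(members.size),
            )
        )
        lower = float(upper)
    return SEEModel(atc_code, bound, tuple(clusters), fallback, int(kept.size))


def _cluster_1d(values: np.ndarray, k_range: tuple[int, int]) -> np.ndarray:
    """Deterministic 1-D k-means with silhouette-based choice of k."""
    distinct = np.unique(values)
    x = values.reshape(-1, 1)
    k_lo = max(1, k_range[0])
    k_hi = min(k_range[1], distinct.size)
    best_labels: np.ndarray | None = None
    best_score = -np.inf
    for k in range(max(2, k_lo), k_hi + 1):
        init = np.quantile(values, (2 * np.arange(k) + 1) / (2 * k)).reshape(-1, 1)
        if np.unique(init).size < k:
            # mass-concentrated data: space centers over distinct values instead
            idx = np.unique(np.round(np.linspace(0, distinct.size - 1, k)).astype(int))
            if idx.size < k:
                continue
            init = distinct[idx].reshape(-1, 1)
        km = KMeans(n_clusters=k, init=init, n_init=1, max_iter=100, random_state=0).fit(x)
        labels = km.labels_
        if np.unique(labels).size < 2:
            continue
        try:
            score = silhouette_score(
                x, labels,
                sample_size=min(_SILHOUETTE_SAMPLE, values.size),
                random_state=0,
            )
        except ValueError:  # subsample collapsed to one label
            continue
        if score > best_score + 1e-12:  # ties favor the smaller k
            best_score, best_labels = score, labels
    if best_labels is None:
        return np.zeros(values.size, dtype=int)
    return best_labels


def assign_durations(
    patient_id: str,
    atc_code: str,
    days: Sequence[int],
    model: SEEModel,
    *,
    assignment: str = "per_event",
) -> list[MedicationEvent]:
    """Turn one patient-product redemption sequence into medication events.

    With ``per_event`` assignment each redemption except the last receives
    the duration of the cluster containing its waiting time to the next
    redemption (fallback when the waiting time exceeds the trim bound); the
    final or only redemption receives the fallback. With ``per_drug`` every
    event receives the product-level fallback duration.
    """
    if assignment not in ("per_event", "per_drug"):
        raise ValueError("assignment must be 'per_event' or 'per_drug'")
    if any(b <= a for a, b in zip(days, days[1:])):
        raise ValueError(f"redemption days for {patient_id!r}/{atc_code} must be strictly increasing")
    events: list[MedicationEvent] = []
    for i, day in enumerate(days):
        if assignment == "per_drug" or i == len(days) - 1:
            duration = model.fallback_duration_days
        else:
            duration = model.duration_for(days[i + 1] - day)
        events.append(MedicationEvent(patient_id, atc_code, day, duration))
    return events
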