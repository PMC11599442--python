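# Methods

## Day grid and interval conventions

All exposure is represented on an integer day grid relative to each
patient's index date (day 0). Intervals are closed at both ends: an event
`[s, e]` covers `e − s + 1` days, two intervals overlap iff
`max(starts) ≤ min(ends)`, and the overlap length is
`min(ends) − max(starts) + 1`. The follow-up window is days
`0 .. followup_days − 1` (730 covered days by default), so "total coverage
≤ 730 days" is an assertable invariant. Whether published day counts treat
the index day as day 0 or day 1 is a convention, not something the data can
decide; here the index day is day 0 internally and maps to printed day 1 in
the stage definitions (early stage = internal days 0–179).

Same-day duplicate redemptions of one product are collapsed to a single
record: the register grain the method consumes is one redemption event, and
duplicates would double-count supply.

## Duration estimation (Sessa Empirical Estimator)

The SEE assigns durations from the empirical distribution of refill waiting
times, pooled across patients per product (per-patient distributions are
too sparse for a population-level empirical estimator). The concrete
variant is fixed and fully configurable:

| parameter | default | meaning |
|---|---|---|
| `trim_percentile` | 0.8 | waiting times above this empirical quantile are discarded as discontinuation gaps |
| `k_min .. k_max` | 2 .. 10 | k-means cluster range; k chosen by maximum mean silhouette (k = 1 when < 2 distinct values) |
| `duration_statistic` | median | per-cluster assigned duration and the fallback |
| `default_duration_days` | 30 | fallback when a product has no waiting times at all |
| `see_assignment` | per_event | each event takes its own cluster's duration; `per_drug` gives every event the product-level statistic |

Clustering is deterministic: centers initialized from evenly spaced
quantiles of the retained waiting times, one k-means run with a 100
iteration cap, no random restarts; the silhouette score subsamples at most
2,000 points with a fixed random state, so repeated runs give identical
models. Cluster boundaries are midpoints between adjacent cluster extremes,
partitioning `(0, trim bound]` so every in-bound waiting time maps to
exactly one cluster. The last (or only) redemption of a patient-product
sequence, and any event whose waiting time exceeds the trim bound, receives
the fallback duration.

Two numerical properties of this variant are worth knowing. First, the trim
is designed for registers in which a fraction of waiting times are
discontinuation gaps; on a *gap-free* register an 80th-percentile trim
necessarily clips the upper part of the largest-duration cluster and biases
its median low by a few days. Second, silhouette-based k-selection
degenerates on discrete (integer-day) data when the retained support has no
more distinct values than `k_max`: one-value-per-cluster partitions have
zero within-cluster distance and a silhouette near 1, so the model
fragments into per-integer clusters. The fragmentation is harmless for
duration *assignment* (each waiting time maps to approximately itself) but
changes the cluster table; with wider jitter it can move individual cluster
medians a day or two from the pack-size center.

## Treatment episodes

Events of one patient-product are merged with same-product carry-over: a
running coverage end `C` starts at the first event's end; an event at day
`t` with duration `d` joins the episode iff `t − C − 1 ≤ permissible_gap`
(a redemption the day after coverage ends is a 0-day gap) and updates
`C ← max(C, t − 1) + d`, so early refills push unused supply forward;
otherwise the episode closes at `min(C, followup − 1)` and a new one opens.
Carry-over accumulates without bound inside an episode, but visible
coverage is truncated at follow-up end. The construction is proven (by
property test) equal to a literal day-pouring simulation: pour each event's
supply day by day, shifting overlapping same-product supply forward, and
split coverage runs at supply-free gaps longer than the permissible gap.
Setting the gap to infinity collapses everything into one episode.
Cross-product carry-over is deliberately not supported.

## Co-exposure algebra

Free-dose co-exposure is the overlap of treatment episodes of distinct
products; one period per overlapping episode pair, labelled with the union
agent set. A fixed-dose combination product's episodes *are* co-exposure:
they pass through directly with the product's component agents, with no
overlap computation. Higher-order combinations are computed as the fixed
point of pairwise intersection of overlapping periods with differing agent
sets — equivalent to iterating over pairs but independent of iteration
order, which an iterative description leaves unspecified. Every emitted
k-agent interval is thus the exact intersection of all k member agents'
coverage. Same-agent-set periods are canonicalized (overlapping fragments
merged) because a free-dose product co-occurring with an FDC that contains
it would otherwise double-count days.

The final co-exposure episode merges all periods over day-adjacent
intervals ("no gaps" on a closed day grid means adjacency is continuity);
it never applies carry-over and a single uncovered day always separates
episodes. Whether a single FDC product alone counts as co-exposure is a
config switch (`count_fdc_alone`, default on, consistent with treating FDC
supply as co-exposure by definition).

Agent identity is the full-precision product code; FDC components are
expanded through a user-supplied map. Combination labels therefore name
active agents, not products.

## Cohort design

New users: a patient's index date is the first redemption inside the
enrollment window that matches a study-drug prefix and whose nearest prior
redemption is at least `washout_days` earlier (a redemption *exactly* 365
days before does not disqualify). An optional age filter requires the age
threshold to be reached for at least one day inside the study window.
Censoring truncates all intervals at `min(censor_day − 1, followup − 1)`.

Stages: early = internal days 0–179, late = 180–729. A combination is
*incident* in the stage containing its first co-exposed day; its per-stage
duration is the day count clipped to that stage's window (early-stage
durations are therefore ≤ 180). Per-combination tables report incident
patient counts, the percentage among all patients co-exposed at any point
of the stage, and median (Q1–Q3) durations with quartiles by linear
interpolation between order statistics (stated so tests are exact). Ranking
is by descending count with lexicographic tie-break. Multiplicity is the
size of the largest agent set with ≥ 1 co-exposed day in the stage.
Calendar timelines bin patients by index year (default five groups covering
1996–2018) and rank the top 5 incident combinations per bin and stage.
Every emitted count below `min_cell_size` (default 5) is masked as `"<5"`,
and masked combinations are excluded from timeline rankings.

## Synthetic registers and what passing tests show

The generator emulates a redemption register: per-patient refill sequences
with product-specific pack-size mixes (one- and three-month supplies),
uniform refill jitter of a few days, staggered add-on starts,
discontinuations, injected adherence gaps of 45–120 days (long enough to
split episodes under the 30-day permissible gap), one fixed-dose product,
5% censoring, and two decoy classes exercised by the cohort filters:
washout violators (an extra redemption inside the washout window, placed
before the enrollment window so it cannot itself become an index) and
redemptions beyond the follow-up window. Ground truth records the true
supply days of every product per patient. The default validation register
has 600 patients; the large oracle-equivalence suite uses 1,100; the
duration-recovery register uses 40 single-product regimens with pack sizes
{28, 84}, jitter of one day, and an 8% discontinuation-gap rate with gaps
of 150–400 days, so the 0.8 trim discards gaps rather than supply. These
sizes keep the full suite under a minute while exercising every code path.

The oracle runs in two modes. *Episode mode* enumerates days from the
method's own treatment episodes and is the validation criterion: it audits
the overlap algebra (Steps 2–3) in isolation, which is what a manual audit
of plotted medication events checks. *Truth mode* enumerates the
generator's true supply days and audits the whole chain; because SEE
durations are statistical estimates, day-exact truth-mode agreement is not
expected and not a target. Passing episode-mode at 100% therefore shows the
interval algebra is exact, not that estimated durations equal true ones.
What the generator does not emulate: demographic structure, prescription
quantity/strength fields, dose changes, stockpiling behaviour correlated
across drugs, or calendar trends in drug popularity (the timeline test
constructs its own shifted mixes).

## Known limitations

- The SEE variant here is one concrete, documented choice among the
  published family; results are sensitive to the trim percentile when the
  waiting-time distribution has little mass above the true durations.
- Silhouette k-selection on integer waiting times can fragment clusters
  when the retained support is small (see above).
- Quantity/DDD-based duration fallbacks are not implemented; products
  without refills fall back to a configured default duration.
- Percentage denominators in combination tables use all patients co-exposed
  in the stage; registers published with a different denominator convention
  will differ by a scale factor.
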