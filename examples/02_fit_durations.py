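"""Estimate prescription supply durations from refill waiting times (SEE).

A product dispensed in one-month and three-month packs produces a bimodal
waiting-time distribution; the estimator trims long discontinuation gaps,
clusters the rest, and assigns each redemption the median duration of its
cluster.
"""
import numpy as np

from coexpose import assign_durations, compute_waiting_times, fit_see

rng = np.random.default_rng(0)
# two patients alternating 28- and 84-day packs, with one long gap
redemptions = [("A", d) for d in np.cumsum([0, 28, 29, 84, 27, 200])]
redemptions += [("B", d) for d in np.cumsum([0, 84, 83, 28, 85])]

waits = compute_waiting_times(redemptions)
print("waiting times:", waits)

model = fit_see(waits, trim_percentile=0.8, atc_code="C09AA02")
print(f"trim bound: {model.trim_bound_days:.0f} d "
      f"(gaps above this are treated as discontinuation)")
for c in model.clusters:
    print(f"  cluster {c.cluster_id}: waits in ({c.lower_bound_days:.0f}, "
          f"{c.upper_bound_days:.0f}] d -> assigned duration {c.assigned_duration_days} d "
          f"({c.n_members} waits)")
print("fallback duration (last redemptions, out-of-bound gaps):",
      model.fallback_duration_days, "d")

events = assign_durations("A", "C09AA02", [0, 28, 57, 141, 168, 368], model)
for e in events:
    print(f"  redemption day {e.start_day:>3} -> covered [{e.start_day}, {e.end_day}]")
# The day-368 redemption follows a 200-day gap: its predecessor falls back to
# the overall median rather than inheriting an implausible 200-day supply.
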