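"""Cohort-level summaries: combination tables, multiplicity, calendar timelines.

Runs the pipeline on a synthetic register and prints the early-stage top
combinations with median (Q1-Q3) durations, the multiplicity histogram, and
the top combinations per calendar period - all with small-cell suppression.
"""
from coexpose import (
    StudyConfig,
    generate_register,
    multiplicity_counts,
    summarize_combinations,
    timeline_top_combinations,
)
from coexpose.pipeline import run_pipeline

config = StudyConfig()
register = generate_register(600, seed=20240101)
result = run_pipeline(register.records, config,
                      fdc_map=register.fdc_map, censoring=register.censoring)
periods = result.all_periods()
kwargs = dict(early_end=config.early_stage_end_day, followup_days=config.followup_days)

print("top 5 incident combinations, early stage (days 1-180):")
table = summarize_combinations(periods, stage="early",
                               min_cell_size=config.min_cell_size, top_n=5, **kwargs)
for row in table.itertuples(index=False):
    print(f"  {row.label:<30} n={row.n_display:<5} "
          f"median {row.median_days:.0f} (Q1-Q3 {row.q1_days:.0f}-{row.q3_days:.0f}) d")

print("\npatients by largest concurrent combination, early stage:")
mult = multiplicity_counts(periods, stage="early", bucket_top=4,
                           min_cell_size=config.min_cell_size, **kwargs)
for row in mult.itertuples(index=False):
    print(f"  {row.multiplicity} agents: {row.n_display} patients "
          f"({row.pct_patients:.1f}%)")

print("\ntop combination per calendar period (early stage):")
timeline = timeline_top_combinations(periods, result.index_dates,
                                     bins=config.calendar_bins,
                                     min_cell_size=config.min_cell_size, **kwargs)
top1 = timeline[(timeline.stage == "early") & (timeline["rank"] == 1)]
for row in top1.itertuples(index=False):
    print(f"  {row.bin}: {row.label} (n={row.n_patients})")
# Counts below the minimum cell size are rendered "<5" and excluded from
# timeline rankings, mirroring register disclosure rules.
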