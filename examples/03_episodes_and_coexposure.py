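"""From medication events to treatment episodes to co-exposure periods.

Shows carry-over (an early refill extends coverage), the 30-day permissible
gap (a longer gap splits the episode), pairwise overlap, fixed-dose
expansion and the final gap-free co-exposure episode.
"""
from coexpose import MedicationEvent, build_episodes, patient_co_exposure

def events(atc, *pairs):
    return [MedicationEvent("P1", atc, s, d) for s, d in pairs]

# thiazide: early refill at day 20 carries 10 unused days forward;
# the day-120 refill follows a 60-day supply-free gap and starts a new episode
thz = build_episodes(events("C03AB01", (0, 30), (20, 30), (120, 100)), 30, 730)
for ep in thz:
    print(f"thiazide episode {ep.episode_index}: days [{ep.start_day}, {ep.end_day}] "
          f"({ep.n_events} redemptions)")

aml = build_episodes(events("C08CA01", (40, 100), (140, 100)), 30, 730)
fdc = build_episodes(events("C09BB04", (150, 100)), 30, 730)

periods, finals = patient_co_exposure(
    {"C03AB01": thz, "C08CA01": aml, "C09BB04": fdc},
    fdc_map={"C09BB04": frozenset({"C09AA04", "C08CA01"})},
)
print("\nco-exposure periods (agent sets with >= 2 agents):")
for p in sorted(periods, key=lambda p: (len(p.agent_set), p.start_day)):
    print(f"  {' + '.join(p.agent_set):<30} days [{p.start_day}, {p.end_day}] "
          f"= {p.n_days} d")
print("\nfinal gap-free co-exposure episodes:")
for f in finals:
    print(f"  [{f.start_day}, {f.end_day}] = {f.total_days} d")
# The FDC contributes its two components directly, so its overlap with the
# free-dose drugs yields three- and four-agent combinations.
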