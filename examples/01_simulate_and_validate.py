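"""Generate a synthetic redemption register and audit the method against the oracle.

Builds a 600-patient register of mixed antihypertensive regimens (including
one fixed-dose combination product and injected refill gaps), runs the full
co-exposure pipeline, and scores a 400-patient random sample against the
brute-force day-enumeration oracle.
"""
from coexpose import StudyConfig, generate_register
from coexpose.pipeline import run_pipeline, validate_against_oracle

register = generate_register(600, seed=20240101)
print(f"register: {len(register.records)} redemptions, "
      f"{len(register.eligible)} washout-clean patients")

result = run_pipeline(register.records, StudyConfig(),
                      fdc_map=register.fdc_map, censoring=register.censoring)
print(f"cohort: {len(result.index_dates)} new users, "
      f"{len(result.models)} products with fitted duration models")

accuracy = validate_against_oracle(result, mode="episode",
                                   sample_size=400, seed=20240101)
print(f"accuracy: {accuracy.percent_correct:.1f}% of {accuracy.n_sampled} sampled "
      f"patients have exactly correct co-exposure start and end dates")
# 100.0% means the interval algebra agrees with literal day enumeration on
# every sampled patient - the method's validation target.
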