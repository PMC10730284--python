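"""Generate a synthetic NIS-style discharge dataset with known ground truth.

The generator emulates a weighted, stratified, hospital-clustered discharge
sample under a configurable structural model race -> mediators -> treatment
-> outcomes, and records every coefficient it used.
"""

from egsdisparity import GeneratorConfig, generate_dataset

config = GeneratorConfig(n_discharges=20_000, n_hospitals=60, seed=7)
discharges, hospitals, truth = generate_dataset(config)

print(f"{len(discharges)} discharges across {len(hospitals)} hospitals "
      f"in {hospitals['stratum_id'].nunique()} design strata")
print("\nFirst rows:")
print(discharges[["record_id", "year", "age", "race_raw", "diagnosis_codes",
                  "procedure_codes", "los_days", "died", "discwt"]].head())
print("\nStructural black-vs-white effects used (link scale):")
print("  direct effects:", truth.direct_race_effects)
print("  race -> mediator shifts:", {k: v for k, v in truth.race_to_mediator.items() if v})
# Each row is one hospital stay: coded diagnoses (first = primary), day-
# stamped procedure codes, survey weights (discwt/trendwt) and the design
# identifiers (stratum, hospital) that drive all variance estimation.
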