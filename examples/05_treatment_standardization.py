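"""How much of the LOS disparity is carried by differential treatment?

Standardizes the black group's joint (age band x wait time x surgery type)
distribution to the white group's and reports the percent of the gap that
adjustment removes — the machinery behind 'X% of the LOS disparity is
explained by treatment differences'."""

import dataclasses

import numpy as np

from egsdisparity import (
    GeneratorConfig, SurveyDesign, build_cohort, generate_dataset,
    load_codemaps, standardize_for_treatment,
)

# a scenario where the whole LOS gap flows through longer waits for surgery
config = dataclasses.replace(
    GeneratorConfig(n_discharges=50_000, seed=3).null(),
    direct_race_effects={"any_surgery": 0.0, "surgery_delay": -1.0,
                         "died": 0.0, "los": 0.0},
)
discharges, _, _ = generate_dataset(config)
cohort = build_cohort(discharges, load_codemaps()["cholecystitis"])
operated = cohort.loc[cohort["any_surgery"] == 1].dropna(
    subset=["time_to_surgery"]).copy()
operated["tts_band"] = np.minimum(operated["time_to_surgery"], 10).astype(int)

res = standardize_for_treatment(
    operated, SurveyDesign(), ["tts_band", "surgery_category"])
print(f"age-adjusted LOS gap (black-white): {res.unadjusted.value:+.2f} days "
      f"(95% CI {res.unadjusted.ci_low:+.2f}..{res.unadjusted.ci_high:+.2f})")
print(f"after treatment standardization:    {res.adjusted.value:+.2f} days")
print(f"percent explained by treatment:     {res.percent_change:.0f}%")
# Because the generated gap flows entirely through the wait before surgery,
# standardizing for treatment removes essentially all of it (~100%).
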