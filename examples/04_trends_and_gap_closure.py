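"""Yearly disparity series with the trend weights, the simple-regression
trend test, and gap-closure extrapolation."""

from egsdisparity import (
    GeneratorConfig, SurveyDesign, build_cohort, build_series, fit_trend,
    generate_dataset, load_codemaps,
)

config = GeneratorConfig(
    n_discharges=60_000, seed=11,
    years=tuple(y for y in range(2005, 2018) if y != 2015),  # 2015 excluded
)
discharges, _, _ = generate_dataset(config)
cohort = build_cohort(discharges, load_codemaps()["cholecystitis"])

design = SurveyDesign(weight="trendwt")  # trendwt for across-year series
series = build_series(cohort, design, "any_surgery")
print("year  disparity (black-white, surgery share)  SE")
for _, row in series.table.iterrows():
    print(f"{int(row['year'])}  {row['disparity']:+.4f}  ({row['se']:.4f})")

fit = fit_trend(series)
print(f"\nOLS slope {fit.slope:+.5f} per year (SE {fit.slope_se:.5f}, "
      f"p={fit.p_value:.3f}) -> trend {fit.direction}")
if fit.years_to_closure is not None:
    print(f"years until the gap closes at this rate: {fit.years_to_closure:.1f}")
else:
    print("no closure extrapolation (gap not significantly shrinking)")
# Closure is |final-year disparity / slope|, reported only when the fitted
# slope is significant (p < 0.05) and opposes the sign of the final gap.
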