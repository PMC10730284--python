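"""Grouped difference-of-coefficients mediation for the LOS disparity.

Decomposes the total black-white effect into the unexplained (direct)
part, the unique contribution of each mediator group, and the overlap
attributable non-uniquely to several groups."""

from egsdisparity import (
    FactorGroups, GeneratorConfig, SurveyDesign, build_cohort,
    decompose, generate_dataset, load_codemaps,
)
from egsdisparity.workflow import prepare_mediation_frame

discharges, hospitals, _ = generate_dataset(
    GeneratorConfig(n_discharges=40_000, seed=7))
maps = load_codemaps()
design = SurveyDesign()
cohort = build_cohort(discharges, maps["cholecystitis"])
cohort, _, _ = prepare_mediation_frame(cohort, hospitals, design,
                                       maps["cholecystitis"])

dec = decompose(cohort, "los", FactorGroups(), design)
print(f"LOS disparity decomposition (log discharge-rate scale, n={dec.n_obs}):")
print(f"  total effect     {dec.total:+.4f}   "
      f"(discharge-per-day IRR {dec.ratios()['total']:.2f})")
print(f"  direct (unexplained) {dec.direct:+.4f}")
for g, u in dec.unique.items():
    print(f"  unique to {g:14s} {u:+.4f}")
print(f"  overlap (multi-attributable) {dec.overlap:+.4f}")
print(f"  additivity residual: {dec.additivity_residual():.1e}")
# total = direct + sum(unique) + overlap holds exactly on the link scale.
# An IRR below 1 means black patients are discharged at a lower daily rate,
# i.e. stay longer.  Treatment mediators are excluded automatically when
# the outcome is itself a treatment variable.
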