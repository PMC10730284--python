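# Illustrative diagnosis/procedure code map for six urgent abdominal diagnoses.
# The codes are a small ICD-9-style demonstration set matching the synthetic
# generator's output; real analyses supply their own map in this format.
#
# Per diagnosis:
#   primary_dx          - inclusion codes for the first-listed diagnosis
#   secondary_required  - if present, at least one of these codes must appear
#                         among the secondary diagnoses (e.g. gallstones for
#                         gallstone pancreatitis)
#   surgery             - definitive operative codes by invasiveness category
#                         (least / intermediate / most); categories are
#                         nominal, never ordered in computation
#   temporizing         - non-definitive interventions (drainage, ERCP, ...)
#   unusual             - procedure codes flagging unusual operative steps
#   comorbidities       - comorbidity-flag columns entering the crude
#                         excess-mortality score
appendicitis:
  primary_dx: ["540.0", "540.1", "540.9"]
  surgery:
    least: ["47.01", "47.09"]
    intermediate: ["47.11"]
    most: ["45.62"]
  temporizing: ["54.91"]
  unusual: ["54.59"]
  comorbidities: &cm
    chf: ["cm_chf"]
    diabetes: ["cm_diabetes"]
    renal: ["cm_renal"]
cholecystitis:
  primary_dx: ["575.0", "575.1", "575.12"]
  surgery:
    least: ["51.23", "51.22"]
    intermediate: ["51.21"]
    most: ["51.32"]
  temporizing: ["51.01", "51.10"]
  unusual: ["54.59"]
  comorbidities: *cm
gallstone_pancreatitis:
  primary_dx: ["577.0", "577.1", "577.2"]
  secondary_required: ["574.0", "574.2", "574.5"]
  surgery:
    least: ["51.23", "51.22"]
    intermediate: ["51.21"]
    most: ["52.6"]
  temporizing: ["51.10", "51.01"]
  unusual: ["54.59"]
  comorbidities: *cm
hernia:
  primary_dx: ["550.0", "550.1", "551.1", "552.21"]
  surgery:
    least: ["53.05"]
    intermediate: ["53.00"]
    most: ["45.62"]
  temporizing: ["96.07"]
  unusual: ["54.59"]
  comorbidities: *cm
obstruction:
  primary_dx: ["560.1", "560.81", "560.9"]
  surgery:
    least: ["54.59"]
    intermediate: ["46.01"]
    most: ["45.62", "45.79"]
  temporizing: ["96.08"]
  unusual: ["54.21"]
  comorbidities: *cm
perforation:
  primary_dx: ["569.83", "531.1", "532.1"]
  surgery:
    least: ["44.42"]
    intermediate: ["46.10"]
    most: ["45.62"]
  temporizing: ["54.91"]
  unusual: ["54.59"]
  comorbidities: *cm
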