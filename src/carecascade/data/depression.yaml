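# Bundled worked example: depression management in Australian general
# practice. Baseline is usual care; each intervention scenario improves a
# single filter (detection screening, GP training for treatment offer, or
# telephone adherence support) at a per-person cost. AUD throughout.
schema_version: 1
population:
  size: 15055403
  label: Australian population aged 18-75 years
steps:
  - label: target_group
    description: Point prevalence of current depression
    proportion: 0.089
  - label: attendance
    description: Attend a general practitioner at least once per year
    proportion: 0.81
  - label: detection
    description: Detected as at risk of depression by the GP
    proportion: 0.47
  - label: reach
    description: Offered evidence-based depression treatment
    proportion: 0.28
  - label: adherence
    description: Adhere to the offered treatment
    proportion: 0.51
  - label: remission
    description: Achieve remission at six-month follow-up
    proportion: 0.37
scenarios:
  baseline:
    baseline: true
    description: Usual care, no intervention
  filter1:
    description: Routine waiting-room depression screening (touchscreen)
    overrides:
      detection:
        proportion: 0.77
        unit_cost: 5
  filter2:
    description: GP education and training in depression management
    overrides:
      reach:
        proportion: 0.69
        unit_cost: 247
  filter3:
    description: Telephone follow-up to support treatment adherence
    overrides:
      adherence:
        proportion: 0.65
        unit_cost: 98
bounds:
  - scenario: filter1
    intervals:
      - step: detection
        parameter: proportion
        lower: 0.47
        upper: 0.77
report:
  currency_label: AUD
  rounding: true
  format: table
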