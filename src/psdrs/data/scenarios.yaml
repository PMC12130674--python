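# Canonical simulation scenario catalogue: 25 cells of the
# treatment-prevalence x sample-size x structure x outcome-risk grid.
scenarios:
- scenario_id: 1
  treatment_prevalence: 0.01
  outcome_risk: 0.5
  sample_size: 500
  structure: linear
- scenario_id: 2
  treatment_prevalence: 0.05
  outcome_risk: 0.5
  sample_size: 500
  structure: linear
- scenario_id: 3
  treatment_prevalence: 0.1
  outcome_risk: 0.5
  sample_size: 500
  structure: linear
- scenario_id: 4
  treatment_prevalence: 0.25
  outcome_risk: 0.5
  sample_size: 500
  structure: linear
- scenario_id: 5
  treatment_prevalence: 0.5
  outcome_risk: 0.5
  sample_size: 500
  structure: linear
- scenario_id: 6
  treatment_prevalence: 0.01
  outcome_risk: 0.5
  sample_size: 10000
  structure: linear
- scenario_id: 7
  treatment_prevalence: 0.05
  outcome_risk: 0.5
  sample_size: 10000
  structure: linear
- scenario_id: 8
  treatment_prevalence: 0.1
  outcome_risk: 0.5
  sample_size: 10000
  structure: linear
- scenario_id: 9
  treatment_prevalence: 0.25
  outcome_risk: 0.5
  sample_size: 10000
  structure: linear
- scenario_id: 10
  treatment_prevalence: 0.5
  outcome_risk: 0.5
  sample_size: 10000
  structure: linear
- scenario_id: 11
  treatment_prevalence: 0.01
  outcome_risk: 0.5
  sample_size: 500
  structure: nonlinear
- scenario_id: 12
  treatment_prevalence: 0.05
  outcome_risk: 0.5
  sample_size: 500
  structure: nonlinear
- scenario_id: 13
  treatment_prevalence: 0.1
  outcome_risk: 0.5
  sample_size: 500
  structure: nonlinear
- scenario_id: 14
  treatment_prevalence: 0.25
  outcome_risk: 0.5
  sample_size: 500
  structure: nonlinear
- scenario_id: 15
  treatment_prevalence: 0.5
  outcome_risk: 0.5
  sample_size: 500
  structure: nonlinear
- scenario_id: 16
  treatment_prevalence: 0.01
  outcome_risk: 0.5
  sample_size: 10000
  structure: nonlinear
- scenario_id: 17
  treatment_prevalence: 0.05
  outcome_risk: 0.5
  sample_size: 10000
  structure: nonlinear
- scenario_id: 18
  treatment_prevalence: 0.1
  outcome_risk: 0.5
  sample_size: 10000
  structure: nonlinear
- scenario_id: 19
  treatment_prevalence: 0.25
  outcome_risk: 0.5
  sample_size: 10000
  structure: nonlinear
- scenario_id: 20
  treatment_prevalence: 0.5
  outcome_risk: 0.5
  sample_size: 10000
  structure: nonlinear
- scenario_id: 21
  treatment_prevalence: 0.01
  outcome_risk: 0.02
  sample_size: 10000
  structure: nonlinear
- scenario_id: 22
  treatment_prevalence: 0.05
  outcome_risk: 0.02
  sample_size: 10000
  structure: nonlinear
- scenario_id: 23
  treatment_prevalence: 0.1
  outcome_risk: 0.02
  sample_size: 10000
  structure: nonlinear
- scenario_id: 24
  treatment_prevalence: 0.25
  outcome_risk: 0.02
  sample_size: 10000
  structure: nonlinear
- scenario_id: 25
  treatment_prevalence: 0.5
  outcome_risk: 0.02
  sample_size: 10000
  structure: nonlinear
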