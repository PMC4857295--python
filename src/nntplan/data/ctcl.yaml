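schema_version: 1
clinical_scenario: >
  Early-stage cutaneous T-cell lymphoma (CTCL). Most stage IA-IIA patients
  have slowly progressive disease and do well without aggressive therapy,
  but roughly 15% follow an unexpectedly rapid progressive course.
principal_goal: >
  Identify, among patients newly diagnosed with early-stage CTCL, those who
  should receive aggressive therapy immediately.
clinical_benefit: >
  A progression-risk classifier separating high- and low-risk patients
  would let aggressive up-front therapy be directed to the patients at
  highest risk of rapid progression.
discomfort_range:
  nnt_lower: 2
  nnt_upper: 30
prospective:
  n_total: 40
  positive_fraction: 0.25
  target_nnt_pos: 2
  target_nnt_neg: 30
  followup_note: accrual over 3 years with a minimum of 2 years follow-up
retrospective:
  prevalence: 0.15
  n_cases: 22
  n_controls: 40
  anticipated_sn:
    successes: 18
    trials: 22
  anticipated_sp:
    successes: 34
    trials: 40
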