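[
  {"parameter": "pretest_prob", "level": "low", "overrides": {"pretest_prob": 0.79}},
  {"parameter": "pretest_prob", "level": "high", "overrides": {"pretest_prob": 0.85}},
  {"parameter": "psg_specificity", "level": "low", "overrides": {"psg_specificity": 0.90}},
  {"parameter": "psg_sensitivity", "level": "low", "overrides": {"psg_sensitivity": 0.90}},
  {"parameter": "psg_sensitivity", "level": "high", "overrides": {"psg_sensitivity": 1.00}},
  {"parameter": "compliance", "level": "low", "overrides": {"cpap_initial_refusal": 0.204, "cpap_cessation_year1": 0.20, "cpap_cessation_later": 0.12}},
  {"parameter": "compliance", "level": "high", "overrides": {"cpap_initial_refusal": 0.0, "cpap_cessation_year1": 0.0, "cpap_cessation_later": 0.0}},
  {"parameter": "discount_rate", "level": "low", "overrides": {"discount_rate": 0.0}},
  {"parameter": "discount_rate", "level": "high", "overrides": {"discount_rate": 0.05}},
  {"parameter": "cost_psg", "level": "low", "overrides": {"cost_psg": 669.6}},
  {"parameter": "cost_psg", "level": "high", "overrides": {"cost_psg": 1004.4}},
  {"parameter": "cost_cpap_annual", "level": "low", "overrides": {"cost_cpap_annual": 420}},
  {"parameter": "cost_cpap_annual", "level": "high", "overrides": {"cost_cpap_annual": 1400}},
  {"parameter": "cost_cp_program", "level": "low", "overrides": {"cost_cp_program": 25}},
  {"parameter": "cost_cp_program", "level": "high", "overrides": {"cost_cp_program": 125}},
  {"parameter": "cost_untreated_annual", "level": "low", "overrides": {"cost_untreated_annual": 441}},
  {"parameter": "cost_untreated_annual", "level": "high", "overrides": {"cost_untreated_annual": 2714}}
]
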