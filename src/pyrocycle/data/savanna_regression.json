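{
  "annual_gpp": 759.2252171636135,
  "annual_fire": 82.46647703659691,
  "mean_som": 6816.750856109922,
  "window_dfire": -11.660910307955252,
  "window_dnee": -27.51672999273654,
  "legacy_dnee_1_5": -6.952904403474202,
  "legacy_dnee_6_10": 3.863002378223915,
  "legacy_dnee_11_20": 3.361929171948565,
  "legacy_ratio_6_10": 0.5555954970837316,
  "legacy_ratio_11_20": 0.4835287495494241,
  "nbe_neutrality_years": 11
}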