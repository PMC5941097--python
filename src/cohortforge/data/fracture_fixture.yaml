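# Deterministic fixture reproducing the worked example's cohort flow:
# 4698 indexed; 557 / 1769 / 179 excluded for prior malignancy / fracture /
# AOM; 2193 incident; 1808 with follow-up; 464 treated.
counts:
  eligible_untreated: 1344
  eligible_treated: 464
  no_followup: 385
  prior_malignancy: 557
  prior_fracture: 1769
  prior_aom: 179
seed: 0
observation: {start: 2010-01-01, end: 2014-12-31}
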