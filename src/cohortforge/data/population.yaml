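# Stochastic population emulating the worked example's regime.
n_patients: 5000
yearly_incidence: 0.06
p_treat: 0.21
p_fu: 0.82
age_mean: 76.47
age_sd: 10.10
female_fraction: 0.828
bmi_mean: 22.95
bmi_sd: 3.86
prior_malignancy_rate: 0.08
prior_aom_rate: 0.04
prior_fracture_rate: 0.05
paget_rate: 0.005
observation: {start: 2010-01-01, end: 2014-12-31}
seed: 0
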