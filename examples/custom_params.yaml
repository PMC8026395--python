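# Example SimulationParams file for `lynchrrs simulate --gene MLH1 --params ...`
# Flat 1%/year endometrial hazard from 40, no ovarian risk, no surgery uptake.
gene: MLH1
n: 10000
seed: 0
ec_hazard: {25: 0.0, 30: 0.0, 35: 0.0, 40: 0.01, 45: 0.01, 50: 0.01, 55: 0.01, 60: 0.01, 65: 0.01, 70: 0.01}
oc_hazard: {25: 0.0, 30: 0.0, 35: 0.0, 40: 0.0, 45: 0.0, 50: 0.0, 55: 0.0, 60: 0.0, 65: 0.0, 70: 0.0}
surgery_uptake: {25: 0.0, 30: 0.0, 35: 0.0, 40: 0.0, 45: 0.0, 50: 0.0, 55: 0.0, 60: 0.0, 65: 0.0, 70: 0.0}
inclusion_age_dist: {25: 0.14, 30: 0.14, 35: 0.13, 40: 0.12, 45: 0.11, 50: 0.10, 55: 0.08, 60: 0.07, 65: 0.06, 70: 0.05}
followup_mean: 7.0
followup_max: 25.0
# endpoint -> [cure_fraction, event_time_scale_years]
survival_model:
  EC: [0.8859, 3.0]
  OC: [0.8341, 3.0]
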