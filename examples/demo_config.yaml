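# Demo pipeline: simulated MLH1 + MSH2 cohorts of 50,000 women each,
# default calibrated hazards, fixed seed.
genes: [MLH1, MSH2]
endpoints: [EC, OC]
n: 50000
seed: 1
output_dir: lynchrrs_demo_out
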