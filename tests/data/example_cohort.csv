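id,gene,age_inclusion,age_last_obs,age_hysterectomy,age_bso,age_ec_dx,age_oc_dx,age_death,died_of_followup_cancer
W001,MLH1,32.00,45.50,,,,,,false
W002,MLH1,40.25,52.00,,,43.50,,,false
W003,MLH1,38.00,50.00,44.00,44.00,,,,false
W004,MLH1,55.00,68.00,,,60.00,,63.50,true
W005,MLH1,29.50,31.00,,,,,,false
W006,MSH2,27.00,41.00,,,,,,false
W007,MSH2,45.00,59.75,,,,52.25,,false
W008,MSH2,36.50,55.00,40.00,40.00,40.00,,,false
W009,MSH2,50.00,70.00,,,,,68.00,false
W010,MSH2,62.00,74.00,,,66.00,,,false
W011,MSH6,33.00,47.00,,,,,,false
W012,MSH6,41.00,56.00,46.00,46.00,,,,false
W013,MSH6,52.00,66.50,,,61.25,,,false
W014,MSH6,28.00,39.00,,,28.00,,,false
W015,MSH6,47.50,62.00,,,,,,false
W016,PMS2,30.00,44.00,,,,,,false
W017,PMS2,42.00,58.00,,,,,,false
W018,PMS2,51.00,67.00,55.00,55.00,,,,false
W019,PMS2,64.00,74.90,,,,,,false
W020,MLH1,26.00,74.00,,,,70.50,72.00,true
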