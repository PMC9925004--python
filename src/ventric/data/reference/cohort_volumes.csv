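heart,sex,geometry,myocardial_volume_cm3,n_long_ft,avg_lv_thickness_cm
A,male,detailed,394.2,3,0.85
A,male,smoothed,329.8,3,0.85
B,male,detailed,199.6,0,0.83
B,male,smoothed,180.5,0,0.83
C,female,detailed,170.6,4,0.58
C,female,smoothed,155.8,4,0.58
D,female,detailed,299.2,3,0.76
D,female,smoothed,268,3,0.76
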