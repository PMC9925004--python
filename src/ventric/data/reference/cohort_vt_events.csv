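geometry,sex,site,events,simulations
detailed,female,RV_apex,2,13
detailed,female,RVOT,0,12
detailed,female,LV_apex,0,8
smoothed,female,RV_apex,1,11
smoothed,female,RVOT,2,10
smoothed,female,LV_apex,0,8
detailed,male,RV_apex,4,10
detailed,male,RVOT,7,15
detailed,male,LV_apex,6,10
smoothed,male,RV_apex,2,10
smoothed,male,RVOT,1,9
smoothed,male,LV_apex,1,10
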