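heart,sex,lead_i_mv,lead_ii_mv,lead_iii_mv
A,female,2.3,6.6,7.2
B,female,2.6,4.0,2.5
C,female,1.1,3.3,2.7
D,female,1.5,5.2,4.9
A,male,2.6,7.1,6.9
B,male,2.7,4.0,2.3
C,male,1.2,3.1,2.4
D,male,1.9,5.9,5.2
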