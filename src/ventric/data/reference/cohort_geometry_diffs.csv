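heart,sex,qrs_gdiff_ms,cv_gdiff_cm_s,qt_gdiff_ms,tat_gdiff_ms,tat10_gdiff_ms,tat90_gdiff_ms,edi_gdiff_ms
A,male,-2,10,10,4.5,-1.5,-4.5,-1.2
A,female,-5,10,24,4.3,-1.5,-4,-1.2
B,male,12,-7,4,12.2,-1.5,5,2.1
B,female,11,0,9,12.1,-1.5,5,2.1
C,male,-3,-2,8,-1.9,-2.5,-2,-0.2
C,female,-1,-2,5,-1.9,-2.5,-2,-0.2
D,male,5,-1,-2,-1.4,0.5,-3.5,-1.3
D,female,4,-3,-8,-1.2,0.5,-4,-1.2
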