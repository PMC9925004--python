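heart,geometry,sex,qrs_ms,qrs_diff_printed_ms,cv_cm_s,qt_ms,qt_diff_printed_ms,tat_ms,tat10_ms,tat90_ms,edi_ms
A,detailed,male,97,-1,90,349,42,104.3,12.3,66.8,20.1
A,detailed,female,96,-1,90,391,42,104.3,12.3,66.8,20.1
A,smoothed,male,99,2,80,339,28,99.8,13.8,71.3,21.3
A,smoothed,female,101,2,80,367,28,100.0,13.8,70.8,21.3
B,detailed,male,95,0,81,339,37,96.6,9.3,64.8,20.2
B,detailed,female,95,0,86,376,37,96.5,9.3,64.8,20.2
B,smoothed,male,83,1,88,335,63,84.4,10.8,59.8,18.1
B,smoothed,female,84,1,86,367,63,84.4,10.8,59.8,18.1
C,detailed,male,90,3,83,337,27,92.5,7.3,58.3,18.8
C,detailed,female,93,3,84,364,27,92.6,7.3,58.3,18.8
C,smoothed,male,93,1,85,329,30,94.4,9.8,60.3,19
C,smoothed,female,94,1,86,359,30,94.5,9.8,60.3,19
D,detailed,male,104,4,85,357,34,119.2,11.3,67.8,21.3
D,detailed,female,108,4,83,391,34,119.3,11.3,67.8,21.4
D,smoothed,male,99,5,86,359,40,120.6,11.8,71.3,22.6
D,smoothed,female,104,5,86,399,40,120.5,11.8,71.8,22.6
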