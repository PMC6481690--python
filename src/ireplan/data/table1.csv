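patient_id,psa_pre,max_voltage,max_spacing,delta_current,threshold_dynamic,ablation_volume
P1,10.03,3000,2.2,11,412,21.08
P2,9.1,3000,2.0,19,436,16.73
P3,8.7,3000,2.1,12,521,11.10
P4,7.8,2850,1.9,11,499,15.82
P5,7.1,2850,1.9,11,512,10.34
P6,6.7,3000,2.0,10,472,19.07
P7,6.5,2700,1.8,10,525,10.05
P8,5.5,2250,1.5,10,614,4.09
P9,3.9,2400,1.6,9,467,10.21
P10,3.8,2100,1.4,6,606,4.63
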